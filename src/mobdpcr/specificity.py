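"""In-silico PCR and probe-mismatch screening of pmoA sequence panels.

Given a panel of pmoA / pmoA2 / pxmA / amoA sequences with group labels,
this module extracts the amplicon delimited by a universal primer pair
(best ungapped placements, IUPAC-aware) and slides each hydrolysis probe
along the amplicon to find its minimum mismatch count. A base pair
"matches" iff the IUPAC sets of the two symbols intersect, so an N on
either side never counts as a mismatch and degenerate probe positions
match any base in their set. Detection calls follow the hydrolysis-probe
sensitivity pattern observed empirically: 0-1 mismatches detect, 3 or
more do not, exactly 2 is uncertain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .assay import (
    IUPAC_SETS,
    Assay,
    Oligo,
    OligoError,
    _validate_iupac,
    revcomp_iupac,
)

__all__ = [
    "PanelRecord",
    "Amplicon",
    "SpecificityResult",
    "NoAmpliconError",
    "iupac_match",
    "mismatch_count",
    "extract_amplicon",
    "probe_mismatch",
    "classify_sensitivity",
    "aggregate_detection",
    "coverage_table",
    "read_panel",
    "MISMATCH_BINS",
]

logger = logging.getLogger(__name__)

GROUPS = ("Ia", "Ib", "Ic", "IIa", "IIa_pmoA2", "IIb", "RPC1", "pxmA", "amoA", "other")
MISMATCH_BINS = ("0", "1", "2", "3plus")

DETECT_POSITIVE = "+"
DETECT_NEGATIVE = "-"
DETECT_UNCERTAIN = "uncertain"
NO_AMPLICON = "no_amplicon"


class NoAmpliconError(ValueError):
    """No primer-site pair within the allowed mismatch budget."""


@dataclass(frozen=True)
class PanelRecord:
    """One panel sequence with its taxonomic group label.

    ``gene_copies`` is the number of target-gene copies this record
    represents in its source genome (multi-copy genomes are screened
    per copy and detection is aggregated with a logical OR).
    ``antisense=True`` flags records stored as the reverse complement
    of the sense strand; they are flipped on use.
    """

    id: str
    group: str
    sequence: str
    gene_copies: int = 1
    accession: str | None = None
    antisense: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_iupac(self.sequence))
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.gene_copies < 1:
            raise ValueError("gene_copies must be >= 1")

    @property
    def sense_sequence(self) -> str:
        return revcomp_iupac(self.sequence) if self.antisense else self.sequence


@dataclass(frozen=True)
class Amplicon:
    """Primer-to-primer region on the sense strand, primers included."""

    sequence: str
    start: int  # 0-based, half-open on the template sense strand
    end: int
    fwd_mismatches: int
    rev_mismatches: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpecificityResult:
    record_id: str
    probe: str
    mismatches: int | None
    match_start: int | None  # 0-based half-open window on the amplicon
    primer_mismatches_fwd: int | None
    primer_mismatches_rev: int | None
    predicted_detection: str
    group: str = "other"
    gene_copy: int = 1


def iupac_match(a: str, b: str) -> bool:
    """True iff the IUPAC base sets of ``a`` and ``b`` intersect."""
    try:
        return bool(IUPAC_SETS[a] & IUPAC_SETS[b])
    except KeyError as exc:
        raise OligoError(f"invalid IUPAC symbol {exc.args[0]!r}") from exc


def mismatch_count(query: str, window: str) -> int:
    """Positional mismatches between two equal-length IUPAC strings."""
    if len(query) != len(window):
        raise ValueError("sequences must have equal length")
    return sum(1 for a, b in zip(query, window) if not (IUPAC_SETS[a] & IUPAC_SETS[b]))


def _site_mismatches(template: str, site: str) -> list[int]:
    """Mismatch count of ``site`` at every start position on ``template``."""
    n, m = len(template), len(site)
    return [mismatch_count(site, template[i : i + m]) for i in range(n - m + 1)]


def extract_amplicon(
    template: PanelRecord | str,
    forward: Oligo,
    reverse: Oligo,
    max_primer_mismatch: int = 3,
) -> Amplicon:
    """Locate the best primer pair on the sense strand and cut the amplicon.

    The forward primer is matched as written; the reverse primer binds the
    antisense strand, so its sense-strand image (reverse complement) is
    matched downstream of the forward site. The placement minimizing total
    primer mismatches wins; ties break to the 5'-most pair (with a warning).
    Raises :class:`NoAmpliconError` when no placement keeps both primers
    within ``max_primer_mismatch`` mismatches.
    """
    seq = template.sense_sequence if isinstance(template, PanelRecord) else _validate_iupac(template)
    fwd = forward.sequence if forward.orientation == "sense" else revcomp_iupac(forward.sequence)
    rev = revcomp_iupac(reverse.sequence) if reverse.orientation == "antisense" else reverse.sequence
    if len(seq) < len(fwd) + len(rev):
        raise NoAmpliconError("template shorter than combined primer lengths")

    fwd_mm = _site_mismatches(seq, fwd)
    rev_mm = _site_mismatches(seq, rev)

    best: tuple[int, int, int] | None = None  # (total, fwd_start, rev_start)
    tie = False
    for i, mf in enumerate(fwd_mm):
        if mf > max_primer_mismatch:
            continue
        for j in range(i + len(fwd), len(rev_mm)):
            mr = rev_mm[j]
            if mr > max_primer_mismatch:
                continue
            total = mf + mr
            if best is None or total < best[0]:
                best = (total, i, j)
                tie = False
            elif total == best[0] and (i, j) != (best[1], best[2]):
                tie = True
    if best is None:
        raise NoAmpliconError(
            f"no primer-site pair with <= {max_primer_mismatch} mismatches per primer"
        )
    if tie:
        logger.warning("multiple equally good primer placements; using the 5'-most pair")
    _, i, j = best
    end = j + len(rev)
    return Amplicon(
        sequence=seq[i:end],
        start=i,
        end=end,
        fwd_mismatches=fwd_mm[i],
        rev_mismatches=rev_mm[j],
    )


def probe_mismatch(amplicon: Amplicon | str, probe: Oligo) -> tuple[int, int]:
    """Minimum probe mismatches over all ungapped windows of the amplicon.

    The probe's sense-strand image slides along the amplicon; per-position
    match is IUPAC set intersection. Returns ``(min_mismatches, start)``
    with the 5'-most window among ties (0-based half-open start).
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else _validate_iupac(amplicon)
    image = probe.sense_image
    if len(seq) < len(image):
        raise ValueError("amplicon shorter than probe")
    mm = _site_mismatches(seq, image)
    best = min(mm)
    return best, mm.index(best)


def classify_sensitivity(
    mismatches: int,
    *,
    positive_max: int = 1,
    negative_min: int = 3,
) -> str:
    """Detection call from a mismatch count: <=1 '+', >=3 '-', else uncertain."""
    if mismatches < 0:
        raise ValueError("mismatch count must be >= 0")
    if mismatches <= positive_max:
        return DETECT_POSITIVE
    if mismatches >= negative_min:
        return DETECT_NEGATIVE
    return DETECT_UNCERTAIN


def aggregate_detection(calls: list[str]) -> str:
    """Genome-level call over gene copies: '+' if ANY copy is '+'.

    A genome with several gene copies lights a well as soon as one copy
    amplifies and hybridizes, so detection is a logical OR on '+'.
    """
    if not calls:
        raise ValueError("no calls to aggregate")
    if DETECT_POSITIVE in calls:
        return DETECT_POSITIVE
    if DETECT_UNCERTAIN in calls:
        return DETECT_UNCERTAIN
    return DETECT_NEGATIVE


def screen_record(
    record: PanelRecord,
    assay: Assay,
    max_primer_mismatch: int = 3,
) -> list[SpecificityResult]:
    """Screen one panel record against every probe of the assay."""
    results = []
    try:
        amp = extract_amplicon(record, assay.forward, assay.reverse, max_primer_mismatch)
    except NoAmpliconError:
        for probe in assay.probes:
            results.append(
                SpecificityResult(
                    record_id=record.id, probe=probe.name, mismatches=None,
                    match_start=None, primer_mismatches_fwd=None,
                    primer_mismatches_rev=None, predicted_detection=NO_AMPLICON,
                    group=record.group,
                )
            )
        return results
    for probe in assay.probes:
        mm, start = probe_mismatch(amp, probe)
        results.append(
            SpecificityResult(
                record_id=record.id, probe=probe.name, mismatches=mm,
                match_start=start, primer_mismatches_fwd=amp.fwd_mismatches,
                primer_mismatches_rev=amp.rev_mismatches,
                predicted_detection=classify_sensitivity(mm),
                group=record.group,
            )
        )
    return results


def _bin_label(mm: int) -> str:
    return str(mm) if mm < 3 else "3plus"


def coverage_table(
    panel: list[PanelRecord],
    assay: Assay,
    max_primer_mismatch: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe mismatch-bin counts on target groups + full per-record report.

    Returns ``(bins, report)``:

    * ``bins`` — one row per probe with counts of target-group records in
      mismatch bins {0, 1, 2, >=3} and their total. Records whose amplicon
      extraction fails are logged and excluded from the bins.
    * ``report`` — one row per (record, probe) over the whole panel with
      mismatches, primer mismatches and the predicted detection call.
    """
    if not panel:
        raise ValueError("empty panel")
    rows = []
    for record in panel:
        for res in screen_record(record, assay, max_primer_mismatch):
            rows.append(res)
            if res.predicted_detection == NO_AMPLICON:
                logger.info("record %s: no amplicon; excluded from bins", record.id)
    report = pd.DataFrame(
        {
            "record_id": [r.record_id for r in rows],
            "group": [r.group for r in rows],
            "probe": [r.probe for r in rows],
            "mismatches": [r.mismatches for r in rows],
            "primer_mm_fwd": [r.primer_mismatches_fwd for r in rows],
            "primer_mm_rev": [r.primer_mismatches_rev for r in rows],
            "predicted_detection": [r.predicted_detection for r in rows],
        }
    )
    bin_rows = []
    for probe in assay.probes:
        targets = set(assay.probe_targets.get(probe.name, ()))
        sub = report[
            (report["probe"] == probe.name)
            & report["group"].isin(targets)
            & report["mismatches"].notna()
        ]
        counts = dict.fromkeys(MISMATCH_BINS, 0)
        for mm in sub["mismatches"]:
            counts[_bin_label(int(mm))] += 1
        bin_rows.append(
            {
                "probe": probe.name,
                "target_groups": ",".join(sorted(targets)),
                "bin0": counts["0"],
                "bin1": counts["1"],
                "bin2": counts["2"],
                "bin3plus": counts["3plus"],
                "total": int(sub.shape[0]),
            }
        )
    return pd.DataFrame(bin_rows), report


def read_panel(fasta_path, meta_path) -> list[PanelRecord]:
    """Read a FASTA panel plus a sidecar TSV (id, group, gene_copies[, accession])."""
    meta = pd.read_csv(meta_path, sep="\t", dtype={"id": str})
    meta = meta.set_index("id")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta.index:
            raise KeyError(f"FASTA record {rec.id!r} missing from sidecar table")
        row = meta.loc[rec.id]
        records.append(
            PanelRecord(
                id=rec.id,
                group=str(row["group"]),
                sequence=str(rec.seq),
                gene_copies=int(row.get("gene_copies", 1)),
                accession=(str(row["accession"]) if "accession" in row and pd.notna(row["accession"]) else None),
                antisense=bool(row.get("antisense", False)),
            )
        )
    return records
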