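"""Oligonucleotide and assay model for hydrolysis-probe digital PCR.

Probes and primers for pmoA typing are written with IUPAC degenerate
codes (W, Y, R, S, M, ...), each standing for a set of concrete bases.
This module validates such oligos, computes their degeneracy (number of
concrete expansions), reverse-complements them under the IUPAC
complement map, and estimates nearest-neighbour melting temperatures.

Probes are stored 5'->3' as synthesized. The shipped pmoA probes
hybridize to the sense strand of the target, i.e. the synthesized
sequence is the reverse complement of the sense-strand image; matching
against sense-strand templates therefore goes through
:func:`revcomp_iupac` (handled in :mod:`mobdpcr.specificity`).
"""

from __future__ import annotations

import itertools
import tomllib
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterator, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "Oligo",
    "Assay",
    "parse_oligo",
    "revcomp_iupac",
    "degeneracy",
    "expand_iupac",
    "iter_expansions",
    "melting_temperature",
    "load_assay",
    "default_assay",
    "OligoError",
]

# Map each IUPAC code to its frozenset of concrete bases (A/C/G/T).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

ROLES = ("probe", "primer_fwd", "primer_rev")
ORIENTATIONS = ("sense", "antisense")


class OligoError(ValueError):
    """Invalid oligonucleotide definition."""


def _normalize(sequence: str) -> str:
    """Upper-case and map RNA U to T; no other rewriting."""
    return sequence.upper().replace("U", "T")


def _validate_iupac(sequence: str) -> str:
    seq = _normalize(sequence)
    if not seq:
        raise OligoError("empty sequence")
    for i, base in enumerate(seq):
        if base not in IUPAC_CODES:
            raise OligoError(
                f"invalid IUPAC symbol {base!r} at position {i + 1}"
            )
    return seq


@dataclass(frozen=True)
class Oligo:
    """A named IUPAC oligo with its role in the assay.

    ``orientation`` records which strand the synthesized sequence
    corresponds to relative to the target region: ``antisense`` probes
    hybridize to the sense strand (their sense-strand image is the
    reverse complement of ``sequence``).
    """

    name: str
    sequence: str
    role: str
    fluorophore: str | None = None
    quenchers: tuple[str, ...] = ()
    orientation: str = "antisense"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_iupac(self.sequence))
        if self.role not in ROLES:
            raise OligoError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.orientation not in ORIENTATIONS:
            raise OligoError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        object.__setattr__(self, "quenchers", tuple(self.quenchers))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence)

    @property
    def sense_image(self) -> str:
        """The 5'->3' sequence as it appears on the sense strand."""
        if self.orientation == "antisense":
            return revcomp_iupac(self.sequence)
        return self.sequence

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Oligo":
        d = dict(d)
        d["quenchers"] = tuple(d.get("quenchers") or ())
        return cls(**d)


def parse_oligo(
    name: str,
    sequence: str,
    role: str,
    *,
    fluorophore: str | None = None,
    quenchers: Sequence[str] = (),
    orientation: str = "antisense",
) -> Oligo:
    """Validate and build an :class:`Oligo`.

    Raises :class:`OligoError` naming the 1-based offending position for
    any character outside the 15 IUPAC nucleotide codes.
    """
    return Oligo(
        name=name,
        sequence=sequence,
        role=role,
        fluorophore=fluorophore,
        quenchers=tuple(quenchers),
        orientation=orientation,
    )


def degeneracy(sequence: str) -> int:
    """Product of per-position IUPAC set sizes (# concrete expansions)."""
    seq = _validate_iupac(sequence)
    n = 1
    for base in seq:
        n *= len(IUPAC_SETS[base])
    return n


def iter_expansions(sequence: str) -> Iterator[str]:
    """Yield every concrete (ACGT-only) expansion of an IUPAC sequence."""
    seq = _validate_iupac(sequence)
    for combo in itertools.product(*(sorted(IUPAC_SETS[b]) for b in seq)):
        yield "".join(combo)


def expand_iupac(sequence: str, limit: int | None = None) -> list[str]:
    """All concrete expansions; raises if degeneracy exceeds ``limit``."""
    if limit is not None and degeneracy(sequence) > limit:
        raise OligoError(
            f"degeneracy {degeneracy(sequence)} exceeds limit {limit}"
        )
    return list(iter_expansions(sequence))


def revcomp_iupac(sequence: str) -> str:
    """Reverse complement under the full IUPAC complement map.

    R<->Y, K<->M, B<->V, D<->H; S, W and N are self-complementary.
    """
    seq = _validate_iupac(sequence)
    return str(Seq(seq).reverse_complement())


def melting_temperature(
    oligo: Oligo | str,
    *,
    na_mm: float = 50.0,
    oligo_nm: float = 250.0,
    max_expansions: int = 256,
    seed: int = 0,
) -> float:
    """Nearest-neighbour melting temperature in deg C.

    For degenerate oligos the Tm is the arithmetic mean over all concrete
    expansions when the degeneracy is at most ``max_expansions``;
    otherwise over a seeded uniform sample of ``max_expansions``
    expansions (each position drawn independently from its IUPAC set).

    Uses the unified nearest-neighbour parameter set at ``na_mm`` mM
    monovalent salt and ``oligo_nm`` nM oligo (probe in excess, no
    complement correction). The vendor software used for the published
    probe Tm values is proprietary, so only ordering and approximate
    agreement are meaningful.
    """
    seq = oligo.sequence if isinstance(oligo, Oligo) else _validate_iupac(oligo)
    deg = degeneracy(seq)
    if deg <= max_expansions:
        seqs = list(iter_expansions(seq))
    else:
        rng = np.random.default_rng(seed)
        sets = [sorted(IUPAC_SETS[b]) for b in seq]
        seqs = [
            "".join(s[rng.integers(len(s))] for s in sets)
            for _ in range(max_expansions)
        ]
    tms = [
        _mt.Tm_NN(s, Na=na_mm, dnac1=oligo_nm, dnac2=0) for s in seqs
    ]
    return float(np.mean(tms))


@dataclass(frozen=True)
class Assay:
    """One digital-PCR assay: primer pair, probe set and chip geometry."""

    forward: Oligo
    reverse: Oligo
    probes: tuple[Oligo, ...]
    annealing_c: dict = field(default_factory=dict)  # probe name -> deg C
    probe_targets: dict = field(default_factory=dict)  # probe name -> groups
    chip_wells: int = 20_000
    loaded_volume_ul: float = 14.5
    reaction_volume_ul: float = 15.0
    template_volume_ul: float = 1.5

    def __post_init__(self) -> None:
        if self.chip_wells <= 0:
            raise ValueError("chip_wells must be positive")
        if not 0 < self.loaded_volume_ul <= self.reaction_volume_ul:
            raise ValueError("need 0 < loaded_volume_ul <= reaction_volume_ul")
        if not 0 < self.template_volume_ul < self.reaction_volume_ul:
            raise ValueError("need 0 < template_volume_ul < reaction_volume_ul")
        object.__setattr__(self, "probes", tuple(self.probes))

    def probe(self, name: str) -> Oligo:
        for p in self.probes:
            if p.name == name:
                return p
        raise KeyError(name)


def load_assay(path) -> Assay:
    """Read an assay definition from a TOML file."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return _assay_from_doc(doc)


def _assay_from_doc(doc: dict) -> Assay:
    a = doc.get("assay", {})
    fwd = doc["primers"]["forward"]
    rev = doc["primers"]["reverse"]
    forward = parse_oligo(fwd["name"], fwd["sequence"], "primer_fwd",
                          orientation="sense")
    reverse = parse_oligo(rev["name"], rev["sequence"], "primer_rev",
                          orientation="antisense")
    probes, annealing, targets = [], {}, {}
    for p in doc.get("probes", []):
        oligo = parse_oligo(
            p["name"], p["sequence"], "probe",
            fluorophore=p.get("fluorophore"),
            quenchers=tuple(p.get("quenchers", ())),
            orientation=p.get("orientation", "antisense"),
        )
        probes.append(oligo)
        if "annealing_c" in p:
            annealing[p["name"]] = float(p["annealing_c"])
        if "target_groups" in p:
            targets[p["name"]] = tuple(p["target_groups"])
    return Assay(
        forward=forward,
        reverse=reverse,
        probes=tuple(probes),
        annealing_c=annealing,
        probe_targets=targets,
        chip_wells=int(a.get("chip_wells", 20_000)),
        loaded_volume_ul=float(a.get("loaded_volume_ul", 14.5)),
        reaction_volume_ul=float(a.get("reaction_volume_ul", 15.0)),
        template_volume_ul=float(a.get("template_volume_ul", 1.5)),
    )


def default_assay() -> Assay:
    """The shipped pmoA typing assay (A189f/A682r + three type probes)."""
    ref = resources.files("mobdpcr.data").joinpath("assay.toml")
    with ref.open("rb") as fh:
        return _assay_from_doc(tomllib.load(fh))
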