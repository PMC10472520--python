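"""In-silico PCR amplicon extraction and probe mismatch screening."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobdpcr import (
    NoAmpliconError,
    PanelRecord,
    classify_sensitivity,
    coverage_table,
    extract_amplicon,
    iupac_match,
    mismatch_count,
    probe_mismatch,
    read_panel,
    revcomp_iupac,
)
from mobdpcr.assay import IUPAC_SETS, expand_iupac, parse_oligo
from mobdpcr.specificity import aggregate_detection

IUPAC = "ACGTRYSWKMBDHVN"


def make_template(fwd, rev, insert, flank5="", flank3=""):
    """Sense-strand template: 5'flank + fwd site + insert + rev site + 3'flank."""
    return flank5 + fwd.sequence + insert + revcomp_iupac(rev.sequence) + flank3


@pytest.fixture()
def primers(assay):
    return assay.forward, assay.reverse


def test_extract_amplicon_by_construction(assay, primers, rng):
    fwd, rev = primers
    insert = "".join(rng.choice(list("ACGT"), size=100))
    template = make_template(fwd, rev, insert, flank5="TT" * 10, flank3="AA" * 7)
    amp = extract_amplicon(template, fwd, rev, max_primer_mismatch=0)
    assert len(amp) == len(fwd) + 100 + len(rev)
    assert (amp.fwd_mismatches, amp.rev_mismatches) == (0, 0)
    assert amp.start == 20 and amp.end == 20 + len(amp)


def test_extract_amplicon_anchors_on_amplicon_length_fragment(assay, primers, rng):
    fwd, rev = primers
    insert = "".join(rng.choice(list("ACGT"), size=60))
    template = make_template(fwd, rev, insert)
    amp = extract_amplicon(template, fwd, rev)
    assert (amp.start, amp.end) == (0, len(template))


def test_extract_amplicon_missing_reverse_site(assay, primers, rng):
    fwd, rev = primers
    template = fwd.sequence + "".join(rng.choice(list("ACGT"), size=100))
    with pytest.raises(NoAmpliconError):
        extract_amplicon(template, fwd, rev, max_primer_mismatch=0)
    with pytest.raises(NoAmpliconError):
        extract_amplicon("ACGTACGT", fwd, rev)  # too short


def test_extract_amplicon_counts_primer_mismatches(assay, primers, rng):
    fwd, rev = primers
    insert = "".join(rng.choice(list("ACGT"), size=50))
    rev_site = list(revcomp_iupac(rev.sequence))
    # force two concrete mismatches in the reverse site
    rev_site[3] = "A" if rev_site[3] in "GC" else "G"
    rev_site[7] = "A" if rev_site[7] in "GC" else "G"
    template = fwd.sequence + insert + "".join(rev_site)
    amp = extract_amplicon(template, fwd, rev, max_primer_mismatch=3)
    assert amp.fwd_mismatches == 0
    assert amp.rev_mismatches == 2


def test_probe_mismatch_finds_exact_sense_image(assay, rng):
    for probe in assay.probes:
        flank = "".join(rng.choice(list("ACGT"), size=40))
        amp = flank + probe.sense_image + flank
        mm, start = probe_mismatch(amp, probe)
        assert mm == 0
        assert start == 40


def test_probe_against_parent_primer_sequence(assay):
    """II646_mod equals the first 20 nt of primer II646R under IUPAC matching.

    Both oligos are written in the same (antisense) orientation, so they
    compare directly: S vs G and Y vs Y intersect, hence 0 mismatches.
    """
    probe = assay.probe("II646_mod")
    primer_ii646r = "CGTGCCGCGCTCGACCATGYG"
    assert mismatch_count(probe.sequence, primer_ii646r[:20]) == 0
    # same comparison routed through the sense-strand machinery
    mm, _ = probe_mismatch(revcomp_iupac(primer_ii646r), probe)
    assert mm == 0


def test_probe_mismatch_invariant_to_flanking_context(assay, rng):
    # a 2-mismatch image of the probe is the best window under any flank
    probe = assay.probe("mb661_Ia")
    core = list(probe.sense_image)
    for pos in (5, 15):
        core[pos] = next(b for b in "ACGT" if b not in IUPAC_SETS[core[pos]])
    core = "".join(core)
    results = []
    for n in (10, 25, 60):
        flank = "".join(rng.choice(list("ACGT"), size=n))
        results.append(probe_mismatch(flank + core + flank, probe)[0])
    assert results == [2, 2, 2]


def test_probe_shorter_amplicon_error(assay):
    with pytest.raises(ValueError):
        probe_mismatch("ACGT", assay.probe("mb661_Ia"))


@given(st.sampled_from(IUPAC), st.sampled_from(IUPAC))
def test_iupac_match_symmetric_and_n_matches_all(a, b):
    assert iupac_match(a, b) == iupac_match(b, a)
    assert iupac_match("N", a)


@given(
    st.text(alphabet="ACGT", min_size=30, max_size=80),
    st.text(alphabet=IUPAC, min_size=5, max_size=12),
)
@settings(max_examples=30, deadline=None)
def test_set_intersection_agrees_with_expansion_brute_force(amplicon, probe_seq):
    """Min mismatches over windows equals brute force over probe expansions."""
    from mobdpcr.assay import degeneracy

    if degeneracy(probe_seq) > 64:
        return
    probe = parse_oligo("p", probe_seq, "probe", orientation="sense")
    fast, _ = probe_mismatch(amplicon, probe)
    m = len(probe_seq)
    brute = min(
        sum(ch not in IUPAC_SETS[amplicon[i + j]] for j, ch in enumerate(exp))
        for exp in expand_iupac(probe_seq)
        for i in range(len(amplicon) - m + 1)
    )
    assert fast == brute


@pytest.mark.parametrize(
    "mm, call", [(0, "+"), (1, "+"), (2, "uncertain"), (3, "-"), (7, "-")]
)
def test_classify_sensitivity_default_policy(mm, call):
    assert classify_sensitivity(mm) == call


def test_classify_sensitivity_rejects_negative():
    with pytest.raises(ValueError):
        classify_sensitivity(-1)


def test_multicopy_genome_detection_is_logical_or():
    # pmoA '+' dominates a mismatched pmoA2 copy
    assert aggregate_detection(["+", "-"]) == "+"
    assert aggregate_detection(["-", "uncertain"]) == "uncertain"
    assert aggregate_detection(["-", "-"]) == "-"
    with pytest.raises(ValueError):
        aggregate_detection([])


def _embed(assay, sense_image, rng, n_mismatch=0):
    """Amplicon-like record: primer sites around a (mutated) probe image."""
    image = list(sense_image)
    alphabet = "ACGT"
    positions = rng.choice(len(image), size=n_mismatch, replace=False)
    for pos in positions:
        banned = IUPAC_SETS[image[pos]]
        image[pos] = next(b for b in alphabet if b not in banned)
    insert = (
        "".join(rng.choice(list(alphabet), size=20))
        + "".join(image)
        + "".join(rng.choice(list(alphabet), size=20))
    )
    return assay.forward.sequence + insert + revcomp_iupac(assay.reverse.sequence)


def test_coverage_table_diagonal_on_own_probe_images(assay, rng):
    panel = [
        PanelRecord(id=f"rec_{p.name}", group=assay.probe_targets[p.name][0],
                    sequence=_embed(assay, p.sense_image, rng))
        for p in assay.probes
    ]
    bins, report = coverage_table(panel, assay)
    for p in assay.probes:
        row = bins.set_index("probe").loc[p.name]
        assert row["bin0"] == 1 and row["total"] == 1
        own = report[(report["probe"] == p.name) & (report["record_id"] == f"rec_{p.name}")]
        assert own["predicted_detection"].item() == "+"


def test_coverage_table_engineered_bins(assay, rng):
    """Records engineered at 0, 1 and 4 probe mismatches bin as {1,1,0,1}."""
    probe = assay.probe("mb661_Ia")
    panel = [
        PanelRecord(id=f"r{k}", group="Ia",
                    sequence=_embed(assay, probe.sense_image, rng, n_mismatch=k))
        for k in (0, 1, 4)
    ]
    bins, _ = coverage_table(panel, assay)
    row = bins.set_index("probe").loc["mb661_Ia"]
    assert (row["bin0"], row["bin1"], row["bin2"], row["bin3plus"]) == (1, 1, 0, 1)
    assert row["total"] == 3


def test_coverage_table_excludes_no_amplicon_records(assay, rng):
    probe = assay.probe("mb661_Ia")
    good = PanelRecord(id="good", group="Ia",
                       sequence=_embed(assay, probe.sense_image, rng))
    orphan = PanelRecord(id="orphan", group="Ia",
                         sequence="".join(rng.choice(list("ACGT"), size=120)))
    bins, report = coverage_table([good, orphan], assay, max_primer_mismatch=0)
    row = bins.set_index("probe").loc["mb661_Ia"]
    assert row["total"] == 1
    orphan_rows = report[report["record_id"] == "orphan"]
    assert (orphan_rows["predicted_detection"] == "no_amplicon").all()


def test_bins_sum_to_amplicon_yielding_target_records(assay, rng):
    probe = assay.probe("Ib547")
    panel = [
        PanelRecord(id=f"t{k}", group=g,
                    sequence=_embed(assay, probe.sense_image, rng, n_mismatch=k % 3))
        for k, g in enumerate(["Ib", "Ib", "RPC1", "IIa", "amoA"])
    ]
    bins, _ = coverage_table(panel, assay)
    row = bins.set_index("probe").loc["Ib547"]
    assert row[["bin0", "bin1", "bin2", "bin3plus"]].sum() == row["total"] == 3


def test_antisense_record_flag(assay, rng):
    probe = assay.probe("mb661_Ia")
    sense_seq = _embed(assay, probe.sense_image, rng)
    rec = PanelRecord(id="flip", group="Ia", sequence=revcomp_iupac(sense_seq),
                      antisense=True)
    amp = extract_amplicon(rec, assay.forward, assay.reverse)
    assert probe_mismatch(amp, probe)[0] == 0


def test_read_panel_roundtrip(tmp_path, assay, rng):
    probe = assay.probe("mb661_Ia")
    seq = _embed(assay, probe.sense_image, rng)
    (tmp_path / "panel.fasta").write_text(f">rec1 test\n{seq}\n")
    (tmp_path / "panel.tsv").write_text(
        "id\tgroup\tgene_copies\taccession\nrec1\tIa\t2\tXX000001\n"
    )
    panel = read_panel(tmp_path / "panel.fasta", tmp_path / "panel.tsv")
    assert len(panel) == 1
    assert panel[0].group == "Ia"
    assert panel[0].gene_copies == 2
    assert panel[0].sequence == seq
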