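"""Domain profile, scanning, conservation, classification, properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bhlhfam.domain import (
    AA,
    DOMAIN_LEN,
    REGION_BOUNDS,
    BindingCall,
    DomainHit,
    build_profile,
    classify_binding,
    conservation,
    isoelectric_point,
    molecular_weight,
    net_charge,
    partition_regions,
    protein_properties,
    scan_domain,
)
from bhlhfam.io import SequenceRecord


def _hit(aligned55: str) -> DomainHit:
    return DomainHit("p", 0, aligned55, 0.0)


# ---------------------------------------------------------------------------
# profile
# ---------------------------------------------------------------------------

def test_profile_single_row_consensus_and_max_self_score():
    row = ("ARNDCQEGHILKMFPSTWYV" * 3)[:55]
    prof = build_profile([row], pseudocount=1e-9)
    assert prof.consensus == row
    # self-scan achieves the maximal attainable score
    best = sum(prof.weights[j].max() for j in range(55))
    self_score = sum(prof.weights[j, AA.index(c)] for j, c in enumerate(row))
    assert self_score == pytest.approx(best)


def test_profile_pure_column_weight_closed_form():
    # a column of all 'R' at background 0.05 and vanishing pseudocount
    # carries log2(1/0.05) = 4.3219 bits
    rows = ["R" * 55]
    prof = build_profile(rows, pseudocount=1e-12)
    assert prof.weights[0, AA.index("R")] == pytest.approx(np.log2(20), abs=1e-6)


def test_profile_probabilities_sum_to_one_for_random_alignments():
    rng = np.random.default_rng(0)
    for _ in range(100):
        rows = ["".join(rng.choice(list(AA), size=55)) for _ in range(rng.integers(1, 9))]
        prof = build_profile(rows, pseudocount=float(rng.uniform(0.1, 5)))
        assert np.allclose(prof.probs.sum(axis=1), 1.0, atol=1e-9)


def test_profile_rejects_ragged_and_illegal_rows():
    with pytest.raises(ValueError):
        build_profile(["A" * 54])
    with pytest.raises(ValueError):
        build_profile(["B" * 55])


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_scan_finds_planted_consensus_at_offset(profile, threshold):
    rng = np.random.default_rng(1)
    flank = lambda n: "".join(rng.choice(list(AA), size=n))
    seq = flank(30) + profile.consensus + flank(30)
    hit = scan_domain(SequenceRecord("p", seq), profile, threshold)
    assert hit is not None
    assert hit.start == 30
    assert hit.aligned55 == profile.consensus


def test_scan_consensus_window_is_global_maximum(profile):
    # the consensus window scores the profile maximum, so it always wins
    rng = np.random.default_rng(2)
    for trial in range(5):
        pad = "".join(rng.choice(list(AA), size=100))
        seq = pad[:50] + profile.consensus + pad[50:]
        hit = scan_domain(SequenceRecord("p", seq), profile, threshold=-1e9)
        assert hit.start == 50


def test_scan_random_proteins_rarely_pass_threshold(profile, threshold):
    rng = np.random.default_rng(3)
    n = 200
    false_pos = 0
    for _ in range(n):
        seq = "".join(rng.choice(list(AA), size=500))
        if scan_domain(SequenceRecord("r", seq), profile, threshold) is not None:
            false_pos += 1
    assert false_pos / n <= 0.01


def test_scan_recovers_planted_domain_with_substitutions(profile, threshold):
    rng = np.random.default_rng(4)
    dom = list(profile.consensus)
    for j in rng.choice(55, size=5, replace=False):
        dom[j] = rng.choice([a for a in AA if a != dom[j]])
    seq = "".join(rng.choice(list(AA), size=40)) + "".join(dom) + "".join(
        rng.choice(list(AA), size=40)
    )
    hit = scan_domain(SequenceRecord("p", seq), profile, threshold)
    assert hit is not None and hit.start == 40


def test_scan_short_protein_is_padded_with_gaps(profile):
    seq = profile.consensus[:30]
    hit = scan_domain(SequenceRecord("p", seq), profile, threshold=-1e9)
    assert hit.aligned55 == seq + "-" * 25


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def test_partition_lengths_and_concatenation():
    s = "B" * 17 + "H" * 15 + "L" * 8 + "X" * 15
    regions = partition_regions(_hit(s))
    assert [len(regions[r]) for r in ("basic", "helix1", "loop", "helix2")] == [17, 15, 8, 15]
    assert regions["basic"] + regions["helix1"] + regions["loop"] + regions["helix2"] == s


@pytest.mark.parametrize("column,region", [(27, "helix1"), (40, "loop"), (16, "basic"), (55, "helix2")])
def test_known_conserved_columns_fall_in_their_regions(column, region):
    lo, hi = REGION_BOUNDS[region]
    assert lo <= column <= hi


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def test_conservation_identical_domains():
    cols = conservation(["A" * 55] * 98)
    assert all(c.identity == 1.0 and c.consensus_flag for c in cols)
    assert all(c.top_residue == "A" for c in cols)


def test_conservation_majority_arithmetic():
    domains = ["L" + "A" * 54] * 50 + ["M" + "A" * 54] * 48
    col1 = conservation(domains)[0]
    assert col1.top_residue == "L"
    assert col1.identity == pytest.approx(50 / 98)
    assert col1.consensus_flag  # 0.5102 > 0.5


def test_conservation_gaps_count_in_denominator_and_ties_alphabetical():
    domains = ["L" + "A" * 54, "M" + "A" * 54, "-" + "A" * 54, "M" + "A" * 54, "L" + "A" * 54]
    col1 = conservation(domains)[0]
    assert col1.top_residue == "L"  # tie L=2, M=2 -> alphabetical
    assert col1.identity == pytest.approx(2 / 5)
    assert not col1.consensus_flag


def test_conservation_identity_is_multiple_of_one_over_n():
    rng = np.random.default_rng(5)
    n = 13
    domains = ["".join(rng.choice(list(AA), size=55)) for _ in range(n)]
    for col in conservation(domains):
        assert (col.identity * n) == pytest.approx(round(col.identity * n))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _call_from_basic(basic: str) -> BindingCall:
    return classify_binding(_hit(basic + "A" * 38))


def oracle_category(basic: str, basic_set="RKH", cutoff=6) -> str:
    """Independent re-statement of the published decision rules."""
    count = sum(basic.count(c) for c in basic_set)
    if count < cutoff:
        return "non_DNA_binding"
    p9, p13, p16, p17 = basic[8], basic[12], basic[15], basic[16]
    if p13 == "E" and p16 == "R":
        if p9 in ("H", "K") and p17 == "R":
            return "G_box"
        return "E_box_non_G_box"
    return "non_E_box"


def test_classify_trivial_cases():
    assert _call_from_basic("A" * 17).category == "non_DNA_binding"
    g = list("R" * 17)
    g[8] = "H"
    g[12] = "E"
    call = _call_from_basic("".join(g))
    assert call.category == "G_box"
    assert call.basic_count == 16
    non_e = list("R" * 17)
    non_e[12] = "A"
    assert _call_from_basic("".join(non_e)).category == "non_E_box"


def test_classify_gap_at_rule_position_fails_that_test():
    basic = list("R" * 17)
    basic[12] = "-"
    assert _call_from_basic("".join(basic)).category == "non_E_box"


def test_classify_exhaustive_sweep_matches_independent_oracle():
    """Every residue combination at rule positions x every basic count."""
    residues = ["A", "E", "R", "H", "K"]
    checked = 0
    for p9 in residues:
        for p13 in residues:
            for p16 in residues:
                for p17 in residues:
                    for n_extra_basic in range(14):  # basic count in non-rule positions
                        basic = list("A" * 17)
                        basic[8], basic[12], basic[15], basic[16] = p9, p13, p16, p17
                        free = [j for j in range(17) if j not in (8, 12, 15, 16)]
                        for j in free[:n_extra_basic]:
                            basic[j] = "R"
                        b = "".join(basic)
                        assert _call_from_basic(b).category == oracle_category(b)
                        checked += 1
    assert checked == 5**4 * 14


def test_classify_category_counts_sum_and_additivity(family98, profile, threshold):
    recs, truth = family98
    calls = [
        classify_binding(scan_domain(r, profile, threshold))
        for r in recs
    ]
    counts = {c: sum(1 for x in calls if x.category == c) for c in
              ("G_box", "E_box_non_G_box", "non_E_box", "non_DNA_binding")}
    assert sum(counts.values()) == 98
    e_box = counts["G_box"] + counts["E_box_non_G_box"]
    dna = e_box + counts["non_E_box"]
    assert dna + counts["non_DNA_binding"] == 98


# ---------------------------------------------------------------------------
# physical properties
# ---------------------------------------------------------------------------

def test_molecular_weight_glycine():
    assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)


def test_net_charge_at_pi_is_zero():
    rng = np.random.default_rng(6)
    for _ in range(100):
        seq = "".join(rng.choice(list(AA), size=rng.integers(5, 60)))
        pi = isoelectric_point(seq)
        assert abs(net_charge(seq, pi)) < 1e-3


def test_basic_peptides_have_higher_pi_than_acidic():
    assert isoelectric_point("K" * 20) > isoelectric_point("D" * 20)


def test_pi_agrees_with_biopython_reference():
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

    rng = np.random.default_rng(7)
    for _ in range(20):
        seq = "".join(rng.choice(list(AA), size=50))
        ours = isoelectric_point(seq)
        theirs = IsoelectricPoint(seq).pi()
        assert abs(ours - theirs) < 1.0


def test_protein_properties_bundle():
    p = protein_properties(SequenceRecord("p", "MKVR"))
    assert p.length == 4 and p.mw > 0 and 0 < p.pi < 14


def test_pi_rejects_ambiguity_codes():
    with pytest.raises(ValueError):
        isoelectric_point("MKX")


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    st.text(alphabet=AA, min_size=1, max_size=30),
    st.text(alphabet=AA, min_size=1, max_size=30),
)
def test_molecular_weight_additive_up_to_one_water(a, b):
    from bhlhfam.domain import WATER_MASS

    assert molecular_weight(a + b) == pytest.approx(
        molecular_weight(a) + molecular_weight(b) - WATER_MASS
    )


@settings(derandomize=True, deadline=None, max_examples=40)
@given(st.permutations(list(range(17))))
def test_classifier_depends_only_on_rule_positions_and_basic_count(perm):
    """Permuting non-rule basic-region residues never changes the call."""
    base = list("RASRNQAKHSQAEKARR")
    rule = {8, 12, 15, 16}
    permuted = base[:]
    free = [j for j in range(17) if j not in rule]
    free_vals = [base[j] for j in free]
    reordered = [perm[j] for j in range(17) if perm[j] not in rule][: len(free)]
    for j, src in zip(free, reordered):
        permuted[j] = base[src] if src not in rule else base[j]
    a = _call_from_basic("".join(base))
    b = _call_from_basic("".join(permuted))
    if a.basic_count == b.basic_count:
        assert a.category == b.category
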