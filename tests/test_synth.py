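"""Generator contracts: determinism, planted-feature truth, forced cases."""

import numpy as np
import pandas as pd
import pytest

from bhlhfam.expression import ddct
from bhlhfam.synth import (
    TIER_BOUNDS,
    default_categories,
    default_clade_spec,
    make_expression,
    make_family,
    make_gene,
    make_promoters,
    make_qpcr,
)


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

def test_family_zero_mutation_gives_identical_domains_within_clade():
    recs, truth = make_family(
        4, {"c": 4}, mutation_rate=0.0, seed=1, categories=["G_box"] * 4
    )
    doms = [truth.planted_domains[r.id]["domain"] for r in recs]
    assert len(set(doms)) == 1
    for r in recs:
        off = truth.planted_domains[r.id]["offset"]
        assert r.sequence[off : off + 55] == doms[0]


def test_family_g_box_category_forced_by_construction():
    recs, truth = make_family(
        6, {"c": 6}, mutation_rate=0.1, seed=2, categories=["G_box"] * 6
    )
    for r in recs:
        basic = truth.planted_domains[r.id]["basic_region"]
        assert basic[8] in "HK" and basic[12] == "E" and basic[15] == "R" and basic[16] == "R"
        assert sum(basic.count(c) for c in "RKH") >= 6


def test_family_non_binder_has_few_basic_residues():
    recs, truth = make_family(
        4, {"c": 4}, mutation_rate=0.1, seed=3, categories=["non_DNA_binding"] * 4
    )
    for r in recs:
        basic = truth.planted_domains[r.id]["basic_region"]
        assert sum(basic.count(c) for c in "RKH") < 6


def test_family_determinism_same_seed_identical_sequences():
    a, _ = make_family(98, default_clade_spec(), mutation_rate=0.05, seed=1)
    b, _ = make_family(98, default_clade_spec(), mutation_rate=0.05, seed=1)
    assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]
    c, _ = make_family(98, default_clade_spec(), mutation_rate=0.05, seed=2)
    assert [r.sequence for r in a] != [r.sequence for r in c]


def test_family_input_validation():
    with pytest.raises(ValueError):
        make_family(4, {"c": 4}, mutation_rate=0.5)
    with pytest.raises(ValueError):
        make_family(4, {"c": 3})
    with pytest.raises(ValueError):
        make_family(3, {"a": 2, "b": 1})


def test_default_categories_mirror_survey_mix():
    cats = default_categories(98)
    assert len(cats) == 98
    assert cats.count("G_box") == 61
    assert cats.count("E_box_non_G_box") == 4
    assert cats.count("non_E_box") == 11
    assert cats.count("non_DNA_binding") == 22


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

def test_gene_intronless_genomic_equals_cds():
    genomic, cds, truth = make_gene(0, seed=1)
    assert genomic.sequence == cds.sequence
    assert truth.planted_introns[genomic.id] == []


def test_gene_eleven_introns_all_gt_ag_at_recorded_positions():
    genomic, cds, truth = make_gene(11, seed=2)
    introns = truth.planted_introns[genomic.id]
    exons = truth.planted_exons[genomic.id]
    assert len(introns) == 11 and len(exons) == 12
    for s, e in introns:
        assert genomic.sequence[s : s + 2] == "GT"
        assert genomic.sequence[e - 2 : e] == "AG"
    assert "".join(genomic.sequence[s:e] for s, e in exons) == cds.sequence


def test_gene_intron_lengths_within_requested_range():
    genomic, _, truth = make_gene(5, intron_len_range=(44, 2000), seed=3)
    for s, e in truth.planted_introns[genomic.id]:
        assert 44 <= e - s <= 2000


def test_gene_rejects_bad_ranges():
    with pytest.raises(ValueError):
        make_gene(1, intron_len_range=(2000, 44))
    with pytest.raises(ValueError):
        make_gene(1, intron_len_range=(10, 30))


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

LIB = {"G-box": "CACGTG", "ERE": "ATTTCAAA", "MBS": "CAACTG"}


def test_promoters_planted_counts_recorded():
    recs, truth = make_promoters(5, plant={"G-box": 3}, seed=1, library=LIB)
    for r in recs:
        hits = truth.planted_motifs[r.id]
        assert len(hits) == 3
        assert all(h["motif"] == "G-box" for h in hits)
        assert len(r.sequence) == 2000


def test_promoters_empty_plant_and_determinism():
    a, truth = make_promoters(3, plant={}, seed=2, library=LIB)
    assert all(truth.planted_motifs[r.id] == [] for r in a)
    b, _ = make_promoters(3, plant={}, seed=2, library=LIB)
    assert [r.sequence for r in a] == [r.sequence for r in b]


def test_promoters_planted_site_matches_pattern_on_recorded_strand():
    from bhlhfam.io import reverse_complement

    recs, truth = make_promoters(4, plant={"ERE": 2, "MBS": 1}, seed=3, library=LIB)
    for r in recs:
        for h in truth.planted_motifs[r.id]:
            pat = LIB[h["motif"]]
            site = r.sequence[h["position"] : h["position"] + len(pat)]
            if h["strand"] == "-":
                site = reverse_complement(site)
            assert all(
                s in {"A": "A", "C": "C", "G": "G", "T": "T"}.get(p, "ACGT")
                for s, p in zip(site, pat)
            )


def test_promoters_infeasible_packing_rejected():
    with pytest.raises(ValueError):
        make_promoters(1, length=100, plant={"G-box": 20}, library=LIB)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def test_expression_zero_noise_respects_tier_bounds():
    tissues = ["a", "b", "c", "d", "e", "f", "g", "h"]
    matrix, truth = make_expression(
        3,
        tissues=tissues,
        group_spec=[("hi", 3, {t: "abundant" for t in tissues})],
        noise_sd=0.0,
        seed=1,
    )
    assert (matrix.values >= 50).all() and (matrix.values < 300).all()


def test_expression_root_specific_pattern():
    tissues = ["leaf", "stem", "white_root", "green_root_tip"]
    matrix, truth = make_expression(
        2,
        tissues=tissues,
        group_spec=[("root", 2, {"white_root": "abundant", "green_root_tip": "moderate"})],
        noise_sd=0.0,
        seed=2,
    )
    assert (matrix[["leaf", "stem"]].values < 2).all()
    assert (matrix[["white_root", "green_root_tip"]].values >= 2).all()


def test_expression_group_bookkeeping_partitions_genes():
    spec = [(f"g{i}", 15, {}) for i in range(5)]
    matrix, truth = make_expression(75, group_spec=spec, seed=3)
    sizes = pd.Series(truth.planted_groups).value_counts()
    assert sorted(sizes) == [15] * 5 and sizes.sum() == 75


def test_expression_unknown_tier_rejected():
    with pytest.raises(ValueError, match="tier"):
        make_expression(2, group_spec=[("x", 2, {"leaf": "huge"})], tissues=["leaf"])


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def test_qpcr_noiseless_ct_shift_equals_planted_fold():
    table, truth = make_qpcr(
        ["g1"], {"g1": {("MeJA", "3h"): 2.0}}, ct_noise_sd=0.0, seed=1
    )
    res = ddct(table, "DoActin")
    row = res[(res["gene"] == "g1") & (res["condition"] == "MeJA") & (res["timepoint"] == "3h")]
    assert row["fold"].iloc[0] == pytest.approx(4.0)
    assert row["log2fc"].iloc[0] == pytest.approx(2.0)


def test_qpcr_null_spec_recovers_fold_one():
    table, _ = make_qpcr(["g1", "g2"], {}, ct_noise_sd=0.0, seed=2)
    res = ddct(table, "DoActin")
    assert np.allclose(res["fold"], 1.0)


def test_qpcr_monte_carlo_recovery_within_three_se():
    """At CT noise 0.2 and 3 bio reps, the recovered log2fc lies within
    3 standard errors of the planted value in >= 95% of replicates."""
    inside = total = 0
    for seed in range(200):
        table, truth = make_qpcr(
            ["g1"], {"g1": {("MeJA", "3h"): 1.5}}, ct_noise_sd=0.2, seed=seed
        )
        res = ddct(table, "DoActin")
        row = res[(res["condition"] == "MeJA") & (res["timepoint"] == "3h")]
        # ddCT variance: two means of 3 bio-rep dCTs, each dCT the
        # difference of two tech-averaged CTs
        se = np.sqrt(2 * (2 * 0.2**2 / 3) / 3)
        inside += abs(row["log2fc"].iloc[0] - 1.5) <= 3 * se
        total += 1
    assert inside / total >= 0.95


def test_qpcr_requires_two_bio_reps():
    with pytest.raises(ValueError):
        make_qpcr(["g1"], {}, n_bio=1)
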