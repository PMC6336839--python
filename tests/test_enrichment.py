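"""Wilcoxon exact path, BH adjustment, bootstrap, odds ratios, driver."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mosaicscan.enrichment import (
    bh_adjust,
    bootstrap_success,
    haldane_anscombe_or,
    per_individual_set_counts,
    results_frame,
    run_enrichment,
    wilcoxon_rank_sum,
)
from mosaicscan.io_model import GeneSetCollection, load_enrichment_table


# ---------------------------------------------------------------------------
# Wilcoxon


def test_exact_p_for_two_tied_hits_among_nineteen_donors():
    # both nonzero donors must land in the 9-donor cohort:
    # p = C(9,2)/C(19,2) = 36/171
    x = [2, 2, 0, 0, 0, 0, 0, 0, 0]
    y = [0] * 10
    assert wilcoxon_rank_sum(x, y, "greater") == pytest.approx(36 / 171, abs=1e-12)


def test_exact_p_single_extreme_arrangement():
    # y strictly dominates x: one arrangement in C(6,3) = 20
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "less") == pytest.approx(1 / 20)


def test_identical_constant_vectors_give_p_one():
    assert wilcoxon_rank_sum([1, 1, 1], [1, 1, 1], "two-sided") == 1.0


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 3), min_size=2, max_size=4),
       st.lists(st.integers(0, 3), min_size=2, max_size=4),
       st.sampled_from(["greater", "less"]))
def test_exact_path_matches_permutation_oracle(x, y, alternative):
    """Tie-aware exact enumeration agrees with an independent permutation
    oracle for all pooled samples of size <= 8."""
    def rank_sum(a, b, axis=-1):
        pooled = np.concatenate([a, b], axis=axis)
        ranks = np.apply_along_axis(stats.rankdata, axis, pooled)
        return np.take(ranks, range(np.shape(a)[axis]), axis=axis).sum(axis=axis)

    oracle = stats.permutation_test(
        (np.array(x, float), np.array(y, float)), rank_sum,
        permutation_type="independent", alternative=alternative,
        n_resamples=np.inf)
    assert wilcoxon_rank_sum(x, y, alternative) == pytest.approx(oracle.pvalue,
                                                                 abs=1e-12)


def test_large_sample_normal_approximation_is_reasonable():
    rng = np.random.default_rng(0)
    x = rng.normal(1.0, 1.0, 30)
    y = rng.normal(0.0, 1.0, 30)
    p = wilcoxon_rank_sum(x, y, "greater")
    ref = stats.mannwhitneyu(x, y, alternative="greater").pvalue
    assert p == pytest.approx(ref, rel=1e-9)
    assert p < 0.02


# ---------------------------------------------------------------------------
# BH


def test_bh_reproduces_published_fdr_column():
    p = [0.026, 0.026, 0.060, 0.060, 0.060, 0.145, 0.145, 1.0]
    adjusted = bh_adjust(p)
    expected = [0.096, 0.096, 0.096, 0.096, 0.096, 8 * 0.145 / 7, 8 * 0.145 / 7, 1.0]
    np.testing.assert_allclose(adjusted, expected, atol=1e-12)
    # printed FDR column rounds to 0.096 / 0.166
    assert round(float(adjusted[5]), 3) == 0.166


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
def test_bh_matches_bruteforce_definition(p):
    adjusted = bh_adjust(p)
    n = len(p)
    order = np.argsort(p, kind="stable")
    expected = np.empty(n)
    sorted_p = np.asarray(p)[order]
    # brute force: adj(i) = min_{j >= i} p(j) * n / (j+1), capped at 1
    for i in range(n):
        expected[order[i]] = min(1.0,
                                 min(sorted_p[j] * n / (j + 1) for j in range(i, n)))
    np.testing.assert_allclose(adjusted, expected, atol=1e-12)
    assert (adjusted >= np.asarray(p) - 1e-12).all()


def test_bh_edge_cases():
    np.testing.assert_allclose(bh_adjust([0.03]), [0.03])
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    with pytest.raises(ValueError):
        bh_adjust([0.0, 0.5])


# ---------------------------------------------------------------------------
# odds ratio


def test_haldane_anscombe_or():
    assert haldane_anscombe_or(2, 1, 1, 2) == pytest.approx(4.0)
    assert haldane_anscombe_or(4, 19, 0, 7) == pytest.approx(
        (4.5 * 7.5) / (19.5 * 0.5), abs=1e-12)  # = 3.4615...
    assert haldane_anscombe_or(0, 23, 0, 7) == pytest.approx(
        (0.5 * 7.5) / (23.5 * 0.5), abs=1e-4)   # = 0.319
    with pytest.raises(ValueError):
        haldane_anscombe_or(-1, 1, 1, 1)


def test_correction_branch_inactive_for_positive_tables():
    rng = np.random.default_rng(1)
    for _ in range(50):
        a, b, c, d = rng.integers(1, 30, size=4)
        plain = (a * d) / (b * c)
        assert haldane_anscombe_or(int(a), int(b), int(c), int(d)) == pytest.approx(plain)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_success_separated_and_null():
    rng = np.random.default_rng(2)
    x = rng.normal(5.0, 0.5, 20)
    y = rng.normal(0.0, 0.5, 20)
    assert bootstrap_success(x, y, B=1000, seed=3) >= 99.0
    z = rng.normal(0.0, 1.0, 20)
    assert bootstrap_success(z, z.copy(), B=1000, seed=3) <= 10.0


def test_bootstrap_deterministic_and_monotone_in_effect():
    x0 = np.array([0, 0, 1, 0, 0, 2, 0, 0, 0], float)
    y = np.zeros(10)
    a = bootstrap_success(x0, y, B=500, seed=7)
    assert a == bootstrap_success(x0, y, B=500, seed=7)
    successes = [bootstrap_success(x0 + shift * (x0 > 0), y, B=500, seed=7)
                 for shift in (0.0, 2.0, 8.0)]
    assert successes[0] <= successes[1] <= successes[2]


def test_bootstrap_input_validation():
    with pytest.raises(ValueError):
        bootstrap_success([1.0], [0.0, 0.0], B=500)
    with pytest.raises(ValueError):
        bootstrap_success([1.0, 2.0], [0.0, 0.0], B=50)


# ---------------------------------------------------------------------------
# per-individual counts and driver on the published call set


def test_per_individual_counts_on_published_table(table1_cohort):
    donors, _, candidates = table1_cohort
    denovo = frozenset({"PMFBP1", "TEX15", "EP300", "OBSCN"})
    cases, controls = per_individual_set_counts(candidates, denovo, donors)
    assert sorted(cases.tolist(), reverse=True) == [2, 2, 0, 0, 0, 0, 0, 0, 0]
    assert controls.tolist() == [0] * 10
    all_genes = frozenset(c.gene for c in candidates)
    cases_all, controls_all = per_individual_set_counts(candidates, all_genes, donors)
    assert cases_all.sum() == 25 and controls_all.sum() == 7


def test_per_individual_counts_empty_set(table1_cohort):
    donors, _, candidates = table1_cohort
    cases, controls = per_individual_set_counts(candidates, frozenset(["NOPE"]), donors)
    assert not cases.any() and not controls.any()


def _published_style_sets(table2) -> GeneSetCollection:
    """Synthetic stand-ins for the hypothesis-driven collection: each set
    carries the published case-gene overlap plus filler symbols up to the
    published size."""
    import pandas as pd

    sets, filler_i = {}, 0
    for _, row in table2.iterrows():
        raw = row["case_genes"]
        genes = set() if (pd.isna(raw) or raw == "NA") else set(str(raw).split(";"))
        while len(genes) < int(row["set_size"]):
            filler_i += 1
            genes.add(f"FILLER{filler_i:05d}")
        sets[row["gene_set"]] = frozenset(genes)
    return GeneSetCollection(sets, {n: "hypothesis_driven" for n in sets})


def test_run_enrichment_reproduces_published_overlaps(table1_cohort):
    donors, _, candidates = table1_cohort
    table2 = load_enrichment_table()
    results = run_enrichment(candidates, _published_style_sets(table2), donors,
                             mode="hypothesis_driven", B=200, seed=1)
    by_name = {r.set_name: r for r in results}
    for _, row in table2.iterrows():
        r = by_name[row["gene_set"]]
        assert r.overlap_case == int(row["overlap_case"])
        assert r.overlap_control == int(row["overlap_control"])
        assert r.set_size == int(row["set_size"])
    # the standard Haldane-Anscombe formula on the published 2x2 overlap
    denovo = by_name["De novo in schizophrenia"]
    assert denovo.odds_ratio == pytest.approx((4.5 * 7.5) / (19.5 * 0.5))
    assert set(denovo.case_genes) == {"PMFBP1", "TEX15", "EP300", "OBSCN"}
    assert all(r.fdr >= r.p_value - 1e-12 for r in results)
    frame = results_frame(results)
    assert len(frame) == 8


def test_hypothesis_free_mode_filters_by_size(table1_cohort):
    donors, _, candidates = table1_cohort
    sets = GeneSetCollection({
        "tiny": frozenset({"EP300"}),
        "ok": frozenset({f"G{i}" for i in range(99)} | {"EP300"}),
        "huge": frozenset({f"H{i}" for i in range(2000)}),
    })
    results = run_enrichment(candidates, sets, donors, mode="hypothesis_free",
                             B=200, seed=1)
    assert [r.set_name for r in results] == ["ok"]


def test_run_enrichment_requires_gene_annotations(table1_cohort):
    donors, _, candidates = table1_cohort
    stripped = []
    for c in candidates:
        c2 = type(c)(chrom=c.chrom, pos=c.pos, ref_allele=c.ref_allele,
                     alt_allele=c.alt_allele, specimen_id=c.specimen_id)
        c2.extras.update(c.extras)
        stripped.append(c2)
    with pytest.raises(ValueError, match="gene annotations"):
        run_enrichment(stripped, GeneSetCollection({"s": frozenset({"X"})}),
                       donors, B=200)


def test_planted_enrichment_detected():
    """A set with strongly elevated case counts is flagged at FDR <= 0.1
    with bootstrap success > 99%."""
    rng = np.random.default_rng(9)
    from mosaicscan.io_model import Donor, CandidateVariant

    donors = ([Donor(f"S{i}", "case") for i in range(10)]
              + [Donor(f"C{i}", "control") for i in range(10)])
    risk = frozenset(f"R{i}" for i in range(500))
    other = [f"O{i}" for i in range(500)]
    variants = []
    pos = 100
    for d in donors:
        n = 4 if d.diagnosis == "case" else 3
        for _ in range(n):
            in_risk = rng.random() < (0.9 if d.diagnosis == "case" else 0.05)
            gene = (sorted(risk)[int(rng.integers(500))] if in_risk
                    else other[int(rng.integers(500))])
            pos += 20
            v = CandidateVariant(chrom="1", pos=pos, ref_allele="C",
                                 alt_allele="T", specimen_id=f"{d.donor_id}_n")
            v.gene = gene
            v.extras["donor_id"] = d.donor_id
            variants.append(v)
    sets = GeneSetCollection({"risk": risk,
                              "decoy": frozenset(f"D{i}" for i in range(300))})
    results = run_enrichment(variants, sets, donors, B=1000, seed=5,
                             alternative="greater")
    flagged = {r.set_name: r.significant for r in results}
    assert flagged["risk"] and not flagged["decoy"]
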