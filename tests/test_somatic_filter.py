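"""Consensus intersection, the QC cascade, outlier exclusion, concordance."""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import make_candidate, oracle_cascade, random_candidates
from mosaicscan.somatic_filter import (
    CascadeThresholds,
    apply_cascade,
    concordance_from_frame,
    consensus_intersect,
    exclude_outlier_specimens,
    genotype_concordance,
    inspection_queue,
)


# ---------------------------------------------------------------------------
# consensus


def test_consensus_is_site_level_intersection():
    v1 = make_candidate(pos=1010)
    v2a, v2b = make_candidate(pos=1020), make_candidate(pos=1020)
    v3 = make_candidate(pos=1030)
    out = consensus_intersect({"a": [v1, v2a], "b": [v2b, v3]})
    assert [c.pos for c in out] == [1020]
    assert out[0].callers == {"a", "b"}


def test_consensus_requires_same_alt_allele():
    a = make_candidate(pos=1020, alt_allele="T")
    b = make_candidate(pos=1020, alt_allele="G")
    assert consensus_intersect({"a": [a], "b": [b]}) == []


def test_consensus_missing_caller_errors():
    with pytest.raises(ValueError, match="two callers"):
        consensus_intersect({"a": [make_candidate()]})
    with pytest.raises(ValueError, match="missing"):
        consensus_intersect({"a": [make_candidate()], "b": None})


def test_consensus_prefers_higher_depth_evidence():
    from mosaicscan.io_model import SiteEvidence

    a = make_candidate(pos=1020)
    b = make_candidate(pos=1020)
    a.extras["caller_evidence"] = {"a": SiteEvidence(100, 5, 60, 30)}
    b.extras["caller_evidence"] = {"b": SiteEvidence(300, 9, 60, 30)}
    b.evidence = {t: SiteEvidence(300, 9, 60, 30) for t in b.evidence}
    (kept,) = consensus_intersect({"a": [a], "b": [b]})
    assert kept.evidence["neuronal"].depth == 300
    assert set(kept.extras["caller_evidence"]) == {"a", "b"}


# ---------------------------------------------------------------------------
# cascade rules


def test_depth_threshold_is_strict(small_targets):
    ok = make_candidate(depth=(250, 250, 11))
    boundary = make_candidate(pos=2050, depth=(250, 250, 10))
    survivors, report = apply_cascade([ok, boundary], small_targets)
    assert survivors == [ok]
    assert report.first_failures()[boundary.candidate_id] == "depth"


def test_quality_required_in_all_three_tissues(small_targets):
    bad_mq = make_candidate(mq=(60.0, 60.0, 9.0))
    bad_bq = make_candidate(pos=2050, bq=(30.0, 8.0, 30.0))
    survivors, report = apply_cascade([bad_mq, bad_bq], small_targets)
    assert survivors == []
    assert report.first_failures()[bad_mq.candidate_id] == "mapping_quality"
    assert report.first_failures()[bad_bq.candidate_id] == "base_quality"


def test_proximity_removes_both_cluster_members(small_targets):
    a = make_candidate(pos=1000)
    b = make_candidate(pos=1008)  # 8 bp apart: both fail
    far = make_candidate(pos=2050)
    survivors, report = apply_cascade([a, b, far], small_targets)
    assert survivors == [far]
    assert report.first_failures()[a.candidate_id] == "proximity"
    assert report.first_failures()[b.candidate_id] == "proximity"
    # 11 bp apart passes (strict > 10)
    c = make_candidate(pos=3000)
    d = make_candidate(pos=3011)
    survivors, _ = apply_cascade([c, d], small_targets)
    assert len(survivors) == 2


def test_proximity_only_within_same_specimen(small_targets):
    a = make_candidate(pos=1050, specimen="SP1")
    b = make_candidate(pos=1055, specimen="SP2")
    survivors, _ = apply_cascade([a, b], small_targets)
    assert len(survivors) == 2


def test_target_distance_boundary(small_targets):
    # target at 1000-1100 (0-based); 1-based positions past the end
    at_349 = make_candidate(pos=1100 + 349)
    at_350 = make_candidate(pos=1100 + 350, specimen="SP2")
    survivors, report = apply_cascade([at_349, at_350], small_targets)
    assert survivors == [at_349]
    assert report.first_failures()[at_350.candidate_id] == "target_distance"


@pytest.mark.parametrize("af,passes", [
    (1.48e-05, True),   # published gnomAD frequency well under the cutoff
    (0.000999, True),
    (0.001, False),     # strict <
    (0.01, False),
])
def test_population_af_threshold(small_targets, af, passes):
    cand = make_candidate(pop_af=af)
    survivors, _ = apply_cascade([cand], small_targets)
    assert bool(survivors) == passes


def test_indels_and_multiallelic_sites_fail(small_targets):
    indel = make_candidate(ref_allele="C", alt_allele="CA")
    triallelic = make_candidate(pos=2050, n_alleles=3)
    survivors, report = apply_cascade([indel, triallelic], small_targets)
    assert survivors == []
    assert report.first_failures()[indel.candidate_id] == "snv"
    assert report.first_failures()[triallelic.candidate_id] == "two_alleles"


def test_missing_tissue_evidence_errors(small_targets):
    cand = make_candidate()
    del cand.evidence["reference"]
    with pytest.raises(ValueError, match="reference"):
        apply_cascade([cand], small_targets)


def test_threshold_validation():
    with pytest.raises(ValueError):
        CascadeThresholds(max_pop_af=2.0)
    with pytest.raises(ValueError):
        CascadeThresholds(min_depth=-1)


# ---------------------------------------------------------------------------
# properties


@pytest.mark.parametrize("seed", range(8))
def test_cascade_matches_bruteforce_oracle(small_targets, seed):
    rng = np.random.default_rng(seed)
    cands = random_candidates(rng, int(rng.integers(5, 50)), small_targets)
    survivors, report = apply_cascade(cands, small_targets)
    expected = oracle_cascade(cands, small_targets)
    assert {c.candidate_id for c in survivors} == {c.candidate_id for c in expected}
    # ledger conservation: every candidate is survivor xor has a failed rule
    assert len(report.ledger) == len(cands)
    assert report.n_survivors() + (~report.ledger["passed_all"]).sum() == len(cands)


@pytest.mark.parametrize("field,relaxed", [
    ("min_mq", 5.0), ("min_bq", 5.0), ("min_depth", 5),
    ("max_proximity", 4), ("max_target_distance", 1000), ("max_pop_af", 0.05),
])
def test_relaxing_any_threshold_never_shrinks_survivors(small_targets, field, relaxed):
    rng = np.random.default_rng(99)
    cands = random_candidates(rng, 40, small_targets)
    strict_surv, _ = apply_cascade(cands, small_targets, CascadeThresholds())
    loose = dataclasses.replace(CascadeThresholds(), **{field: relaxed})
    loose_surv, _ = apply_cascade(cands, small_targets, loose)
    assert {c.candidate_id for c in strict_surv} <= {c.candidate_id for c in loose_surv}


# ---------------------------------------------------------------------------
# outlier exclusion


def test_outlier_specimen_excluded_by_mad_rule():
    counts = {f"sp{i}": c for i, c in enumerate([0, 1, 1, 2, 0, 3, 1, 2, 0, 1,
                                                 2, 1, 0, 1, 3, 2, 1, 0, 40])}
    excluded = exclude_outlier_specimens(counts)
    assert list(excluded) == ["sp18"]


def test_outlier_rule_edge_cases():
    assert exclude_outlier_specimens({f"s{i}": 2 for i in range(10)}) == {}
    assert exclude_outlier_specimens({"a": 0, "b": 1, "c": 50}) == {}  # <4 specimens
    counts = {f"s{i}": c for i, c in enumerate([0, 1, 2, 100])}
    assert exclude_outlier_specimens(counts, k_mad=float("inf")) == {}


# ---------------------------------------------------------------------------
# genotype concordance


def _genotypes(rng, n=120):
    return {f"P{i}": int(rng.integers(0, 3)) for i in range(n)}


def test_identical_genotypes_fully_concordant():
    rng = np.random.default_rng(1)
    g = _genotypes(rng)
    res = genotype_concordance("D1", {"a": g, "b": dict(g), "c": dict(g)})
    assert all(v == 1.0 for v in res.pairwise.values())
    assert not res.flagged and not res.indeterminate


def test_swapped_specimen_is_flagged():
    rng = np.random.default_rng(2)
    donor_g = _genotypes(rng)
    other_donor_g = _genotypes(np.random.default_rng(3))
    res = genotype_concordance("D1", {
        "neuronal": donor_g, "non_neuronal": dict(donor_g),
        "muscle": other_donor_g})
    assert res.pairwise[("neuronal", "non_neuronal")] == 1.0
    assert res.pairwise[("muscle", "neuronal")] < 0.8
    assert res.flagged


def test_too_few_shared_sites_is_indeterminate_not_pass():
    rng = np.random.default_rng(4)
    g = _genotypes(rng, n=50)
    res = genotype_concordance("D1", {"a": g, "b": dict(g)})
    assert res.indeterminate and not res.flagged


def test_concordance_from_frame_groups_by_donor():
    rng = np.random.default_rng(5)
    rows = []
    for donor in ("D1", "D2"):
        g = _genotypes(rng)
        for spec in ("n", "nn", "ref"):
            gg = g if donor == "D1" or spec != "ref" else _genotypes(rng)
            rows += [{"donor_id": donor, "specimen_id": f"{donor}_{spec}",
                      "site_id": k, "genotype": v} for k, v in gg.items()]
    res = concordance_from_frame(pd.DataFrame(rows))
    assert not res["D1"].flagged
    assert res["D2"].flagged


def test_inspection_queue_preserves_manual_review_hook(small_targets):
    cand = make_candidate()
    q = inspection_queue([cand])
    assert list(q["strand_bias_flag"]) == [""]
    assert q.loc[0, "variant"] == cand.key
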