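"""Burden tables, group rates, the REML/Satterthwaite model, VAF tests."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from conftest import simulate_burden_table
from mosaicscan import burden_stats
from mosaicscan.burden_stats import (
    build_burden_table,
    design_matrix,
    fit_burden_lmm,
    group_rate,
    summarize_vaf,
    vaf_group_test,
)
from mosaicscan.io_model import CandidateVariant, SiteEvidence

DATA = Path(__file__).parent / "data" / "lmm"


# ---------------------------------------------------------------------------
# tables and rates


def test_burden_counts_from_published_table(table1_cohort):
    donors, specimens, candidates = table1_cohort
    table = build_burden_table(candidates, specimens, donors)
    by = table.groupby("diagnosis")[["count_all", "count_ns_lof"]].sum()
    assert by.loc["case", "count_all"] == 25
    assert by.loc["control", "count_all"] == 7
    assert by.loc["case", "count_ns_lof"] == 12
    assert by.loc["control", "count_ns_lof"] == 5
    # one row per included brain specimen: 19 donors x 2 minus the excluded one
    assert len(table) == 37


def test_group_rates_match_published_values(table1_cohort):
    donors, specimens, candidates = table1_cohort
    table = build_burden_table(candidates, specimens, donors)
    assert group_rate(table, "case", "all") == pytest.approx(25 / 9)
    assert group_rate(table, "control", "all") == pytest.approx(0.70)
    assert group_rate(table, "case", "ns_lof") == pytest.approx(12 / 9)
    assert group_rate(table, "control", "ns_lof") == pytest.approx(0.50)
    # subset relation holds per group
    for grp in ("case", "control"):
        assert group_rate(table, grp, "all") >= group_rate(table, grp, "ns_lof")


def test_empty_survivors_give_zero_table(table1_cohort):
    donors, specimens, _ = table1_cohort
    table = build_burden_table([], specimens, donors)
    assert (table["count_all"] == 0).all()
    with pytest.raises(ValueError, match="no donors"):
        group_rate(table.iloc[0:0], "case")


def test_unknown_specimen_reference_errors(table1_cohort):
    donors, specimens, candidates = table1_cohort
    rogue = CandidateVariant(chrom="1", pos=5, ref_allele="A", alt_allele="G",
                             specimen_id="GHOST",
                             evidence={"neuronal": SiteEvidence(100, 5, 60, 30)})
    rogue.extras["tissue"] = "neuronal"
    with pytest.raises(ValueError, match="GHOST"):
        build_burden_table(candidates + [rogue], specimens, donors)


# ---------------------------------------------------------------------------
# mixed model


def test_lmm_matches_frozen_lmer_results():
    """REML estimates, Satterthwaite df and p values agree with a reference
    mixed-model implementation on five seeded datasets (frozen goldens)."""
    name_map = {"(Intercept)": "intercept", "diagnosiscase": "diagnosis[case]",
                "cell_typeneuronal": "cell_type[neuronal]", "sexmale": "sex[male]",
                "ancestry1": "ancestry1",
                "diagnosiscase:cell_typeneuronal":
                    "diagnosis[case]:cell_type[neuronal]"}
    for i in range(1, 6):
        data = pd.read_csv(DATA / f"dataset{i}.csv").rename(columns={"y": "count_all"})
        golden = pd.read_csv(DATA / f"golden{i}.tsv", sep="\t")
        res = fit_burden_lmm(data)
        assert res.sigma2_donor == pytest.approx(golden["sigma2_donor"][0], abs=1e-4)
        assert res.sigma2_resid == pytest.approx(golden["sigma2_resid"][0], abs=1e-4)
        for _, row in golden.iterrows():
            eff = res.effect(name_map[row["term"]])
            assert eff.estimate == pytest.approx(row["estimate"], abs=1e-4)
            assert eff.se == pytest.approx(row["se"], abs=1e-4)
            assert eff.df == pytest.approx(row["df"], abs=0.5)
            assert eff.p_value == pytest.approx(row["p"], abs=1e-3)


def test_lmm_cross_checked_against_statsmodels():
    import statsmodels.formula.api as smf

    data = pd.read_csv(DATA / "dataset1.csv")
    res = fit_burden_lmm(data.rename(columns={"y": "count_all"}))
    sm_fit = smf.mixedlm(
        "y ~ C(diagnosis, Treatment('control')) * C(cell_type, Treatment('non_neuronal'))"
        " + C(sex, Treatment('female')) + ancestry1",
        data, groups=data["donor_id"]).fit(reml=True)
    assert res.effect("diagnosis[case]").estimate == pytest.approx(
        sm_fit.params["C(diagnosis, Treatment('control'))[T.case]"], abs=1e-4)
    assert res.effect("intercept").estimate == pytest.approx(
        sm_fit.params["Intercept"], abs=1e-4)
    assert res.sigma2_donor == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), abs=1e-3)


def test_zero_donor_variance_collapses_to_ols():
    """With no between-donor variation the REML fit sits on the boundary:
    coefficients equal OLS and the Satterthwaite df equal the residual df."""
    rng = np.random.default_rng(8)
    rows = []
    for d in range(12):
        diag = "case" if d < 6 else "control"
        e = rng.normal()
        for cell, sign in (("neuronal", 1.0), ("non_neuronal", -1.0)):
            # residuals cancel within donor: donor means carry no extra variance
            rows.append(dict(donor_id=f"D{d}", diagnosis=diag, cell_type=cell,
                             sex="unknown", count_all=0.5 * (diag == "case") + sign * e))
    table = pd.DataFrame(rows)
    res = fit_burden_lmm(table)
    assert res.singular
    X, names = design_matrix(table)
    beta_ols = np.linalg.lstsq(X, table["count_all"].to_numpy(), rcond=None)[0]
    for j, name in enumerate(names):
        assert res.effect(name).estimate == pytest.approx(beta_ols[j], abs=1e-6)
        assert res.effect(name).df == pytest.approx(len(table) - len(names), abs=1e-3)


def test_satterthwaite_df_bounded_and_monotone_toward_ols():
    """df stays in (0, n-p] and, across fits on the same balanced design,
    smaller estimated donor variance always means df closer to the OLS
    residual df."""
    rng = np.random.default_rng(21)
    base = simulate_burden_table(rng, n_donors=20, donor_sd=1.0)
    noise = rng.normal(size=len(base))
    fits = []
    for scale in (1.0, 0.5, 0.2, 0.0):
        t = base.copy()
        donor_effect = t.groupby("donor_id")["count_all"].transform("mean")
        t["count_all"] = scale * donor_effect + noise
        res = fit_burden_lmm(t)
        eff = res.effect("diagnosis[case]")
        n_p = res.n_obs - len(res.design_columns)
        assert 0 < eff.df <= n_p + 1e-9
        fits.append((res.sigma2_donor / res.sigma2_resid, eff.df))
    fits.sort()  # ascending variance ratio
    dfs = [df for _, df in fits]
    assert all(dfs[i] >= dfs[i + 1] - 1e-6 for i in range(len(dfs) - 1))


def test_lmm_requires_two_donors_per_group():
    rng = np.random.default_rng(0)
    t = simulate_burden_table(rng, n_donors=4)
    t = t[t["donor_id"] != "D000"]
    t = t[t["donor_id"] != "D001"]
    with pytest.raises(ValueError, match="case"):
        fit_burden_lmm(t)


def test_poisson_glmm_flag_runs():
    rng = np.random.default_rng(3)
    t = simulate_burden_table(rng, n_donors=20, donor_sd=0.3, delta=1.0)
    t["count_all"] = np.round(np.exp(0.2 * t["count_all"])).astype(int)
    fit = burden_stats.fit_burden_poisson_glmm(t)
    assert np.isfinite(fit.params).all()


# ---------------------------------------------------------------------------
# VAF statistics


def _mini_variants(case_vafs, control_vafs):
    out = []
    for i, (diag, vafs) in enumerate((("case", case_vafs),
                                      ("control", control_vafs))):
        for j, vaf in enumerate(vafs):
            c = CandidateVariant(chrom="1", pos=100 + 20 * (10 * i + j),
                                 ref_allele="C", alt_allele="T",
                                 specimen_id=f"{diag}{j}")
            c.extras.update(diagnosis=diag, vaf=vaf, tissue="neuronal")
            out.append(c)
    return out


def test_vaf_group_test_on_published_table(table1_cohort):
    _, _, candidates = table1_cohort
    for c in candidates:
        c.extras["diagnosis"] = ("case" if c.extras["donor_id"].startswith("S")
                                 else "control")
    t, p, means = vaf_group_test(candidates)
    assert abs(means["case"] - means["control"]) < 0.01  # < 1 percentage point
    assert p > 0.05


def test_vaf_group_test_degenerate_and_separated():
    t, p, _ = vaf_group_test(_mini_variants([0.05, 0.05], [0.05, 0.05]))
    assert (t, p) == (0.0, 1.0)
    t, p, _ = vaf_group_test(_mini_variants([0.10] * 10, [0.02] * 10))
    assert p < 1e-6
    with pytest.raises(ValueError):
        vaf_group_test(_mini_variants([0.1], [0.02, 0.03]))


def test_summarize_vaf():
    mean, lo, hi = summarize_vaf(_mini_variants([0.02], [0.06]))
    assert (mean, lo, hi) == (0.04, 0.02, 0.06)
    mean, lo, hi = summarize_vaf(_mini_variants([0.05], []))
    assert (mean, lo, hi) == (0.05, 0.05, 0.05)
    with pytest.raises(ValueError):
        summarize_vaf([])
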