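"""Mutational-burden tables and the case/control mixed-effects test.

The burden model is a Gaussian linear mixed-effects regression of the
per-specimen somatic SNV count on diagnosis, cell type, their interaction,
sex and ancestry covariates (fixed effects), with a random intercept per
donor, fit by REML.  Each fixed effect is tested with a t statistic whose
degrees of freedom come from the Satterthwaite approximation: for a
contrast c,

    df = 2 * var(c'beta)^2 / Var[var(c'beta)],

where the denominator is the delta-method variance of the estimated
contrast variance under the REML variance-component covariance.

The single-random-intercept structure admits a robust one-dimensional fit:
Z Z' is eigendecomposed once, making the profiled REML criterion O(n) per
variance-ratio value; the ratio is profiled on a log grid and refined by
bounded scalar minimization, with the zero-variance boundary handled
explicitly (the model then collapses to OLS and df to the residual df).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_model import (
    BRAIN_TISSUES,
    NS_LOF_CLASSES,
    CandidateVariant,
    Donor,
    Specimen,
)


# ---------------------------------------------------------------------------
# burden tables and rates


def build_burden_table(survivors: Sequence[CandidateVariant],
                       specimens: Sequence[Specimen],
                       donors: Sequence[Donor]) -> pd.DataFrame:
    """One row per included brain specimen with per-class variant counts.

    Reference and excluded specimens are omitted; ``count_all`` counts every
    surviving variant in the specimen, ``count_ns_lof`` only those annotated
    non-synonymous or loss-of-function.
    """
    donor_by_id = {d.donor_id: d for d in donors}
    included = [s for s in specimens
                if s.tissue in BRAIN_TISSUES and not s.excluded]
    valid_ids = {s.specimen_id for s in included}
    all_ids = {s.specimen_id for s in specimens}
    counts_all: dict[str, int] = {s.specimen_id: 0 for s in included}
    counts_nslof: dict[str, int] = {s.specimen_id: 0 for s in included}
    for v in survivors:
        if v.specimen_id not in all_ids:
            raise ValueError(f"survivor references unknown specimen {v.specimen_id!r}")
        if v.specimen_id not in valid_ids:
            continue  # excluded or reference specimen
        counts_all[v.specimen_id] += 1
        if v.functional_class in NS_LOF_CLASSES:
            counts_nslof[v.specimen_id] += 1
    rows = []
    n_anc = max((len(d.ancestry_covariates) for d in donors), default=0)
    for s in included:
        d = donor_by_id[s.donor_id]
        row = {"specimen_id": s.specimen_id, "donor_id": d.donor_id,
               "diagnosis": d.diagnosis, "cell_type": s.tissue, "sex": d.sex,
               "count_all": counts_all[s.specimen_id],
               "count_ns_lof": counts_nslof[s.specimen_id]}
        for i in range(n_anc):
            row[f"ancestry{i + 1}"] = (d.ancestry_covariates[i]
                                       if i < len(d.ancestry_covariates) else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def group_rate(table: pd.DataFrame, group: str, class_filter: str = "all") -> float:
    """Somatic variants per donor in one diagnosis group."""
    col = {"all": "count_all", "ns_lof": "count_ns_lof"}[class_filter]
    sub = table[table["diagnosis"] == group]
    n_donors = sub["donor_id"].nunique()
    if n_donors == 0:
        raise ValueError(f"no donors in group {group!r}")
    return float(sub[col].sum()) / n_donors


# ---------------------------------------------------------------------------
# REML random-intercept LMM with Satterthwaite df


@dataclass
class FixedEffect:
    name: str
    estimate: float
    se: float
    df: float
    t_stat: float
    p_value: float


@dataclass
class LmmResult:
    effects: list[FixedEffect]
    sigma2_donor: float
    sigma2_resid: float
    converged: bool
    singular: bool
    reml_loglik: float
    n_obs: int
    n_donors: int
    design_columns: list[str] = field(default_factory=list)

    def effect(self, name: str) -> FixedEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"term": e.name, "estimate": e.estimate, "se": e.se,
                              "df": e.df, "t": e.t_stat, "p": e.p_value}
                             for e in self.effects])


def design_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept, diagnosis, cell type, sex, ancestry,
    diagnosis x cell type.  Constant columns (e.g. single-sex cohorts) are
    dropped so the matrix stays full rank."""
    diag = (table["diagnosis"] == "case").to_numpy(float)
    cell = (table["cell_type"] == "neuronal").to_numpy(float)
    cols: list[tuple[str, np.ndarray]] = [
        ("intercept", np.ones(len(table))),
        ("diagnosis[case]", diag),
        ("cell_type[neuronal]", cell),
    ]
    if "sex" in table.columns and table["sex"].nunique() > 1:
        cols.append(("sex[male]", (table["sex"] == "male").to_numpy(float)))
    for c in sorted(c for c in table.columns if c.startswith("ancestry")):
        if table[c].nunique() > 1:
            cols.append((c, table[c].to_numpy(float)))
    cols.append(("diagnosis[case]:cell_type[neuronal]", diag * cell))
    names = [n for n, v in cols if np.ptp(v) > 0 or n == "intercept"]
    X = np.column_stack([v for n, v in cols if n in names])
    return X, names


class _RemlProblem:
    """Profiled REML machinery in the eigenbasis of Z Z'."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        codes, uniques = pd.factorize(groups)
        Z = np.zeros((self.n, len(uniques)))
        Z[np.arange(self.n), codes] = 1.0
        d, U = np.linalg.eigh(Z @ Z.T)
        self.d = np.clip(d, 0.0, None)
        self.Xt = U.T @ X
        self.yt = U.T @ y
        self.n_groups = len(uniques)

    def _gls(self, v: np.ndarray):
        w = 1.0 / v
        Xw = self.Xt * w[:, None]
        XtWX = self.Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ self.yt)
        resid = self.yt - self.Xt @ beta
        return beta, resid, XtWX, w

    def profiled_neg2reml(self, gamma: float) -> float:
        # -2 l_R(gamma) with sigma2_resid profiled out: for V = s2 (I + g ZZ'),
        # ln|V| + ln|X'V^-1 X| collapses to (n-p) ln s2 + ln|V0| + ln|X'V0^-1 X|
        v = 1.0 + gamma * self.d
        beta, resid, XtWX, w = self._gls(v)
        rss = float(resid @ (w * resid))
        s2 = rss / (self.n - self.p)
        sign, logdet = np.linalg.slogdet(XtWX)
        return ((self.n - self.p) * (np.log(2 * np.pi * s2) + 1.0)
                + float(np.log(v).sum()) + logdet)

    def neg2reml(self, theta: np.ndarray) -> float:
        """-2 REML log-likelihood at theta = (sigma2_donor, sigma2_resid)."""
        v = theta[1] + theta[0] * self.d
        if (v <= 0).any():
            return np.inf
        beta, resid, XtWX, w = self._gls(v)
        sign, logdet = np.linalg.slogdet(XtWX)
        return (float(np.log(v).sum()) + logdet + float(resid @ (w * resid))
                + (self.n - self.p) * np.log(2 * np.pi))

    def contrast_variances(self, theta: np.ndarray) -> np.ndarray:
        """Diagonal of (X' V^-1 X)^-1 at theta."""
        v = theta[1] + theta[0] * self.d
        w = 1.0 / v
        XtWX = self.Xt.T @ (self.Xt * w[:, None])
        return np.diag(np.linalg.inv(XtWX)).copy()

    def fit(self) -> tuple[np.ndarray, np.ndarray, float, bool]:
        """Return (theta, beta, -2 reml loglik, boundary_flag)."""
        log_grid = np.linspace(-8, 8, 65)
        vals = [self.profiled_neg2reml(np.exp(g)) for g in log_grid]
        vals0 = self.profiled_neg2reml(0.0)
        i_best = int(np.argmin(vals))
        if vals0 <= vals[i_best]:
            gamma = 0.0
        else:
            lo = log_grid[max(i_best - 1, 0)]
            hi = log_grid[min(i_best + 1, len(log_grid) - 1)]
            res = optimize.minimize_scalar(
                lambda g: self.profiled_neg2reml(np.exp(g)),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10})
            gamma = float(np.exp(res.x))
            if self.profiled_neg2reml(0.0) <= res.fun:
                gamma = 0.0
        v = 1.0 + gamma * self.d
        beta, resid, XtWX, w = self._gls(v)
        s2 = float(resid @ (w * resid)) / (self.n - self.p)
        theta = np.array([gamma * s2, s2])
        return theta, beta, self.neg2reml(theta), gamma == 0.0


def _numeric_grad(f, x: np.ndarray, rel: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        h = rel * max(abs(x[i]), 1e-8)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 0.0) if i == 0 else xm[i] - h
        g[i] = (f(xp) - f(xm)) / (xp[i] - xm[i])
    return g


def _numeric_hess(f, x: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    h = np.array([rel * max(abs(xi), 1e-8) for xi in x])
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = ((f(xpp) - f(xpm) - f(xmp) + f(xmm))
                                     / (4 * h[i] * h[j]))
    return H


def fit_burden_lmm(table: pd.DataFrame, response: str = "count_all") -> LmmResult:
    """Fit the Gaussian random-intercept burden model by REML.

    Returns estimates, standard errors, Satterthwaite degrees of freedom
    and two-sided p values for every fixed effect, plus the two variance
    components.  A zero donor variance is reported as a (flagged) boundary
    fit for which the Satterthwaite df reduce to the OLS residual df.
    """
    for group in ("case", "control"):
        if table.loc[table["diagnosis"] == group, "donor_id"].nunique() < 2:
            raise ValueError(f"need >= 2 donors in group {group!r}")
    y = table[response].to_numpy(float)
    X, names = design_matrix(table)
    if len(table) <= X.shape[1]:
        raise ValueError(f"need more observations ({len(table)}) than fixed "
                         f"effects ({X.shape[1]}) to fit the burden model")
    groups = table["donor_id"].to_numpy()
    prob = _RemlProblem(X, y, groups)
    theta, beta, neg2ll, singular = prob.fit()
    n, p = prob.n, prob.p
    ols_df = float(n - p)
    contrast_var = prob.contrast_variances(theta)

    if singular or theta[0] <= 1e-12 * max(theta[1], 1.0):
        dfs = np.full(p, ols_df)
    else:
        H = _numeric_hess(lambda t: 0.5 * prob.neg2reml(t), theta)
        try:
            A = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            A = np.linalg.pinv(H)
        dfs = np.empty(p)
        for j in range(p):
            g = _numeric_grad(lambda t, j=j: prob.contrast_variances(t)[j], theta)
            denom = float(g @ A @ g)
            v = contrast_var[j]
            dfs[j] = 2.0 * v * v / denom if denom > 0 else ols_df
        dfs = np.clip(dfs, 1e-6, ols_df)

    effects = []
    for j, name in enumerate(names):
        se = float(np.sqrt(contrast_var[j]))
        t = float(beta[j] / se) if se > 0 else 0.0
        pval = float(2.0 * stats.t.sf(abs(t), dfs[j]))
        effects.append(FixedEffect(name, float(beta[j]), se, float(dfs[j]), t, pval))
    return LmmResult(effects=effects, sigma2_donor=float(theta[0]),
                     sigma2_resid=float(theta[1]), converged=True,
                     singular=bool(singular or theta[0] <= 1e-12),
                     reml_loglik=-0.5 * neg2ll, n_obs=n,
                     n_donors=prob.n_groups, design_columns=names)


def fit_burden_poisson_glmm(table: pd.DataFrame, response: str = "count_all"):
    """Poisson GLMM sensitivity check (variational Bayes, statsmodels).

    Offered as an alternative likelihood for count responses; the Gaussian
    REML model remains the default.  Returns the fitted
    ``PoissonBayesMixedGLM`` results object.
    """
    from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

    X, names = design_matrix(table)
    y = table[response].to_numpy(float)
    codes, uniques = pd.factorize(table["donor_id"].to_numpy())
    Z = np.zeros((len(table), len(uniques)))
    Z[np.arange(len(table)), codes] = 1.0
    ident = np.zeros(len(uniques), dtype=int)  # one shared donor-variance parameter
    model = PoissonBayesMixedGLM(y, X, Z, ident)
    return model.fit_vb()


# ---------------------------------------------------------------------------
# VAF comparisons


def _vaf_arrays(survivors: Sequence[CandidateVariant],
                diagnosis_of: dict[str, str] | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    cases, controls = [], []
    for v in survivors:
        diag = v.extras.get("diagnosis")
        if diag is None and diagnosis_of is not None:
            donor = v.extras.get("donor_id")
            diag = diagnosis_of.get(donor)
        if diag == "case":
            cases.append(v.vaf)
        elif diag == "control":
            controls.append(v.vaf)
    return np.asarray(cases), np.asarray(controls)


def vaf_group_test(survivors: Sequence[CandidateVariant],
                   diagnosis_of: dict[str, str] | None = None
                   ) -> tuple[float, float, dict[str, float]]:
    """Welch two-sample t test of per-variant VAF, cases vs controls."""
    x, y = _vaf_arrays(survivors, diagnosis_of)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 VAF observations per group")
    means = {"case": float(x.mean()), "control": float(y.mean())}
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if means["case"] == means["control"]:
            return 0.0, 1.0, means
        return float(np.inf if means["case"] > means["control"] else -np.inf), 0.0, means
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p), means


def summarize_vaf(survivors: Sequence[CandidateVariant]) -> tuple[float, float, float]:
    """(mean, min, max) VAF over surviving variants, as fractions."""
    vafs = [v.vaf for v in survivors]
    if not vafs:
        raise ValueError("no survivors to summarize")
    return float(np.mean(vafs)), float(min(vafs)), float(max(vafs))
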