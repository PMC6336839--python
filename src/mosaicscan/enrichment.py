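"""Case/control gene-set mutation enrichment (MEGA-V-style).

For each gene set, every donor contributes the number of their somatic
variants falling in set genes (both brain specimens pooled); the case and
control count distributions are compared by a Wilcoxon rank-sum test
(exact, tie-aware enumeration when the pooled sample is small), p values
are Benjamini-Hochberg adjusted across the tested family, stability is
assessed by a donor-level bootstrap, and effect size is a 2x2 odds ratio
over unique affected genes with the Haldane-Anscombe 0.5 correction when a
cell is zero.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CandidateVariant, Donor, GeneSetCollection

EXACT_MAX_N = 20  # pooled-sample bound for the exact enumeration path


# ---------------------------------------------------------------------------
# per-individual counts


def per_individual_set_counts(survivors: Sequence[CandidateVariant],
                              gene_set: frozenset[str] | set[str],
                              donors: Sequence[Donor],
                              diagnosis_of: Mapping[str, str] | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-donor counts of somatic variants in set genes (cases, controls).

    Counts are variants, not unique genes; a donor's neuronal and
    non-neuronal variants are pooled.
    """
    diag = dict(diagnosis_of or {})
    for d in donors:
        diag.setdefault(d.donor_id, d.diagnosis)
    counts: dict[str, int] = {d.donor_id: 0 for d in donors}
    for v in survivors:
        donor = v.extras.get("donor_id")
        if donor is None or donor not in counts:
            raise ValueError(f"survivor {v.candidate_id} has unknown donor {donor!r}")
        if v.gene is not None and v.gene in gene_set:
            counts[donor] += 1
    cases = np.array([counts[d.donor_id] for d in donors if diag[d.donor_id] == "case"])
    controls = np.array([counts[d.donor_id] for d in donors
                         if diag[d.donor_id] == "control"])
    return cases, controls


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


@lru_cache(maxsize=8)
def _combo_matrix(n_x: int, n_total: int) -> np.ndarray:
    idx = np.fromiter((i for combo in combinations(range(n_total), n_x) for i in combo),
                      dtype=np.int64)
    return idx.reshape(-1, n_x)


def _exact_tail_probs(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(P[W >= obs], P[W <= obs]) for the x-group midrank sum under
    exchangeability, by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks handle ties
    n_x, n = len(x), len(pooled)
    combos = _combo_matrix(n_x, n)
    w_all = ranks[combos].sum(axis=1)
    w_obs = ranks[:n_x].sum()
    greater = float(np.mean(w_all >= w_obs - 1e-9))
    less = float(np.mean(w_all <= w_obs + 1e-9))
    return greater, less


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p value comparing two samples.

    Exact tie-aware permutation enumeration when n_x + n_y <= 20; otherwise
    the tie-corrected normal approximation with continuity correction.
    ``alternative`` refers to the first sample: "greater" tests whether x
    tends larger than y.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if len(x) + len(y) <= EXACT_MAX_N:
        greater, less = _exact_tail_probs(x, y)
        if alternative == "greater":
            return greater
        if alternative == "less":
            return less
        return min(1.0, 2.0 * min(greater, less))
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# bootstrap stability


def bootstrap_success(x: Sequence[float], y: Sequence[float], B: int = 1000,
                      alpha: float = 0.05, seed: int = 0,
                      alternative: str = "two-sided") -> float:
    """Percent of donor-resampled replicates with Wilcoxon p < alpha.

    Each cohort is resampled with replacement independently; exact p values
    are memoized on the resampled multisets, which repeat heavily for
    sparse integer counts.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if B < 100:
        raise ValueError("B must be >= 100")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("bootstrap needs >= 2 donors per cohort")
    rng = np.random.default_rng(seed)
    cache: dict[tuple, float] = {}
    successes = 0
    for _ in range(B):
        xs = np.sort(rng.choice(x, size=len(x), replace=True))
        ys = np.sort(rng.choice(y, size=len(y), replace=True))
        key = (tuple(xs), tuple(ys))
        p = cache.get(key)
        if p is None:
            p = wilcoxon_rank_sum(xs, ys, alternative=alternative)
            cache[key] = p
        if p < alpha:
            successes += 1
    return 100.0 * successes / B


# ---------------------------------------------------------------------------
# odds ratio


def haldane_anscombe_or(a: int, b: int, c: int, d: int) -> float:
    """Odds ratio for the 2x2 table [[a, b], [c, d]].

    The plain cross-ratio when every cell is positive; with any zero cell,
    0.5 is added to all four cells (Haldane-Anscombe) first.
    """
    cells = (a, b, c, d)
    if any(v < 0 for v in cells):
        raise ValueError("cell counts must be >= 0")
    if 0 in cells:
        a, b, c, d = (v + 0.5 for v in cells)
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# driver


@dataclass
class EnrichmentResult:
    set_name: str
    p_value: float
    fdr: float
    bootstrap_success: float
    set_size: int
    overlap_case: int
    overlap_control: int
    odds_ratio: float
    case_genes: tuple[str, ...]
    control_genes: tuple[str, ...]
    significant: bool

    def __post_init__(self) -> None:
        if not (self.overlap_case <= self.set_size
                and self.overlap_control <= self.set_size):
            raise ValueError("overlap cannot exceed set size")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if self.fdr < self.p_value - 1e-12:
            raise ValueError("BH-adjusted p cannot be smaller than raw p")


def run_enrichment(survivors: Sequence[CandidateVariant], sets: GeneSetCollection,
                   donors: Sequence[Donor], mode: str = "hypothesis_driven",
                   B: int = 1000, seed: int = 0, alpha: float = 0.05,
                   alternative: str = "two-sided",
                   fdr_threshold: float = 0.1,
                   success_threshold: float = 99.0,
                   size_range: tuple[int, int] = (100, 1000)
                   ) -> list[EnrichmentResult]:
    """Full enrichment pass over a gene-set collection.

    In ``hypothesis_free`` mode, sets outside ``size_range`` genes are
    dropped before testing.  BH adjustment runs across the retained family;
    the odds ratio contrasts unique affected genes in vs out of the set,
    with each cohort's universe its own unique affected genes.  Sets with
    FDR <= ``fdr_threshold`` and bootstrap success > ``success_threshold``
    are flagged significant.
    """
    if mode not in ("hypothesis_driven", "hypothesis_free"):
        raise ValueError(f"unknown mode {mode!r}")
    if not any(v.gene for v in survivors):
        raise ValueError("survivors carry no gene annotations")
    collection = (sets.filtered_by_size(*size_range)
                  if mode == "hypothesis_free" else sets)
    if len(collection) == 0:
        raise ValueError("no gene sets retained for testing")

    diag = {d.donor_id: d.diagnosis for d in donors}
    case_gene_universe = sorted({v.gene for v in survivors
                                 if v.gene and diag.get(v.extras.get("donor_id")) == "case"})
    control_gene_universe = sorted({v.gene for v in survivors
                                    if v.gene and diag.get(v.extras.get("donor_id")) == "control"})

    names = sorted(collection.sets)
    raw_p, payload = [], []
    for name in names:
        genes = collection.sets[name]
        x, y = per_individual_set_counts(survivors, genes, donors)
        p = wilcoxon_rank_sum(x, y, alternative=alternative) if (x.any() or y.any()) else 1.0
        raw_p.append(p)
        payload.append((name, genes, x, y))
    fdrs = bh_adjust(raw_p)

    results = []
    for (name, genes, x, y), p, fdr in zip(payload, raw_p, fdrs):
        case_hits = tuple(g for g in case_gene_universe if g in genes)
        control_hits = tuple(g for g in control_gene_universe if g in genes)
        a = len(case_hits)
        b = len(case_gene_universe) - a
        c = len(control_hits)
        d = len(control_gene_universe) - c
        orr = haldane_anscombe_or(a, b, c, d)
        success = bootstrap_success(x, y, B=B, alpha=alpha, seed=seed,
                                    alternative=alternative)
        results.append(EnrichmentResult(
            set_name=name, p_value=float(p), fdr=float(fdr),
            bootstrap_success=success, set_size=len(genes),
            overlap_case=a, overlap_control=c, odds_ratio=float(orr),
            case_genes=case_hits, control_genes=control_hits,
            significant=bool(fdr <= fdr_threshold and success > success_threshold)))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_set": r.set_name, "p_value": r.p_value, "fdr": r.fdr,
        "success_rate_percent": r.bootstrap_success, "set_size": r.set_size,
        "overlap_case": r.overlap_case, "overlap_control": r.overlap_control,
        "odds_ratio": r.odds_ratio,
        "case_genes": ";".join(r.case_genes) or "NA",
        "significant": r.significant,
    } for r in results])
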