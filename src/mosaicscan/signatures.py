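"""Trinucleotide-context mutation spectra and NMF signature extraction.

Substitutions are collapsed onto the pyrimidine strand and classified into
the canonical 96 channels: 6 substitution classes (C>A, C>G, C>T, T>A, T>C,
T>G) x 16 flanking-base pairs, ordered A<C<G<T on each flank.  Signatures
are extracted by maximum-likelihood nonnegative matrix factorization under
a Poisson observation model (multiplicative KL updates, multiple random
restarts), with the number of signatures chosen by BIC.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.special import gammaln

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITIONS = ({"A", "G"}, {"C", "T"})
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"

#: canonical channel labels, e.g. "A[C>A]A" ... "T[T>G]T"
CHANNEL_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _FLANKS
    for three in _FLANKS
)


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError:
        raise ValueError(f"non-ACGT base in {seq!r}") from None


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as transition or transversion."""
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"invalid bases {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    return "transition" if {ref, alt} in _TRANSITIONS else "transversion"


def titv_ratio(variants: Iterable) -> float:
    """Transition/transversion ratio over (ref, alt) pairs or variant objects.

    Returns ``inf`` when every substitution is a transition; raises on empty
    input.
    """
    n_ti = n_tv = 0
    for v in variants:
        ref, alt = (v.ref_allele, v.alt_allele) if hasattr(v, "ref_allele") else (v[0], v[1])
        if classify_substitution(ref, alt) == "transition":
            n_ti += 1
        else:
            n_tv += 1
    if n_ti + n_tv == 0:
        raise ValueError("no substitutions supplied")
    return float("inf") if n_tv == 0 else n_ti / n_tv


def context_channel(ref: str, alt: str, context: str) -> int:
    """Map a substitution with its 3-base context to its channel index (0..95).

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand first (strand symmetry).
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    classify_substitution(ref, alt)  # validates bases
    if ref in "AG":
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], reverse_complement(context)
    sub = SUBSTITUTION_CLASSES.index(f"{ref}>{alt}")
    return sub * 16 + _FLANKS.index(context[0]) * 4 + _FLANKS.index(context[2])


def channel_label(index: int) -> str:
    return CHANNEL_LABELS[index]


@dataclass
class ContextMatrix:
    """96 x G matrix of per-group mutation counts over the canonical channels."""

    counts: np.ndarray
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96, len(self.groups)):
            raise ValueError(f"counts must be 96 x {len(self.groups)}, "
                             f"got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CHANNEL_LABELS),
                            columns=list(self.groups))


def build_context_matrix(variants: Iterable, group_of) -> ContextMatrix:
    """Tally variants (with ref/alt/context annotations) into group columns.

    ``group_of`` maps a variant to its column label (e.g. diagnosis).
    Variants without a trinucleotide context are skipped.
    """
    tallies: dict[str, np.ndarray] = {}
    for v in variants:
        ctx = getattr(v, "trinucleotide_context", None)
        if ctx is None:
            continue
        g = group_of(v)
        col = tallies.setdefault(g, np.zeros(96, dtype=np.int64))
        col[context_channel(v.ref_allele, v.alt_allele, ctx)] += 1
    groups = tuple(sorted(tallies))
    counts = (np.stack([tallies[g] for g in groups], axis=1)
              if groups else np.zeros((96, 0), dtype=np.int64))
    return ContextMatrix(counts, groups)


# ---------------------------------------------------------------------------
# KL-NMF


@dataclass
class SignatureModel:
    P: np.ndarray                       # 96 x k, column-stochastic profiles
    E: np.ndarray                       # k x G, non-negative exposures
    k: int
    groups: tuple[str, ...]
    kl_divergence: float
    log_likelihood: float
    bic: float
    bic_by_k: dict[int, float] = field(default_factory=dict)
    kl_history: np.ndarray | None = None

    def profiles_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=list(CHANNEL_LABELS),
                            columns=[f"signature_{i + 1}" for i in range(self.k)])

    def exposures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.E, columns=list(self.groups),
                            index=[f"signature_{i + 1}" for i in range(self.k)])

    def class_mass(self, substitution_class: str) -> np.ndarray:
        """Per-signature probability mass on one substitution class."""
        i = SUBSTITUTION_CLASSES.index(substitution_class)
        return self.P[i * 16:(i + 1) * 16].sum(axis=0)


_EPS = 1e-12


def _kl_divergence(X: np.ndarray, M: np.ndarray) -> float:
    mask = X > 0
    return float((X[mask] * np.log(X[mask] / M[mask])).sum() - X.sum() + M.sum())


def _kl_nmf(X: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int = 5000, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF minimizing generalized KL divergence."""
    n, g = X.shape
    scale = X.mean() or 1.0
    P = rng.uniform(0.5, 1.5, size=(n, k)) * np.sqrt(scale / k)
    E = rng.uniform(0.5, 1.5, size=(k, g)) * np.sqrt(scale / k)
    history = []
    prev = np.inf
    for _ in range(max_iter):
        M = P @ E + _EPS
        P *= (X / M) @ E.T / np.maximum(E.sum(axis=1), _EPS)
        M = P @ E + _EPS
        E *= P.T @ (X / M) / np.maximum(P.sum(axis=0), _EPS)[:, None]
        kl = _kl_divergence(X, P @ E + _EPS)
        history.append(kl)
        if kl > prev + 1e-9 * max(abs(prev), 1.0):
            raise RuntimeError("KL divergence increased during multiplicative updates")
        if prev - kl < tol * max(abs(prev), 1.0):
            break
        prev = kl
    return P, E, np.array(history)


def _poisson_loglik(X: np.ndarray, M: np.ndarray) -> float:
    M = M + _EPS
    return float((X * np.log(M) - M - gammaln(X + 1)).sum())


def extract_signatures(matrix: ContextMatrix, k_range: Sequence[int] = (1, 2, 3, 4),
                       n_restarts: int = 20, seed: int = 0,
                       max_iter: int = 5000, tol: float = 1e-8) -> SignatureModel:
    """Fit KL-NMF over a range of ranks and return the BIC-selected model.

    BIC = -2 logLik + (96 k + k G - k) ln(N) with N the total mutation
    count; the smallest rank within one BIC unit of the minimum is chosen
    (parsimony tie-break).  ``n_restarts`` random initializations are run
    per rank and the best by likelihood kept.
    """
    X = np.asarray(matrix.counts, dtype=float)
    g = X.shape[1]
    if g == 0 or X.sum() == 0:
        raise ValueError("context matrix has no mutations")
    if (X.sum(axis=0) == 0).any():
        raise ValueError("every group column must have at least one mutation")
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 1 or k_range[-1] > min(96, 3 * g):
        raise ValueError(f"invalid rank range {k_range} for {g} groups")
    total = X.sum()
    rng = np.random.default_rng(seed)
    fits: dict[int, tuple] = {}
    bic_by_k: dict[int, float] = {}
    for k in k_range:
        best = None
        for _ in range(n_restarts):
            P, E, hist = _kl_nmf(X, k, rng, max_iter=max_iter, tol=tol)
            ll = _poisson_loglik(X, P @ E)
            if best is None or ll > best[0]:
                best = (ll, P, E, hist)
        ll, P, E, hist = best
        n_params = 96 * k + k * g - k
        bic_by_k[k] = -2.0 * ll + n_params * np.log(total)
        fits[k] = (ll, P, E, hist)
    best_bic = min(bic_by_k.values())
    k_sel = min(k for k, b in bic_by_k.items() if b <= best_bic + 1.0)
    ll, P, E, hist = fits[k_sel]
    col_sums = np.maximum(P.sum(axis=0), _EPS)
    P = P / col_sums
    E = E * col_sums[:, None]
    return SignatureModel(P=P, E=E, k=k_sel, groups=matrix.groups,
                          kl_divergence=_kl_divergence(X, P @ E + _EPS),
                          log_likelihood=ll, bic=bic_by_k[k_sel],
                          bic_by_k=bic_by_k, kl_history=hist)


# ---------------------------------------------------------------------------
# clustering against a reference catalog


@dataclass
class CatalogClustering:
    labels: list[str]
    linkage_matrix: np.ndarray
    nearest: pd.DataFrame  # extracted signature -> nearest catalog member(s)

    def to_newick(self) -> str:
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree)


def cluster_with_catalog(model: SignatureModel, catalog,
                         extra: Sequence[tuple[str, np.ndarray]] = (),
                         method: str = "average",
                         n_nearest: int = 3) -> CatalogClustering:
    """Hierarchically cluster extracted signatures with a reference catalog.

    Distance is 1 - Pearson correlation across the 96 channels; linkage is
    average by default.  ``extra`` supplies additional named 96-vector
    profiles (e.g. signatures published by other studies).
    """
    cols: list[np.ndarray] = []
    labels: list[str] = []
    n_extracted = model.k
    for i in range(model.k):
        cols.append(model.P[:, i])
        labels.append(f"extracted_{i + 1}")
    for name, profile in extra:
        profile = np.asarray(profile, dtype=float).ravel()
        if profile.shape != (96,):
            raise ValueError(f"extra profile {name!r} is not a 96-vector")
        cols.append(profile)
        labels.append(name)
    for name in catalog.names:
        cols.append(catalog.profiles[name].to_numpy())
        labels.append(name)
    mat = np.stack(cols, axis=1)
    if mat.shape[0] != 96:
        raise ValueError("all profiles must be on the 96-channel order")
    corr = np.corrcoef(mat.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(dist, checks=False), method=method)
    rows = []
    catalog_idx = [i for i, lab in enumerate(labels) if lab in set(catalog.names)]
    for i in range(n_extracted):
        order = sorted(catalog_idx, key=lambda j: (dist[i, j], labels[j]))
        for rank, j in enumerate(order[:n_nearest], 1):
            rows.append({"extracted": labels[i], "rank": rank, "reference": labels[j],
                         "correlation": corr[i, j], "distance": dist[i, j]})
    return CatalogClustering(labels=labels, linkage_matrix=Z,
                             nearest=pd.DataFrame(rows))
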