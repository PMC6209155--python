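"""HSIC relevance scoring and the permutation confidence filter (stage 1).

The Hilbert–Schmidt Independence Criterion is the squared Hilbert–Schmidt
norm of the cross-covariance operator between kernel embeddings of a
feature and a target; it is zero iff the two are independent (for
characteristic kernels such as the Gaussian).  This module scores each
feature column against a continuous body-composition target with the
biased plug-in estimator

    HSIC_b = tr(K H L H) / (n - 1)^2,      H = I - (1/n) 11^T,

where K and L are the feature and target Gram matrices, and attaches a
permutation-test p-value so that an "80 % confidence" filter translates
into keeping features with p <= 0.20.

Kernels default to Gaussian (rbf) with the median heuristic bandwidth;
scores are intended to be computed on z-scored features so bandwidths are
comparable across columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dataio import FeatureMatrix

log = logging.getLogger("biafs")

__all__ = [
    "KernelSpec", "HSICScore", "FilterResult",
    "gram_matrix", "median_bandwidth", "empirical_hsic",
    "hsic_score", "permutation_pvalue", "rank_and_filter",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice for one side of the HSIC statistic.

    ``bandwidth`` applies to rbf only: a positive number, or ``"median"``
    for the median of the non-zero pairwise absolute differences.
    """

    kind: str = "rbf"            # "rbf" | "linear"
    bandwidth: float | str = "median"

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median":
                raise ValueError(f"unknown bandwidth rule {self.bandwidth!r}")
        elif self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class HSICScore:
    """Per-feature dependence score versus the target."""

    feature_name: str
    score: float
    p_value: float | None
    rank: int


@dataclass
class FilterResult:
    """Stage-1 outcome: scores and the surviving feature set F'."""

    scores: list[HSICScore]          # ordered by rank (descending score)
    kept: list[str]                  # surviving names, descending score
    alpha: float | None
    top_k: int | None
    excluded_constant: list[str]

    def score_map(self) -> dict[str, HSICScore]:
        return {s.feature_name: s for s in self.scores}


def median_bandwidth(v: np.ndarray) -> float:
    """Median of the non-zero pairwise absolute differences of ``v``."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two values")
    d = pdist(v[:, None], metric="cityblock")
    nz = d[d > 0]
    if nz.size == 0:
        raise ValueError("constant input: no non-zero pairwise differences")
    return float(np.median(nz))


def gram_matrix(v: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel Gram matrix of a 1-D sample vector.

    rbf uses k(x, x') = exp(-(x-x')^2 / (2 sigma^2)) with unit diagonal.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two samples")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in kernel input")
    if spec.kind == "linear":
        return np.outer(v, v)
    if spec.bandwidth == "median":
        sigma = median_bandwidth(v)
    else:
        sigma = float(spec.bandwidth)
    if sigma <= 0:
        raise ValueError("rbf bandwidth must be positive")
    d2 = squareform(pdist(v[:, None], metric="sqeuclidean"))
    return np.exp(-d2 / (2.0 * sigma * sigma))


def _center(K: np.ndarray) -> np.ndarray:
    """H K H without forming H (row/column/total mean subtraction)."""
    rm = K.mean(axis=0)
    return K - rm[None, :] - K.mean(axis=1)[:, None] + rm.mean()


def empirical_hsic(K: np.ndarray, L: np.ndarray) -> float:
    """Biased plug-in HSIC estimate tr(KHLH)/(n-1)^2.

    Non-negative (up to rounding) for PSD Gram inputs, and symmetric in
    its two arguments.
    """
    K = np.asarray(K, dtype=float)
    L = np.asarray(L, dtype=float)
    if K.shape != L.shape or K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"Gram size mismatch: {K.shape} vs {L.shape}")
    n = K.shape[0]
    return float((_center(K) * _center(L)).sum() / (n - 1) ** 2)


def _feature_gram(v: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix with a constant-input fallback (bandwidth 1, warning)."""
    try:
        return gram_matrix(v, spec)
    except ValueError as err:
        if spec.kind == "rbf" and "constant input" in str(err):
            warnings.warn("constant feature under rbf median bandwidth; "
                          "falling back to bandwidth 1 (score will be 0)")
            return gram_matrix(v, KernelSpec("rbf", 1.0))
        raise


def hsic_score(
    feature: np.ndarray,
    target: np.ndarray,
    fspec: KernelSpec = KernelSpec(),
    cspec: KernelSpec = KernelSpec(),
) -> float:
    """HSIC dependence score of one feature against the target."""
    feature = np.asarray(feature, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if feature.size != target.size:
        raise ValueError("feature and target lengths differ")
    if feature.size < 4:
        raise ValueError("need at least 4 samples for a meaningful score")
    K = _feature_gram(feature, fspec)
    L = _feature_gram(target, cspec)
    return empirical_hsic(K, L)


def permutation_pvalue(
    feature: np.ndarray,
    target: np.ndarray,
    fspec: KernelSpec = KernelSpec(),
    cspec: KernelSpec = KernelSpec(),
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Permutation-test p-value for HSIC independence.

    p = (1 + #{permuted score >= observed}) / (n_perm + 1).  Permuting the
    feature's sample labels permutes both axes of its Gram matrix, so the
    Gram is built once and re-indexed per shuffle.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    feature = np.asarray(feature, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Kc = _center(_feature_gram(feature, fspec))
    Lc = _center(_feature_gram(target, cspec))
    observed = float((Kc * Lc).sum())
    tol = 1e-12 * max(1.0, abs(observed))
    n = feature.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s = float((Kc[np.ix_(perm, perm)] * Lc).sum())
        if s >= observed - tol:
            count += 1
    return (1 + count) / (n_perm + 1)


def rank_and_filter(
    fm: FeatureMatrix,
    target: np.ndarray,
    fspec: KernelSpec = KernelSpec(),
    cspec: KernelSpec = KernelSpec(),
    alpha: float = 0.20,
    top_k: int | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> FilterResult:
    """Rank features by HSIC and keep the relevant ones (stage-1 set F').

    Exactly one retention rule is active: if ``top_k`` is given the k
    best-scoring features are kept (no permutation tests run); otherwise
    features with permutation p-value <= ``alpha`` survive.  Ties in the
    ranking are broken by original column order.  Constant columns are
    excluded from scoring altogether.
    """
    target = np.asarray(target, dtype=float).ravel()
    if target.size != fm.n_samples:
        raise ValueError("target length does not match feature matrix")
    if target.std() == 0:
        raise ValueError("constant target")
    if top_k is None and not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")

    scored_idx = [j for j in range(fm.n_features) if not fm.constant_mask[j]]
    excluded = [fm.feature_names[j] for j in range(fm.n_features) if fm.constant_mask[j]]
    if not scored_idx:
        raise ValueError("no non-constant features to score")

    L = _feature_gram(target, cspec)
    Lc = _center(L)
    n = fm.n_samples

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(scored_idx))

    raw: list[tuple[int, float, float | None]] = []
    for child, j in zip(children, scored_idx):
        K = _feature_gram(fm.values[:, j], fspec)
        Kc = _center(K)
        score = float((Kc * Lc).sum() / (n - 1) ** 2)
        p = None
        if top_k is None:
            rng = np.random.default_rng(child)
            observed = float((Kc * Lc).sum())
            tol = 1e-12 * max(1.0, abs(observed))
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                if float((Kc[np.ix_(perm, perm)] * Lc).sum()) >= observed - tol:
                    count += 1
            p = (1 + count) / (n_perm + 1)
        raw.append((j, score, p))

    # descending score, stable ties by original column order
    order = sorted(range(len(raw)), key=lambda i: (-raw[i][1], raw[i][0]))
    scores = [
        HSICScore(feature_name=fm.feature_names[raw[i][0]], score=raw[i][1],
                  p_value=raw[i][2], rank=r + 1)
        for r, i in enumerate(order)
    ]
    if top_k is not None:
        if not (1 <= top_k <= len(scores)):
            raise ValueError(f"top_k must be in 1..{len(scores)}")
        kept = [s.feature_name for s in scores[:top_k]]
    else:
        kept = [s.feature_name for s in scores if s.p_value is not None and s.p_value <= alpha]
    if not kept:
        raise ValueError("no features survive the filter; increase alpha or use top_k")
    return FilterResult(scores=scores, kept=kept,
                        alpha=None if top_k is not None else alpha,
                        top_k=top_k, excluded_constant=excluded)


def scores_to_frame(result: FilterResult):
    """Scores as a DataFrame (feature_name, hsic, p_value, rank, kept)."""
    import pandas as pd

    kept = set(result.kept)
    return pd.DataFrame(
        {
            "feature_name": [s.feature_name for s in result.scores],
            "hsic": [s.score for s in result.scores],
            "p_value": [s.p_value for s in result.scores],
            "rank": [s.rank for s in result.scores],
            "kept": [s.feature_name in kept for s in result.scores],
        }
    )
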