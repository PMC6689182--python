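"""Multipart OLS, BIC forward selection, bootstrap CIs and collinearity.

A "multipart" model fits an independent OLS (own intercept and coefficients)
to each group of genes, pools the predictions, and reports a single R^2
computed from pooled observed/predicted responses; that pooled R^2 equals the
squared Pearson correlation between observation and prediction.

BIC uses the Gaussian form ``n * ln(RSS_pooled / n) + k_total * ln(n)`` where
``k_total`` counts every fitted parameter across parts (intercepts included).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fold_features import FeatureMatrix

logger = logging.getLogger(__name__)


class UndersizedPartError(ValueError):
    """A regression part has too few genes for its number of features."""


@dataclass
class FitResult:
    selected_features: list[str]
    per_part_coefficients: dict[str, tuple[float, np.ndarray]]
    r2: float
    n_genes: int
    bic: float
    bootstrap_ci: tuple[float, float] | None = None
    predictions: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class OverlapResult:
    r2_a: float
    r2_b: float
    r2_ab: float
    overlap_pct: float | None  # None when undefined (r2_a or r2_b <= 0)


def _part_indices(part_labels: Sequence[str]) -> dict[str, np.ndarray]:
    labels = np.asarray(part_labels)
    return {p: np.flatnonzero(labels == p) for p in sorted(set(labels))}


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit with intercept; returns (coefs incl. intercept, yhat)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("rank-deficient design; aliased columns effectively dropped", stacklevel=3)
    return beta, A @ beta


def fit_multipart(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    parts: Sequence[str],
    feature_names: Sequence[str] | None = None,
) -> FitResult:
    """Independent per-part OLS with pooled predictions and pooled R^2."""
    if isinstance(X, FeatureMatrix):
        feature_names = X.feature_names
        Xm = X.design()
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        feature_names = list(feature_names or [f"x{i}" for i in range(Xm.shape[1])])
    y = np.asarray(y, dtype=float)
    n, k = Xm.shape
    groups = _part_indices(parts)
    yhat = np.empty(n)
    coefs: dict[str, tuple[float, np.ndarray]] = {}
    for part, idx in groups.items():
        if len(idx) <= k + 1:
            raise UndersizedPartError(
                f"part {part!r} has {len(idx)} genes for {k} features"
            )
        beta, fitted = _ols(Xm[idx], y[idx])
        coefs[part] = (float(beta[0]), beta[1:])
        yhat[idx] = fitted
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    k_total = len(groups) * (1 + k)
    bic = n * math.log(max(rss, 1e-300) / n) + k_total * math.log(n)
    return FitResult(list(feature_names), coefs, r2, n, bic, predictions=yhat)


# ---------------------------------------------------------------------------
# BIC forward selection (Gram-matrix implementation)


class _GramParts:
    """Per-part sufficient statistics for fast subset RSS evaluation."""

    def __init__(self, Xm: np.ndarray, y: np.ndarray, groups: Mapping[str, np.ndarray]):
        self.parts = []
        self.n = len(y)
        for part, idx in groups.items():
            A = np.column_stack([np.ones(len(idx)), Xm[idx]])
            self.parts.append(
                (part, len(idx), A.T @ A, A.T @ y[idx], float(y[idx] @ y[idx]))
            )

    def rss(self, cols: Sequence[int]) -> float:
        """Pooled RSS of the model using candidate columns ``cols`` (+intercepts)."""
        take = np.concatenate([[0], np.asarray(cols, dtype=int) + 1])
        total = 0.0
        for _, _, G, g, yy in self.parts:
            Gs = G[np.ix_(take, take)]
            gs = g[take]
            beta, _, _, _ = np.linalg.lstsq(Gs, gs, rcond=None)
            total += max(yy - float(beta @ gs), 0.0)
        return total

    def min_part_size(self) -> int:
        return min(sz for _, sz, _, _, _ in self.parts)


def bic_score(n: int, rss: float, k_total: int) -> float:
    return n * math.log(max(rss, 1e-300) / n) + k_total * math.log(n)


def forward_select_bic(
    candidates: FeatureMatrix,
    y: np.ndarray,
    parts: Sequence[str],
    max_features: int | None = None,
) -> FitResult:
    """Greedy forward selection minimizing pooled-Gaussian BIC.

    Starts from the intercept-only multipart model and at each step adds the
    candidate that lowers BIC the most (ties resolved toward the earliest
    column), stopping when no addition lowers BIC.
    """
    names = candidates.feature_names
    if not names:
        raise ValueError("no candidate features")
    Xm = candidates.design()
    y = np.asarray(y, dtype=float)
    groups = _part_indices(parts)
    gram = _GramParts(Xm, y, groups)
    n = len(y)
    P = len(groups)

    selected: list[int] = []
    current_bic = bic_score(n, gram.rss([]), P)
    while True:
        if max_features is not None and len(selected) >= max_features:
            break
        if len(selected) + 3 >= gram.min_part_size():
            break  # a part would become undersized
        best_j, best_bic, best_rss = None, current_bic, None
        k_next = P * (2 + len(selected))
        for j in range(len(names)):
            if j in selected:
                continue
            rss = gram.rss(selected + [j])
            b = bic_score(n, rss, k_next)
            if b < best_bic - 1e-12:
                best_j, best_bic, best_rss = j, b, rss
        if best_j is None:
            break
        selected.append(best_j)
        current_bic = best_bic
        logger.debug("BIC selection: + %s -> BIC %.3f (RSS %.4f)", names[best_j], best_bic, best_rss)

    chosen = [names[j] for j in selected]
    if chosen:
        fit = fit_multipart(candidates.select(chosen), y, parts)
    else:
        fit = fit_multipart(np.empty((n, 0)), y, parts, feature_names=[])
    fit.bic = current_bic
    return fit


def exhaustive_select_bic(
    candidates: FeatureMatrix, y: np.ndarray, parts: Sequence[str]
) -> tuple[list[str], float]:
    """Exact BIC optimum over all candidate subsets (small pools only)."""
    names = candidates.feature_names
    if len(names) > 20:
        raise ValueError("exhaustive search limited to 20 candidates")
    Xm = candidates.design()
    y = np.asarray(y, dtype=float)
    groups = _part_indices(parts)
    gram = _GramParts(Xm, y, groups)
    n, P = len(y), len(groups)
    best: tuple[float, list[int]] = (bic_score(n, gram.rss([]), P), [])
    for mask in range(1, 1 << len(names)):
        cols = [j for j in range(len(names)) if mask >> j & 1]
        if len(cols) + 3 >= gram.min_part_size():
            continue
        b = bic_score(n, gram.rss(cols), P * (1 + len(cols)))
        if b < best[0] - 1e-12:
            best = (b, cols)
    return [names[j] for j in best[1]], best[0]


# ---------------------------------------------------------------------------
# Bootstrap and collinearity


def bootstrap_r2(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    parts: Sequence[str],
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% CI of the pooled R^2 under gene resampling within parts.

    The feature set is frozen; only coefficients are refitted per resample.
    """
    Xm = X.design() if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    groups = _part_indices(parts)
    stats = np.empty(B)
    for b in range(B):
        yhat_all, yobs_all = [], []
        for _, idx in groups.items():
            take = rng.choice(idx, size=len(idx), replace=True)
            _, fitted = _ols(Xm[take], y[take])
            yhat_all.append(fitted)
            yobs_all.append(y[take])
        yo = np.concatenate(yobs_all)
        yh = np.concatenate(yhat_all)
        tss = float(np.sum((yo - yo.mean()) ** 2))
        stats[b] = 1.0 - float(np.sum((yo - yh) ** 2)) / tss if tss > 0 else 0.0
    return float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))


def collinearity_overlap(
    setA: FeatureMatrix,
    setB: FeatureMatrix,
    y: np.ndarray,
    parts: Sequence[str],
) -> OverlapResult:
    """Shared explained variance between two feature sets.

    overlap% = 100 * max((R2A + R2B - R2AB)/R2A, (R2A + R2B - R2AB)/R2B),
    clipped to [0, 100]; undefined (None) when either marginal R^2 <= 0.
    """
    r2_a = fit_multipart(setA, y, parts).r2
    r2_b = fit_multipart(setB, y, parts).r2
    r2_ab = fit_multipart(setA.join(setB), y, parts).r2
    if r2_a <= 0 or r2_b <= 0:
        return OverlapResult(r2_a, r2_b, r2_ab, None)
    shared = r2_a + r2_b - r2_ab
    pct = 100.0 * max(shared / r2_a, shared / r2_b)
    pct = min(max(pct, 0.0), 100.0 + 1e-6)
    return OverlapResult(r2_a, r2_b, r2_ab, min(pct, 100.0))


def combined_model(
    feature_sets: Mapping[str, FeatureMatrix],
    y: np.ndarray,
    parts: Sequence[str],
    bootstrap: int = 0,
    seed: int = 0,
    reselect: bool = False,
) -> tuple[FitResult, dict[str, dict[str, float]]]:
    """Fit the union of (pre-selected) feature sets as one multipart model.

    Returns the fit plus per-set contribution shares computed two ways:
    as a share of the summed univariate-set R^2 values, and as a share
    within the combined model's R^2.
    """
    sets = {k: v for k, v in feature_sets.items() if v.feature_names}
    if not sets:
        raise ValueError("no non-empty feature sets")
    union = None
    for fm in sets.values():
        union = fm if union is None else union.join(fm)
    assert union is not None
    if reselect:
        fit = forward_select_bic(union, y, parts)
    else:
        fit = fit_multipart(union, y, parts)
    if bootstrap:
        sel = fit.selected_features
        Xs = union.select(sel) if sel else union
        fit.bootstrap_ci = bootstrap_r2(Xs, y, parts, B=bootstrap, seed=seed)
    singles = {k: fit_multipart(v, y, parts).r2 for k, v in sets.items()}
    total = sum(singles.values())
    contributions = {
        k: {
            "r2": r2,
            "share_of_sum_pct": 100.0 * r2 / total if total > 0 else math.nan,
            "share_of_combined_pct": 100.0 * r2 / fit.r2 if fit.r2 > 0 else math.nan,
        }
        for k, r2 in singles.items()
    }
    return fit, contributions


def utr_length_increment(
    base: FeatureMatrix,
    utr5_lens: Sequence[int],
    y: np.ndarray,
    parts: Sequence[str],
) -> float:
    """Delta R^2 (percentage points) from adding log10(5'UTR length + 1)."""
    base_r2 = fit_multipart(base, y, parts).r2
    extra = FeatureMatrix.from_dict(
        base.gene_ids, {"log10_utr5_len": np.log10(np.asarray(utr5_lens, dtype=float) + 1.0)}
    )
    full_r2 = fit_multipart(base.join(extra), y, parts).r2
    return 100.0 * (full_r2 - base_r2)
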