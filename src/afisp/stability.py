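"""Worst-performing subset identification and the performance stability curve.

The audit asks: over all subsets of the evaluation data that can be defined
through the subgroup features ``W`` and that carry a probability mass
``alpha``, how bad can the model's expected loss get?  The plug-in estimator
used here ranks rows by a cross-fitted regression estimate of
``E[loss | W]`` and takes the top ``alpha`` fraction.  Sweeping ``alpha``
over a grid traces the performance stability curve: the model's metric
(AUROC by default) on its worst-performing subset of each size, with
percentile bootstrap confidence bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import (
    ConfigurationError,
    DataError,
    DegenerateEffectError,
    UndefinedMetricError,
)
from .frames_io import EvaluationFrame, auroc, encode_features

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "ConditionalLossEstimate",
    "StabilityPoint",
    "StabilityCurve",
    "fit_conditional_loss",
    "worst_subset",
    "stability_curve",
    "select_alpha",
    "max_effect_alpha",
]

#: 0.05 .. 1.00 in steps of 0.05.
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(round(0.05 * k, 2) for k in range(1, 21))


@dataclass
class ConditionalLossEstimate:
    """Out-of-fold predictions of the conditional loss E[loss | W]."""

    predictions: np.ndarray
    folds: int
    seed: int
    estimator: str

    def __post_init__(self):
        self.predictions = np.asarray(self.predictions, dtype=float)
        if np.any(~np.isfinite(self.predictions)):
            raise DataError("conditional-loss predictions must be finite")

    @property
    def n(self) -> int:
        return len(self.predictions)


def fit_conditional_loss(
    frame: EvaluationFrame,
    W: Sequence[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    estimator: str = "gbrt",
) -> ConditionalLossEstimate:
    """Cross-fitted flexible regression of the per-row loss on W.

    Each row's prediction comes from a model trained on the folds that
    exclude it, so high predicted loss is not an artifact of in-sample
    overfitting.  ``estimator`` is ``"gbrt"`` (histogram gradient boosting,
    the default) or ``"rf"`` (random forest).
    """
    from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
    from sklearn.model_selection import KFold

    if frame.loss is None:
        raise ConfigurationError("frame has no losses; call frame.with_loss() first")
    if folds < 2:
        raise ConfigurationError("cross-fitting needs folds >= 2")
    if frame.n < folds:
        raise ConfigurationError(f"N={frame.n} rows cannot be split into {folds} folds")

    X, _ = encode_features(frame.W, frame.schema, W)
    loss = frame.loss
    preds = np.empty(frame.n, dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(X):
        if estimator == "gbrt":
            model = HistGradientBoostingRegressor(random_state=seed)
        elif estimator == "rf":
            model = RandomForestRegressor(
                n_estimators=200, min_samples_leaf=5, random_state=seed, n_jobs=1
            )
        else:
            raise ConfigurationError(f"unknown conditional-loss estimator {estimator!r}")
        model.fit(X[train_idx], loss[train_idx])
        preds[test_idx] = model.predict(X[test_idx])
    # losses are nonnegative; regressors may slightly undershoot
    np.clip(preds, 0.0, None, out=preds)
    return ConditionalLossEstimate(preds, folds=folds, seed=seed, estimator=estimator)


def worst_subset(cond_loss: ConditionalLossEstimate, alpha: float) -> np.ndarray:
    """Indices of the ceil(alpha*N) rows with the highest conditional loss.

    Ties at the cutoff are broken by ascending row index.  Returned sorted.
    """
    if not (0 < alpha <= 1):
        raise DataError(f"alpha must lie in (0, 1], got {alpha}")
    n = cond_loss.n
    k = math.ceil(alpha * n)
    order = np.lexsort((np.arange(n), -cond_loss.predictions))
    return np.sort(order[:k])


@dataclass
class StabilityPoint:
    alpha: float
    metric: float
    ci_low: float
    ci_high: float
    n_subset: int


@dataclass
class StabilityCurve:
    """Per-alpha worst-case-subset metric values with bootstrap CIs.

    The realized subsets are nested: the worst subset at a smaller alpha is
    contained in the worst subset at any larger alpha.
    """

    points: list[StabilityPoint] = field(default_factory=list)
    metric_name: str = "auroc"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "alpha": p.alpha,
                    "n_subset": p.n_subset,
                    "metric": p.metric,
                    "ci_low": p.ci_low,
                    "ci_high": p.ci_high,
                }
                for p in self.points
            ]
        )


def _subset_metric(frame: EvaluationFrame, idx: np.ndarray, metric: str) -> float:
    if metric == "auroc":
        return auroc(frame.score[idx], frame.y[idx])
    if metric == "mean_loss":
        if frame.loss is None:
            raise ConfigurationError("mean_loss metric requires losses on the frame")
        return float(frame.loss[idx].mean())
    raise ConfigurationError(f"unknown stability metric {metric!r}")


def stability_curve(
    frame: EvaluationFrame,
    cond_loss: ConditionalLossEstimate,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    n_boot: int = 100,
    seed: int = 0,
    metric: str = "auroc",
) -> StabilityCurve:
    """Metric on the worst subset per alpha, with a percentile bootstrap CI.

    The subset is identified once per alpha and its rows are then resampled
    ``n_boot`` times; for AUROC, single-class resamples are redrawn (up to
    100 rounds).  An alpha whose subset holds a single outcome class at the
    full sample yields a missing point (NaN metric).
    """
    alphas = list(alphas)
    if any(not (0 < a <= 1) for a in alphas):
        raise DataError("alphas must lie in (0, 1]")
    if sorted(alphas) != alphas:
        raise DataError("alphas must be sorted ascending")
    rng = np.random.default_rng(seed)
    curve = StabilityCurve(metric_name=metric)
    for alpha in alphas:
        idx = worst_subset(cond_loss, alpha)
        try:
            point = _subset_metric(frame, idx, metric)
        except UndefinedMetricError:
            curve.points.append(StabilityPoint(alpha, math.nan, math.nan, math.nan, len(idx)))
            continue
        try:
            boots = _bootstrap_subset_metric(frame, idx, metric, n_boot, rng)
        except UndefinedMetricError:
            # single-class resamples persisted through all redraw rounds
            curve.points.append(
                StabilityPoint(alpha, point, math.nan, math.nan, len(idx))
            )
            continue
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(lo, point), max(hi, point)
        curve.points.append(StabilityPoint(alpha, point, float(lo), float(hi), len(idx)))
    return curve


def _bootstrap_subset_metric(frame, idx, metric, n_boot, rng) -> np.ndarray:
    from .subgroup_stats import _bootstrap_aurocs  # shared vectorized kernel

    m = len(idx)
    if metric == "mean_loss":
        take = rng.integers(0, m, size=(n_boot, m))
        return frame.loss[idx][take].mean(axis=1)
    return _bootstrap_aurocs(frame.score[idx], frame.y[idx], n_boot, rng)


def select_alpha(curve: StabilityCurve, threshold: float) -> float | None:
    """Largest grid alpha whose point-estimate metric falls below the
    threshold; ``None`` if every point is at or above it."""
    chosen = None
    for p in curve.points:
        if not math.isnan(p.metric) and p.metric < threshold:
            chosen = p.alpha if chosen is None else max(chosen, p.alpha)
    return chosen


def max_effect_alpha(
    frame: EvaluationFrame,
    cond_loss: ConditionalLossEstimate,
    alphas: Sequence[float],
) -> float:
    """Grid alpha maximizing Cohen's d between per-row losses inside and
    outside the worst subset.

    Fallback selection rule for when no reference performance threshold is
    available.  Alphas of 1 are skipped (no outside rows).
    """
    from .subgroup_stats import cohens_d

    if frame.loss is None:
        raise ConfigurationError("max_effect_alpha requires losses on the frame")
    usable = [a for a in alphas if a < 1]
    if len(alphas) < 2 or not usable:
        raise ConfigurationError("need >=2 grid points with at least one alpha < 1")
    best_alpha, best_d = None, -math.inf
    n = frame.n
    for alpha in usable:
        idx = worst_subset(cond_loss, alpha)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        try:
            d = cohens_d(frame.loss[mask], frame.loss[~mask])
        except DegenerateEffectError:
            continue
        if d > best_d:
            best_alpha, best_d = alpha, d
    if best_alpha is None:
        raise DegenerateEffectError("effect size undefined at every grid alpha (constant losses?)")
    return best_alpha
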