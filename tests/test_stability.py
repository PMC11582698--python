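"""Worst-subset identification and the stability curve."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from afisp.exceptions import ConfigurationError, DataError, DegenerateEffectError
from afisp.frames_io import EvaluationFrame, FeatureSchema, FeatureSpec
from afisp.stability import (
    ConditionalLossEstimate,
    fit_conditional_loss,
    max_effect_alpha,
    select_alpha,
    stability_curve,
    worst_subset,
    StabilityCurve,
    StabilityPoint,
)


def _frame_from_losses(losses, scores=None, y=None):
    n = len(losses)
    rng = np.random.default_rng(0)
    schema = FeatureSchema([FeatureSpec("g", "binary", (0, 1))])
    W = pd.DataFrame({"g": rng.integers(0, 2, n)})
    y = rng.integers(0, 2, n) if y is None else np.asarray(y)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    scores = rng.random(n) if scores is None else scores
    return EvaluationFrame(W=W, y=y, score=scores, schema=schema, loss=np.asarray(losses, float))


def _cond(values):
    return ConditionalLossEstimate(np.asarray(values, float), folds=5, seed=0, estimator="given")


# ---------------------------------------------------------------------------
# Conditional loss fitting
# ---------------------------------------------------------------------------


def test_constant_loss_predicts_the_constant():
    frame = _frame_from_losses(np.full(100, 0.37))
    est = fit_conditional_loss(frame, seed=0)
    assert np.allclose(est.predictions, 0.37, atol=1e-6)


def test_group_means_recovered_for_single_binary_feature():
    rng = np.random.default_rng(3)
    n = 400
    g = np.repeat([0, 1], n // 2)
    loss = np.where(g == 1, 0.9, 0.1) + rng.normal(0, 0.02, n)
    loss = np.clip(loss, 0, None)
    schema = FeatureSchema([FeatureSpec("g", "binary", (0, 1))])
    frame = EvaluationFrame(
        W=pd.DataFrame({"g": g}),
        y=rng.integers(0, 2, n),
        score=rng.random(n),
        schema=schema,
        loss=loss,
    )
    est = fit_conditional_loss(frame, seed=0)
    assert np.all(np.abs(est.predictions[g == 1] - 0.9) < 0.05)
    assert np.all(np.abs(est.predictions[g == 0] - 0.1) < 0.05)


def test_pure_noise_features_shrink_prediction_spread():
    rng = np.random.default_rng(4)
    n = 2000
    loss = rng.exponential(1.0, n)
    schema = FeatureSchema([FeatureSpec(f"b{i}", "binary", (0, 1)) for i in range(5)])
    W = pd.DataFrame({f"b{i}": rng.integers(0, 2, n) for i in range(5)})
    frame = EvaluationFrame(
        W=W, y=rng.integers(0, 2, n), score=rng.random(n), schema=schema, loss=loss
    )
    est = fit_conditional_loss(frame, seed=0)
    assert est.predictions.std() < loss.std()


def test_cross_fitting_needs_enough_rows():
    frame = _frame_from_losses([0.1, 0.2, 0.3])
    with pytest.raises(ConfigurationError):
        fit_conditional_loss(frame, folds=5)


# ---------------------------------------------------------------------------
# Worst subset
# ---------------------------------------------------------------------------


def test_worst_subset_alpha_one_is_everything():
    cond = _cond([0.3, 0.1, 0.2])
    assert worst_subset(cond, 1.0).tolist() == [0, 1, 2]


def test_worst_subset_picks_top_mean_half():
    cond = _cond([0.9, 0.1, 0.8, 0.2])
    assert worst_subset(cond, 0.5).tolist() == [0, 2]


def test_worst_subset_tie_broken_by_row_index():
    cond = _cond([0.5, 0.5, 0.1])
    assert worst_subset(cond, 1 / 3).tolist() == [0]


def test_worst_subset_rejects_bad_alpha():
    cond = _cond([0.5, 0.5])
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(DataError):
            worst_subset(cond, bad)


def test_worst_subset_matches_exhaustive_enumeration():
    rng = np.random.default_rng(9)
    for _ in range(20):
        n = int(rng.integers(4, 11))
        vals = rng.random(n)
        cond = _cond(vals)
        k = int(rng.integers(1, n + 1))
        idx = worst_subset(cond, k / n)
        assert len(idx) == k
        best = max(vals[list(c)].mean() for c in itertools.combinations(range(n), k))
        assert vals[idx].mean() == pytest.approx(best)


def test_worst_subset_nesting_and_monotone_mean(planted_audit):
    cond = planted_audit["cond"]
    prev = None
    prev_mean = math.inf
    for alpha in planted_audit["grid"]:
        idx = worst_subset(cond, alpha)
        if prev is not None:
            assert set(prev).issubset(idx)
        mean = cond.predictions[idx].mean()
        assert mean <= prev_mean + 1e-12
        prev, prev_mean = idx, mean


def test_cell_union_oracle_on_discrete_frames():
    """When W has few discrete cells and the conditional loss equals the
    per-cell mean, top-k selection attains the exhaustive cell-union optimum
    at cell-aligned subset sizes."""
    rng = np.random.default_rng(12)
    n_per, means = 25, [0.9, 0.5, 0.2, 0.7]
    cell = np.repeat(np.arange(4), n_per)
    loss = np.array([means[c] for c in cell]) + rng.normal(0, 0.01, 4 * n_per)
    cell_mean = {c: loss[cell == c].mean() for c in range(4)}
    cond = _cond([cell_mean[c] for c in cell])
    for k_cells in (1, 2, 3):
        idx = worst_subset(cond, k_cells * n_per / (4 * n_per))
        best = max(
            np.mean([cell_mean[c] for c in combo])
            for combo in itertools.combinations(range(4), k_cells)
        )
        assert np.mean([cell_mean[c] for c in cell[idx]]) == pytest.approx(best)


# ---------------------------------------------------------------------------
# Stability curve and alpha selection
# ---------------------------------------------------------------------------


def test_curve_at_alpha_one_equals_full_sample_metric(toy_frame):
    from afisp.frames_io import auroc

    cond = _cond(toy_frame.loss)
    curve = stability_curve(toy_frame, cond, [0.5, 1.0], n_boot=30, seed=0)
    assert curve.points[-1].metric == pytest.approx(auroc(toy_frame.score, toy_frame.y))
    for p in curve.points:
        assert 0.0 <= p.ci_low <= p.metric <= p.ci_high <= 1.0
        assert p.n_subset == math.ceil(p.alpha * toy_frame.n)


def test_mean_loss_curve_is_non_increasing_in_alpha():
    rng = np.random.default_rng(5)
    frame = _frame_from_losses(rng.exponential(1, 300))
    cond = _cond(frame.loss)
    curve = stability_curve(
        frame, cond, [0.1, 0.25, 0.5, 0.75, 1.0], n_boot=20, seed=0, metric="mean_loss"
    )
    metrics = [p.metric for p in curve.points]
    assert all(a >= b - 1e-12 for a, b in zip(metrics, metrics[1:]))


def test_constant_conditional_loss_gives_flat_curve(toy_frame):
    cond = _cond(np.ones(toy_frame.n))
    curve = stability_curve(toy_frame, cond, [0.3, 0.6, 1.0], n_boot=30, seed=0)
    metrics = [p.metric for p in curve.points]
    # exchangeable rows: differences are bootstrap-scale noise only
    assert max(metrics) - min(metrics) < 0.15


def _toy_curve(points):
    return StabilityCurve(
        points=[StabilityPoint(a, m, m - 0.01, m + 0.01, 10) for a, m in points]
    )


def test_select_alpha_largest_below_threshold():
    curve = _toy_curve([(0.05, 0.90), (0.1, 0.93), (0.2, 0.95)])
    assert select_alpha(curve, 0.944) == 0.1


def test_select_alpha_none_when_all_above():
    curve = _toy_curve([(0.05, 0.95), (0.1, 0.96)])
    assert select_alpha(curve, 0.944) is None


def test_select_alpha_max_grid_when_all_below():
    curve = _toy_curve([(0.05, 0.80), (0.1, 0.85), (0.2, 0.90)])
    assert select_alpha(curve, 0.944) == 0.2


# ---------------------------------------------------------------------------
# Effect-size fallback
# ---------------------------------------------------------------------------


def test_max_effect_alpha_finds_the_planted_cluster():
    from afisp.subgroup_stats import cohens_d

    rng = np.random.default_rng(6)
    n = 200
    loss = np.concatenate([np.full(20, 0.9), np.full(180, 0.1)]) + rng.normal(0, 0.01, n)
    loss = np.clip(loss, 0, None)
    frame = _frame_from_losses(loss)
    cond = _cond(loss)
    grid = [0.05, 0.1, 0.2]
    expected = max(
        grid,
        key=lambda a: cohens_d(
            loss[worst_subset(cond, a)],
            np.delete(loss, worst_subset(cond, a)),
        ),
    )
    assert expected == 0.1  # the cluster occupies exactly 10% of rows
    assert max_effect_alpha(frame, cond, grid) == expected


def test_max_effect_alpha_degenerate_on_constant_losses():
    frame = _frame_from_losses(np.full(50, 0.4))
    cond = _cond(frame.loss)
    with pytest.raises(DegenerateEffectError):
        max_effect_alpha(frame, cond, [0.2, 0.5])


def test_max_effect_alpha_isolates_a_tiny_outlier_cluster():
    n = 50
    loss = np.full(n, 0.1)
    loss[[7, 13]] = 5.0  # two rows so both effect-size groups are testable
    loss += np.linspace(0, 0.01, n)  # break exact ties
    frame = _frame_from_losses(loss)
    cond = _cond(loss)
    grid = [2 / n, 0.2, 0.5]
    assert max_effect_alpha(frame, cond, grid) == 2 / n
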