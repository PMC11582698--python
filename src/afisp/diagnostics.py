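"""Subgroup learning-curve diagnostic.

Once an underperforming subgroup is identified, the actionable question is
whether the gap is correctable by targeted data collection.  The diagnostic
holds the non-subgroup training data fixed, adds increasing amounts of
subgroup training data drawn from an external pool, refits the model, and
tracks the subgroup-specific and full-population AUROC.  A rising subgroup
curve indicates a correctable gap; a flat curve near chance (as with label
noise confined to the subgroup) indicates the outcome is unlearnable there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, UndefinedMetricError
from .frames_io import EvaluationFrame, Phenotype, Trainer, auroc, members

__all__ = ["TrainingSet", "LearningCurvePoint", "LearningCurve", "learning_curve"]


@dataclass
class TrainingSet:
    """Feature rows plus binary labels the trainer can refit on."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y).astype(int)
        if len(self.X) != len(self.y):
            raise DataError("X and y must have identical length")

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class LearningCurvePoint:
    n_subgroup_train: int
    subgroup_mean: float
    subgroup_ci_low: float
    subgroup_ci_high: float
    full_mean: float
    full_ci_low: float
    full_ci_high: float
    n_rep: int


@dataclass
class LearningCurve:
    points: list[LearningCurvePoint] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_subgroup_train": p.n_subgroup_train,
                    "subgroup_auroc_mean": p.subgroup_mean,
                    "subgroup_ci_low": p.subgroup_ci_low,
                    "subgroup_ci_high": p.subgroup_ci_high,
                    "full_auroc_mean": p.full_mean,
                    "full_ci_low": p.full_ci_low,
                    "full_ci_high": p.full_ci_high,
                }
                for p in self.points
            ]
        )


def _normal_ci(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(values.mean())
    if values.size < 2:
        return mean, mean, mean
    half = 1.96 * values.std(ddof=1) / np.sqrt(values.size)
    return mean, mean - half, mean + half


def learning_curve(
    base_train: TrainingSet,
    subgroup_pool: TrainingSet,
    eval_frame: EvaluationFrame,
    phenotype: Phenotype,
    sizes: Sequence[int],
    trainer: Trainer,
    n_rep: int = 10,
    seed: int = 0,
) -> LearningCurve:
    """Effect of targeted subgroup data collection on model performance.

    For each size s, the trainer refits on ``base_train`` plus s rows
    subsampled without replacement from ``subgroup_pool`` (which must consist
    entirely of subgroup members), repeated ``n_rep`` times with derived
    seeds; the subgroup and full-population AUROC on ``eval_frame`` are
    averaged with 95% normal-approximation CIs.  Size 0 is the baseline
    model, evaluated once with no resampling variance.
    """
    sizes = sorted(int(s) for s in sizes)
    if sizes and sizes[-1] > len(subgroup_pool):
        raise DataError(
            f"requested subgroup draw of {sizes[-1]} exceeds pool of {len(subgroup_pool)}"
        )
    pool_mask = members(phenotype, subgroup_pool.X, eval_frame.schema)
    if not pool_mask.all():
        raise DataError("subgroup_pool contains rows that do not satisfy the phenotype")
    eval_mask = members(phenotype, eval_frame)
    sub_y = eval_frame.y[eval_mask]
    if eval_mask.sum() < 2 or sub_y.min() == sub_y.max():
        raise UndefinedMetricError("evaluation subgroup is single-class or too small")

    curve = LearningCurve()
    for s in sizes:
        sub_aucs, full_aucs = [], []
        reps = 1 if s == 0 else n_rep
        for r in range(reps):
            rep_seed = int(np.random.SeedSequence([seed, s, r]).generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(rep_seed)
            if s == 0:
                X_fit, y_fit = base_train.X, base_train.y
            else:
                draw = rng.choice(len(subgroup_pool), size=s, replace=False)
                X_fit = pd.concat(
                    [base_train.X, subgroup_pool.X.iloc[draw]], ignore_index=True
                )
                y_fit = np.concatenate([base_train.y, subgroup_pool.y[draw]])
            adapter = trainer.fit(X_fit, y_fit, seed=rep_seed)
            scores = np.asarray(adapter.predict_score(eval_frame.W), dtype=float)
            sub_aucs.append(auroc(scores[eval_mask], eval_frame.y[eval_mask]))
            full_aucs.append(auroc(scores, eval_frame.y))
        sm, slo, shi = _normal_ci(np.asarray(sub_aucs))
        fm, flo, fhi = _normal_ci(np.asarray(full_aucs))
        curve.points.append(
            LearningCurvePoint(s, sm, slo, shi, fm, flo, fhi, n_rep=reps)
        )
    return curve
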