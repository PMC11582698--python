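"""Statistical filtering of candidate subgroups.

Each candidate phenotype is scored with a bootstrap distribution of its
within-subgroup AUROC, tested one-sided against the performance threshold
(z-test using the bootstrap SD as standard error), corrected across the
candidate family with Holm–Bonferroni, and gated on Cohen's d computed on
the cross-fitted conditional losses inside vs. outside the subgroup.
Survivors form the reported findings table, ordered by ascending AUROC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .exceptions import DataError, DegenerateEffectError, UndefinedMetricError
from .frames_io import EvaluationFrame, Phenotype, auroc, members
from .stability import ConditionalLossEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "SubgroupFinding",
    "bootstrap_metric",
    "one_sided_z",
    "holm",
    "cohens_d",
    "wilson",
    "evaluate_candidates",
    "findings_to_frame",
]


@dataclass
class SubgroupFinding:
    """One row of the findings table: a phenotype with its size, AUROC,
    bootstrap CI, raw/adjusted p-value, and loss effect size."""

    phenotype: Phenotype
    n: int
    metric: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adj: float
    cohen_d: float
    source: str = "rules"

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype.canonical_key,
            "n": self.n,
            "auroc": self.metric,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "cohen_d": self.cohen_d,
            "source": self.source,
        }


def findings_to_frame(findings: Sequence[SubgroupFinding]):
    """Findings as a DataFrame mirroring the ``subgroups.csv`` layout."""
    import pandas as pd

    cols = ["phenotype", "n", "auroc", "ci_low", "ci_high", "p_raw", "p_adj", "cohen_d", "source"]
    return pd.DataFrame([f.to_dict() for f in findings], columns=cols)


def _bootstrap_aurocs(
    scores: np.ndarray,
    y: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    max_redraw: int = 100,
) -> np.ndarray:
    """AUROC over ``n_boot`` with-replacement resamples of (scores, y).

    Resampling duplicates rows but never creates new score values, so each
    resample's Mann–Whitney statistic can be computed from fixed tie groups
    of the sorted original scores and per-resample draw counts — O(B·m)
    instead of re-ranking every resample.  Single-class resamples are
    redrawn up to ``max_redraw`` rounds.
    """
    m = scores.size
    order = np.argsort(scores, kind="stable")
    ys = y[order] == 1
    s_sorted = scores[order]
    group_starts = np.flatnonzero(np.r_[True, s_sorted[1:] != s_sorted[:-1]])
    inv = np.empty(m, dtype=np.intp)
    inv[order] = np.arange(m)

    take = rng.integers(0, m, size=(n_boot, m))
    yb_pos = y[take].sum(axis=1)
    for _ in range(max_redraw):
        bad = np.flatnonzero((yb_pos == 0) | (yb_pos == m))
        if bad.size == 0:
            break
        take[bad] = rng.integers(0, m, size=(bad.size, m))
        yb_pos[bad] = y[take[bad]].sum(axis=1)
    else:
        raise UndefinedMetricError("could not draw two-class bootstrap resamples")

    counts = np.empty((n_boot, m), dtype=np.float64)
    for b in range(n_boot):
        counts[b] = np.bincount(inv[take[b]], minlength=m)
    cpos = counts * ys
    cneg = counts * ~ys
    if group_starts.size < m:  # ties across rows: aggregate per tie group
        cpos = np.add.reduceat(cpos, group_starts, axis=1)
        cneg = np.add.reduceat(cneg, group_starts, axis=1)
    cum_neg_below = np.cumsum(cneg, axis=1) - cneg
    n_pos = cpos.sum(axis=1)
    n_neg = cneg.sum(axis=1)
    wins = (cpos * cum_neg_below).sum(axis=1) + 0.5 * (cpos * cneg).sum(axis=1)
    return wins / (n_pos * n_neg)


def bootstrap_metric(
    frame: EvaluationFrame,
    mask: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """Bootstrap the within-mask AUROC.

    Rows inside the mask are resampled with replacement ``n_boot`` times;
    resamples holding a single outcome class are redrawn (up to 100 rounds).
    Returns (bootstrap mean, bootstrap SD, percentile 2.5%, percentile 97.5%).
    """
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    m = idx.size
    if m < 2:
        raise DataError("bootstrap_metric needs a mask selecting >= 2 rows")
    scores, y = frame.score[idx], frame.y[idx]
    if y.min() == y.max():
        raise UndefinedMetricError("mask selects a single outcome class")
    rng = np.random.default_rng(seed)
    aucs = _bootstrap_aurocs(scores, y, n_boot, rng)
    boot_mean = float(aucs.mean())
    boot_sd = float(aucs.std(ddof=1))
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return boot_mean, boot_sd, float(min(lo, boot_mean)), float(max(hi, boot_mean))


def one_sided_z(boot_mean: float, boot_sd: float, threshold: float) -> float:
    """P-value for the alternative "subgroup metric < threshold".

    Treats the bootstrap SD as the standard error of the metric.  A zero SD
    degenerates to p = 0 if the mean is below the threshold, else p = 1.
    """
    if boot_sd < 0:
        raise DataError("bootstrap SD must be nonnegative")
    if boot_sd == 0:
        return 0.0 if boot_mean < threshold else 1.0
    return float(norm.cdf((boot_mean - threshold) / boot_sd))


def holm(p_values: Sequence[float], fwer: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm–Bonferroni step-down adjustment with monotonicity enforcement.

    Returns (adjusted p-values, rejection flags); a hypothesis is rejected
    iff its adjusted p-value is strictly below the family-wise error rate.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=fwer, method="holm")
    return p_adj, p_adj < fwer


def cohens_d(a, b) -> float:
    """Standardized mean difference (x̄_a − x̄_b) / s with s the pooled SD
    (sample variances, denominator n−1).

    A pooled SD at rounding-noise scale (relative to the data magnitude)
    counts as zero, so near-constant groups raise rather than producing an
    arbitrarily inflated ratio.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise DataError("cohens_d needs >= 2 observations per group")
    s1, s2 = a.var(ddof=1), b.var(ddof=1)
    pooled = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    scale = max(1.0, float(np.abs(a).max()), float(np.abs(b).max()))
    if pooled <= 1e-12 * scale:
        raise DegenerateEffectError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / pooled)


def wilson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if not (0 <= k <= n) or n < 1:
        raise DataError("wilson requires 0 <= k <= n and n >= 1")
    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)


def evaluate_candidates(
    frame: EvaluationFrame,
    cond_loss: ConditionalLossEstimate,
    candidates: Sequence[Phenotype],
    threshold: float,
    fwer: float = 0.05,
    d_min: float = 0.4,
    min_n: int = 100,
    n_boot: int = 100,
    seed: int = 0,
    source: str = "rules",
    keep_all: bool = False,
) -> list[SubgroupFinding]:
    """Run the full test battery over a family of candidate phenotypes.

    Candidates whose membership holds a single outcome class (or fewer than
    two rows) are skipped with a warning and do not enter the Holm family.
    A finding is kept when its Holm-adjusted p-value rejects at ``fwer``,
    its conditional-loss Cohen's d is at least ``d_min``, and its size is at
    least ``min_n``; pass ``keep_all=True`` to get every tested candidate
    regardless.  Output is sorted by ascending AUROC.
    """
    if not candidates:
        raise DataError("evaluate_candidates requires a non-empty candidate list")
    # deduplicate by canonical key, preserving first occurrence
    seen: set[str] = set()
    unique: list[Phenotype] = []
    for c in candidates:
        if c.canonical_key not in seen:
            seen.add(c.canonical_key)
            unique.append(c)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(unique)) % (2**31)

    records = []
    for pheno, child in zip(unique, child_seeds):
        mask = members(pheno, frame)
        n = int(mask.sum())
        if n < 2:
            logger.warning("candidate %s skipped: %d member rows", pheno, n)
            continue
        try:
            point = auroc(frame.score[mask], frame.y[mask])
            bm, bsd, lo, hi = bootstrap_metric(frame, mask, n_boot=n_boot, seed=int(child))
        except UndefinedMetricError:
            logger.warning("candidate %s skipped: single-class membership", pheno)
            continue
        p_raw = one_sided_z(bm, bsd, threshold)
        inside = cond_loss.predictions[mask]
        outside = cond_loss.predictions[~mask]
        try:
            d = cohens_d(inside, outside)
        except (DataError, DegenerateEffectError):
            d = math.nan
        records.append((pheno, n, point, lo, hi, p_raw, d))

    if not records:
        return []
    p_adj, reject = holm([r[5] for r in records], fwer=fwer)
    findings = []
    for (pheno, n, point, lo, hi, p_raw, d), padj, rej in zip(records, p_adj, reject):
        keep = bool(rej) and not math.isnan(d) and d >= d_min and n >= min_n
        if keep or keep_all:
            findings.append(
                SubgroupFinding(
                    phenotype=pheno,
                    n=n,
                    metric=point,
                    ci_low=min(lo, point),
                    ci_high=max(hi, point),
                    p_raw=float(p_raw),
                    p_adj=float(padj),
                    cohen_d=float(d),
                    source=source,
                )
            )
    findings.sort(key=lambda f: (f.metric, f.phenotype.canonical_key))
    return findings
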