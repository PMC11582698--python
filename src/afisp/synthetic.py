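"""Simulated-data study: planted-fault generation and recovery experiments.

The generating process draws d iid Rademacher (±1) features, a coefficient
vector from the mixture 0.5·N(1, 0.5²) + 0.5·N(−1, 0.5²), and labels
Y ~ Bernoulli(sigmoid(Xᵀβ)).  A well-specified logistic model fit on clean
training data is the audit target.  A problematic subgroup is planted in
the evaluation set by flipping labels with probability 0.5 inside the slice
X2 = −1 ∧ X3 = 1 (a quarter of the data), which drives the model's AUROC
inside the slice to chance while leaving the rest intact.

A recovery trial runs the full rule-based audit pipeline and the exhaustive
slice-search baseline on one such evaluation set and records whether each
method reports a subgroup semantically identical to the planted slice
(membership-vector equality on the evaluation set).  Repeating over many
independent draws of the generating process yields each method's recovery
accuracy with a Wilson score interval.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AfispError, DataError
from .frames_io import (
    EvaluationFrame,
    FeatureSchema,
    FeatureSpec,
    Literal,
    LogisticRegressionTrainer,
    Op,
    Phenotype,
    auroc,
    members,
)
from .phenotype_rules import RuleExtractionConfig, learn_phenotypes
from .slice_baseline import SliceSearchConfig, slice_search
from .stability import fit_conditional_loss, max_effect_alpha, worst_subset
from .subgroup_stats import evaluate_candidates, wilson

logger = logging.getLogger(__name__)

__all__ = [
    "DgpSpec",
    "TrialResult",
    "make_schema",
    "default_flip_phenotype",
    "draw_beta",
    "sample_dgp",
    "plant_fault",
    "recovery_trial",
    "recovery_experiment",
    "null_control_experiment",
    "scalability_experiment",
    "SCALABILITY_FEATURE_COUNTS",
]

#: Feature counts swept in the scalability experiment.
SCALABILITY_FEATURE_COUNTS: tuple[int, ...] = (25, 50, 250, 500, 2500, 5000)

_SIGMOID = lambda z: 1.0 / (1.0 + np.exp(-z))  # noqa: E731


def make_schema(d: int) -> FeatureSchema:
    """Schema of d binary ±1 features named X1..Xd."""
    return FeatureSchema(FeatureSpec(f"X{i}", "binary", (-1, 1)) for i in range(1, d + 1))


def default_flip_phenotype() -> Phenotype:
    """The planted slice X2 = −1 ∧ X3 = 1 (25% of the data)."""
    return Phenotype(
        (Literal("X2", Op.EQ, -1), Literal("X3", Op.EQ, 1))
    )


@dataclass
class DgpSpec:
    """Conditions of the simulated audit study."""

    d: int = 10
    n_train: int = 50_000
    n_eval: int = 10_000
    flip_phenotype: Phenotype = field(default_factory=default_flip_phenotype)
    flip_prob: float = 0.5
    seed: int = 0
    #: draw the audit features W independently of the model inputs.  With
    #: flip_prob = 0 this makes every slice an exchangeable random subsample
    #: (true within-slice performance equals pooled performance), the only
    #: regime in which reported findings are false positives by construction.
    w_independent: bool = False

    def __post_init__(self):
        if not (0 <= self.flip_prob <= 1):
            raise DataError("flip_prob must lie in [0, 1]")
        idxs = [
            int(l.feature[1:])
            for l in self.flip_phenotype.literals
            if l.feature.startswith("X") and l.feature[1:].isdigit()
        ]
        if idxs and self.d < max(idxs):
            raise DataError(f"d={self.d} smaller than max feature index {max(idxs)} in flip slice")

    @property
    def schema(self) -> FeatureSchema:
        return make_schema(self.d)


def draw_beta(d: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Coefficients from the two-component normal mixture around ±1."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = np.where(rng.random(d) < 0.5, 1.0, -1.0)
    return rng.normal(loc=centers, scale=0.5)


def sample_dgp(
    spec: DgpSpec, n: int, beta: np.ndarray, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw n rows: X iid uniform on {−1, +1}, Y ~ Bernoulli(sigmoid(Xβ))."""
    beta = np.asarray(beta, dtype=float)
    if beta.size != spec.d:
        raise DataError(f"beta has length {beta.size}, expected d={spec.d}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, spec.d)) * 2 - 1
    p = _SIGMOID(X @ beta)
    y = (rng.random(n) < p).astype(int)
    Xdf = pd.DataFrame(X, columns=[f"X{i}" for i in range(1, spec.d + 1)])
    return Xdf, y


def plant_fault(
    X: pd.DataFrame,
    y: np.ndarray,
    phenotype: Phenotype,
    flip_prob: float,
    seed: int | np.random.Generator = 0,
    schema: FeatureSchema | None = None,
) -> np.ndarray:
    """Flip labels independently with probability ``flip_prob`` inside the
    phenotype; labels outside are untouched."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schema = schema or make_schema(X.shape[1])
    mask = members(phenotype, X, schema)
    flips = mask & (rng.random(len(y)) < flip_prob)
    y = np.asarray(y).copy()
    y[flips] = 1 - y[flips]
    return y


@dataclass
class TrialResult:
    seed: int
    found: dict
    found_exact_key: dict
    found_containment: dict
    n_findings: dict
    n_candidates: dict
    alpha: float | None
    threshold: float
    timings: dict


def _derived_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def recovery_trial(
    spec: DgpSpec,
    methods: Sequence[str] = ("afisp", "slicefinder"),
    seed: int = 0,
    alphas: Sequence[float] | None = None,
    rule_config: RuleExtractionConfig | None = None,
    min_n_rules: int = 100,
    min_n_slices: int = 400,
    d_min: float = 0.4,
    fwer: float = 0.05,
    n_boot: int = 100,
    cond_folds: int = 5,
) -> TrialResult:
    """One full replication of the planted-fault recovery experiment.

    The subgroup test threshold is the full-evaluation-set AUROC point
    estimate, and the subset fraction is chosen by the maximum-effect-size
    rule (no external reference model exists in the simulation).  A method
    "finds" the fault when one of its reported findings has an
    evaluation-set membership vector identical to the planted slice's;
    looser criteria (canonical-key equality, planted-slice containment) are
    recorded alongside for sensitivity analysis.  A method failure is
    logged and counted as not-found.
    """
    (
        s_beta, s_train, s_eval, s_fault, s_cond, s_rules, s_ev_r, s_ev_s, s_w
    ) = _derived_seeds(seed, 9)
    schema = spec.schema

    beta = draw_beta(spec.d, s_beta)
    X_train, y_train = sample_dgp(spec, spec.n_train, beta, s_train)
    trainer = LogisticRegressionTrainer(schema)
    model = trainer.fit(X_train, y_train, seed=s_train)

    X_eval, y_eval = sample_dgp(spec, spec.n_eval, beta, s_eval)
    scores = model.predict_score(X_eval)
    if spec.w_independent:
        rng_w = np.random.default_rng(s_w)
        W_audit = pd.DataFrame(
            rng_w.integers(0, 2, size=(spec.n_eval, spec.d)) * 2 - 1,
            columns=[f"X{i}" for i in range(1, spec.d + 1)],
        )
    else:
        W_audit = X_eval
    y_faulted = plant_fault(W_audit, y_eval, spec.flip_phenotype, spec.flip_prob, s_fault, schema)
    frame = EvaluationFrame(
        W=W_audit, y=y_faulted, score=scores, schema=schema
    ).with_loss("log")

    threshold = auroc(frame.score, frame.y)
    t0 = time.perf_counter()
    cond = fit_conditional_loss(frame, folds=cond_folds, seed=s_cond)
    cond_time = time.perf_counter() - t0

    planted_mask = members(spec.flip_phenotype, frame)
    planted_key = spec.flip_phenotype.canonical_key

    found: dict[str, bool] = {}
    found_key: dict[str, bool] = {}
    found_contain: dict[str, bool] = {}
    n_findings: dict[str, int] = {}
    n_candidates: dict[str, int] = {}
    timings: dict[str, float] = {}
    alpha_star: float | None = None

    def _score_findings(findings):
        hit = hit_key = hit_contain = False
        for f in findings:
            fmask = members(f.phenotype, frame)
            if np.array_equal(fmask, planted_mask):
                hit = True
            if f.phenotype.canonical_key == planted_key:
                hit_key = True
            if np.all(fmask[planted_mask]):
                hit_contain = True
        return hit, hit_key, hit_contain

    if "afisp" in methods:
        t0 = time.perf_counter()
        try:
            grid = list(alphas) if alphas is not None else [round(0.05 * k, 2) for k in range(1, 20)]
            alpha_star = max_effect_alpha(frame, cond, grid)
            idx = worst_subset(cond, alpha_star)
            cfg = rule_config or RuleExtractionConfig(seed=s_rules)
            if cfg.seed != s_rules:
                cfg = replace(cfg, seed=s_rules)
            candidates = learn_phenotypes(frame, idx, config=cfg)
            n_candidates["afisp"] = len(candidates)
            findings = (
                evaluate_candidates(
                    frame,
                    cond,
                    candidates,
                    threshold=threshold,
                    fwer=fwer,
                    d_min=d_min,
                    min_n=min_n_rules,
                    n_boot=n_boot,
                    seed=s_ev_r,
                    source="rules",
                )
                if candidates
                else []
            )
        except AfispError as exc:
            logger.warning("trial seed %d: afisp failed (%s)", seed, exc)
            findings, n_candidates["afisp"] = [], n_candidates.get("afisp", 0)
        timings["afisp"] = cond_time + (time.perf_counter() - t0)
        n_findings["afisp"] = len(findings)
        found["afisp"], found_key["afisp"], found_contain["afisp"] = _score_findings(findings)

    if "slicefinder" in methods:
        t0 = time.perf_counter()
        try:
            sf_cfg = SliceSearchConfig(
                threshold=threshold, max_degree=2, min_n=min_n_slices, d_min=d_min, fwer=fwer
            )
            findings = slice_search(frame, cond, sf_cfg, n_boot=n_boot, seed=s_ev_s)
            n_candidates["slicefinder"] = 2 * spec.d + 2 * spec.d * (spec.d - 1)
        except AfispError as exc:
            logger.warning("trial seed %d: slicefinder failed (%s)", seed, exc)
            findings = []
        timings["slicefinder"] = cond_time + (time.perf_counter() - t0)
        n_findings["slicefinder"] = len(findings)
        (
            found["slicefinder"],
            found_key["slicefinder"],
            found_contain["slicefinder"],
        ) = _score_findings(findings)

    return TrialResult(
        seed=seed,
        found=found,
        found_exact_key=found_key,
        found_containment=found_contain,
        n_findings=n_findings,
        n_candidates=n_candidates,
        alpha=alpha_star,
        threshold=threshold,
        timings=timings,
    )


def recovery_experiment(
    spec: DgpSpec,
    n_trials: int = 50,
    master_seed: int = 0,
    methods: Sequence[str] = ("afisp", "slicefinder"),
    **trial_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat the recovery trial over independent draws of the generating
    process.

    Returns (per-trial log, summary).  The summary holds each method's
    recovery accuracy (fraction of trials in which the planted slice was
    reported) with its 95% Wilson score interval.  Bit-identical given
    ``master_seed``.
    """
    if n_trials < 1:
        raise DataError("n_trials must be >= 1")
    seeds = _derived_seeds(master_seed, n_trials)
    rows = []
    for t, s in enumerate(seeds):
        res = recovery_trial(spec, methods=methods, seed=s, **trial_kwargs)
        for m in methods:
            rows.append(
                {
                    "trial": t,
                    "method": m,
                    "found": bool(res.found[m]),
                    "found_exact_key": bool(res.found_exact_key[m]),
                    "found_containment": bool(res.found_containment[m]),
                    "n_findings": res.n_findings[m],
                    "seed": s,
                    "alpha": res.alpha,
                    "threshold": res.threshold,
                    "runtime_s": res.timings[m],
                }
            )
        logger.info(
            "trial %d/%d: %s", t + 1, n_trials, {m: res.found[m] for m in methods}
        )
    results = pd.DataFrame(rows)
    summary_rows = []
    for m in methods:
        k = int(results.loc[results["method"] == m, "found"].sum())
        lo, hi = wilson(k, n_trials)
        summary_rows.append(
            {"method": m, "accuracy": k / n_trials, "wilson_low": lo, "wilson_high": hi}
        )
    return results, pd.DataFrame(summary_rows)


def null_control_experiment(
    n_runs: int = 100,
    master_seed: int = 0,
    spec: DgpSpec | None = None,
    **trial_kwargs,
) -> pd.DataFrame:
    """False-discovery control of the audit pipeline under an exchangeable null.

    Runs the full rule-based pipeline on evaluation sets with no planted
    fault and audit features drawn independently of the model inputs, with
    the test threshold at the full-sample AUROC.  Every slice is then a
    random subsample whose true performance equals the pooled performance,
    so any reported finding is a false positive.  Returns one row per run
    with the finding count; the fraction of runs with >= 1 finding is the
    empirical family-wise error rate of the (approximate) bootstrap z-test
    battery.

    Defaults run at a reduced problem size (n_train 20,000 / n_eval 4,000,
    200 trees) so that 100 replicates complete in a few minutes.
    """
    from .phenotype_rules import RuleExtractionConfig

    if spec is None:
        spec = DgpSpec(n_train=20_000, n_eval=4_000, flip_prob=0.0, w_independent=True)
    if spec.flip_prob != 0 or not spec.w_independent:
        raise DataError("null control requires flip_prob=0 and w_independent=True")
    trial_kwargs.setdefault("rule_config", RuleExtractionConfig(n_trees=200))
    seeds = _derived_seeds(master_seed, n_runs)
    rows = []
    for run, s in enumerate(seeds):
        res = recovery_trial(spec, methods=("afisp",), seed=s, **trial_kwargs)
        rows.append(
            {
                "run": run,
                "seed": s,
                "n_findings": res.n_findings["afisp"],
                "any_finding": res.n_findings["afisp"] > 0,
            }
        )
    return pd.DataFrame(rows)


def scalability_experiment(
    feature_counts: Sequence[int] = SCALABILITY_FEATURE_COUNTS,
    n_trials: int = 5,
    master_seed: int = 0,
    methods: Sequence[str] = ("afisp", "slicefinder"),
    n_train: int = 50_000,
    n_eval: int = 10_000,
    **trial_kwargs,
) -> pd.DataFrame:
    """Wall-clock runtime of each method as the feature count grows.

    Runtimes are reported, never asserted — they are hardware-dependent.  A
    failed trial is recorded as missing.  Columns: method, d, mean_minutes,
    se_minutes.
    """
    rows = []
    for d in feature_counts:
        spec = DgpSpec(d=d, n_train=n_train, n_eval=n_eval)
        seeds = _derived_seeds(master_seed + d, n_trials)
        times: dict[str, list[float]] = {m: [] for m in methods}
        for s in seeds:
            try:
                res = recovery_trial(spec, methods=methods, seed=s, **trial_kwargs)
            except AfispError as exc:
                logger.warning("scalability d=%d seed=%d failed: %s", d, s, exc)
                continue
            for m in methods:
                times[m].append(res.timings[m] / 60.0)
        for m in methods:
            arr = np.asarray(times[m])
            rows.append(
                {
                    "method": m,
                    "d": d,
                    "mean_minutes": float(arr.mean()) if arr.size else np.nan,
                    "se_minutes": (
                        float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
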