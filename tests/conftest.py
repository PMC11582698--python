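"""Shared fixtures: toy frames and one full-scale planted-fault audit run."""

import numpy as np
import pandas as pd
import pytest

from afisp.frames_io import (
    EvaluationFrame,
    FeatureSchema,
    FeatureSpec,
    LogisticRegressionTrainer,
    auroc,
)
from afisp.phenotype_rules import RuleExtractionConfig, extract_rules, fit_rule_forest
from afisp.stability import fit_conditional_loss, max_effect_alpha, worst_subset
from afisp.subgroup_stats import evaluate_candidates
from afisp.synthetic import DgpSpec, draw_beta, plant_fault, sample_dgp


@pytest.fixture
def toy_schema():
    return FeatureSchema(
        [
            FeatureSpec("sex", "binary", ("F", "M")),
            FeatureSpec("age", "numeric"),
            FeatureSpec("season", "categorical", ("winter", "spring", "summer", "fall")),
        ]
    )


@pytest.fixture
def toy_frame(toy_schema):
    rng = np.random.default_rng(0)
    n = 200
    W = pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], n),
            "age": rng.uniform(20, 90, n),
            "season": rng.choice(["winter", "spring", "summer", "fall"], n),
        }
    )
    y = rng.integers(0, 2, n)
    score = np.clip(0.5 * y + 0.25 + 0.2 * rng.random(n) - 0.1, 0, 1)
    return EvaluationFrame(W=W, y=y, score=score, schema=toy_schema).with_loss()


@pytest.fixture(scope="session")
def planted_audit():
    """One full-scale planted-fault evaluation plus the audit artifacts the
    structural tests inspect (worst subsets, stable rules, findings)."""
    spec = DgpSpec()
    seeds = np.random.SeedSequence(11).generate_state(8) % 2**31
    beta = draw_beta(spec.d, int(seeds[0]))
    X_train, y_train = sample_dgp(spec, spec.n_train, beta, int(seeds[1]))
    model = LogisticRegressionTrainer(spec.schema).fit(X_train, y_train, seed=0)
    X_eval, y_eval = sample_dgp(spec, spec.n_eval, beta, int(seeds[2]))
    y_flip = plant_fault(X_eval, y_eval, spec.flip_phenotype, spec.flip_prob, int(seeds[3]))
    frame = EvaluationFrame(
        W=X_eval, y=y_flip, score=model.predict_score(X_eval), schema=spec.schema
    ).with_loss()
    cond = fit_conditional_loss(frame, seed=int(seeds[4]))
    grid = [round(0.05 * k, 2) for k in range(1, 20)]
    alpha = max_effect_alpha(frame, cond, grid)
    idx = worst_subset(cond, alpha)
    membership = np.zeros(frame.n, dtype=bool)
    membership[idx] = True
    cfg = RuleExtractionConfig(seed=int(seeds[5]))
    forest = fit_rule_forest(frame, membership, cfg)
    ruleset = extract_rules(forest, cfg.p0)
    candidates = [r.phenotype for r in ruleset.rules]
    threshold = auroc(frame.score, frame.y)
    findings = evaluate_candidates(
        frame, cond, candidates, threshold=threshold, seed=int(seeds[6])
    )
    return {
        "spec": spec,
        "frame": frame,
        "cond": cond,
        "grid": grid,
        "alpha": alpha,
        "config": cfg,
        "ruleset": ruleset,
        "candidates": candidates,
        "threshold": threshold,
        "findings": findings,
    }
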