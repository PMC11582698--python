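"""Quantization, the shallow rule forest, and stable rule extraction."""

import dataclasses
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from afisp.exceptions import DataError
from afisp.frames_io import (
    EvaluationFrame,
    FeatureSchema,
    FeatureSpec,
    Literal,
    Op,
    Phenotype,
    auroc,
    members,
)
from afisp.phenotype_rules import (
    Rule,
    RuleExtractionConfig,
    RuleSet,
    extract_rules,
    fit_rule_forest,
    learn_phenotypes,
    quantize,
    ruleset_score,
    select_p0,
)


def _binary_schema(names):
    return FeatureSchema([FeatureSpec(n, "binary", (0, 1)) for n in names])


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------


def test_quantize_constant_numeric_feature_has_no_cutpoints():
    schema = FeatureSchema([FeatureSpec("x", "numeric")])
    W = pd.DataFrame({"x": np.full(50, 3.0)})
    assert quantize(W, q=10, schema=schema)["x"].size == 0


def test_quantize_deciles_of_1_to_100():
    schema = FeatureSchema([FeatureSpec("x", "numeric")])
    W = pd.DataFrame({"x": np.arange(1, 101, dtype=float)})
    cuts = quantize(W, q=10, schema=schema)["x"]
    assert cuts.size == 9
    assert np.all(np.diff(cuts) > 0)
    np.testing.assert_allclose(cuts, np.quantile(W["x"], np.arange(1, 10) / 10))


def test_quantize_skips_binary_features():
    schema = FeatureSchema([FeatureSpec("b", "binary", (0, 1))])
    W = pd.DataFrame({"b": [0, 1, 0, 1]})
    assert "b" not in quantize(W, q=10, schema=schema)


# ---------------------------------------------------------------------------
# Rule forest
# ---------------------------------------------------------------------------


def _noiseless_toy(n=500, seed=0):
    """Membership fully determined by a single binary feature."""
    rng = np.random.default_rng(seed)
    schema = _binary_schema(["a", "b", "c"])
    W = pd.DataFrame({k: rng.integers(0, 2, n) for k in "abc"})
    membership = W["a"].to_numpy() == 1
    return W, membership, schema


def test_every_root_splits_on_the_decisive_feature():
    W, membership, schema = _noiseless_toy()
    cfg = RuleExtractionConfig(n_trees=50, max_depth=2, seed=0, max_features=None)
    rf = fit_rule_forest(W, membership, cfg, schema=schema)
    a_col = [i for i, c in enumerate(rf.columns) if c.feature == "a"][0]
    for est in rf.forest.estimators_:
        assert est.tree_.feature[0] == a_col


def test_depth_limit_is_honored(planted_audit):
    cfg = planted_audit["config"]
    for phenotype in planted_audit["candidates"]:
        assert len(phenotype.literals) <= cfg.max_depth


def test_same_seed_gives_identical_path_counts():
    W, membership, schema = _noiseless_toy()
    cfg = RuleExtractionConfig(n_trees=20, seed=7)
    c1 = fit_rule_forest(W, membership, cfg, schema=schema).path_counts()
    c2 = fit_rule_forest(W, membership, cfg, schema=schema).path_counts()
    assert {k: v[1] for k, v in c1.items()} == {k: v[1] for k, v in c2.items()}


def test_single_class_membership_is_an_error():
    W, membership, schema = _noiseless_toy()
    with pytest.raises(DataError):
        fit_rule_forest(W, np.ones(len(W), bool), RuleExtractionConfig(), schema=schema)


# ---------------------------------------------------------------------------
# Rule extraction
# ---------------------------------------------------------------------------


def test_unanimous_single_split_gives_frequency_one_pair():
    W, membership, schema = _noiseless_toy()
    cfg = RuleExtractionConfig(n_trees=30, max_depth=1, seed=1, max_features=None)
    rf = fit_rule_forest(W, membership, cfg, schema=schema)
    rs = extract_rules(rf, p0=1.0)  # p0 = 1: only rules present in every tree
    keys = {r.phenotype.canonical_key for r in rs.rules}
    assert keys == {"a == 0", "a == 1"}
    assert all(r.frequency == 1.0 for r in rs.rules)
    by_key = {r.phenotype.canonical_key: r for r in rs.rules}
    assert by_key["a == 1"].inside_mean == 1.0
    assert by_key["a == 1"].outside_mean == 0.0


def _recount_paths(rf):
    """Independent path recount walking the raw sklearn tree arrays."""
    totals = {}
    for est in rf.forest.estimators_:
        t = est.tree_
        seen = set()
        stack = [(0, [])]
        while stack:
            node, lits = stack.pop()
            if lits:
                seen.add(Phenotype.build(lits, rf.schema).canonical_key)
            if t.children_left[node] == -1:
                continue
            col = rf.columns[t.feature[node]]
            if col.kind == "binary":
                left = Literal(col.feature, Op.EQ, col.payload[0])
                right = Literal(col.feature, Op.EQ, col.payload[1])
            elif col.kind == "onehot":
                left = Literal(col.feature, Op.NEQ, col.payload[0])
                right = Literal(col.feature, Op.EQ, col.payload[0])
            else:
                cut = col.payload[int(np.floor(t.threshold[node]))]
                left = Literal(col.feature, Op.LE, cut)
                right = Literal(col.feature, Op.GT, cut)
            stack.append((t.children_left[node], lits + [left]))
            stack.append((t.children_right[node], lits + [right]))
        for k in seen:
            totals[k] = totals.get(k, 0) + 1
    return totals


def test_path_frequencies_match_independent_recount():
    rng = np.random.default_rng(2)
    schema = _binary_schema(["a", "b", "c", "d"])
    W = pd.DataFrame({k: rng.integers(0, 2, 300) for k in "abcd"})
    membership = (W["a"].to_numpy() == 1) & (rng.random(300) < 0.8)
    if membership.all() or not membership.any():
        raise AssertionError("bad fixture")
    cfg = RuleExtractionConfig(n_trees=25, max_depth=3, seed=3)
    rf = fit_rule_forest(W, membership, cfg, schema=schema)
    expected = _recount_paths(rf)
    got = {k: v[1] for k, v in rf.path_counts().items()}
    assert got == expected


def test_extraction_invariant_to_tree_order():
    W, membership, schema = _noiseless_toy(seed=5)
    cfg = RuleExtractionConfig(n_trees=15, seed=4)
    rf = fit_rule_forest(W, membership, cfg, schema=schema)
    reversed_rf = dataclasses.replace(
        rf, forest=SimpleNamespace(estimators_=list(reversed(rf.forest.estimators_)))
    )
    a = {(r.phenotype.canonical_key, r.frequency) for r in extract_rules(rf, 0.1).rules}
    b = {(r.phenotype.canonical_key, r.frequency) for r in extract_rules(reversed_rf, 0.1).rules}
    assert a == b


def test_all_extracted_frequencies_respect_p0(planted_audit):
    ruleset = planted_audit["ruleset"]
    assert ruleset.rules
    assert all(r.frequency >= planted_audit["config"].p0 for r in ruleset.rules)
    keys = [r.phenotype.canonical_key for r in ruleset.rules]
    assert len(keys) == len(set(keys))  # deduplicated


# ---------------------------------------------------------------------------
# Rule-set scoring and p0 selection
# ---------------------------------------------------------------------------


def test_ruleset_score_hand_computed():
    schema = _binary_schema(["a", "b"])
    W = pd.DataFrame({"a": [1, 1, 0], "b": [1, 0, 1]})
    r1 = Rule(Phenotype((Literal("a", Op.EQ, 1),)), 0.9, inside_mean=0.8, outside_mean=0.1)
    r2 = Rule(Phenotype((Literal("b", Op.EQ, 1),)), 0.8, inside_mean=0.6, outside_mean=0.2)
    rs = RuleSet([r1, r2], training_prevalence=0.3, schema=schema)
    np.testing.assert_allclose(
        ruleset_score(rs, W), [(0.8 + 0.6) / 2, (0.8 + 0.2) / 2, (0.1 + 0.6) / 2]
    )
    empty = RuleSet([], training_prevalence=0.3, schema=schema)
    np.testing.assert_allclose(ruleset_score(empty, W), [0.3, 0.3, 0.3])


def test_select_p0_singleton_grid_is_identity():
    W, membership, schema = _noiseless_toy()
    assert select_p0(W, membership, schema, [0.022]) == 0.022


def test_select_p0_prefers_largest_within_one_se():
    W, membership, schema = _noiseless_toy(n=300)
    cfg = RuleExtractionConfig(n_trees=10, max_depth=1, max_features=None)
    # noiseless: every grid value keeps the decisive rule, so parsimony wins
    assert select_p0(W, membership, schema, [0.1, 0.5, 1.0], seed=0, config=cfg) == 1.0


def test_select_p0_avoids_thresholds_that_empty_the_rule_set():
    W, membership, schema = _noiseless_toy(n=400, seed=8)
    # mtry=1 makes root splits vary, so no rule reaches frequency 0.95
    cfg = RuleExtractionConfig(n_trees=40, max_depth=2, max_features=1)
    assert select_p0(W, membership, schema, [0.05, 0.95], seed=0, config=cfg) == 0.05


def test_noiseless_toy_reaches_perfect_cv_auroc():
    from sklearn.model_selection import StratifiedKFold

    W, membership, schema = _noiseless_toy(n=400, seed=9)
    cfg = RuleExtractionConfig(n_trees=20, max_depth=2, seed=0)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
    for tr, te in skf.split(W, membership):
        rf = fit_rule_forest(W.iloc[tr], membership[tr], cfg, schema=schema)
        rs = extract_rules(rf, 0.1)
        pred = ruleset_score(rs, W.iloc[te], schema)
        assert auroc(pred, membership[te].astype(int)) == 1.0


# ---------------------------------------------------------------------------
# End-to-end candidate learning
# ---------------------------------------------------------------------------


def test_learn_phenotypes_recovers_single_literal_membership():
    rng = np.random.default_rng(10)
    schema = _binary_schema(["a", "b", "c"])
    n = 500
    W = pd.DataFrame({k: rng.integers(0, 2, n) for k in "abc"})
    y = rng.integers(0, 2, n)
    frame = EvaluationFrame(W=W, y=y, score=rng.random(n), schema=schema).with_loss()
    membership_idx = np.flatnonzero(W["a"].to_numpy() == 1)
    cands = learn_phenotypes(
        frame, membership_idx, config=RuleExtractionConfig(n_trees=30, seed=0)
    )
    assert "a == 1" in {c.canonical_key for c in cands}


def test_learn_phenotypes_rejects_trivial_subsets(toy_frame):
    with pytest.raises(DataError):
        learn_phenotypes(toy_frame, np.array([], dtype=int))
    with pytest.raises(DataError):
        learn_phenotypes(toy_frame, np.arange(toy_frame.n))


def test_planted_slice_is_among_stable_candidates(planted_audit):
    keys = {c.canonical_key for c in planted_audit["candidates"]}
    assert "X2 == -1 AND X3 == 1" in keys


def test_planted_membership_ruleset_cv_auroc_is_high(planted_audit):
    """Rule-set membership classification on the planted-slice task: 5-fold
    CV AUROC must reach at least 0.95 at n = 10,000."""
    from sklearn.model_selection import StratifiedKFold

    frame = planted_audit["frame"]
    spec = planted_audit["spec"]
    membership = members(spec.flip_phenotype, frame)
    cfg = RuleExtractionConfig(n_trees=100, seed=0)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
    aucs = []
    for tr, te in skf.split(frame.W, membership):
        rf = fit_rule_forest(frame.W.iloc[tr], membership[tr], cfg, schema=frame.schema)
        rs = extract_rules(rf, cfg.p0)
        pred = ruleset_score(rs, frame.W.iloc[te], frame.schema)
        aucs.append(auroc(pred, membership[te].astype(int)))
    assert np.mean(aucs) >= 0.95
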