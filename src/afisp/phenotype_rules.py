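"""Stable rule extraction: interpretable phenotypes for the worst-case subset.

The worst-performing subset found by the stability stage is a bag of rows,
not an explanation.  This module characterizes it by fitting a shallow
random forest to the membership indicator (member of the worst subset vs.
not) over quantized subgroup features, then harvesting every root-to-node
decision path that appears in at least a fraction ``p0`` of the trees.
Paths that recur across many independently grown trees are stable under
resampling, which is what makes the resulting phenotypes reproducible
rather than artifacts of a single tree's variance.

Numeric features are discretized to ``q``-quantile cutpoints before fitting
so that split thresholds land on a small shared grid and identical rules
can be recognized across trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .frames_io import EvaluationFrame, FeatureSchema, Literal, Op, Phenotype, auroc, members

logger = logging.getLogger(__name__)

__all__ = [
    "RuleExtractionConfig",
    "Rule",
    "RuleSet",
    "RuleForest",
    "quantize",
    "fit_rule_forest",
    "extract_rules",
    "select_p0",
    "ruleset_score",
    "learn_phenotypes",
]


@dataclass
class RuleExtractionConfig:
    """Knobs of the rule learner.

    ``max_depth`` doubles as the maximum phenotype degree (a depth-3 path
    involves at most three features).  ``p0`` is the across-tree frequency a
    path needs to enter the rule set; the shipped default of 0.022 follows
    the cross-validated value used for the clinical audit this tool models.
    """

    n_trees: int = 500
    max_depth: int = 3
    q: int = 10
    p0: float = 0.022
    seed: int = 0
    max_features: str | int | float = "sqrt"

    def __post_init__(self):
        if not (0 < self.p0 <= 1):
            raise ConfigurationError("p0 must lie in (0, 1]")
        if self.n_trees < 1 or self.max_depth < 1 or self.q < 2:
            raise ConfigurationError("n_trees/max_depth must be >=1 and q >= 2")


@dataclass
class Rule:
    """One extracted condition with its stability and response statistics."""

    phenotype: Phenotype
    frequency: float
    inside_mean: float
    outside_mean: float


@dataclass
class RuleSet:
    rules: list[Rule]
    training_prevalence: float
    schema: FeatureSchema | None = None


def quantize(
    frame: EvaluationFrame | pd.DataFrame,
    W: Sequence[str] | None = None,
    q: int = 10,
    schema: FeatureSchema | None = None,
) -> dict[str, np.ndarray]:
    """Empirical q-quantile cutpoints per numeric feature.

    Binary/categorical features pass through unquantized (no entry in the
    returned table); a constant numeric feature yields an empty list.
    """
    if isinstance(frame, EvaluationFrame):
        Wdf, schema = frame.W, frame.schema
    else:
        Wdf = frame
        if schema is None:
            raise ConfigurationError("quantize on a bare DataFrame needs a schema")
    if q < 2:
        raise ConfigurationError("q must be >= 2")
    feats = list(W) if W is not None else [c for c in Wdf.columns if c in schema]
    cuts: dict[str, np.ndarray] = {}
    for f in feats:
        if schema[f].kind != "numeric":
            continue
        vals = Wdf[f].to_numpy(dtype=float)
        qs = np.quantile(vals, np.arange(1, q) / q)
        uniq = np.unique(qs)
        # a cutpoint at (or above) the max splits off nothing
        uniq = uniq[uniq < vals.max()]
        cuts[f] = uniq
    return cuts


# ---------------------------------------------------------------------------
# Encoding for tree fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Column:
    feature: str
    kind: str  # binary | onehot | numeric
    payload: tuple  # binary: (cat0, cat1); onehot: (category,); numeric: cutpoints


def _encode_for_rules(
    Wdf: pd.DataFrame,
    schema: FeatureSchema,
    feats: Sequence[str],
    cutpoints: dict[str, np.ndarray],
) -> tuple[np.ndarray, list[_Column]]:
    cols, meta = [], []
    for f in feats:
        spec = schema[f]
        if spec.kind == "binary":
            ref = str(spec.categories[1])
            cols.append((Wdf[f].astype(str).to_numpy() == ref).astype(np.float64))
            meta.append(_Column(f, "binary", tuple(spec.categories)))
        elif spec.kind == "categorical":
            svals = Wdf[f].astype(str).to_numpy()
            for c in spec.categories:
                cols.append((svals == str(c)).astype(np.float64))
                meta.append(_Column(f, "onehot", (c,)))
        else:
            cuts = cutpoints.get(f, np.array([]))
            vals = Wdf[f].to_numpy(dtype=float)
            cols.append(np.searchsorted(cuts, vals, side="left").astype(np.float64))
            meta.append(_Column(f, "numeric", tuple(cuts)))
    return np.column_stack(cols), meta


def _split_literals(col: _Column, threshold: float) -> tuple[Literal, Literal] | None:
    """(left-child literal, right-child literal) for a split on this column."""
    if col.kind == "binary":
        cat0, cat1 = col.payload
        return Literal(col.feature, Op.EQ, cat0), Literal(col.feature, Op.EQ, cat1)
    if col.kind == "onehot":
        (cat,) = col.payload
        return Literal(col.feature, Op.NEQ, cat), Literal(col.feature, Op.EQ, cat)
    cuts = col.payload
    j = int(np.floor(threshold))
    if j >= len(cuts):  # defensive: threshold beyond the cut grid
        j = len(cuts) - 1
    if j < 0:
        return None
    cut = cuts[j]
    return Literal(col.feature, Op.LE, cut), Literal(col.feature, Op.GT, cut)


@dataclass
class RuleForest:
    """A fitted shallow forest together with everything needed to decode its
    decision paths back into schema-level phenotypes."""

    forest: object
    columns: list[_Column]
    schema: FeatureSchema
    W: pd.DataFrame
    membership: np.ndarray
    config: RuleExtractionConfig

    def path_counts(self) -> dict[str, tuple[Phenotype, int]]:
        """Across-tree counts of canonicalized root-to-node paths.

        Every node at depth >= 1 contributes its path (internal prefixes
        included); a canonical phenotype counts at most once per tree.
        """
        counts: dict[str, tuple[Phenotype, int]] = {}
        for est in self.forest.estimators_:
            tree = est.tree_
            per_tree: dict[str, Phenotype] = {}

            def walk(node: int, lits: list[Literal]):
                if lits:
                    pheno = Phenotype.build(lits, self.schema)
                    per_tree.setdefault(pheno.canonical_key, pheno)
                if tree.children_left[node] == -1:
                    return
                col = self.columns[tree.feature[node]]
                pair = _split_literals(col, tree.threshold[node])
                if pair is None:
                    return
                left_lit, right_lit = pair
                walk(tree.children_left[node], lits + [left_lit])
                walk(tree.children_right[node], lits + [right_lit])

            walk(0, [])
            for key, pheno in per_tree.items():
                prev = counts.get(key)
                counts[key] = (pheno, 1 if prev is None else prev[1] + 1)
        return counts


def fit_rule_forest(
    frame: EvaluationFrame | pd.DataFrame,
    membership: np.ndarray,
    config: RuleExtractionConfig,
    W: Sequence[str] | None = None,
    schema: FeatureSchema | None = None,
    cutpoints: dict[str, np.ndarray] | None = None,
) -> RuleForest:
    """Grow ``n_trees`` depth-limited trees on the quantized features against
    the membership indicator (bootstrap rows, random feature subsets)."""
    from sklearn.ensemble import RandomForestClassifier

    if isinstance(frame, EvaluationFrame):
        Wdf, schema = frame.W, frame.schema
    else:
        Wdf = frame
        if schema is None:
            raise ConfigurationError("fit_rule_forest on a bare DataFrame needs a schema")
    membership = np.asarray(membership, dtype=bool)
    if len(membership) != len(Wdf):
        raise DataError("membership must have one value per row")
    if membership.all() or not membership.any():
        raise DataError("membership must contain both classes")

    feats = list(W) if W is not None else [c for c in Wdf.columns if c in schema]
    if cutpoints is None:
        cutpoints = quantize(Wdf, feats, q=config.q, schema=schema)
    X, meta = _encode_for_rules(Wdf, schema, feats, cutpoints)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features=config.max_features,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, membership.astype(int))
    return RuleForest(forest, meta, schema, Wdf, membership, config)


def extract_rules(rule_forest: RuleForest, p0: float | None = None) -> RuleSet:
    """Keep the decision paths appearing in at least ``p0`` of the trees.

    Rules are deduplicated by canonical key across trees; each carries the
    membership rate inside/outside its condition on the training rows.
    """
    cfg = rule_forest.config
    p0 = cfg.p0 if p0 is None else p0
    if not (0 < p0 <= 1):
        raise ConfigurationError("p0 must lie in (0, 1]")
    n_trees = len(rule_forest.forest.estimators_)
    membership = rule_forest.membership.astype(float)
    rules: list[Rule] = []
    for key, (pheno, count) in rule_forest.path_counts().items():
        freq = count / n_trees
        if freq < p0:
            continue
        mask = members(pheno, rule_forest.W, rule_forest.schema)
        inside = float(membership[mask].mean()) if mask.any() else 0.0
        outside = float(membership[~mask].mean()) if (~mask).any() else 0.0
        rules.append(Rule(pheno, freq, inside, outside))
    rules.sort(key=lambda r: (-r.frequency, r.phenotype.canonical_key))
    return RuleSet(rules, training_prevalence=float(membership.mean()), schema=rule_forest.schema)


def ruleset_score(ruleset: RuleSet, Wdf: pd.DataFrame, schema: FeatureSchema | None = None) -> np.ndarray:
    """Per-row membership score: the mean over rules of the rule's inside
    (condition satisfied) or outside membership rate.  An empty rule set
    returns the training prevalence for every row."""
    schema = schema or ruleset.schema
    n = len(Wdf)
    if not ruleset.rules:
        return np.full(n, ruleset.training_prevalence)
    acc = np.zeros(n)
    for rule in ruleset.rules:
        mask = members(rule.phenotype, Wdf, schema)
        acc += np.where(mask, rule.inside_mean, rule.outside_mean)
    return acc / len(ruleset.rules)


def select_p0(
    Wdf: pd.DataFrame,
    membership: np.ndarray,
    schema: FeatureSchema,
    p0_grid: Sequence[float],
    k_folds: int = 5,
    seed: int = 0,
    config: RuleExtractionConfig | None = None,
) -> float:
    """Cross-validated choice of the rule-frequency threshold.

    For each candidate ``p0`` the membership-classification AUROC of the
    resulting rule set is estimated by stratified k-fold CV; the largest
    ``p0`` whose mean AUROC is within one standard error of the best is
    returned (parsimony preference: higher thresholds mean fewer, more
    stable rules).
    """
    from sklearn.model_selection import StratifiedKFold

    p0_grid = sorted(p0_grid)
    if not p0_grid:
        raise ConfigurationError("p0 grid must be non-empty")
    if len(p0_grid) == 1:
        return p0_grid[0]
    membership = np.asarray(membership, dtype=bool)
    base = config or RuleExtractionConfig()

    scores = np.zeros((len(p0_grid), k_folds))
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(Wdf, membership)):
        import dataclasses as _dc

        fold_seed = int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))
        cfg = _dc.replace(base, seed=fold_seed)
        rf = fit_rule_forest(Wdf.iloc[tr], membership[tr], cfg, schema=schema)
        counts = rf.path_counts()
        n_trees = len(rf.forest.estimators_)
        W_te = Wdf.iloc[te]
        for gi, p0 in enumerate(p0_grid):
            rules = []
            for key, (pheno, count) in counts.items():
                freq = count / n_trees
                if freq < p0:
                    continue
                mask = members(pheno, rf.W, schema)
                inside = float(rf.membership[mask].mean()) if mask.any() else 0.0
                outside = float(rf.membership[~mask].mean()) if (~mask).any() else 0.0
                rules.append(Rule(pheno, freq, inside, outside))
            rs = RuleSet(rules, float(rf.membership.mean()), schema)
            pred = ruleset_score(rs, W_te, schema)
            if np.ptp(pred) == 0:
                scores[gi, fold] = 0.5  # constant score: chance discrimination
            else:
                scores[gi, fold] = auroc(pred, membership[te].astype(int))
    means = scores.mean(axis=1)
    ses = scores.std(axis=1, ddof=1) / np.sqrt(k_folds)
    best = int(np.argmax(means))
    cutoff = means[best] - ses[best]
    eligible = [p0 for gi, p0 in enumerate(p0_grid) if means[gi] >= cutoff]
    return max(eligible)


def learn_phenotypes(
    frame: EvaluationFrame,
    worst_subset_indices: np.ndarray,
    W: Sequence[str] | None = None,
    config: RuleExtractionConfig | None = None,
) -> list[Phenotype]:
    """Full rule-learning pipeline: quantize, fit the shallow forest on
    worst-subset membership, extract frequency-stable paths, and return the
    unique candidate phenotypes (both split polarities are represented
    because every path through either child is counted)."""
    config = config or RuleExtractionConfig()
    idx = np.asarray(worst_subset_indices)
    membership = np.zeros(frame.n, dtype=bool)
    membership[idx] = True
    k = int(membership.sum())
    if k == 0 or k == frame.n:
        raise DataError("worst subset must be non-trivial (0 < |subset| < N)")
    rf = fit_rule_forest(frame, membership, config, W=W)
    ruleset = extract_rules(rf, config.p0)
    out, seen = [], set()
    for rule in ruleset.rules:
        key = rule.phenotype.canonical_key
        if key not in seen:
            seen.add(key)
            out.append(rule.phenotype)
    logger.info(
        "rule learning: %d stable phenotypes at p0=%.3g from %d trees",
        len(out),
        config.p0,
        config.n_trees,
    )
    return out
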