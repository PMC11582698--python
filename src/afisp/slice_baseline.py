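"""Exhaustive slice-search baseline.

Enumerates every data slice of degree at most two over binary/categorical
features (all single EQ literals plus all cross-feature EQ pairs) and runs
the same significance/effect-size test battery as the rule-based pipeline.
This reproduces the behaviour of exhaustive slice finders at their usual
settings — minimum slice size 400, Cohen's d >= 0.4 — while sharing the
statistical filter, so any difference to the rule pipeline reflects the
search strategy alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .frames_io import EvaluationFrame, FeatureSchema, FeatureSpec, Literal, Op, Phenotype
from .stability import ConditionalLossEstimate
from .subgroup_stats import SubgroupFinding, evaluate_candidates

__all__ = ["SliceSearchConfig", "enumerate_slices", "slice_search", "bin_numeric_features"]


@dataclass
class SliceSearchConfig:
    threshold: float
    max_degree: int = 2
    min_n: int = 400
    d_min: float = 0.4
    fwer: float = 0.05

    def __post_init__(self):
        if self.max_degree < 1:
            raise ConfigurationError("max_degree must be >= 1")


def enumerate_slices(
    schema: FeatureSchema,
    max_degree: int = 2,
    features: Sequence[str] | None = None,
) -> list[Phenotype]:
    """All EQ-conjunction slices of degree <= max_degree.

    The count follows the product formula over category cardinalities:
    sum_f |cats(f)| singles plus sum_{f<g} |cats(f)|*|cats(g)| pairs, and so
    on for higher degrees.  Numeric features must be binned first (see
    :func:`bin_numeric_features`).
    """
    feats = list(features) if features is not None else schema.names
    for f in feats:
        if schema[f].kind == "numeric":
            raise ConfigurationError(
                f"feature {f!r} is numeric; bin it before slice enumeration"
            )
    slices: list[Phenotype] = []
    for degree in range(1, max_degree + 1):
        for combo in itertools.combinations(feats, degree):
            cat_lists = [schema[f].categories for f in combo]
            for values in itertools.product(*cat_lists):
                lits = [Literal(f, Op.EQ, v) for f, v in zip(combo, values)]
                slices.append(Phenotype.build(lits, schema))
    return slices


def bin_numeric_features(
    frame: EvaluationFrame, q: int = 10
) -> EvaluationFrame:
    """Replace numeric features by decile-bin categoricals so the frame can
    be slice-enumerated.  Bin labels are half-open interval strings."""
    from .phenotype_rules import quantize

    cuts = quantize(frame, q=q)
    W = frame.W.copy()
    specs = []
    for spec in frame.schema:
        if spec.kind != "numeric":
            specs.append(spec)
            continue
        edges = [-np.inf, *cuts.get(spec.name, []), np.inf]
        labels = [f"({edges[i]:g},{edges[i+1]:g}]" for i in range(len(edges) - 1)]
        idx = np.searchsorted(np.asarray(edges[1:-1]), W[spec.name].to_numpy(float), side="left")
        W[spec.name] = np.asarray(labels, dtype=object)[idx]
        specs.append(FeatureSpec(spec.name, "categorical", tuple(labels)))
    schema = FeatureSchema(specs)
    return EvaluationFrame(W=W, y=frame.y, score=frame.score, schema=schema, loss=frame.loss)


def slice_search(
    frame: EvaluationFrame,
    cond_loss: ConditionalLossEstimate,
    config: SliceSearchConfig,
    n_boot: int = 100,
    seed: int = 0,
    features: Sequence[str] | None = None,
) -> list[SubgroupFinding]:
    """Enumerate all slices and push them through the shared test battery."""
    candidates = enumerate_slices(frame.schema, config.max_degree, features)
    findings = evaluate_candidates(
        frame,
        cond_loss,
        candidates,
        threshold=config.threshold,
        fwer=config.fwer,
        d_min=config.d_min,
        min_n=config.min_n,
        n_boot=n_boot,
        seed=seed,
        source="slices",
    )
    return findings
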