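"""Evaluation-frame data model: schemas, phenotypes, losses, and AUROC.

An audit run revolves around an :class:`EvaluationFrame`: one row per unit
(e.g. patient encounter), the subgroup-defining features ``W``, the binary
outcome ``y``, the model's risk score, and a per-row loss.  Subgroups are
described by :class:`Phenotype` objects — conjunctions of feature literals
such as ``anemia == 1 AND lung_disease_nonspecific == 1`` — whose membership
on a frame is computed by :func:`members`.

Categorical and binary feature values are compared by their string form so
that frames built in memory (e.g. with ``int`` categories ``-1``/``1``) and
frames loaded from CSV behave identically.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from .exceptions import DataError, SchemaError, UndefinedMetricError

logger = logging.getLogger(__name__)

_LOSS_EPS = 1e-12

__all__ = [
    "FeatureSpec",
    "FeatureSchema",
    "EvaluationFrame",
    "Op",
    "Literal",
    "Phenotype",
    "ModelAdapter",
    "Trainer",
    "SklearnAdapter",
    "LogisticRegressionTrainer",
    "load_frame",
    "load_schema",
    "pointwise_loss",
    "auroc",
    "members",
    "encode_features",
    "parse_phenotype",
]


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

_KINDS = ("binary", "categorical", "numeric")


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one subgroup-defining feature."""

    name: str
    kind: str
    categories: tuple | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SchemaError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "numeric":
            if self.categories is not None:
                raise SchemaError(f"numeric feature {self.name!r} cannot declare categories")
        else:
            cats = self.categories
            if not cats:
                raise SchemaError(f"{self.kind} feature {self.name!r} must declare >=1 category")
            if self.kind == "binary" and len(cats) != 2:
                raise SchemaError(f"binary feature {self.name!r} must declare exactly 2 categories")
            if len({str(c) for c in cats}) != len(cats):
                raise SchemaError(f"feature {self.name!r} has duplicate categories")


class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec`, keyed by feature name."""

    def __init__(self, specs: Iterable[FeatureSpec]):
        specs = list(specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        self._specs: dict[str, FeatureSpec] = {s.name: s for s in specs}

    # -- container protocol -------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def __getitem__(self, name: str) -> FeatureSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise SchemaError(f"feature {name!r} not declared in schema") from None

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureSchema) and list(self) == list(other)

    def __repr__(self) -> str:
        return f"FeatureSchema({list(self._specs)})"

    # -- construction helpers ----------------------------------------------
    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "FeatureSchema":
        """Build a schema from a plain mapping, as parsed from YAML.

        Accepted per-feature forms::

            age: numeric
            sex: {kind: binary, categories: [F, M]}
            season: {kind: categorical, categories: [winter, spring, summer, fall]}
        """
        specs = []
        for name, decl in mapping.items():
            if isinstance(decl, str):
                if decl != "numeric":
                    raise SchemaError(
                        f"feature {name!r}: shorthand declaration only valid for 'numeric'"
                    )
                specs.append(FeatureSpec(name, "numeric"))
            elif isinstance(decl, Mapping):
                kind = decl.get("kind")
                cats = decl.get("categories")
                specs.append(
                    FeatureSpec(name, kind, tuple(cats) if cats is not None else None)
                )
            else:
                raise SchemaError(f"feature {name!r}: cannot parse declaration {decl!r}")
        return cls(specs)

    def to_mapping(self) -> dict:
        out: dict[str, Any] = {}
        for s in self:
            if s.kind == "numeric":
                out[s.name] = "numeric"
            else:
                out[s.name] = {"kind": s.kind, "categories": list(s.categories)}
        return out


def load_schema(path) -> FeatureSchema:
    """Read a feature schema from a YAML key-value file."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise SchemaError(f"schema file {path} does not contain a mapping")
    return FeatureSchema.from_mapping(mapping)


# ---------------------------------------------------------------------------
# Literals and phenotypes
# ---------------------------------------------------------------------------


class Op(str, enum.Enum):
    EQ = "=="
    NEQ = "!="
    LE = "<="
    GT = ">"


_OP_ORDER = {Op.EQ: 0, Op.NEQ: 1, Op.LE: 2, Op.GT: 3}


@dataclass(frozen=True)
class Literal:
    """One condition atom, e.g. ``sex == F`` or ``age > 75``."""

    feature: str
    op: Op
    value: Any

    def __str__(self) -> str:
        return f"{self.feature} {self.op.value} {self.value}"

    def validate(self, schema: FeatureSchema) -> None:
        spec = schema[self.feature]
        if spec.kind == "numeric":
            if self.op not in (Op.LE, Op.GT):
                raise SchemaError(f"literal {self}: numeric features take <=/> only")
        else:
            if self.op not in (Op.EQ, Op.NEQ):
                raise SchemaError(f"literal {self}: {spec.kind} features take ==/!= only")
            if str(self.value) not in {str(c) for c in spec.categories}:
                raise SchemaError(
                    f"literal {self}: value not among declared categories {spec.categories}"
                )


def _canonicalize(literals: Sequence[Literal], schema: FeatureSchema | None) -> tuple[Literal, ...]:
    """Normalize a conjunction: binary != rewritten to ==, duplicate literals
    dropped, same-feature numeric bounds merged into a single interval."""
    norm: list[Literal] = []
    for lit in literals:
        if (
            schema is not None
            and lit.feature in schema
            and schema[lit.feature].kind == "binary"
            and lit.op is Op.NEQ
        ):
            cats = schema[lit.feature].categories
            other = [c for c in cats if str(c) != str(lit.value)]
            if len(other) == 1:
                lit = Literal(lit.feature, Op.EQ, other[0])
        norm.append(lit)

    by_feature: dict[str, list[Literal]] = {}
    for lit in norm:
        by_feature.setdefault(lit.feature, []).append(lit)

    out: list[Literal] = []
    for feat, lits in by_feature.items():
        numeric = [l for l in lits if l.op in (Op.LE, Op.GT)]
        if numeric:
            lowers = [float(l.value) for l in numeric if l.op is Op.GT]
            uppers = [float(l.value) for l in numeric if l.op is Op.LE]
            if lowers:
                out.append(Literal(feat, Op.GT, max(lowers)))
            if uppers:
                out.append(Literal(feat, Op.LE, min(uppers)))
        eqs = {str(l.value): l for l in lits if l.op is Op.EQ}
        neqs = {str(l.value): l for l in lits if l.op is Op.NEQ}
        if eqs:
            out.extend(eqs.values())
            # an EQ literal subsumes any != on a different value
            out.extend(l for v, l in neqs.items() if v in eqs)
        else:
            out.extend(neqs.values())

    out.sort(key=lambda l: (l.feature, _OP_ORDER[l.op], str(l.value)))
    return tuple(out)


@dataclass(frozen=True)
class Phenotype:
    """A conjunction of literals defining a subgroup ("data slice").

    Construct through :meth:`build` so that semantically equal conjunctions
    share a canonical key.
    """

    literals: tuple

    @classmethod
    def build(
        cls,
        literals: Iterable[Literal],
        schema: FeatureSchema | None = None,
        max_degree: int | None = None,
    ) -> "Phenotype":
        lits = _canonicalize(list(literals), schema)
        if not lits:
            raise SchemaError("phenotype needs at least one literal")
        if max_degree is not None:
            feats = {l.feature for l in lits}
            if len(feats) > max_degree:
                raise SchemaError(f"phenotype exceeds max degree {max_degree}: {lits}")
        if schema is not None:
            for l in lits:
                l.validate(schema)
        return cls(lits)

    @property
    def canonical_key(self) -> str:
        return " AND ".join(str(l) for l in self.literals)

    @property
    def degree(self) -> int:
        return len({l.feature for l in self.literals})

    def __str__(self) -> str:
        return self.canonical_key


def parse_phenotype(text: str, schema: FeatureSchema) -> Phenotype:
    """Parse a canonical phenotype string like ``sex == F AND age > 75``."""
    literals = []
    for atom in text.split(" AND "):
        atom = atom.strip()
        for op in (Op.LE, Op.GT, Op.EQ, Op.NEQ):  # order avoids '>' matching '>='? ops distinct
            token = f" {op.value} "
            if token in atom:
                feat, val = atom.split(token, 1)
                feat, val = feat.strip(), val.strip()
                spec = schema[feat]
                if spec.kind == "numeric":
                    literals.append(Literal(feat, op, float(val)))
                else:
                    match = [c for c in spec.categories if str(c) == val]
                    if not match:
                        raise SchemaError(
                            f"phenotype atom {atom!r}: {val!r} not a category of {feat!r}"
                        )
                    literals.append(Literal(feat, op, match[0]))
                break
        else:
            raise SchemaError(f"cannot parse phenotype atom {atom!r}")
    return Phenotype.build(literals, schema)


# ---------------------------------------------------------------------------
# Evaluation frame
# ---------------------------------------------------------------------------


@dataclass
class EvaluationFrame:
    """Rows with subgroup features W, binary outcome y, model score, and an
    optional per-row loss ℓ(score, y)."""

    W: pd.DataFrame
    y: np.ndarray
    score: np.ndarray
    schema: FeatureSchema
    loss: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.score = np.asarray(self.score, dtype=float)
        n = len(self.W)
        if n < 1:
            raise DataError("evaluation frame needs at least one row")
        if len(self.y) != n or len(self.score) != n:
            raise DataError("W, y and score must have identical length")
        if not np.isin(self.y, (0, 1)).all():
            raise DataError("outcome values must be 0/1")
        self.y = self.y.astype(int)
        if np.any(~np.isfinite(self.score)) or self.score.min() < 0 or self.score.max() > 1:
            raise DataError("scores must be finite and within [0, 1]")
        for col in self.W.columns:
            if col not in self.schema:
                raise SchemaError(f"W column {col!r} not declared in schema")
        if self.loss is not None:
            self.loss = np.asarray(self.loss, dtype=float)
            if len(self.loss) != n:
                raise DataError("loss must have one value per row")
            if np.any(~np.isfinite(self.loss)) or self.loss.min() < 0:
                raise DataError("losses must be finite and nonnegative")
        self.W = self.W.reset_index(drop=True)
        self._lit_cache: dict = {}  # literal membership masks, per frame

    @property
    def n(self) -> int:
        return len(self.W)

    def with_loss(self, kind: str = "log") -> "EvaluationFrame":
        """Return a copy of the frame with per-row losses attached."""
        return dataclasses.replace(self, loss=pointwise_loss(self.score, self.y, kind))

    def subset(self, mask_or_idx) -> "EvaluationFrame":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EvaluationFrame(
            W=self.W.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            score=self.score[idx],
            schema=self.schema,
            loss=None if self.loss is None else self.loss[idx],
        )


def load_frame(path, schema: FeatureSchema, outcome_col: str, score_col: str) -> EvaluationFrame:
    """Load an evaluation dataset from a CSV with a header row.

    Every schema feature plus ``outcome_col`` and ``score_col`` must be
    present.  Rows with missing values in any schema feature are dropped with
    a logged count (imputation is out of scope).  Losses are left unset; call
    :meth:`EvaluationFrame.with_loss` to attach them.
    """
    dtypes = {s.name: str for s in schema if s.kind in ("binary", "categorical")}
    df = pd.read_csv(path, dtype=dtypes)
    missing = [c for c in [*schema.names, outcome_col, score_col] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    na_mask = df[schema.names].isna().any(axis=1)
    if na_mask.any():
        logger.warning("%s: dropping %d rows with missing subgroup features", path, na_mask.sum())
        df = df.loc[~na_mask].reset_index(drop=True)
    if df.empty:
        raise DataError(f"{path}: no rows left after dropping missing subgroup features")

    y_raw = df[outcome_col]
    try:
        y = y_raw.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: outcome column {outcome_col!r} is not numeric") from exc
    if not np.isin(y, (0.0, 1.0)).all():
        bad = df.index[~np.isin(y, (0.0, 1.0))][0]
        raise DataError(f"{path}: non-binary outcome value at row {bad}")

    for s in schema:
        if s.kind == "numeric":
            df[s.name] = df[s.name].astype(float)
            continue
        allowed = {str(c) for c in s.categories}
        bad = ~df[s.name].astype(str).isin(allowed)
        if bad.any():
            row = int(df.index[bad][0])
            raise DataError(
                f"{path}: value {df[s.name].iloc[row]!r} in column {s.name!r} (row {row}) "
                f"is not a declared category"
            )

    return EvaluationFrame(
        W=df[schema.names].copy(),
        y=y.astype(int),
        score=df[score_col].astype(float).to_numpy(),
        schema=schema,
    )


# ---------------------------------------------------------------------------
# Losses and the performance metric
# ---------------------------------------------------------------------------


def pointwise_loss(score, y, kind: str = "log"):
    """Per-row loss of a probabilistic risk score against a 0/1 outcome.

    ``log``  : −ln p for y=1, −ln(1−p) for y=0, with p clipped to
               [1e−12, 1−1e−12] (proper scoring rule; the default).
    ``brier``: squared error (p − y)².
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(y)
    if np.any(score < 0) or np.any(score > 1):
        raise DataError("scores must lie in [0, 1]")
    if kind == "log":
        p = np.clip(score, _LOSS_EPS, 1 - _LOSS_EPS)
        out = np.where(y == 1, -np.log(p), -np.log(1 - p))
    elif kind == "brier":
        out = (score - y) ** 2
    else:
        raise DataError(f"unknown loss kind {kind!r}")
    return out if out.ndim else float(out)


def auroc(scores, y) -> float:
    """Area under the ROC curve via the Mann–Whitney statistic.

    Equals the fraction of (positive, negative) pairs where the positive
    outscores the negative, with ties credited 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = y == 1
    npos = int(pos.sum())
    nneg = len(y) - npos
    if npos == 0 or nneg == 0:
        raise UndefinedMetricError("AUROC undefined: sample contains a single outcome class")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - npos * (npos + 1) / 2) / (npos * nneg))


# ---------------------------------------------------------------------------
# Phenotype membership
# ---------------------------------------------------------------------------


def members(
    phenotype: Phenotype,
    frame: "EvaluationFrame | pd.DataFrame",
    schema: FeatureSchema | None = None,
) -> np.ndarray:
    """Boolean membership vector of a phenotype on a frame (conjunction)."""
    cache: dict | None = None
    if isinstance(frame, EvaluationFrame):
        W, schema, cache = frame.W, frame.schema, frame._lit_cache
    else:
        W = frame
        if schema is None:
            raise SchemaError("members() on a bare DataFrame requires a schema")
    mask = np.ones(len(W), dtype=bool)
    for lit in phenotype.literals:
        key = (lit.feature, lit.op.value, str(lit.value))
        hit = cache.get(key) if cache is not None else None
        if hit is None:
            if lit.feature not in schema:
                raise SchemaError(f"literal on unknown feature {lit.feature!r}")
            if lit.feature not in W.columns:
                raise SchemaError(f"feature {lit.feature!r} missing from frame")
            col = W[lit.feature]
            if lit.op in (Op.LE, Op.GT):
                vals = col.to_numpy(dtype=float)
                hit = vals <= float(lit.value) if lit.op is Op.LE else vals > float(lit.value)
            else:
                eq = col.astype(str).to_numpy() == str(lit.value)
                hit = eq if lit.op is Op.EQ else ~eq
            if cache is not None:
                cache[key] = hit
        mask = mask & hit
    return mask


# ---------------------------------------------------------------------------
# Model contracts
# ---------------------------------------------------------------------------


@runtime_checkable
class ModelAdapter(Protocol):
    """Scoring contract: rows of model features in, risk scores in [0,1] out.

    Implementations must be deterministic for fixed input and must not see
    the outcome.
    """

    def predict_score(self, X: pd.DataFrame) -> np.ndarray: ...


@runtime_checkable
class Trainer(Protocol):
    """Fitting contract: (feature rows, 0/1 labels, seed) -> ModelAdapter."""

    def fit(self, X: pd.DataFrame, y: np.ndarray, seed: int) -> ModelAdapter: ...


def encode_features(
    W: pd.DataFrame, schema: FeatureSchema, features: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Encode schema-typed columns into a float design matrix.

    Binary features map to a 0/1 code by category index, categoricals are
    one-hot expanded, numerics pass through.  Returns the matrix and the
    generated column names.
    """
    feats = list(features) if features is not None else [c for c in W.columns if c in schema]
    cols: list[np.ndarray] = []
    names: list[str] = []
    for f in feats:
        spec = schema[f]
        if spec.kind == "numeric":
            cols.append(W[f].to_numpy(dtype=float))
            names.append(f)
        elif spec.kind == "binary":
            ref = str(spec.categories[1])
            cols.append((W[f].astype(str).to_numpy() == ref).astype(float))
            names.append(f"{f}=={spec.categories[1]}")
        else:
            svals = W[f].astype(str).to_numpy()
            for c in spec.categories:
                cols.append((svals == str(c)).astype(float))
                names.append(f"{f}=={c}")
    if not cols:
        raise SchemaError("no features to encode")
    return np.column_stack(cols), names


@dataclass
class SklearnAdapter:
    """Wrap a fitted scikit-learn classifier as a :class:`ModelAdapter`."""

    model: Any
    schema: FeatureSchema
    features: list[str] = field(default_factory=list)

    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        M, _ = encode_features(X, self.schema, self.features or None)
        return self.model.predict_proba(M)[:, 1]


@dataclass
class LogisticRegressionTrainer:
    """Reference :class:`Trainer` fitting an L2-regularized logistic model."""

    schema: FeatureSchema
    features: list[str] | None = None
    C: float = 1.0
    max_iter: int = 1000

    def fit(self, X: pd.DataFrame, y: np.ndarray, seed: int) -> SklearnAdapter:
        from sklearn.linear_model import LogisticRegression

        M, _ = encode_features(X, self.schema, self.features)
        model = LogisticRegression(C=self.C, max_iter=self.max_iter, random_state=seed)
        model.fit(M, np.asarray(y))
        return SklearnAdapter(model, self.schema, list(self.features or []))
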