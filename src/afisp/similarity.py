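"""Joint vector embedding of subgroups for similarity comparison.

Subgroups from different discovery routes (rule learning, exhaustive slice
search, random slices) are compared by regressing the per-row conditional
loss on the stacked subgroup-indicator matrix with a 2-component partial
least squares model.  Each subgroup's row of the X-block loading matrix is
its 2-D coordinate; subgroups that cover overlapping, similarly-performing
rows point in similar directions, so cosine similarity between loading rows
measures subgroup relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, DegenerateEffectError
from .frames_io import EvaluationFrame, FeatureSchema, Phenotype, members
from .slice_baseline import enumerate_slices

__all__ = [
    "EmbeddingResult",
    "indicator_matrix",
    "pls_loadings",
    "cosine",
    "sample_random_slices",
]


@dataclass
class EmbeddingResult:
    """Per-subgroup loading vectors plus labels and source tags.

    ``weights`` holds the PLS weight vectors (one column per component);
    the first weight vector is proportional to the covariance of the
    centered indicators with the centered response.
    """

    loadings: np.ndarray  # (J, n_components)
    labels: list[str]
    sources: list[str]
    weights: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subgroup": self.labels,
                "source": self.sources,
            }
        )
        for k in range(self.loadings.shape[1]):
            df[f"load{k + 1}"] = self.loadings[:, k]
        return df


def indicator_matrix(frame: EvaluationFrame, subgroups: Sequence[Phenotype]) -> np.ndarray:
    """N x J binary matrix; column j indicates membership in subgroup j."""
    if not subgroups:
        raise DataError("indicator_matrix requires >= 1 subgroup")
    cols = [members(p, frame) for p in subgroups]
    return np.column_stack(cols).astype(np.uint8)


def pls_loadings(
    X_ind: np.ndarray,
    y: np.ndarray,
    n_components: int = 2,
    labels: Sequence[str] | None = None,
    sources: Sequence[str] | None = None,
) -> EmbeddingResult:
    """X-block loadings of a mean-centered NIPALS PLS of y on the indicators.

    No variance scaling is applied (indicator columns share a scale).  The
    sign of each component is fixed so that the largest-magnitude entry of
    its weight vector is positive, making the embedding deterministic.
    """
    from sklearn.cross_decomposition import PLSRegression

    X = np.asarray(X_ind, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise DataError("X_ind must be (N, J) with y of length N")
    nonconst = np.ptp(X, axis=0) > 0
    if nonconst.sum() < 2:
        raise DegenerateEffectError("PLS needs at least two non-constant indicator columns")
    if X.shape[0] <= n_components:
        raise DataError("need more rows than components")

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    loadings = np.array(pls.x_loadings_, dtype=float)
    weights = np.array(pls.x_weights_, dtype=float)
    for k in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(weights[:, k])))
        if weights[i, k] < 0:
            loadings[:, k] *= -1
            weights[:, k] *= -1

    J = X.shape[1]
    labels = list(labels) if labels is not None else [f"subgroup_{j}" for j in range(J)]
    sources = list(sources) if sources is not None else ["unknown"] * J
    if len(labels) != J or len(sources) != J:
        raise DataError("labels/sources must match the number of indicator columns")
    return EmbeddingResult(loadings, labels, sources, weights=weights)


def cosine(u, v) -> float:
    """Cosine of the angle between two vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateEffectError("cosine undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def sample_random_slices(
    schema: FeatureSchema,
    count: int,
    max_degree: int = 2,
    seed: int = 0,
    features: Sequence[str] | None = None,
) -> list[Phenotype]:
    """Uniform sample without replacement from the full slice enumeration."""
    all_slices = enumerate_slices(schema, max_degree, features)
    if count > len(all_slices):
        raise DataError(f"requested {count} slices but only {len(all_slices)} exist")
    if count == len(all_slices):
        return all_slices
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(all_slices), size=count, replace=False))
    return [all_slices[i] for i in idx]
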