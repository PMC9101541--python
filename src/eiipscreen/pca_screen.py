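"""PCA similarity screening: rank candidates by centroid distance.

A principal-component model (default five components) is fitted on a
learning set of known actives described by any numeric per-molecule
descriptor table.  Candidates are projected into component space, where the
learning-set centroid is the origin, and ranked by the Euclidean norm of
their score vector — the "shortest centroid distance" rule.  The top-k
(default ten) per screening window go forward to docking.

The descriptor source is pluggable: any molecules × descriptors matrix is
accepted.  Descriptors are centered always and autoscaled to unit variance
by default, since descriptor columns typically mix units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorMatrix",
    "PCAModel",
    "fit_pca",
    "project",
    "centroid_distance_rank",
    "nearest_neighbor_rank",
    "select_top_k",
]


@dataclass
class DescriptorMatrix:
    """Ids + molecules × descriptors numeric matrix with column names."""

    ids: list[str]
    X: np.ndarray
    descriptor_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (molecules × descriptors)")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids length must match the number of rows")
        if len(self.descriptor_names) != self.X.shape[1]:
            raise ValueError("descriptor_names length must match the number of columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("descriptor matrix contains non-finite entries")


@dataclass
class PCAModel:
    """Fitted component model: per-descriptor means/scales + loadings."""

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # descriptors × k, orthonormal columns
    descriptor_names: list[str]
    explained_variance_fraction: np.ndarray = field(default=None)  # per component

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_explained_variance(self) -> float:
        return float(np.sum(self.explained_variance_fraction))


def _drop_constant_columns(m: DescriptorMatrix) -> DescriptorMatrix:
    sd = m.X.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(m.descriptor_names, keep) if not k]
        logger.info("dropping constant descriptor column(s): %s", ", ".join(dropped))
        return DescriptorMatrix(
            ids=m.ids,
            X=m.X[:, keep],
            descriptor_names=[n for n, k in zip(m.descriptor_names, keep) if k],
        )
    return m


def fit_pca(learning: DescriptorMatrix, k: int = 5, scale: bool = True) -> PCAModel:
    """Fit a k-component PCA on the learning-set descriptor matrix.

    Centering is always applied; autoscaling (unit variance) by default.
    Constant columns are removed before fitting.  Component signs are fixed
    so the largest-magnitude loading in each column is positive, making the
    fit deterministic.
    """
    learning = _drop_constant_columns(learning)
    n, p = learning.X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} learning rows for k={k}, got {n}")
    usable_rank = min(n - 1, p)
    if k > usable_rank:
        raise ValueError(f"k={k} exceeds the usable rank {usable_rank}")
    means = learning.X.mean(axis=0)
    scales = learning.X.std(axis=0, ddof=1) if scale else np.ones(p)
    Z = (learning.X - means) / scales
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()  # descriptors × k
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(
        means=means,
        scales=scales,
        loadings=loadings,
        descriptor_names=list(learning.descriptor_names),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def _align(model: PCAModel, candidates: DescriptorMatrix) -> np.ndarray:
    if candidates.descriptor_names == model.descriptor_names:
        return candidates.X
    cand = set(candidates.descriptor_names)
    modl = set(model.descriptor_names)
    missing = sorted(modl - cand)
    if missing:
        raise ValueError(
            f"candidate matrix lacks model descriptor(s): {', '.join(missing)}"
        )
    idx = [candidates.descriptor_names.index(n) for n in model.descriptor_names]
    return candidates.X[:, idx]


def project(model: PCAModel, candidates: DescriptorMatrix) -> np.ndarray:
    """Scores = scaled, centered candidate data times the loadings."""
    X = _align(model, candidates)
    return ((X - model.means) / model.scales) @ model.loadings


def centroid_distance_rank(
    model: PCAModel, candidates: DescriptorMatrix
) -> list[tuple[str, float]]:
    """Rank candidates by Euclidean distance to the learning centroid.

    The centroid of the learning set is the origin of component space, so
    the distance is just the norm of each score vector.  Ties keep input
    order (stable sort).
    """
    scores = project(model, candidates)
    dists = np.linalg.norm(scores, axis=1)
    order = np.argsort(dists, kind="stable")
    return [(candidates.ids[i], float(dists[i])) for i in order]


def nearest_neighbor_rank(
    model: PCAModel, learning: DescriptorMatrix, candidates: DescriptorMatrix
) -> list[tuple[str, float]]:
    """Alternative reading of "shortest centroid distance": distance to the
    nearest learning-set member in component space."""
    lscores = project(model, learning)
    cscores = project(model, candidates)
    d = np.linalg.norm(cscores[:, None, :] - lscores[None, :, :], axis=2).min(axis=1)
    order = np.argsort(d, kind="stable")
    return [(candidates.ids[i], float(d[i])) for i in order]


def select_top_k(
    ranked: Sequence[tuple[str, float]], k: int = 10
) -> list[str]:
    """First k ids of a ranked list; fewer (with a warning) if shorter."""
    if len(ranked) < k:
        warnings.warn(
            f"requested top {k} but only {len(ranked)} candidates ranked", stacklevel=2
        )
    return [rid for rid, _ in ranked[:k]]
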