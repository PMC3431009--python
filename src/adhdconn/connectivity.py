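"""Connectivity feature extraction.

Two feature families feed the classifiers:

* **Motor-network (M1) features** — the 10 Pearson correlations between the
  mean time courses of the five M1 parcels, in the canonical pair order
  (see :mod:`adhdconn.constants`).
* **Whole-brain seed features** — correlations between mean time courses
  around a set of reference seed voxels (264 by default), reduced across
  subjects with a column-centred SVD (PCA) to a handful of components.

Multi-session subjects have their feature rows averaged within subject
before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import PAIR_NAMES, PARCELS
from .synthetic_data import Scan4D

__all__ = [
    "ConnectivityVector",
    "PCAReduction",
    "parcel_mean_timecourses",
    "pairwise_correlations",
    "seed_connectivity_vector",
    "pca_reduce",
    "average_sessions",
]


@dataclass
class ConnectivityVector:
    """Pearson correlations of all unordered region pairs, fixed order."""

    subject_id: str
    pair_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.pair_labels) != self.values.size:
            raise ValueError("pair labels and values length mismatch")
        if np.any(np.abs(self.values) > 1 + 1e-10):
            raise ValueError("correlations outside [-1, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.pair_labels), name=self.subject_id)


@dataclass
class PCAReduction:
    """Column-centred SVD of a subjects x features matrix.

    ``scores`` are the top-k left singular vectors scaled by their singular
    values; ``loadings`` (features x k) are orthonormal with a deterministic
    sign convention (the largest-magnitude entry of each loading is
    positive).
    """

    scores: np.ndarray
    loadings: np.ndarray
    column_means: np.ndarray
    explained_variance: np.ndarray
    k: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.column_means) @ self.loadings

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T + self.column_means


def parcel_mean_timecourses(scan: Scan4D, parcel_labels: np.ndarray) -> np.ndarray:
    """Spatial mean time course of each parcel; T x 5, canonical order."""
    parcel_labels = np.asarray(parcel_labels)
    if parcel_labels.shape != scan.data.shape[:-1]:
        raise ValueError("parcel label grid does not match scan grid")
    cols = []
    for code, name in enumerate(PARCELS, start=1):
        vox = parcel_labels == code
        if not vox.any():
            raise ValueError(f"parcel {name} is empty")
        cols.append(scan.data[vox].mean(axis=0))
    return np.column_stack(cols)


def pairwise_correlations(
    tcs: np.ndarray,
    labels: tuple[str, ...] | None = None,
    subject_id: str = "",
) -> ConnectivityVector:
    """Pearson correlations of all unordered column pairs.

    Columns are taken in canonical parcel order when ``labels`` is omitted
    and the matrix has five columns; otherwise pair names are formed from
    the given labels.  Zero-variance columns are an error.
    """
    tcs = np.asarray(tcs, dtype=float)
    if tcs.ndim != 2 or tcs.shape[1] < 2:
        raise ValueError("need a T x p matrix with p >= 2")
    sds = tcs.std(axis=0)
    bad = np.flatnonzero(sds <= 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    p = tcs.shape[1]
    corr = np.corrcoef(tcs.T)
    iu = np.triu_indices(p, k=1)
    if labels is None and p == len(PARCELS):
        pair_labels = PAIR_NAMES
    else:
        if labels is None:
            labels = tuple(f"r{i}" for i in range(p))
        pair_labels = tuple(f"{labels[i]},{labels[j]}" for i, j in zip(*iu))
    return ConnectivityVector(
        subject_id=subject_id, pair_labels=pair_labels, values=corr[iu]
    )


def seed_connectivity_vector(
    scan: Scan4D,
    seeds: np.ndarray,
    radius: int = 1,
    subject_id: str = "",
) -> ConnectivityVector:
    """Seed-to-seed correlations from local mean time courses.

    Each seed contributes the mean time course of in-mask voxels within
    ``radius`` (Euclidean, in voxels) of its coordinate; ``radius=0`` uses
    the seed voxel's own series.  Returns the upper-triangle (diagonal
    excluded) correlations, n(n-1)/2 values.
    """
    seeds = np.asarray(seeds, dtype=int)
    if seeds.ndim != 2 or seeds.shape[1] != 3:
        raise ValueError("seeds must be an n x 3 coordinate array")
    mask = scan.mask.astype(bool)
    dims = np.array(scan.data.shape[:-1])
    cols = []
    r = int(radius)
    offsets = [
        np.array(off)
        for off in np.ndindex(2 * r + 1, 2 * r + 1, 2 * r + 1)
        if np.sum((np.array(off) - r) ** 2) <= r**2
    ]
    for seed in seeds:
        if not mask[tuple(seed)]:
            raise ValueError(f"seed {seed.tolist()} outside mask")
        series = []
        for off in offsets:
            voxel = seed + off - r
            if np.any(voxel < 0) or np.any(voxel >= dims):
                continue
            if mask[tuple(voxel)]:
                series.append(scan.data[tuple(voxel)])
        if not series:
            raise ValueError(f"seed {seed.tolist()} has no in-mask voxels")
        cols.append(np.mean(series, axis=0))
    tcs = np.column_stack(cols)
    labels = tuple(f"seed{i:03d}" for i in range(len(seeds)))
    return pairwise_correlations(tcs, labels=labels, subject_id=subject_id)


def pca_reduce(features: np.ndarray, k: int = 10) -> PCAReduction:
    """Column-centred SVD reduction of a subjects x d matrix to k scores."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (subjects x variables)")
    n, d = X.shape
    if not 1 <= k <= min(n, d):
        raise ValueError(f"k={k} must lie in [1, min(n, d)] = [1, {min(n, d)}]")
    means = X.mean(axis=0)
    Xc = X - means
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u[:, :k] * s[:k]
    explained = s[:k] ** 2 / max(n - 1, 1)
    return PCAReduction(
        scores=scores,
        loadings=vt[:k].T.copy(),
        column_means=means,
        explained_variance=explained,
        k=k,
    )


def average_sessions(rows: pd.DataFrame, subject_column: str = "subject_id") -> pd.DataFrame:
    """Average feature rows within subject (sessions/visits collapse to one).

    All rows must carry the same feature columns with no missing entries;
    single-session subjects pass through unchanged.  Output is sorted by
    subject id with one row each.
    """
    if subject_column not in rows.columns:
        raise ValueError(f"missing {subject_column!r} column")
    feature_cols = [c for c in rows.columns if c != subject_column]
    if not feature_cols:
        raise ValueError("no feature columns to average")
    block = rows[feature_cols]
    if block.isna().any().any():
        raise ValueError("feature rows contain missing values; sessions inconsistent")
    non_numeric = [c for c in feature_cols if not pd.api.types.is_numeric_dtype(block[c])]
    if non_numeric:
        raise ValueError(f"non-numeric feature columns {non_numeric}")
    out = rows.groupby(subject_column, sort=True, as_index=False)[feature_cols].mean()
    return out
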