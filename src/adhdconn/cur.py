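"""CUR-style voxel selection via statistical leverage scores.

The idea: treat a preprocessed scan as a T x V matrix of voxel time
courses, compute each voxel's *leverage score* — the squared mass of its
coordinates in the top-``rank_k`` right singular vectors — and keep the
``c`` highest-leverage voxels (default 20).  Leverage measures a column's
contribution to the dominant low-rank subspace, so the selected voxels are
the ones driving the strongest coherent variability in the scan.  The
vectorised upper triangle (diagonal included) of their c x c covariance
matrix is the per-subject feature vector: 210 values at c=20.

On resting-state data the highest-leverage voxels tend to sit at the brain
periphery and in CSF, where residual head motion dominates the signal, so
the fraction of selected voxels in those compartments doubles as a subtle
in-scanner motion flag (:func:`peripheral_fraction`).

Selection is deterministic (top-c by score, ties to the lower voxel
index); plain per-voxel variance ranking is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_data import BrainTemplate, Scan4D

__all__ = [
    "CURSelection",
    "leverage_scores",
    "variance_scores",
    "select_top_columns",
    "cur_covariance_vector",
    "peripheral_fraction",
]


@dataclass
class CURSelection:
    """Indices and scores of the selected columns (voxels)."""

    column_indices: np.ndarray  # (c,) linear indices into the scored columns
    voxel_coords: np.ndarray | None  # (c, 3) grid coordinates, when known
    leverage_scores: np.ndarray  # scores of *all* scored columns
    c: int
    rank_k: int


def leverage_scores(X: np.ndarray, rank_k: int) -> np.ndarray:
    """Normalised leverage of each column of a (centred) T x V matrix.

    ``score_j = sum_{i<=rank_k} v_{j,i}^2`` over the top-``rank_k`` right
    singular vectors of the column-centred matrix; scores are non-negative
    and sum to ``rank_k`` (orthonormality).  If ``rank_k`` exceeds the
    numerical rank it is reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a T x V matrix")
    T, V = X.shape
    if not 1 <= rank_k <= min(T, V):
        raise ValueError(f"rank_k={rank_k} must lie in [1, min(T, V)] = [1, {min(T, V)}]")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(T, V) * np.finfo(float).eps if s.size else 0.0
    nrank = int((s > tol).sum())
    if rank_k > nrank:
        warnings.warn(
            f"rank_k={rank_k} exceeds numerical rank {nrank}; using {nrank}",
            RuntimeWarning,
            stacklevel=2,
        )
        rank_k = max(nrank, 1)
    return (vt[:rank_k] ** 2).sum(axis=0)


def variance_scores(X: np.ndarray) -> np.ndarray:
    """Per-column sample variance — the naive alternative ranking."""
    X = np.asarray(X, dtype=float)
    return X.var(axis=0, ddof=1)


def select_top_columns(scores: np.ndarray, c: int = 20, rank_k: int | None = None) -> CURSelection:
    """Deterministic top-``c`` columns by score, ties to the lower index."""
    scores = np.asarray(scores, dtype=float)
    V = scores.size
    if not 1 <= c <= V:
        raise ValueError(f"c={c} must lie in [1, {V}]")
    order = np.argsort(-scores, kind="stable")  # stable sort = lowest index wins ties
    chosen = np.sort(order[:c])
    return CURSelection(
        column_indices=chosen,
        voxel_coords=None,
        leverage_scores=scores,
        c=c,
        rank_k=rank_k if rank_k is not None else c,
    )


def cur_covariance_vector(
    scan: Scan4D,
    c: int = 20,
    rank_k: int | None = None,
    ranking: str = "leverage",
    include_diagonal: bool = True,
) -> tuple[np.ndarray, CURSelection]:
    """Per-subject covariance feature vector from the top-``c`` voxels.

    Scores the in-mask voxel time courses (leverage by default, with
    ``rank_k`` defaulting to ``c``; or plain variance), keeps the top ``c``,
    and vectorises the upper triangle of their covariance matrix in
    row-major order.  With the diagonal included (default) the length is
    c(c+1)/2 — 210 at c=20; without it, c(c-1)/2.

    Returns ``(vector, selection)`` where the selection records the chosen
    voxel grid coordinates for downstream localisation diagnostics.
    """
    mask = scan.mask.astype(bool)
    X = scan.data[mask].T  # T x V
    T, V = X.shape
    if V < c:
        raise ValueError(f"only {V} masked voxels, need at least c={c}")
    nonconstant = int((X.std(axis=0) > 0).sum())
    if nonconstant < c:
        raise ValueError(f"only {nonconstant} non-constant voxels, need c={c}")
    if ranking == "leverage":
        k = c if rank_k is None else rank_k
        scores = leverage_scores(X, rank_k=min(k, min(T, V)))
    elif ranking == "variance":
        scores = variance_scores(X)
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    sel = select_top_columns(scores, c=c, rank_k=rank_k if rank_k is not None else c)
    coords = np.argwhere(mask)[sel.column_indices]
    sel.voxel_coords = coords
    sub = X[:, sel.column_indices]
    cov = np.cov(sub, rowvar=False)
    cov = np.atleast_2d(cov)
    iu = np.triu_indices(c, k=0 if include_diagonal else 1)
    return cov[iu].copy(), sel


def peripheral_fraction(selection: CURSelection, template: BrainTemplate) -> float:
    """Fraction of selected voxels in the periphery or CSF compartment.

    High values flag scans whose dominant variability lives at the mask
    edge — the signature of residual in-scanner motion.
    """
    if selection.voxel_coords is None:
        raise ValueError("selection carries no voxel coordinates")
    flagged = template.periphery | template.csf_region
    mask = template.brain_mask.astype(bool)
    hits = 0
    for coord in selection.voxel_coords:
        t = tuple(int(v) for v in coord)
        if not mask[t]:
            raise ValueError(f"selected voxel {t} outside the brain mask")
        hits += bool(flagged[t])
    return hits / len(selection.voxel_coords)
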