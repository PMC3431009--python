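"""Temporal preprocessing of voxel time courses.

Three linear operations, applied column-wise to a T x V matrix (time by
series): polynomial detrending, band-pass filtering, and nuisance
regression against confound time courses (realignment parameters,
white-matter / CSF grand means).  All three are least-squares projections
or Fourier masks, so composing them can only shrink per-column variance,
and each is exactly linear — properties the test suite checks directly.

Band-pass defaults to the conventional resting-state window 0.01-0.1 Hz
via an ideal discrete-Fourier mask (exact and closed-form testable); a
Butterworth alternative is available for users who prefer a causal IIR
filter.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal

from .synthetic_data import Scan4D

__all__ = [
    "detrend_poly",
    "bandpass_filter",
    "nuisance_regress",
    "preprocess_matrix",
    "preprocess_scan",
]


def _as_2d(ts: np.ndarray) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    if ts.ndim != 2:
        raise ValueError(f"expected a T x V matrix, got shape {ts.shape}")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contain non-finite values")
    return ts


def detrend_poly(ts: np.ndarray, order: int = 2) -> np.ndarray:
    """Remove a least-squares polynomial trend of the given order.

    The default order 2 removes mean, linear and quadratic drift.  Returns
    the residuals; they are orthogonal to every polynomial regressor up to
    ``order``.
    """
    ts = _as_2d(ts)
    T = ts.shape[0]
    if order < 0:
        raise ValueError("order must be >= 0")
    if T <= order + 1:
        raise ValueError(f"need T > order+1 (= {order + 1}) timepoints, got {T}")
    tau = np.linspace(-1.0, 1.0, T)
    basis = np.vander(tau, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, ts, rcond=None)
    return ts - basis @ coef


def bandpass_filter(
    ts: np.ndarray,
    tr: float,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
    method: str = "fft",
    butter_order: int = 4,
) -> np.ndarray:
    """Keep only frequency content inside [f_lo, f_hi] (Hz).

    ``method="fft"`` zeroes the discrete-Fourier bins outside the band
    (ideal filter; DC survives only if ``f_lo == 0``).  ``method="butter"``
    applies a zero-phase Butterworth via ``filtfilt``.
    """
    ts = _as_2d(ts)
    if tr <= 0:
        raise ValueError("tr must be positive")
    nyquist = 0.5 / tr
    if not (0.0 <= f_lo < f_hi <= nyquist + 1e-12):
        raise ValueError(
            f"band [{f_lo}, {f_hi}] invalid for Nyquist frequency {nyquist:g} Hz"
        )
    T = ts.shape[0]
    if method == "fft":
        freqs = np.fft.rfftfreq(T, d=tr)
        keep = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
        spec = np.fft.rfft(ts, axis=0)
        spec[~keep] = 0.0
        return np.fft.irfft(spec, n=T, axis=0)
    if method == "butter":
        lo = max(f_lo, 1e-6) / nyquist
        hi = min(f_hi / nyquist, 1.0 - 1e-6)
        sos = sp_signal.butter(butter_order, [lo, hi], btype="band", output="sos")
        return sp_signal.sosfiltfilt(sos, ts, axis=0)
    raise ValueError(f"unknown band-pass method {method!r}")


def nuisance_regress(ts: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualise each column of ``ts`` on an intercept plus confounds.

    Rank-deficient confound sets are handled by dropping linearly dependent
    columns (QR with column pivoting) with a warning; the result is the
    exact least-squares residual, orthogonal to every retained confound.
    """
    ts = _as_2d(ts)
    confounds = _as_2d(confounds)
    if confounds.shape[0] != ts.shape[0]:
        raise ValueError(
            f"confounds have {confounds.shape[0]} rows, time series {ts.shape[0]}"
        )
    design = np.column_stack([np.ones(ts.shape[0]), confounds])
    from scipy.linalg import qr

    q, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < design.shape[1]:
        dropped = sorted(piv[rank:])
        warnings.warn(
            f"dropping {design.shape[1] - rank} linearly dependent confound "
            f"column(s) (design indices {dropped})",
            RuntimeWarning,
            stacklevel=2,
        )
        design = design[:, sorted(piv[:rank])]
    coef, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ coef


def preprocess_matrix(
    ts: np.ndarray,
    tr: float,
    detrend_order: int = 2,
    band: tuple[float, float] | None = (0.01, 0.1),
    confounds: np.ndarray | None = None,
    band_method: str = "fft",
) -> np.ndarray:
    """Detrend -> band-pass -> nuisance-regress a T x V matrix (in that order)."""
    out = detrend_poly(ts, order=detrend_order)
    if band is not None:
        out = bandpass_filter(out, tr, band[0], band[1], method=band_method)
    if confounds is not None:
        out = nuisance_regress(out, confounds)
    return out


def preprocess_scan(
    scan: Scan4D,
    detrend_order: int = 2,
    band: tuple[float, float] | None = (0.01, 0.1),
    use_motion_confounds: bool = True,
    extra_confounds: np.ndarray | None = None,
    band_method: str = "fft",
) -> Scan4D:
    """Apply the temporal pipeline to every in-mask voxel of a scan.

    Confounds default to the scan's motion-parameter table; pass
    ``extra_confounds`` (e.g. CSF / white-matter grand means) to extend the
    design.  Out-of-mask voxels stay zero.
    """
    confounds = None
    parts = []
    if use_motion_confounds and scan.motion_params is not None:
        parts.append(np.asarray(scan.motion_params, dtype=float))
    if extra_confounds is not None:
        parts.append(_as_2d(extra_confounds))
    if parts:
        confounds = np.column_stack(parts)
    mat = scan.masked_matrix()
    out = preprocess_matrix(
        mat,
        tr=scan.tr,
        detrend_order=detrend_order,
        band=band,
        confounds=confounds,
        band_method=band_method,
    )
    return scan.with_masked_matrix(out)
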