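"""Post-ICA time-course conditioning.

Component time courses from a group ICA still carry slow scanner drifts,
motion-related variance, high-frequency noise and motion spikes.  This
module applies the standard conditioning sequence:

1. polynomial detrending (linear, quadratic, cubic),
2. regression of 12 motion parameters,
3. zero-phase low-pass filtering,
4. despiking of high-motion frames (framewise displacement above threshold)
   with cubic-spline interpolation over clean frames.

All steps preserve the T x C shape and operate column-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "SubjectTimecourses",
    "detrend_polynomial",
    "regress_motion",
    "lowpass_filter",
    "despike_spline",
    "preprocess_subject",
]


@dataclass
class SubjectTimecourses:
    """A subject's T x C component time courses plus motion information."""

    data: np.ndarray  # T x C
    tr: float  # seconds
    motion: np.ndarray | None = None  # T x 12
    fd_trace: np.ndarray | None = None  # length T, mm
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be T x C")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        T = self.data.shape[0]
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape[0] != T:
                raise ValueError("motion must have T rows")
        if self.fd_trace is not None:
            self.fd_trace = np.asarray(self.fd_trace, dtype=float)
            if self.fd_trace.shape[0] != T:
                raise ValueError("fd_trace must have length T")
        if np.isnan(self.data).any():
            raise ValueError("data contains missing values")


def _residualize(data: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column of data against the design."""
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def detrend_polynomial(ts: SubjectTimecourses, max_order: int = 3) -> SubjectTimecourses:
    """Remove a polynomial trend of order up to ``max_order`` (1..3) per column."""
    if not 1 <= max_order <= 3:
        raise ValueError("max_order must be in 1..3")
    T = ts.data.shape[0]
    if T <= max_order + 1:
        raise ValueError("too few time points for requested polynomial order")
    t = np.linspace(-1.0, 1.0, T)  # scaled for conditioning
    design = np.vander(t, max_order + 1, increasing=True)
    return replace(ts, data=_residualize(ts.data, design))


def regress_motion(ts: SubjectTimecourses, motion: np.ndarray | None = None) -> SubjectTimecourses:
    """Regress the 12 motion parameters (plus intercept) out of each column.

    Rank-deficient designs (e.g. all-zero motion) are handled by the
    pseudoinverse with a warning rather than an error.
    """
    if motion is None:
        motion = ts.motion
    if motion is None:
        raise ValueError("no motion parameters available")
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != ts.data.shape[0]:
        raise ValueError("motion must have T rows")
    design = np.column_stack([np.ones(motion.shape[0]), motion])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("motion design is rank deficient; using pseudoinverse",
                      stacklevel=2)
    return replace(ts, data=_residualize(ts.data, design))


def lowpass_filter(ts: SubjectTimecourses, cutoff_hz: float = 0.15,
                   order: int = 5) -> SubjectTimecourses:
    """Zero-phase Butterworth low-pass at ``cutoff_hz``.

    A cutoff at or above the Nyquist frequency (1 / (2 TR)) cannot be
    realised on the sampled series; the data pass through unchanged with a
    warning.  The conventional cutoff for windowed connectivity analyses at
    TR ~ 2 s is 0.15 Hz, the default here.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    nyquist = 1.0 / (2.0 * ts.tr)
    if cutoff_hz >= nyquist:
        warnings.warn(
            f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist:.4f} Hz; passing through",
            stacklevel=2,
        )
        return replace(ts, data=ts.data.copy())
    T = ts.data.shape[0]
    # sosfiltfilt needs padlen < T; default padding for order-5 sos is small
    if T < 3 * (2 * order + 1):
        raise ValueError("series too short for the requested filter order")
    sos = butter(order, cutoff_hz / nyquist, btype="low", output="sos")
    return replace(ts, data=sosfiltfilt(sos, ts.data, axis=0))


def despike_spline(ts: SubjectTimecourses, fd_thresh: float = 0.5,
                   spline_order: int = 3) -> tuple[SubjectTimecourses, np.ndarray]:
    """Replace frames with FD > ``fd_thresh`` by cubic-spline interpolation.

    Returns the despiked time courses and the boolean spike mask.  Spikes at
    the sequence ends are extrapolated from the nearest clean frames.  More
    than 50% flagged frames marks the subject unusable (error).
    """
    if spline_order != 3:
        raise ValueError("only cubic (order 3) spline interpolation is supported")
    if ts.fd_trace is None:
        raise ValueError("fd_trace required for despiking")
    mask = ts.fd_trace > fd_thresh
    if not mask.any():
        return replace(ts, data=ts.data.copy()), mask
    if mask.mean() > 0.5:
        raise ValueError(
            f"{mask.mean():.0%} of frames exceed FD {fd_thresh} mm; subject unusable"
        )
    good = np.flatnonzero(~mask)
    if good.size < 4:
        raise ValueError("fewer than 4 clean frames; cannot fit cubic spline")
    out = ts.data.copy()
    spline = CubicSpline(good, ts.data[good], axis=0, extrapolate=True)
    out[mask] = spline(np.flatnonzero(mask))
    return replace(ts, data=out), mask


def preprocess_subject(
    ts: SubjectTimecourses,
    detrend_order: int = 3,
    cutoff_hz: float = 0.15,
    fd_thresh: float = 0.5,
    despike_before_filter: bool = False,
) -> tuple[SubjectTimecourses, np.ndarray]:
    """Full conditioning pipeline: detrend -> motion -> filter -> despike.

    ``despike_before_filter`` swaps the last two stages for users who prefer
    removing spikes before frequency filtering.
    """
    out = detrend_polynomial(ts, detrend_order)
    if out.motion is not None:
        out = regress_motion(out)
    if out.fd_trace is None:
        out = lowpass_filter(out, cutoff_hz=cutoff_hz)
        return out, np.zeros(out.data.shape[0], dtype=bool)
    if despike_before_filter:
        out, mask = despike_spline(out, fd_thresh=fd_thresh)
        out = lowpass_filter(out, cutoff_hz=cutoff_hz)
    else:
        out = lowpass_filter(out, cutoff_hz=cutoff_hz)
        out, mask = despike_spline(out, fd_thresh=fd_thresh)
    return out, mask
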