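"""Pullback traces and elementary operations on them.

A *virtual pullback* is the point-by-point QFR-vs-position curve along a
coronary vessel, analogous to a motorized pressure-wire pullback.  Positions
are millimetres from the proximal landmark (the ostium of the analyzed
segment, position 0); the last position is the total vessel length (TVL).
The QFR value at a single position is the *index QFR* there; the distal
index QFR of a trace is the vessel's QFR value for that phase (pre- or
post-PCI).

All downstream metrics operate on a trace that has been resampled to a
uniform grid and projected onto the non-increasing cone
(:func:`preprocess_trace`): physiologically, distal pressure cannot recover
along a vessel, so upward wiggles are acquisition noise and the isotonic
projection is the minimal, parameter-free way to remove them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.isotonic import IsotonicRegression

from .errors import InvalidParameterError, InvalidTraceError, OutOfRangeError

#: QFR values live in (0, 1.05]; the small allowance above 1 is for
#: acquisition noise at the ostium only.
QFR_MAX = 1.05

#: Default resampling step of the analysis grid, mm.
DEFAULT_STEP_MM = 0.5

PRE_PCI = "pre_pci"
POST_PCI = "post_pci"
_PHASES = (PRE_PCI, POST_PCI)


@dataclass(frozen=True)
class PullbackTrace:
    """A sampled QFR-vs-position curve for one vessel.

    Parameters
    ----------
    vessel_id : str
        Opaque vessel identifier.
    positions_mm : array-like of float
        Strictly increasing, first element 0 (proximal landmark); the last
        element is the total vessel length.
    qfr : array-like of float
        Index QFR at each position, in ``(0, 1.05]``.
    phase : {"pre_pci", "post_pci"}
    """

    vessel_id: str
    positions_mm: np.ndarray
    qfr: np.ndarray
    phase: str = PRE_PCI

    def __post_init__(self):
        pos = np.asarray(self.positions_mm, dtype=float)
        q = np.asarray(self.qfr, dtype=float)
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "qfr", q)
        if pos.ndim != 1 or q.ndim != 1 or pos.shape != q.shape:
            raise InvalidTraceError("positions_mm and qfr must be 1-D and of equal length")
        if pos.size < 2:
            raise InvalidTraceError("a trace needs at least 2 samples")
        if not np.isfinite(pos).all() or not np.isfinite(q).all():
            raise InvalidTraceError("positions and qfr must be finite")
        if abs(pos[0]) > 1e-9:
            raise InvalidTraceError(f"first position must be 0 (got {pos[0]!r})")
        if np.any(np.diff(pos) <= 0):
            raise InvalidTraceError("positions_mm must be strictly increasing")
        if np.any(q <= 0) or np.any(q > QFR_MAX):
            raise InvalidTraceError(f"qfr values must lie in (0, {QFR_MAX}]")
        if self.phase not in _PHASES:
            raise InvalidTraceError(f"phase must be one of {_PHASES}, got {self.phase!r}")

    @property
    def tvl_mm(self) -> float:
        """Total vessel length: distance from proximal to distal landmark."""
        return float(self.positions_mm[-1])

    @property
    def ostial_qfr(self) -> float:
        return float(self.qfr[0])

    @property
    def distal_qfr(self) -> float:
        """Index QFR at the most distal analyzed location (the vessel's
        pre- or post-PCI QFR value, depending on phase)."""
        return float(self.qfr[-1])

    def __len__(self) -> int:
        return int(self.positions_mm.size)


def resample_trace(trace: PullbackTrace, step_mm: float = DEFAULT_STEP_MM) -> PullbackTrace:
    """Resample a trace onto a uniform grid by linear interpolation.

    The grid runs from 0 to TVL inclusive with spacing ``step_mm``; if TVL is
    not a multiple of the step, the distal landmark is appended so TVL is
    preserved exactly.
    """
    tvl = trace.tvl_mm
    if not (0 < step_mm <= tvl):
        raise InvalidParameterError(
            f"step_mm must be in (0, TVL={tvl}], got {step_mm}"
        )
    n = int(np.floor(tvl / step_mm + 1e-9))
    grid = np.arange(n + 1) * step_mm
    if tvl - grid[-1] > 1e-9:
        grid = np.append(grid, tvl)
    else:
        grid[-1] = tvl
    q = np.interp(grid, trace.positions_mm, trace.qfr)
    return replace(trace, positions_mm=grid, qfr=q)


def monotone_envelope(trace: PullbackTrace) -> PullbackTrace:
    """Least-squares non-increasing projection of the QFR values.

    Pool-adjacent-violators (isotonic regression with decreasing constraint);
    idempotent and order-preserving, with no other smoothing.
    """
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    q = iso.fit_transform(trace.positions_mm, trace.qfr)
    return replace(trace, qfr=np.asarray(q, dtype=float))


def preprocess_trace(trace: PullbackTrace, step_mm: float = DEFAULT_STEP_MM) -> PullbackTrace:
    """Standard pre-processing: resample to a uniform grid, then project onto
    the non-increasing cone.  All pattern and QVP computations assume this."""
    return monotone_envelope(resample_trace(trace, step_mm))


def index_qfr(trace: PullbackTrace, position_mm: float) -> float:
    """Index QFR at an arbitrary position (linear interpolation).

    Mirrors reading the value off the pullback by moving the index-QFR
    cursor to ``position_mm``.
    """
    tvl = trace.tvl_mm
    if not (-1e-9 <= position_mm <= tvl + 1e-9):
        raise OutOfRangeError(
            f"position {position_mm} mm outside the analyzed vessel [0, {tvl}]"
        )
    return float(np.interp(position_mm, trace.positions_mm, trace.qfr))


def delta_qfr_vessel(trace: PullbackTrace) -> float:
    """ΔQFR_vessel: ostial minus distal index QFR.

    Zero for a disease-free vessel.  A negative value can only arise on raw
    noisy input used without :func:`monotone_envelope`; it is returned as-is
    but flagged with a warning.
    """
    delta = trace.ostial_qfr - trace.distal_qfr
    if delta < 0:
        warnings.warn(
            f"negative ΔQFR_vessel ({delta:.4f}) on {trace.vessel_id!r}; "
            "apply monotone_envelope before computing vessel metrics",
            stacklevel=2,
        )
    return delta


class PullbackPreprocessor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying :func:`preprocess_trace` to a
    sequence of traces.  Stateless; ``fit`` only validates."""

    def __init__(self, step_mm: float = DEFAULT_STEP_MM):
        self.step_mm = step_mm

    def fit(self, X, y=None) -> "PullbackPreprocessor":
        if self.step_mm <= 0:
            raise InvalidParameterError("step_mm must be positive")
        self.n_traces_in_ = len(X)
        return self

    def transform(self, X) -> list[PullbackTrace]:
        return [preprocess_trace(t, self.step_mm) for t in X]
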