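"""Quantitative method: the QFR virtual-pullback index (QVP index).

The QVP index summarises how *focal* the functional disease of a vessel is:

    QVP = [ (MaxQFR_20mm / ΔQFR_vessel) + (1 − LFD / TVL) ] / 2

where ``MaxQFR_20mm`` is the maximal QFR drop over any 20-mm segment,
``ΔQFR_vessel`` the ostial-minus-distal QFR difference, ``LFD`` the length
of vessel with functional disease (declining QFR) and ``TVL`` the total
vessel length.  On a non-increasing trace both terms lie in [0, 1], so the
index does too: values near 1 indicate focal disease (all the pressure loss
concentrated in one short segment), values near 0 diffuse disease (loss
spread along the whole vessel).

Published cutoffs on the index: >0.71 predicts a focal pattern, ≤0.51 a
diffuse pattern, ≤0.57 a suboptimal PCI result (post-PCI QFR ≤0.89);
tertile bounds are ≤0.54 / 0.55–0.71 / >0.71.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvalidParameterError, NoFunctionalDiseaseError
from .trace import DEFAULT_STEP_MM, PullbackTrace, preprocess_trace

#: Default sliding-window length for the maximal drop, mm.
DEFAULT_WINDOW_MM = 20.0
#: Minimal per-mm QFR decline for a grid cell to count as diseased.
DEFAULT_SLOPE_EPS = 0.002
#: Diseased segments closer than this are merged, mm.
DEFAULT_MERGE_GAP_MM = 2.0
#: ΔQFR_vessel at or below this means "no functional disease".
DEFAULT_MIN_DELTA = 0.02

FOCAL_PREDICTED = "focal_predicted"
DIFFUSE_PREDICTED = "diffuse_predicted"
INTERMEDIATE = "intermediate"

TERTILE_LOWEST = "lowest"
TERTILE_INTERMEDIATE = "intermediate"
TERTILE_HIGHEST = "highest"


@dataclass(frozen=True)
class Thresholds:
    """Published decision thresholds, overridable via configuration.

    All values are in QFR/QVP units.  Boundary semantics follow the printed
    inequality signs exactly: focal predicted for QVP > ``focal_pred_cutoff``,
    diffuse predicted for QVP ≤ ``diffuse_pred_cutoff``, suboptimal-PCI
    prediction for QVP ≤ ``suboptimal_qvp_cutoff``, suboptimal outcome for
    post-PCI QFR ≤ ``suboptimal_post_qfr``; tertiles are
    ≤ ``tertile_bounds[0]``, (bounds[0], bounds[1]], > bounds[1].
    """

    focal_pred_cutoff: float = 0.71
    diffuse_pred_cutoff: float = 0.51
    suboptimal_qvp_cutoff: float = 0.57
    tertile_bounds: tuple[float, float] = (0.54, 0.71)
    suboptimal_post_qfr: float = 0.89

    def __post_init__(self):
        if not (self.diffuse_pred_cutoff < self.suboptimal_qvp_cutoff < self.focal_pred_cutoff):
            raise InvalidParameterError(
                "thresholds must satisfy diffuse < suboptimal < focal cutoff"
            )


@dataclass(frozen=True)
class VesselMetrics:
    """The quantitative-method terms for one vessel, plus the QVP index."""

    vessel_id: str
    tvl_mm: float
    distal_qfr: float
    delta_qfr_vessel: float
    max_qfr_20mm: float
    max20_start_mm: float
    lfd_mm: float
    qvp_index: float


def max_drop_over_window(
    trace: PullbackTrace, window_mm: float = DEFAULT_WINDOW_MM
) -> tuple[float, float]:
    """Maximal QFR drop over any window of ``window_mm`` fully inside the vessel.

    Returns ``(drop, window_start_mm)``.  The window start ranges over the
    grid positions in ``[0, TVL − window_mm]``; ties go to the smallest
    start.  For vessels no longer than the window, ΔQFR_vessel is returned
    with start 0 (short vessels are focal-dominant by construction).

    Expects a pre-processed (uniform, non-increasing) trace.
    """
    if window_mm <= 0:
        raise InvalidParameterError(f"window_mm must be positive, got {window_mm}")
    pos, q = trace.positions_mm, trace.qfr
    tvl = trace.tvl_mm
    if tvl <= window_mm:
        return q[0] - q[-1], 0.0
    mask = pos <= tvl - window_mm + 1e-9
    starts = pos[mask]
    q_end = np.interp(starts + window_mm, pos, q)
    drops = q[mask] - q_end
    i = int(np.argmax(drops))  # argmax returns the first max -> smallest start
    return float(drops[i]), float(starts[i])


def functional_disease_length(
    trace: PullbackTrace,
    slope_eps: float = DEFAULT_SLOPE_EPS,
    merge_gap_mm: float = DEFAULT_MERGE_GAP_MM,
) -> tuple[float, list[tuple[float, float]]]:
    """Length of vessel with functional disease and the diseased segments.

    A grid cell ``[x_i, x_{i+1})`` is diseased iff its QFR decline per mm
    exceeds ``slope_eps``; runs of diseased cells form segments, and
    segments separated by less than ``merge_gap_mm`` are merged.  Returns
    ``(lfd_mm, segments)`` with half-open ``[start, end)`` intervals sorted
    and disjoint.  A flat vessel returns ``(0.0, [])``.
    """
    pos, q = trace.positions_mm, trace.qfr
    dx = np.diff(pos)
    slope = (q[:-1] - q[1:]) / dx
    diseased = slope > slope_eps
    segments: list[list[float]] = []
    for i, flag in enumerate(diseased):
        if not flag:
            continue
        start, end = float(pos[i]), float(pos[i + 1])
        if segments and start - segments[-1][1] < merge_gap_mm:
            segments[-1][1] = end
        else:
            segments.append([start, end])
    out = [(s, e) for s, e in segments]
    lfd = float(sum(e - s for s, e in out))
    return lfd, out


def qvp_from_terms(
    delta_qfr: float,
    max_qfr_20mm: float,
    lfd_mm: float,
    tvl_mm: float,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> float:
    """Evaluate the QVP-index formula from its four terms.

    Raises :class:`NoFunctionalDiseaseError` when ΔQFR_vessel ≤ ``min_delta``:
    the index is undefined for disease-free vessels (the study analyzed
    only vessels undergoing PCI, median pre-PCI QFR 0.74).
    """
    if delta_qfr <= min_delta:
        raise NoFunctionalDiseaseError(
            f"ΔQFR_vessel = {delta_qfr:.4f} ≤ {min_delta}: QVP index undefined "
            "for vessels without functional disease"
        )
    if tvl_mm <= 0:
        raise InvalidParameterError("tvl_mm must be positive")
    if not (0 <= lfd_mm <= tvl_mm + 1e-9):
        raise InvalidParameterError("lfd_mm must lie in [0, tvl_mm]")
    return (max_qfr_20mm / delta_qfr + (1.0 - lfd_mm / tvl_mm)) / 2.0


def compute_vessel_metrics(
    trace: PullbackTrace,
    window_mm: float = DEFAULT_WINDOW_MM,
    slope_eps: float = DEFAULT_SLOPE_EPS,
    merge_gap_mm: float = DEFAULT_MERGE_GAP_MM,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> VesselMetrics:
    """All quantitative-method terms for one pre-processed trace."""
    delta = trace.ostial_qfr - trace.distal_qfr
    max20, start = max_drop_over_window(trace, window_mm)
    lfd, _ = functional_disease_length(trace, slope_eps, merge_gap_mm)
    qvp = qvp_from_terms(delta, max20, lfd, trace.tvl_mm, min_delta)
    return VesselMetrics(
        vessel_id=trace.vessel_id,
        tvl_mm=trace.tvl_mm,
        distal_qfr=trace.distal_qfr,
        delta_qfr_vessel=delta,
        max_qfr_20mm=max20,
        max20_start_mm=start,
        lfd_mm=lfd,
        qvp_index=qvp,
    )


def compute_qvp_index(metrics: VesselMetrics, min_delta: float = DEFAULT_MIN_DELTA) -> float:
    """QVP index from already-extracted vessel metrics."""
    return qvp_from_terms(
        metrics.delta_qfr_vessel,
        metrics.max_qfr_20mm,
        metrics.lfd_mm,
        metrics.tvl_mm,
        min_delta,
    )


def _check_qvp(qvp: float) -> None:
    if not (0.0 <= qvp <= 1.0):
        raise InvalidParameterError(f"QVP index must lie in [0, 1], got {qvp}")


def qvp_predicted_pattern(qvp: float, thresholds: Thresholds | None = None) -> str:
    """Pattern predicted by the index alone: > focal cutoff -> focal,
    ≤ diffuse cutoff -> diffuse, otherwise intermediate."""
    th = thresholds or Thresholds()
    _check_qvp(qvp)
    if qvp > th.focal_pred_cutoff:
        return FOCAL_PREDICTED
    if qvp <= th.diffuse_pred_cutoff:
        return DIFFUSE_PREDICTED
    return INTERMEDIATE


def qvp_tertile(qvp: float, thresholds: Thresholds | None = None) -> str:
    """Study-defined tertile of the QVP index (lowest / intermediate / highest)."""
    th = thresholds or Thresholds()
    _check_qvp(qvp)
    lo, hi = th.tertile_bounds
    if qvp <= lo:
        return TERTILE_LOWEST
    if qvp <= hi:
        return TERTILE_INTERMEDIATE
    return TERTILE_HIGHEST


class QvpIndexExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping pullback traces to quantitative-method metrics.

    ``transform`` accepts a sequence of :class:`PullbackTrace` and returns a
    :class:`pandas.DataFrame` with one row per vessel: the QVP terms, the
    index, the index-predicted pattern and the tertile.

    Parameters
    ----------
    step_mm : resampling step of the analysis grid.
    window_mm : sliding-window length for MaxQFR_20mm.
    slope_eps, merge_gap_mm : disease-segmentation parameters.
    min_delta : ΔQFR below which a vessel counts as disease-free.
    on_no_disease : {"raise", "nan"}
        Whether a disease-free vessel raises or yields NaN metrics.
    thresholds : decision thresholds for pattern prediction and tertiles.
    preprocess : set False if traces are already resampled and monotone.
    """

    def __init__(
        self,
        step_mm: float = DEFAULT_STEP_MM,
        window_mm: float = DEFAULT_WINDOW_MM,
        slope_eps: float = DEFAULT_SLOPE_EPS,
        merge_gap_mm: float = DEFAULT_MERGE_GAP_MM,
        min_delta: float = DEFAULT_MIN_DELTA,
        on_no_disease: str = "raise",
        thresholds: Thresholds | None = None,
        preprocess: bool = True,
    ):
        self.step_mm = step_mm
        self.window_mm = window_mm
        self.slope_eps = slope_eps
        self.merge_gap_mm = merge_gap_mm
        self.min_delta = min_delta
        self.on_no_disease = on_no_disease
        self.thresholds = thresholds
        self.preprocess = preprocess

    def fit(self, X, y=None) -> "QvpIndexExtractor":
        if self.window_mm <= 0:
            raise InvalidParameterError("window_mm must be positive")
        if self.on_no_disease not in ("raise", "nan"):
            raise InvalidParameterError("on_no_disease must be 'raise' or 'nan'")
        self.thresholds_ = self.thresholds or Thresholds()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            self.fit(X)
        rows = []
        for trace in X:
            t = preprocess_trace(trace, self.step_mm) if self.preprocess else trace
            row: dict = {"vessel_id": t.vessel_id, "phase": t.phase}
            try:
                m = compute_vessel_metrics(
                    t, self.window_mm, self.slope_eps, self.merge_gap_mm, self.min_delta
                )
            except NoFunctionalDiseaseError:
                if self.on_no_disease == "raise":
                    raise
                row.update(
                    tvl_mm=t.tvl_mm, distal_qfr=t.distal_qfr,
                    delta_qfr=t.ostial_qfr - t.distal_qfr,
                    max20=np.nan, max20_start_mm=np.nan, lfd_mm=np.nan,
                    qvp_index=np.nan, qvp_predicted_pattern=None, qvp_tertile=None,
                )
                rows.append(row)
                continue
            qvp = min(max(m.qvp_index, 0.0), 1.0)  # guard FP round-off at the ends
            row.update(
                tvl_mm=m.tvl_mm,
                distal_qfr=m.distal_qfr,
                delta_qfr=m.delta_qfr_vessel,
                max20=m.max_qfr_20mm,
                max20_start_mm=m.max20_start_mm,
                lfd_mm=m.lfd_mm,
                qvp_index=m.qvp_index,
                qvp_predicted_pattern=qvp_predicted_pattern(qvp, self.thresholds_),
                qvp_tertile=qvp_tertile(qvp, self.thresholds_),
            )
            rows.append(row)
        return pd.DataFrame(rows)
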