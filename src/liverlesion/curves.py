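"""Contrast curves and the eight kinetic descriptors computed on them.

Four curves are built per lesion:

* TIC — the raw time-intensity curve (per pixel, or ROI average),
* CEC — contrast-enhancement curve: TIC divided by the pixel's
  pre-contrast intensity,
* CE ratio — average lesion CEC divided time-point-wise by the average
  parenchyma CEC,
* TIC ratio — the same ratio on the raw TICs.

Each curve yields eight model-free kinetic features (maximum enhancement,
time to peak, uptake rate, washout rate, area under the curve, average
plateau, early-to-late signal-enhancement ratio, time of arrival). For the
CEC and the per-pixel CE ratio, the within-lesion standard deviation of
each feature is an additional heterogeneity descriptor.

Feature definitions (all relative to the baseline ``c0 = values[0]``):

========================  =====================================================
maximum enhancement (ME)  ``max(values) - c0``
time to peak (TTP)        earliest time attaining the maximum
time of arrival (TOA)     earliest time with ``values - c0 >= 0.1 * ME``
                          (TTP when ME <= 0)
uptake rate               ``ME / max(TTP - TOA, dt_min)``
washout rate              ``(values[TTP] - values[-1]) / max(t_end - TTP, dt_min)``
AUC                       trapezoidal integral of ``values - c0``
average plateau           mean of the last 3 values minus ``c0``
SER                       (mean of values at time points 2-4 minus ``c0``)
                          / (average plateau + eps)
========================  =====================================================

``dt_min`` defaults to the first inter-frame interval, which keeps the two
rates finite on curves peaking at the first or last frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DceSeries, validate_mask

CURVE_FEATURE_NAMES: tuple[str, ...] = (
    "max_enhancement",
    "ttp_s",
    "uptake_rate",
    "washout_rate",
    "auc",
    "average_plateau",
    "ser",
    "time_of_arrival_s",
)

#: Guard against division by (near-)zero pre-contrast or parenchyma values.
DEFAULT_EPSILON = 1e-6
#: Guard in the SER denominator.
DEFAULT_EPS_SER = 1e-6
#: Fraction of maximum enhancement defining the time of arrival.
ARRIVAL_FRACTION = 0.1


@dataclass
class TimeCurve:
    """Real values on a strictly increasing time axis (seconds)."""

    values: np.ndarray
    times_s: np.ndarray
    kind: str = "TIC"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.values.shape != self.times_s.shape or self.values.ndim != 1:
            raise ValueError("values and times must be 1D arrays of equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class CurveFeatureSet:
    """The eight kinetic descriptors of one contrast curve."""

    max_enhancement: float
    ttp_s: float
    uptake_rate: float
    washout_rate: float
    auc: float
    average_plateau: float
    ser: float
    time_of_arrival_s: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in CURVE_FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in CURVE_FEATURE_NAMES])


def pixel_tics(series: DceSeries, mask: np.ndarray) -> list[TimeCurve]:
    """One raw time-intensity curve per masked pixel (row-major pixel order)."""
    mask = validate_mask(mask, series.shape)
    profiles = series.data[:, mask]  # (T, n_pixels)
    return [
        TimeCurve(profiles[:, i], series.times_s, kind="TIC")
        for i in range(profiles.shape[1])
    ]


def average_curve(curves: list[TimeCurve], kind: str | None = None) -> TimeCurve:
    """Point-wise mean of a set of curves sharing a time axis."""
    if not curves:
        raise ValueError("need at least one curve")
    times = curves[0].times_s
    for c in curves[1:]:
        if not np.array_equal(c.times_s, times):
            raise ValueError("curves have mismatched time axes")
    stacked = np.stack([c.values for c in curves])
    return TimeCurve(stacked.mean(axis=0), times, kind=kind or curves[0].kind)


def roi_mean_curve(series: DceSeries, mask: np.ndarray, kind: str = "TIC") -> TimeCurve:
    """ROI mean intensity per frame (equals the average of the pixel TICs)."""
    mask = validate_mask(mask, series.shape)
    return TimeCurve(series.data[:, mask].mean(axis=1), series.times_s, kind=kind)


def cec_from_tic(
    tic: TimeCurve, precontrast_value: float, epsilon: float = DEFAULT_EPSILON
) -> TimeCurve:
    """Contrast-enhancement curve: TIC divided by the pre-contrast intensity."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    denom = max(float(precontrast_value), epsilon)
    return TimeCurve(tic.values / denom, tic.times_s, kind="CEC")


def ratio_curve(
    lesion_avg: TimeCurve,
    parenchyma_avg: TimeCurve,
    epsilon: float = DEFAULT_EPSILON,
    kind: str = "CE_ratio",
) -> TimeCurve:
    """Time-point-wise lesion/parenchyma ratio of two average curves."""
    if not np.array_equal(lesion_avg.times_s, parenchyma_avg.times_s):
        raise ValueError("lesion and parenchyma curves have different time axes")
    denom = np.maximum(parenchyma_avg.values, epsilon)
    return TimeCurve(lesion_avg.values / denom, lesion_avg.times_s, kind=kind)


def curve_features(
    curve: TimeCurve,
    *,
    dt_min_s: float | None = None,
    arrival_fraction: float = ARRIVAL_FRACTION,
    eps_ser: float = DEFAULT_EPS_SER,
) -> CurveFeatureSet:
    """Compute the eight kinetic descriptors of one curve (see module docstring)."""
    values, times = curve.values, curve.times_s
    n = len(values)
    if n < 3:
        raise ValueError("curve features need at least 3 time points")
    if dt_min_s is None:
        dt_min_s = float(times[1] - times[0])

    c0 = values[0]
    enhancement = values - c0
    ttp_index = int(np.argmax(values))  # earliest maximum
    ttp = float(times[ttp_index])
    me = float(values[ttp_index] - c0)

    if me <= 0:
        toa = ttp
    else:
        arrived = np.nonzero(enhancement >= arrival_fraction * me)[0]
        toa = float(times[arrived[0]])

    uptake = me / max(ttp - toa, dt_min_s)
    washout = float(values[ttp_index] - values[-1]) / max(float(times[-1]) - ttp, dt_min_s)
    auc = float(np.trapezoid(enhancement, times))
    plateau = float(enhancement[-3:].mean())
    early = float(enhancement[1:4].mean())
    ser = early / (plateau + eps_ser)

    return CurveFeatureSet(
        max_enhancement=me,
        ttp_s=ttp,
        uptake_rate=uptake,
        washout_rate=washout,
        auc=auc,
        average_plateau=plateau,
        ser=ser,
        time_of_arrival_s=toa,
    )


def per_pixel_feature_sd(curves: list[TimeCurve], **feature_kwargs) -> dict[str, float]:
    """Sample standard deviation (ddof=1) of each kinetic feature across pixel curves.

    With fewer than two curves every SD is reported as 0 (with a warning):
    a one-pixel lesion has no within-lesion heterogeneity to measure.
    """
    if len(curves) < 2:
        warnings.warn("fewer than 2 pixel curves: per-pixel feature SDs set to 0", stacklevel=2)
        return {name: 0.0 for name in CURVE_FEATURE_NAMES}
    table = np.stack([curve_features(c, **feature_kwargs).as_array() for c in curves])
    sds = table.std(axis=0, ddof=1)
    return dict(zip(CURVE_FEATURE_NAMES, sds.tolist()))
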