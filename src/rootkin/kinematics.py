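"""Growth-trend and kinematic features of a root-tip trajectory.

The main growth component is the low-frequency trend of the 3D trajectory
obtained by a centred moving average whose window spans 4 h of samples
(80 samples at the default 3-min interval), long enough to average out
circumnutation (30-120 min periods) while following the slower drift of
the growing tip.  All length-based features are path lengths along that
trend:

* overall length         L = sum_i ||p(i+1) - p(i)||
* absolute growth rate   sum over a chosen interval of d samples
* relative growth rate   the same sum divided by the trend length
                         accumulated up to the interval's end
* average tip velocity   mean of hourly path lengths of the raw trajectory
                         evaluated on a sliding window every 15 min
* max nutation amplitude max of the XY distance between raw trajectory and
                         trend

Indices are 0-based internally; interval definitions (start a, span d)
count samples exactly as in the 1-based formulation, with a shifted by one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import GridMismatchError, SchemaError
from .smoothing import centered_moving_average, half_window
from .spectral import NutationDistanceSeries
from .trajectory import Trajectory3D

__all__ = [
    "MainGrowthComponent",
    "GrowthInterval",
    "FeatureSet",
    "main_growth_component",
    "overall_length",
    "absolute_growth_rate",
    "relative_growth_rate",
    "daily_growth_rates",
    "average_tip_velocity",
    "nutation_distance_series",
    "max_nutation_amplitude",
    "extract_features",
]


@dataclass
class MainGrowthComponent:
    """Smoothed trajectory samples p(i) — the main component of root growth."""

    times: np.ndarray
    points: np.ndarray
    window_samples: int
    source: Optional[Trajectory3D] = None
    edge: str = "shrink"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape != (self.times.size, 3):
            raise SchemaError("MainGrowthComponent: points must be (n, 3)")

    @property
    def sampling_interval(self) -> float:
        if self.source is not None:
            return self.source.sampling_interval
        return float(np.median(np.diff(self.times))) if len(self.times) > 1 else 0.0

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class GrowthInterval:
    """Sample interval for growth rates: start index a (0-based), span d samples."""

    start: int
    span: int

    def __post_init__(self):
        if self.start < 0 or self.span < 0:
            raise ValueError("interval start and span must be non-negative")

    def validate(self, n: int) -> None:
        if self.start + self.span > n - 1:
            raise IndexError(
                f"interval [{self.start}, {self.start + self.span}] out of bounds "
                f"for {n} samples"
            )


@dataclass
class FeatureSet:
    """Scalar/array kinematic features of one plant."""

    overall_length: float
    absolute_daily_rates: np.ndarray
    relative_daily_rates: np.ndarray
    average_tip_velocity: float
    max_nutation_amplitude: float
    main_period: float
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "overall_length_mm": float(self.overall_length),
            "absolute_daily_rates_mm_per_day": [float(v) for v in self.absolute_daily_rates],
            "relative_daily_rates_per_day": [float(v) for v in self.relative_daily_rates],
            "average_tip_velocity_mm_per_h": float(self.average_tip_velocity),
            "max_nutation_amplitude_mm": float(self.max_nutation_amplitude),
            "main_period_h": float(self.main_period),
            "provenance": self.provenance,
        }


def main_growth_component(
    traj: Trajectory3D, window_hours: float = 4.0, edge: str = "shrink"
) -> MainGrowthComponent:
    """Centred moving average of the trajectory coordinates.

    The window holds the samples acquired in ``window_hours``
    (N = round(window_hours * 60 / sampling_interval)).  With the default
    "shrink" edge policy the window contracts symmetrically at the record
    ends and the output keeps the input length; with "trim" only samples
    with a complete window are kept.
    """
    if window_hours <= 0:
        raise ValueError("window_hours must be positive")
    if len(traj) < 2:
        raise SchemaError("trajectory must have at least 2 samples")
    window = max(1, round(window_hours * 60.0 / traj.sampling_interval))
    pts = centered_moving_average(traj.points, window, edge=edge)
    if edge == "trim":
        h = half_window(window)
        times = traj.times[h : len(traj) - h]
    else:
        times = traj.times.copy()
    return MainGrowthComponent(
        times=times, points=pts, window_samples=window, source=traj, edge=edge
    )


def _segment_lengths(points: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(points, axis=0), axis=1)


def overall_length(mgc: MainGrowthComponent) -> float:
    """Overall primary root length: sum of 3D segment lengths along the trend."""
    if len(mgc) < 2:
        return 0.0
    return float(_segment_lengths(mgc.points).sum())


def absolute_growth_rate(mgc: MainGrowthComponent, interval: GrowthInterval) -> float:
    """Path length (mm) along the trend over the d samples starting at a."""
    interval.validate(len(mgc))
    if interval.span == 0:
        return 0.0
    seg = _segment_lengths(
        mgc.points[interval.start : interval.start + interval.span + 1]
    )
    return float(seg.sum())


def relative_growth_rate(mgc: MainGrowthComponent, interval: GrowthInterval) -> float:
    """Interval path length normalized by the trend length accumulated to its end."""
    interval.validate(len(mgc))
    end = interval.start + interval.span
    denom = float(_segment_lengths(mgc.points[: end + 1]).sum())
    if denom <= 0:
        raise ZeroDivisionError(
            "relative growth rate undefined: zero trend length at interval end"
        )
    return absolute_growth_rate(mgc, interval) / denom


def daily_growth_rates(
    mgc: MainGrowthComponent, day_length_h: float = 24.0
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute (mm/day) and relative (/day) growth rates per complete day.

    Days are consecutive non-overlapping intervals of ``day_length_h``
    starting at the first sample; a trailing partial day is dropped.
    """
    dt = mgc.sampling_interval
    spd = round(day_length_h * 60.0 / dt)
    n_days = (len(mgc) - 1) // spd
    if n_days == 0:
        warnings.warn("trajectory spans less than one day: empty daily rates", stacklevel=2)
        return np.array([]), np.array([])
    absolute = np.empty(n_days)
    relative = np.empty(n_days)
    for j in range(n_days):
        iv = GrowthInterval(start=j * spd, span=spd)
        absolute[j] = absolute_growth_rate(mgc, iv)
        relative[j] = relative_growth_rate(mgc, iv)
    return absolute, relative


def average_tip_velocity(
    traj: Trajectory3D,
    eval_step_min: float = 15.0,
    window_min: float = 60.0,
    smoothed: Optional[MainGrowthComponent] = None,
) -> float:
    """Average distance travelled by the tip per hour (mm/h).

    The hourly velocity is the raw-trajectory path length over a sliding
    window of ``window_min`` minutes, divided by the window length in
    hours; it is evaluated every ``eval_step_min`` minutes and the values
    are averaged.  Pass ``smoothed`` to measure the trend instead of the
    raw track.
    """
    points = smoothed.points if smoothed is not None else traj.points
    times = smoothed.times if smoothed is not None else traj.times
    dt = traj.sampling_interval
    span = (times[-1] - times[0]) if len(times) else 0.0
    if span < window_min:
        raise SchemaError("trajectory shorter than the velocity window")
    win = round(window_min / dt)
    step = max(1, round(eval_step_min / dt))
    seg = _segment_lengths(points)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    starts = np.arange(0, len(points) - win, step)
    hourly = (cum[starts + win] - cum[starts]) / (window_min / 60.0)
    return float(hourly.mean())


def nutation_distance_series(
    traj: Trajectory3D, mgc: MainGrowthComponent
) -> NutationDistanceSeries:
    """XY-plane distance between each raw sample and the trend at the same time.

    Pairs samples by time index (no closest-point search); depth (z) is
    ignored.  If the trend was trimmed, the matching raw samples are used.
    """
    if len(mgc) == len(traj) and np.allclose(mgc.times, traj.times):
        raw = traj.points
    else:
        idx = np.searchsorted(traj.times, mgc.times)
        if (
            np.any(idx >= len(traj))
            or not np.allclose(traj.times[idx], mgc.times)
        ):
            raise GridMismatchError("trend time grid is not a subset of the trajectory's")
        raw = traj.points[idx]
    d = np.hypot(
        raw[:, 0] - mgc.points[:, 0],
        raw[:, 1] - mgc.points[:, 1],
    )
    return NutationDistanceSeries(
        times=mgc.times.copy(), distances=d, sampling_interval=traj.sampling_interval
    )


def max_nutation_amplitude(series: NutationDistanceSeries) -> float:
    """Maximum of the nutation-distance array (mm)."""
    if len(series) == 0:
        raise SchemaError("empty nutation-distance series")
    return float(series.distances.max())


def extract_features(
    traj: Trajectory3D,
    window_hours: float = 4.0,
    eval_step_min: float = 15.0,
    velocity_window_min: float = 60.0,
    day_length_h: float = 24.0,
    trim_edges: bool = True,
) -> FeatureSet:
    """Compute the full feature set of one plant from its 3D trajectory.

    With ``trim_edges`` (default) the length-based features, the nutation
    distances and the spectrum are computed on the interior region where
    the smoothing window is complete: the shrinking edge windows leave an
    oscillation residual in the trend that would otherwise leak into path
    lengths and amplitudes.  Velocity always uses the raw trajectory.
    """
    from .spectral import amplitude_spectrum, main_period as _main_period

    edge = "trim" if trim_edges else "shrink"
    mgc = main_growth_component(traj, window_hours=window_hours, edge=edge)
    absolute, relative = daily_growth_rates(mgc, day_length_h=day_length_h)
    series = nutation_distance_series(traj, mgc)
    spec = amplitude_spectrum(series)
    return FeatureSet(
        overall_length=overall_length(mgc),
        absolute_daily_rates=absolute,
        relative_daily_rates=relative,
        average_tip_velocity=average_tip_velocity(
            traj, eval_step_min=eval_step_min, window_min=velocity_window_min
        ),
        max_nutation_amplitude=max_nutation_amplitude(series),
        main_period=_main_period(spec),
        provenance={
            "window_samples": mgc.window_samples,
            "edge_policy": edge,
            "sampling_interval_min": traj.sampling_interval,
            "eval_step_min": eval_step_min,
            "velocity_window_min": velocity_window_min,
            "day_length_h": day_length_h,
            "n_samples": len(traj),
            "water_corrected": traj.water_corrected,
        },
    )
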