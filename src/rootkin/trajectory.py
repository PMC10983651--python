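"""Time-stamped track containers: 2D pixel tracks and 3D trajectories."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import SchemaError

__all__ = ["PixelTrack", "Trajectory3D", "infer_sampling_interval"]


def _check_times(times: np.ndarray, what: str) -> None:
    if times.ndim != 1 or times.size == 0:
        raise SchemaError(f"{what}: times must be a non-empty 1D array")
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1
        raise SchemaError(f"{what}: times not strictly increasing at row {row}")


def infer_sampling_interval(times: np.ndarray, tol: float = 0.01) -> float:
    """Nominal sampling interval (minutes) from a time vector.

    Uses the median step and checks every step is within ``tol`` (relative)
    of it, matching the constant-interval contract of the acquisition
    protocol (one frame every 3 min by default).
    """
    if len(times) < 2:
        return 0.0
    diffs = np.diff(times)
    nominal = float(np.median(diffs))
    bad = np.abs(diffs - nominal) > tol * nominal
    if np.any(bad):
        row = int(np.argmax(bad)) + 1
        raise SchemaError(
            f"sampling interval deviates >{tol:.0%} from nominal "
            f"{nominal:g} min at row {row}"
        )
    return nominal


@dataclass
class PixelTrack:
    """2D track of the root tip from one camera.

    times are minutes since acquisition start, strictly increasing with a
    nominal constant sampling interval; points are (u, v) pixels.
    """

    times: np.ndarray
    points: np.ndarray
    camera_id: str = "left"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        _check_times(self.times, f"PixelTrack[{self.camera_id}]")
        if self.points.shape != (self.times.size, 2):
            raise SchemaError("PixelTrack: points must be (n, 2) matching times")
        if self.camera_id not in ("left", "right"):
            raise SchemaError("camera_id must be 'left' or 'right'")
        infer_sampling_interval(self.times)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class Trajectory3D:
    """3D tip trajectory in the left-camera frame (mm), z = depth."""

    times: np.ndarray
    points: np.ndarray
    sampling_interval: float = 0.0
    water_corrected: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        _check_times(self.times, "Trajectory3D")
        if self.points.shape != (self.times.size, 3):
            raise SchemaError("Trajectory3D: points must be (n, 3) matching times")
        if not self.sampling_interval:
            self.sampling_interval = infer_sampling_interval(self.times)
        if self.times.size > 1 and self.sampling_interval <= 0:
            raise SchemaError("sampling_interval must be positive")

    def __len__(self) -> int:
        return self.times.size
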