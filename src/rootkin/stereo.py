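"""Stereo triangulation (DLT) and linear water-depth correction.

The reconstruction chain mirrors the acquisition protocol: projection
matrices are composed from each camera's intrinsics and the stereo
extrinsics, 2D tip tracks from the two synchronized cameras are
triangulated by a direct linear transformation, and the depth coordinate is
then compensated for the refraction of the flat air/water interface with a
linear map ``z_true = slope * z_apparent + intercept`` fitted on a
submerged chessboard of known geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    AlreadyCorrectedError,
    DegenerateGeometryError,
    GridMismatchError,
    PointAtInfinityError,
    UnderdeterminedFitError,
)
from .geometry import (
    CameraIntrinsics,
    CameraPose,
    ProjectionMatrix,
    camera_center,
    compose_projection,
)
from .trajectory import PixelTrack, Trajectory3D

__all__ = [
    "ChessboardSpec",
    "WaterDepthCorrection",
    "StereoRig",
    "triangulate_dlt",
    "triangulate_points",
    "fit_water_correction",
    "fit_water_correction_sweep",
    "apply_water_correction",
    "triangulate_track",
]

#: smallest-singular-value ratio below which the DLT system is ambiguous
_DEGENERATE_RATIO = 1e-10
#: allowed left/right timestamp misalignment, minutes (1 s)
TIME_PAIR_TOLERANCE_MIN = 1.0 / 60.0


@dataclass(frozen=True)
class ChessboardSpec:
    """Planar calibration target: inner-corner grid and square size (mm).

    Defaults are the 10 x 7 board with 8 mm squares used for rig and
    water calibration.
    """

    inner_corner_cols: int = 10
    inner_corner_rows: int = 7
    square_size: float = 8.0

    def __post_init__(self):
        if min(self.inner_corner_cols, self.inner_corner_rows) <= 0 or self.square_size <= 0:
            raise ValueError("chessboard spec fields must be positive")

    @property
    def n_corners(self) -> int:
        return self.inner_corner_cols * self.inner_corner_rows


@dataclass(frozen=True)
class WaterDepthCorrection:
    """Linear depth compensation z' = slope * z + intercept (mm).

    For a physical air->water interface (refractive index > 1) the apparent
    depth is compressed, so the fitted slope should exceed 1; a slope <= 1
    is allowed but flagged, since it usually indicates a mis-ordered corner
    grid or a dry calibration.
    """

    slope: float
    intercept: float = 0.0
    fit_residual_rms: float = 0.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("water-correction slope must be positive")
        if self.slope <= 1.0:
            warnings.warn(
                "water-correction slope <= 1: expected > 1 for refraction at "
                "an air/water interface",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StereoRig:
    """Calibrated stereo pair; the left camera frame is the world frame."""

    left: CameraIntrinsics
    right: CameraIntrinsics
    right_pose_in_left: CameraPose
    water: Optional[WaterDepthCorrection] = None

    @property
    def P_left(self) -> ProjectionMatrix:
        return compose_projection(self.left, CameraPose.identity())

    @property
    def P_right(self) -> ProjectionMatrix:
        return compose_projection(self.right, self.right_pose_in_left)

    @property
    def baseline(self) -> float:
        """Distance between the camera centres (mm)."""
        return float(np.linalg.norm(self.right_pose_in_left.center))


def _dlt_system(P1: np.ndarray, P2: np.ndarray, uv1, uv2) -> np.ndarray:
    u1, v1 = uv1
    u2, v2 = uv2
    return np.array(
        [
            u1 * P1[2] - P1[0],
            v1 * P1[2] - P1[1],
            u2 * P2[2] - P2[0],
            v2 * P2[2] - P2[1],
        ]
    )


def triangulate_dlt(
    P_left: ProjectionMatrix,
    P_right: ProjectionMatrix,
    uv_left,
    uv_right,
) -> np.ndarray:
    """Triangulate one 3D point (mm) from a stereo pixel correspondence.

    Solves the stacked 4x4 homogeneous DLT system by SVD and returns the
    dehomogenized smallest-singular-vector solution, without iterative
    refinement.

    Raises
    ------
    DegenerateGeometryError
        If the camera centres coincide (zero baseline) or the system is
        rank-deficient (parallel rays).
    PointAtInfinityError
        If the homogeneous solution has w ~ 0.
    """
    c1, c2 = camera_center(P_left), camera_center(P_right)
    if np.linalg.norm(c1 - c2) < 1e-9:
        raise DegenerateGeometryError("camera centres coincide (zero baseline)")
    A = _dlt_system(P_left.matrix, P_right.matrix, uv_left, uv_right)
    _, s, vt = np.linalg.svd(A)
    if s[2] < _DEGENERATE_RATIO * s[0]:
        raise DegenerateGeometryError("DLT system is rank-deficient (parallel rays)")
    X = vt[-1]
    if abs(X[3]) < 1e-12 * np.linalg.norm(X):
        raise PointAtInfinityError("triangulated point at infinity (w ~ 0)")
    return X[:3] / X[3]


def triangulate_points(
    P_left: ProjectionMatrix, P_right: ProjectionMatrix, uv_left: np.ndarray, uv_right: np.ndarray
) -> np.ndarray:
    """Vector form of :func:`triangulate_dlt` over (n, 2) pixel arrays."""
    uv_left = np.atleast_2d(uv_left)
    uv_right = np.atleast_2d(uv_right)
    return np.array(
        [triangulate_dlt(P_left, P_right, a, b) for a, b in zip(uv_left, uv_right)]
    )


def fit_water_correction(
    reconstructed_corners: np.ndarray,
    spec: ChessboardSpec = ChessboardSpec(),
    board_tilt_deg: float = 30.0,
    interface_z: Optional[float] = None,
) -> WaterDepthCorrection:
    """Fit the linear water-depth compensation from a reconstructed chessboard.

    The submerged board is tilted about the vertical axis, so true corner
    depth varies linearly along the column index with step
    ``square_size * sin(tilt)``; the slope of the least-squares line
    ``z_true = slope * z_apparent + intercept`` is determined by the
    board's known size alone.  The intercept needs an absolute anchor:

    * with ``interface_z`` given (the designed depth of the tank wall /
      water surface, where apparent and true depth coincide), the line is
      anchored at that physical fixed point;
    * otherwise the corner nearest the interface (smallest apparent
      depth, the least-displaced point in rank order) is taken as true,
      which leaves a small constant depth offset proportional to that
      corner's distance behind the interface.

    Parameters
    ----------
    reconstructed_corners : array (n_corners, 3)
        Uncorrected triangulated corners, row-major grid order (rows of the
        board, columns fastest).
    spec : ChessboardSpec
        Board geometry; ``n_corners`` must match.
    board_tilt_deg : float
        Tilt of the board about the vertical axis (degrees from the
        camera-facing plane); the protocol uses ~30 deg.
    interface_z : float, optional
        Depth of the flat refractive interface in the left-camera frame.
    """
    corners = np.asarray(reconstructed_corners, dtype=float)
    if corners.shape != (spec.n_corners, 3):
        raise ValueError(
            f"expected {spec.n_corners} corners (got {corners.shape[0]})"
        )
    z_app = corners[:, 2]
    if np.ptp(z_app) < 1e-9:
        raise UnderdeterminedFitError("all corners at a single apparent depth")
    cols = np.arange(spec.n_corners) % spec.inner_corner_cols
    # direction of increasing depth along the column axis, from the data
    sign = np.sign(np.polyfit(cols, z_app, 1)[0]) or 1.0
    depth_step = spec.square_size * np.sin(np.radians(board_tilt_deg))
    z_rel = sign * cols * depth_step
    anchor = int(np.argmin(z_app))
    z_true = z_app[anchor] + (z_rel - z_rel[anchor])
    slope, intercept = np.polyfit(z_app, z_true, 1)
    if interface_z is not None:
        # anchor the line at its physical fixed point instead
        intercept = (1.0 - slope) * interface_z
        resid = (z_true - z_true.mean()) - slope * (z_app - z_app.mean())
    else:
        resid = z_true - (slope * z_app + intercept)
    return WaterDepthCorrection(
        slope=float(slope),
        intercept=float(intercept),
        fit_residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_water_correction_sweep(
    reconstructed_views: Sequence[np.ndarray],
    spec: ChessboardSpec = ChessboardSpec(),
    board_tilt_deg: float = 30.0,
    interface_z: Optional[float] = None,
) -> WaterDepthCorrection:
    """Fit the water correction from a sweep of board placements.

    The apparent-depth compression varies slightly with viewing angle, so
    fitting one board per depth and pooling the per-view slopes yields a
    line that is accurate over the whole working volume rather than at one
    depth.  The returned intercept follows the same anchoring rules as
    :func:`fit_water_correction`; with ``interface_z`` the pooled slope is
    anchored at the interface, otherwise the shallowest view's anchor is
    kept.
    """
    if len(reconstructed_views) == 0:
        raise UnderdeterminedFitError("no board views supplied")
    fits = [
        fit_water_correction(v, spec, board_tilt_deg, interface_z=None)
        for v in reconstructed_views
    ]
    slope = float(np.mean([f.slope for f in fits]))
    rms = float(np.sqrt(np.mean([f.fit_residual_rms**2 for f in fits])))
    if interface_z is not None:
        intercept = (1.0 - slope) * interface_z
    else:
        shallowest = int(np.argmin([np.min(v[:, 2]) for v in reconstructed_views]))
        z_app = np.asarray(reconstructed_views[shallowest])[:, 2]
        # re-anchor the pooled slope at that view's nearest corner
        anchor = float(np.min(z_app))
        intercept = anchor - slope * anchor + fits[shallowest].intercept + (
            fits[shallowest].slope - slope
        ) * (np.mean(z_app) - anchor)
    return WaterDepthCorrection(slope=slope, intercept=float(intercept), fit_residual_rms=rms)


def apply_water_correction(
    traj: Trajectory3D, corr: WaterDepthCorrection
) -> Trajectory3D:
    """Apply z' = slope * z + intercept to every sample; x, y, times untouched."""
    if traj.water_corrected:
        raise AlreadyCorrectedError("trajectory is already water-corrected")
    pts = traj.points.copy()
    pts[:, 2] = corr.slope * pts[:, 2] + corr.intercept
    return Trajectory3D(
        times=traj.times.copy(),
        points=pts,
        sampling_interval=traj.sampling_interval,
        water_corrected=True,
    )


def triangulate_track(
    left: PixelTrack, right: PixelTrack, rig: StereoRig
) -> Trajectory3D:
    """Triangulate paired left/right pixel tracks into a 3D trajectory.

    Timestamps must pair within 1 s (the acquisition synchronization
    bound); the left camera's time base is used for the output.  If the rig
    carries a water correction it is applied to the triangulated depths.
    """
    if len(left) != len(right):
        raise GridMismatchError(
            f"track length mismatch: left {len(left)} vs right {len(right)}"
        )
    dt = np.abs(left.times - right.times)
    if np.any(dt > TIME_PAIR_TOLERANCE_MIN):
        row = int(np.argmax(dt > TIME_PAIR_TOLERANCE_MIN))
        raise GridMismatchError(
            f"left/right timestamps misaligned beyond 1 s at row {row}"
        )
    pts = triangulate_points(rig.P_left, rig.P_right, left.points, right.points)
    traj = Trajectory3D(times=left.times.copy(), points=pts)
    if rig.water is not None:
        traj = apply_water_correction(traj, rig.water)
    return traj
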