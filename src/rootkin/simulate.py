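"""Synthetic stereo rig and circumnutating-root simulator.

Every stage of the pipeline can be exercised without real footage: this
module generates ground-truthed root-tip trajectories (straight growth
plus one or more quasi-elliptic oscillation components and tracking
noise), renders them into left/right pixel tracks through a calibrated
stereo pair — optionally through a flat air/water interface with exact
Snell refraction — and produces submerged-chessboard views for validating
the linear water-depth correction.

The default scene emulates the study conditions at the study's scale: two
1920x1080 cameras with a 100 mm baseline mounted above the tank looking
straight down at the water surface (~250 mm below), the primary root
growing downward (along +z, the optical/depth axis) at ~1 mm/h for 7
days sampled every 3 min, circumnutating in the horizontal (XY) plane
with ~1 mm amplitude and a period in the 30-120 min range, plus a slower
multi-hour drift component.  Looking down the growth axis is what makes
the XY plane the circumnutation plane.

Each oscillation component traces a slightly lopsided loop,
``r(theta) = A (1 + m cos theta) (cos theta e1 + eps sin theta e2)``:
real circumnutation loops are irregular, and a perfectly centred loop
would leave the tip at constant distance from the growth axis (or fold
the oscillation to twice its frequency), hiding the very period the
spectral analysis measures.  ``radial_modulation = 0`` recovers the
perfectly centred loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import OutOfViewError
from .geometry import CameraIntrinsics, CameraPose, compose_projection, project_pinhole
from .stereo import ChessboardSpec, StereoRig
from .trajectory import PixelTrack, Trajectory3D

__all__ = [
    "OscillationComponent",
    "RootSimParams",
    "WaterInterface",
    "BoardPose",
    "SyntheticScene",
    "ChessboardView",
    "default_rig",
    "simulate_root_trajectory",
    "project_through_water",
    "render_scene",
    "simulate_chessboard_views",
]


@dataclass(frozen=True)
class OscillationComponent:
    """One quasi-elliptic oscillation of the tip around its growth axis.

    amplitude in mm, period in minutes, phase in radians; ellipticity is
    the ratio of the loop's second axis to its first (1 = circular, 0 =
    back-and-forth line); radial_modulation m makes the loop radius vary
    over a cycle (lopsided loop), putting the oscillation fundamental into
    the tip-to-axis distance.
    """

    amplitude: float
    period_min: float
    phase_rad: float = 0.0
    ellipticity: float = 1.0
    radial_modulation: float = 0.1

    def __post_init__(self):
        if self.amplitude < 0 or self.period_min <= 0:
            raise ValueError("amplitude must be >= 0 and period positive")
        if not 0.0 <= self.ellipticity <= 1.0:
            raise ValueError("ellipticity must be in [0, 1]")


@dataclass(frozen=True)
class RootSimParams:
    """Ground-truth parameters of a simulated circumnutating root."""

    growth_speed: float = 1.2  # mm/h
    growth_direction: tuple = (0.0, 0.0, 1.0)
    circ_components: tuple = (OscillationComponent(1.0, 60.0),)
    drift_components: tuple = ()
    noise_sigma: float = 0.0  # mm, added per coordinate
    duration_h: float = 168.0
    sampling_interval_min: float = 3.0
    start_point: tuple = (50.0, 0.0, 320.0)
    seed: int = 0

    def __post_init__(self):
        if self.growth_speed < 0 or self.duration_h <= 0 or self.sampling_interval_min <= 0:
            raise ValueError("growth_speed >= 0 and positive duration/interval required")
        for c in tuple(self.circ_components) + tuple(self.drift_components):
            if c.period_min <= 2 * self.sampling_interval_min:
                raise ValueError(
                    f"period {c.period_min} min violates Nyquist at "
                    f"{self.sampling_interval_min} min sampling"
                )
        for c in self.drift_components:
            if c.period_min <= 240.0:
                raise ValueError("drift components must have periods > 240 min")
        g = np.asarray(self.growth_direction, dtype=float)
        if np.linalg.norm(g) < 1e-12:
            raise ValueError("growth_direction must be a non-zero vector")


@dataclass(frozen=True)
class WaterInterface:
    """Flat air/water interface perpendicular to the depth axis."""

    plane_z: float = 250.0
    refractive_index: float = 1.33

    def __post_init__(self):
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class BoardPose:
    """Placement of the calibration board: centre (mm) and tilt about vertical."""

    center: tuple
    tilt_deg: float = 30.0


@dataclass
class ChessboardView:
    """Projected corners of one board pose plus their true 3D positions."""

    uv_left: np.ndarray
    uv_right: np.ndarray
    true_corners: np.ndarray
    pose: BoardPose


@dataclass
class SyntheticScene:
    """A rendered scene: ground truth plus the observable pixel tracks."""

    rig: StereoRig
    interface: Optional[WaterInterface]
    truth: Trajectory3D
    left: PixelTrack
    right: PixelTrack
    pixel_noise_sigma: float


def default_rig(
    focal_px: float = 3000.0,
    baseline_mm: float = 100.0,
    image_size: tuple = (1920, 1080),
) -> StereoRig:
    """Plausible top-down stereo pair at the study's scale (configurable).

    Identical cameras, parallel optical axes, baseline along x.  The true
    rig geometry of the original system is not published; these values are
    a reconstruction consistent with its 2.1 Mpx cameras and ~0.3 m
    working distance.
    """
    w, h = image_size
    intr = CameraIntrinsics(
        focal_x=focal_px,
        focal_y=focal_px,
        principal_x=w / 2.0,
        principal_y=h / 2.0,
        image_size=image_size,
    )
    pose = CameraPose(np.eye(3), np.array([-baseline_mm, 0.0, 0.0]))
    return StereoRig(left=intr, right=intr, right_pose_in_left=pose)


def _orbit_basis(growth_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal pair spanning the plane perpendicular to the growth axis."""
    g = growth_dir / np.linalg.norm(growth_dir)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(g @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ g) * g
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(g, e1)
    return e1, e2


def simulate_root_trajectory(params: RootSimParams) -> Trajectory3D:
    """Ground-truth tip trajectory: drifted growth + oscillations + noise.

    Deterministic for a fixed seed.
    """
    dt = params.sampling_interval_min
    times = np.arange(0.0, params.duration_h * 60.0 + dt / 2, dt)
    g = np.asarray(params.growth_direction, dtype=float)
    g = g / np.linalg.norm(g)
    e1, e2 = _orbit_basis(g)
    pos = np.asarray(params.start_point, dtype=float) + np.outer(
        times / 60.0 * params.growth_speed, g
    )
    for c in tuple(params.circ_components) + tuple(params.drift_components):
        theta = 2.0 * np.pi * times / c.period_min + c.phase_rad
        radius = c.amplitude * (1.0 + c.radial_modulation * np.cos(theta))
        pos += np.outer(radius * np.cos(theta), e1)
        pos += np.outer(radius * c.ellipticity * np.sin(theta), e2)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        pos = pos + rng.normal(0.0, params.noise_sigma, pos.shape)
    return Trajectory3D(times=times, points=pos, sampling_interval=dt)


def _refraction_crossing(
    cam_center: np.ndarray, points: np.ndarray, interface: WaterInterface
) -> np.ndarray:
    """Snell crossing points on the interface plane for camera->point rays.

    For each submerged point the crossing lies on the segment between the
    plane feet of the camera and the point; the radial offset r solves
    n1 r / sqrt(r^2 + h1^2) = n2 (d - r) / sqrt((d - r)^2 + h2^2)
    (stationary optical path), found by bisection on [0, d] where the
    left side minus right side is monotone increasing.
    """
    n1, n2 = 1.0, interface.refractive_index
    h1 = interface.plane_z - cam_center[2]
    if h1 <= 0:
        raise OutOfViewError("camera must be in front of (above) the interface")
    h2 = points[:, 2] - interface.plane_z
    if np.any(h2 <= 0):
        raise OutOfViewError("all scene points must lie behind the interface")
    lateral = points[:, :2] - cam_center[:2]
    d = np.linalg.norm(lateral, axis=1)
    lo = np.zeros_like(d)
    hi = d.copy()
    for _ in range(80):
        r = 0.5 * (lo + hi)
        f = n1 * r / np.sqrt(r**2 + h1**2) - n2 * (d - r) / np.sqrt((d - r) ** 2 + h2**2)
        neg = f < 0
        lo = np.where(neg, r, lo)
        hi = np.where(neg, hi, r)
    r = 0.5 * (lo + hi)
    with np.errstate(invalid="ignore"):
        unit = np.where(d[:, None] > 0, lateral / np.where(d == 0, 1.0, d)[:, None], 0.0)
    crossing = np.empty_like(points)
    crossing[:, :2] = cam_center[:2] + unit * r[:, None]
    crossing[:, 2] = interface.plane_z
    return crossing


def project_through_water(
    points: np.ndarray,
    intrinsics: CameraIntrinsics,
    pose: CameraPose,
    interface: Optional[WaterInterface] = None,
) -> np.ndarray:
    """Project submerged points to pixels with exact flat-interface refraction.

    The ray from the camera (in air) to each point (in water) is bent at
    the plane ``z = plane_z`` according to Snell's law; the pinhole
    projection of the crossing point gives the observed pixel.  With
    ``interface=None`` or refractive index 1 this reduces to the plain
    pinhole projection.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    P = compose_projection(intrinsics, pose)
    if interface is None or interface.refractive_index == 1.0:
        if interface is not None and np.any(pts[:, 2] <= interface.plane_z):
            raise OutOfViewError("all scene points must lie behind the interface")
        return project_pinhole(P, pts)
    crossing = _refraction_crossing(pose.center, pts, interface)
    return project_pinhole(P, crossing)


def _check_in_view(uv: np.ndarray, intr: CameraIntrinsics, times: np.ndarray, cam: str):
    w, h = intr.image_size
    bad = (uv[:, 0] < 0) | (uv[:, 0] >= w) | (uv[:, 1] < 0) | (uv[:, 1] >= h)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise OutOfViewError(
            f"{cam} camera: point leaves the frame at t = {times[i]:g} min "
            f"(pixel {uv[i, 0]:.1f}, {uv[i, 1]:.1f})"
        )


def render_scene(
    params: RootSimParams,
    rig: Optional[StereoRig] = None,
    interface: Optional[WaterInterface] = WaterInterface(),
    pixel_noise_sigma: float = 0.3,
    seed: Optional[int] = None,
) -> SyntheticScene:
    """Render a simulated root into left/right pixel tracks.

    Ground truth is kept alongside the observable tracks; i.i.d. gaussian
    noise of ``pixel_noise_sigma`` pixels is added post-projection (the
    tracking-error model).  Raises :class:`OutOfViewError` naming the
    first offending timestamp if the tip leaves either frustum.
    """
    rig = rig if rig is not None else default_rig()
    truth = simulate_root_trajectory(params)
    uv_l = project_through_water(truth.points, rig.left, CameraPose.identity(), interface)
    uv_r = project_through_water(truth.points, rig.right, rig.right_pose_in_left, interface)
    _check_in_view(uv_l, rig.left, truth.times, "left")
    _check_in_view(uv_r, rig.right, truth.times, "right")
    if pixel_noise_sigma > 0:
        rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
        uv_l = uv_l + rng.normal(0.0, pixel_noise_sigma, uv_l.shape)
        uv_r = uv_r + rng.normal(0.0, pixel_noise_sigma, uv_r.shape)
    return SyntheticScene(
        rig=rig,
        interface=interface,
        truth=truth,
        left=PixelTrack(times=truth.times.copy(), points=uv_l, camera_id="left"),
        right=PixelTrack(times=truth.times.copy(), points=uv_r, camera_id="right"),
        pixel_noise_sigma=pixel_noise_sigma,
    )


def board_corners(spec: ChessboardSpec, pose: BoardPose) -> np.ndarray:
    """True 3D inner-corner grid of a tilted board, row-major (columns fastest).

    The board plane contains the vertical (y) axis; tilting rotates its
    horizontal axis out of the camera-facing plane about y, so depth
    varies along the columns.
    """
    t = np.radians(pose.tilt_deg)
    u_axis = np.array([np.cos(t), 0.0, np.sin(t)])
    v_axis = np.array([0.0, 1.0, 0.0])
    c0 = (spec.inner_corner_cols - 1) / 2.0
    r0 = (spec.inner_corner_rows - 1) / 2.0
    corners = []
    for r in range(spec.inner_corner_rows):
        for c in range(spec.inner_corner_cols):
            corners.append(
                np.asarray(pose.center, dtype=float)
                + (c - c0) * spec.square_size * u_axis
                + (r - r0) * spec.square_size * v_axis
            )
    return np.array(corners)


def simulate_chessboard_views(
    spec: ChessboardSpec,
    poses: Sequence[BoardPose],
    rig: Optional[StereoRig] = None,
    interface: Optional[WaterInterface] = WaterInterface(),
) -> list[ChessboardView]:
    """Project the submerged calibration board for each pose.

    Returns, per pose, the left/right corner pixels (through water when an
    interface is given) and the ground-truth 3D corners, for validating
    the water-correction fit.  Raises if the board crosses the interface
    or leaves a frustum.
    """
    rig = rig if rig is not None else default_rig()
    views = []
    for pose in poses:
        corners = board_corners(spec, pose)
        if interface is not None and np.any(corners[:, 2] <= interface.plane_z):
            raise OutOfViewError("board intersects or crosses the interface")
        uv_l = project_through_water(corners, rig.left, CameraPose.identity(), interface)
        uv_r = project_through_water(corners, rig.right, rig.right_pose_in_left, interface)
        fake_times = np.arange(len(corners), dtype=float)
        _check_in_view(uv_l, rig.left, fake_times, "left")
        _check_in_view(uv_r, rig.right, fake_times, "right")
        views.append(
            ChessboardView(uv_left=uv_l, uv_right=uv_r, true_corners=corners, pose=pose)
        )
    return views
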