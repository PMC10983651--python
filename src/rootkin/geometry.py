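"""Pinhole camera model: intrinsics, poses and projection matrices.

Conventions used throughout the package:

* world frame = left-camera frame; z is depth along the left optical axis,
  assumed perpendicular to the flat refractive interface;
* image origin top-left, u to the right, v down, units of pixels;
* lengths in millimetres, time in minutes.

Pixel inputs are assumed lens-undistorted upstream; the radial/tangential
coefficients are stored only for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidPoseError

__all__ = [
    "CameraIntrinsics",
    "CameraPose",
    "ProjectionMatrix",
    "compose_projection",
    "project_pinhole",
    "camera_center",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class CameraIntrinsics:
    """Internal parameters of one pinhole camera.

    Parameters
    ----------
    focal_x, focal_y : float
        Focal lengths in pixel units; must be positive.
    principal_x, principal_y : float
        Principal point in pixels.
    lens_distortion : tuple of float
        Radial/tangential coefficients kept for provenance; an empty tuple
        means the pixel tracks were already undistorted.
    image_size : tuple of int
        Sensor size ``(width, height)`` in pixels; used only for
        field-of-view checks when rendering synthetic scenes.
    """

    focal_x: float
    focal_y: float
    principal_x: float
    principal_y: float
    lens_distortion: tuple = ()
    image_size: tuple = (1920, 1080)

    def __post_init__(self):
        if self.focal_x <= 0 or self.focal_y <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        """3x3 upper-triangular intrinsics matrix."""
        return np.array(
            [
                [self.focal_x, 0.0, self.principal_x],
                [0.0, self.focal_y, self.principal_y],
                [0.0, 0.0, 1.0],
            ]
        )


@dataclass(frozen=True)
class CameraPose:
    """Rigid transform mapping world points into a camera frame: X_cam = R X + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidPoseError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_TOL):
            raise InvalidPoseError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
            raise InvalidPoseError("rotation determinant must be +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "CameraPose":
        return cls(np.eye(3), np.zeros(3))

    @property
    def center(self) -> np.ndarray:
        """Camera centre expressed in the world frame (-R^T t)."""
        return -self.rotation.T @ self.translation


@dataclass(frozen=True)
class ProjectionMatrix:
    """3x4 matrix mapping homogeneous world mm coordinates to homogeneous pixels."""

    matrix: np.ndarray = field()

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (3, 4):
            raise ValueError("projection matrix must be 3x4")
        if np.linalg.matrix_rank(M) != 3:
            raise ValueError("projection matrix must have rank 3")
        object.__setattr__(self, "matrix", M)


def compose_projection(intrinsics: CameraIntrinsics, pose: CameraPose) -> ProjectionMatrix:
    """Compose P = K [R | t] from intrinsics and a camera pose."""
    Rt = np.hstack([pose.rotation, pose.translation.reshape(3, 1)])
    return ProjectionMatrix(intrinsics.K @ Rt)


def project_pinhole(P: ProjectionMatrix, points: np.ndarray) -> np.ndarray:
    """Project world points (n, 3) to pixels (n, 2) through a projection matrix.

    Raises ZeroDivisionError-like failure only for points on the principal
    plane (w == 0); callers rendering synthetic scenes guard depth positivity.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    homo = np.hstack([pts, np.ones((pts.shape[0], 1))])
    proj = homo @ P.matrix.T
    return proj[:, :2] / proj[:, 2:3]


def camera_center(P: ProjectionMatrix) -> np.ndarray:
    """World-frame camera centre: the right null vector of P, dehomogenized."""
    _, _, vt = np.linalg.svd(P.matrix)
    c = vt[-1]
    return c[:3] / c[3]
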