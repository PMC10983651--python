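"""Readers and writers for tracks, trajectories, rigs, spectra and features.

All tables are headed CSV; rig files are YAML; feature reports are JSON.
Units are fixed package-wide (mm, minutes, Hz, hours for periods) and
converted only here at the boundary.  Trajectory and spectrum CSVs carry
their metadata (sampling interval, correction flag) in ``# key: value``
comment lines so that write-then-read round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError
from .geometry import CameraIntrinsics, CameraPose
from .kinematics import FeatureSet
from .spectral import AmplitudeSpectrum
from .stereo import StereoRig, WaterDepthCorrection
from .trajectory import PixelTrack, Trajectory3D

__all__ = [
    "read_track_csv",
    "write_track_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "load_rig",
    "save_rig",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_feature_report",
    "read_feature_report",
]

TRACK_COLUMNS = ["time_min", "camera", "u_px", "v_px", "label"]
TRAJECTORY_COLUMNS = ["time_min", "x_mm", "y_mm", "z_mm"]


def _read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_track_csv(path, camera: Optional[str] = None, label: Optional[str] = None) -> PixelTrack:
    """Read a 2D pixel track (``time_min,camera,u_px,v_px,label``).

    Files holding both cameras (or several labelled points) are filtered
    with ``camera`` / ``label``; a single-camera file needs no filter.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACK_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if label is not None and "label" in df.columns:
        df = df[df["label"] == label]
    cameras = df["camera"].unique().tolist()
    if camera is not None:
        df = df[df["camera"] == camera]
        if df.empty:
            raise SchemaError(f"{path}: no rows for camera '{camera}'")
    elif len(cameras) > 1:
        raise SchemaError(
            f"{path}: mixed camera ids {cameras}; pass camera='left'|'right'"
        )
    times = df["time_min"].to_numpy(dtype=float)
    decreasing = np.diff(times) <= 0
    if np.any(decreasing):
        row = int(df.index[int(np.argmax(decreasing)) + 1]) + 2  # 1-based incl. header
        raise SchemaError(f"{path}: non-increasing time_min at row {row}")
    return PixelTrack(
        times=times,
        points=df[["u_px", "v_px"]].to_numpy(dtype=float),
        camera_id=str(df["camera"].iloc[0]),
    )


def write_track_csv(track: PixelTrack, path, label: str = "tip") -> None:
    pd.DataFrame(
        {
            "time_min": track.times,
            "camera": track.camera_id,
            "u_px": track.points[:, 0],
            "v_px": track.points[:, 1],
            "label": label,
        }
    ).to_csv(path, index=False)


def read_trajectory_csv(
    path,
    columns: Optional[dict] = None,
    time_unit: str = "min",
) -> Trajectory3D:
    """Read a 3D trajectory CSV (``time_min,x_mm,y_mm,z_mm``).

    ``columns`` maps the standard names to the file's own header, so
    archived trajectory deposits with a different layout can be imported:
    e.g. ``columns={"time_min": "t", "x_mm": "X", ...}``.  ``time_unit``
    ("min", "s" or "h") converts foreign time columns to minutes.
    """
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    mapping = {std: std for std in TRAJECTORY_COLUMNS}
    if columns:
        mapping.update(columns)
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    factor = {"min": 1.0, "s": 1.0 / 60.0, "h": 60.0}[time_unit]
    times = df[mapping["time_min"]].to_numpy(dtype=float) * factor
    decreasing = np.diff(times) <= 0
    if np.any(decreasing):
        row = int(np.argmax(decreasing)) + 2
        raise SchemaError(f"{path}: non-increasing time at row {row}")
    pts = df[[mapping["x_mm"], mapping["y_mm"], mapping["z_mm"]]].to_numpy(dtype=float)
    return Trajectory3D(
        times=times,
        points=pts,
        water_corrected=meta.get("water_corrected", "false").lower() == "true",
    )


def write_trajectory_csv(traj: Trajectory3D, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# water_corrected: {str(traj.water_corrected).lower()}\n")
        fh.write(f"# sampling_interval_min: {traj.sampling_interval:.9g}\n")
        pd.DataFrame(
            {
                "time_min": traj.times,
                "x_mm": traj.points[:, 0],
                "y_mm": traj.points[:, 1],
                "z_mm": traj.points[:, 2],
            }
        ).to_csv(fh, index=False, float_format="%.12g")


def load_rig(path) -> StereoRig:
    """Load a stereo rig from YAML (keys left.K, right.K, R, t_mm, water.*)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        def intr(block):
            K = np.asarray(block["K"], dtype=float)
            return CameraIntrinsics(
                focal_x=K[0, 0],
                focal_y=K[1, 1],
                principal_x=K[0, 2],
                principal_y=K[1, 2],
                lens_distortion=tuple(block.get("distortion", ())),
                image_size=tuple(block.get("image_size", (1920, 1080))),
            )

        left = intr(data["left"])
        right = intr(data["right"])
        pose = CameraPose(np.asarray(data["R"], dtype=float), np.asarray(data["t_mm"], dtype=float))
    except KeyError as exc:
        raise SchemaError(f"{path}: missing rig key {exc}") from exc
    water = None
    if "water" in data and data["water"] is not None:
        water = WaterDepthCorrection(
            slope=float(data["water"]["slope"]),
            intercept=float(data["water"].get("intercept_mm", 0.0)),
            fit_residual_rms=float(data["water"].get("fit_residual_rms_mm", 0.0)),
        )
    return StereoRig(left=left, right=right, right_pose_in_left=pose, water=water)


def save_rig(rig: StereoRig, path) -> None:
    data = {
        "left": {"K": rig.left.K.tolist(), "image_size": list(rig.left.image_size)},
        "right": {"K": rig.right.K.tolist(), "image_size": list(rig.right.image_size)},
        "R": rig.right_pose_in_left.rotation.tolist(),
        "t_mm": rig.right_pose_in_left.translation.tolist(),
    }
    if rig.water is not None:
        data["water"] = {
            "slope": rig.water.slope,
            "intercept_mm": rig.water.intercept,
            "fit_residual_rms_mm": rig.water.fit_residual_rms,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_spectrum_csv(spec: AmplitudeSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_samples: {spec.n_samples}\n")
        fh.write(f"# sampling_interval_min: {spec.sampling_interval:.9g}\n")
        pd.DataFrame({"freq_hz": spec.frequencies, "amplitude": spec.amplitudes}).to_csv(
            fh, index=False, float_format="%.12g"
        )


def read_spectrum_csv(path) -> AmplitudeSpectrum:
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    for col in ("freq_hz", "amplitude"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col}")
    return AmplitudeSpectrum(
        frequencies=df["freq_hz"].to_numpy(dtype=float),
        amplitudes=df["amplitude"].to_numpy(dtype=float),
        n_samples=int(meta.get("n_samples", 2 * len(df))),
        sampling_interval=float(meta.get("sampling_interval_min", 3.0)),
    )


def write_feature_report(features: FeatureSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(features.as_dict(), fh, indent=2)
        fh.write("\n")


def read_feature_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
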