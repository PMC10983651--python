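"""End-to-end cohort pipeline: triangulate -> correct -> smooth -> features -> spectrum.

One :class:`RunConfig` drives the whole analysis for a cohort of plants:
each plant contributes either a left/right pixel-track pair (triangulated
with the rig, water-corrected when the rig carries a correction) or a
precomputed 3D trajectory.  Per-plant artifacts (trajectory CSV, feature
JSON, spectrum CSV) are written to the output directory, a
frequency-based cohort-average spectrum is produced, and when a second
operator's inputs are provided an ICC report over the shared scalar
features is added.  Everything is deterministic given the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as rio
from .exceptions import RootkinError
from .kinematics import FeatureSet, extract_features
from .reliability import RatingsMatrix, icc_a1
from .spectral import AmplitudeSpectrum, amplitude_spectrum, average_spectra
from .stereo import StereoRig, triangulate_track
from .trajectory import Trajectory3D

__all__ = ["PlantInput", "RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("rootkin")

#: scalar features compared between operators in the ICC report
ICC_FEATURES = (
    "overall_length_mm",
    "average_tip_velocity_mm_per_h",
    "max_nutation_amplitude_mm",
    "main_period_h",
)


@dataclass
class PlantInput:
    """Input files for one plant: a stereo track pair or a trajectory."""

    name: str
    left_csv: Optional[str] = None
    right_csv: Optional[str] = None
    trajectory_csv: Optional[str] = None

    def __post_init__(self):
        has_pair = self.left_csv is not None and self.right_csv is not None
        if not has_pair and self.trajectory_csv is None:
            raise ValueError(f"plant '{self.name}': need a track pair or a trajectory")


@dataclass
class RunConfig:
    """Pipeline settings; the defaults are the protocol's stated values."""

    plants: list = field(default_factory=list)
    rig_file: Optional[str] = None
    out_dir: str = "rootkin_out"
    operator_b_plants: list = field(default_factory=list)
    sampling_interval_min: float = 3.0
    smoothing_window_hours: float = 4.0
    velocity_step_min: float = 15.0
    velocity_window_min: float = 60.0
    spectrum_smooth_window: int = 8
    day_length_h: float = 24.0
    trim_edges: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in (
            "sampling_interval_min",
            "smoothing_window_hours",
            "velocity_step_min",
            "velocity_window_min",
            "spectrum_smooth_window",
            "day_length_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        payload = {k: str(v) for k, v in vars(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    features: dict
    spectra: dict
    average_spectrum: AmplitudeSpectrum
    icc_table: Optional[pd.DataFrame]
    out_dir: Path


def _plant_trajectory(plant: PlantInput, rig: Optional[StereoRig]) -> Trajectory3D:
    if plant.trajectory_csv is not None:
        return rio.read_trajectory_csv(plant.trajectory_csv)
    if rig is None:
        raise RootkinError(f"plant '{plant.name}': track pair given but no rig file")
    left = rio.read_track_csv(plant.left_csv, camera="left")
    right = rio.read_track_csv(plant.right_csv, camera="right")
    return triangulate_track(left, right, rig)


def _plant_features(
    traj: Trajectory3D, config: RunConfig
) -> tuple[FeatureSet, AmplitudeSpectrum]:
    feats = extract_features(
        traj,
        window_hours=config.smoothing_window_hours,
        eval_step_min=config.velocity_step_min,
        velocity_window_min=config.velocity_window_min,
        day_length_h=config.day_length_h,
        trim_edges=config.trim_edges,
    )
    from .kinematics import main_growth_component, nutation_distance_series

    mgc = main_growth_component(
        traj,
        window_hours=config.smoothing_window_hours,
        edge="trim" if config.trim_edges else "shrink",
    )
    spec = amplitude_spectrum(nutation_distance_series(traj, mgc))
    return feats, spec


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis for a cohort; see the module docstring."""
    if not config.plants:
        raise RootkinError("empty cohort: no plants in the run configuration")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run config digest %s (seed %d)", config.digest(), config.seed)
    rig = rio.load_rig(config.rig_file) if config.rig_file else None

    features: dict[str, FeatureSet] = {}
    spectra: dict[str, AmplitudeSpectrum] = {}
    for plant in config.plants:
        traj = _plant_trajectory(plant, rig)
        feats, spec = _plant_features(traj, config)
        features[plant.name] = feats
        spectra[plant.name] = spec
        rio.write_trajectory_csv(traj, out / f"{plant.name}_trajectory.csv")
        rio.write_feature_report(feats, out / f"{plant.name}_features.json")
        rio.write_spectrum_csv(spec, out / f"{plant.name}_spectrum.csv")

    avg = average_spectra(list(spectra.values()))
    rio.write_spectrum_csv(avg, out / "average_spectrum.csv")

    icc_table = None
    if config.operator_b_plants:
        if len(config.operator_b_plants) != len(config.plants):
            raise RootkinError("operator-B cohort must match the primary cohort plant-for-plant")
        feats_b = {}
        for plant in config.operator_b_plants:
            traj = _plant_trajectory(plant, rig)
            feats_b[plant.name], _ = _plant_features(traj, config)
        rows = []
        names_a = [p.name for p in config.plants]
        names_b = [p.name for p in config.operator_b_plants]
        for feat in ICC_FEATURES:
            a = [features[n].as_dict()[feat] for n in names_a]
            b = [feats_b[n].as_dict()[feat] for n in names_b]
            result = icc_a1(RatingsMatrix(np.column_stack([a, b]), feature_name=feat))
            rows.append({"feature": feat, "icc": round(result.icc, 3)})
        icc_table = pd.DataFrame(rows)
        icc_table.to_csv(out / "icc.csv", index=False)

    return PipelineResult(
        features=features,
        spectra=spectra,
        average_spectrum=avg,
        icc_table=icc_table,
        out_dir=out,
    )
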