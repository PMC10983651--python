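# rootkin

3D kinematic and oscillatory analysis of plant root tips from calibrated
stereo time-lapse tracks.

Roots growing in hydroponics can be filmed by a stereo camera pair, and
the tip's 2D pixel tracks from the two synchronized views can be
triangulated into a 3D trajectory — once the refraction of the air/water
interface is compensated. `rootkin` implements that reconstruction chain
and the downstream analysis of root growth and **circumnutation** (the
quasi-periodic oscillation of the growing tip around its mean
trajectory, with periods of 30–120 min in maize primary roots). It is a
library for plant biologists and image-analysis engineers working with
tip-tracking data, with a thin CLI for the standard pipeline.

## What it computes

* **Stereo reconstruction** — projection matrices `P = K [R | t]`,
  direct-linear-transformation (DLT) triangulation of paired pixel
  tracks, and a linear water-depth correction
  `z' = slope · z_apparent + intercept` fitted from a submerged 10×7
  chessboard of known square size (the slope recovers the refractive
  index, ≈ 1.33 for water).
* **Kinematic features** — the *main growth component* (centred 4-h
  moving average of the trajectory, 80 samples at 3-min sampling), the
  overall primary-root length `L = Σᵢ ‖p(i+1) − p(i)‖` along it, absolute
  and relative growth rates per day, the average tip velocity (hourly
  path length every 15 min), and the maximum nutation amplitude
  (XY-plane distance between trajectory and trend).
* **Spectral analysis** — one-sided FFT amplitude spectrum of the
  nutation-distance series, the main nutation period (dominant non-DC
  bin), 8-sample spectrum smoothing, and frequency-based cohort-average
  spectra.
* **Reliability** — inter-operator agreement via the intraclass
  correlation ICC(2,1) (two-way random effects, absolute agreement,
  single measure).
* **Synthetic rig** — a ground-truthed simulator (circumnutating root,
  exact Snell refraction at a flat interface, chessboard scenes) so the
  whole chain is testable without any footage.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
import rootkin as rk

rig = rk.default_rig()

# calibrate the water correction from a submerged chessboard sweep
views = rk.simulate_chessboard_views(
    rk.ChessboardSpec(), [rk.BoardPose((50, 0, z), 30.0) for z in (300, 380, 460)], rig
)
recs = [rk.triangulate_points(rig.P_left, rig.P_right, v.uv_left, v.uv_right)
        for v in views]
corr = rk.fit_water_correction_sweep(recs, interface_z=250.0)
wet_rig = rk.StereoRig(rig.left, rig.right, rig.right_pose_in_left, water=corr)
print(f"water slope {corr.slope:.4f}")          # water slope 1.3361

# a week of simulated growth, observed through the water surface
scene = rk.render_scene(rk.RootSimParams(duration_h=168, seed=1),
                        rig, pixel_noise_sigma=0.3)
traj = rk.triangulate_track(scene.left, scene.right, wet_rig)
err = np.linalg.norm(traj.points - scene.truth.points, axis=1)
print(f"median 3D error {np.median(err):.3f} mm")  # median 3D error 0.216 mm

feats = rk.extract_features(traj)
print(f"length {feats.overall_length:.1f} mm, "
      f"period {feats.main_period:.2f} h, "
      f"amplitude {feats.max_nutation_amplitude:.2f} mm")
# length 197.4 mm, period 1.00 h, amplitude 1.13 mm
```

The root grew 1.2 mm/h for the ~164 h covered by complete smoothing
windows (197 mm), and its 60-min, 1-mm circumnutation is recovered as a
1.00-h main period with a ~1.1-mm maximum amplitude (the simulated loops
are slightly lopsided, so the true maximum deviation is 1.05 mm).

The `examples/` directory holds one short script per capability;
each prints the numbers it computes and what they mean. The same stages
are available as a CLI: `rootkin simulate`, `rootkin triangulate`,
`rootkin features`, `rootkin spectrum`, `rootkin spectrum-average`,
`rootkin icc`, `rootkin run`.

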