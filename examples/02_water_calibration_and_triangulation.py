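"""Calibrate the water-depth correction and reconstruct a 3D trajectory.

A submerged 10x7 chessboard (8 mm squares, tilted ~30 deg) is imaged
through the water surface at three depths; the linear depth compensation
z_true = slope * z_apparent + intercept is fitted from its known geometry
and applied to a triangulated root track.
"""

import numpy as np

import rootkin as rk

rig = rk.default_rig()
spec = rk.ChessboardSpec()  # 10 x 7 inner corners, 8 mm squares

views = rk.simulate_chessboard_views(
    spec, [rk.BoardPose((50, 0, z), tilt_deg=30.0) for z in (300, 380, 460)], rig
)
reconstructed = [
    rk.triangulate_points(rig.P_left, rig.P_right, v.uv_left, v.uv_right) for v in views
]
corr = rk.fit_water_correction_sweep(reconstructed, spec, 30.0, interface_z=250.0)
print(f"fitted slope:      {corr.slope:.4f}   (water refractive index is 1.33)")
print(f"fitted intercept:  {corr.intercept:.2f} mm")

wet_rig = rk.StereoRig(rig.left, rig.right, rig.right_pose_in_left, water=corr)
scene = rk.render_scene(rk.RootSimParams(duration_h=48, seed=2), rig, pixel_noise_sigma=0.3)

uncorrected = rk.triangulate_track(scene.left, scene.right, rig)
corrected = rk.triangulate_track(scene.left, scene.right, wet_rig)
for name, traj in [("uncorrected", uncorrected), ("corrected", corrected)]:
    err = np.linalg.norm(traj.points - scene.truth.points, axis=1)
    print(f"{name:12s} median 3D error: {np.median(err):7.3f} mm")
# Refraction compresses apparent depth by ~1/1.33; the fitted linear map
# restores the depth axis to sub-0.5 mm accuracy.
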