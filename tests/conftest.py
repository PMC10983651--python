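import numpy as np
import pytest

import rootkin as rk


@pytest.fixture(scope="session")
def rig():
    return rk.default_rig()


@pytest.fixture(scope="session")
def noiseless_dry_scene():
    """One-day root rendered without water or pixel noise."""
    params = rk.RootSimParams(duration_h=24, seed=7)
    return rk.render_scene(params, interface=None, pixel_noise_sigma=0.0)


@pytest.fixture(scope="session")
def wet_scene():
    """One-day root rendered through water with realistic pixel noise."""
    params = rk.RootSimParams(duration_h=24, seed=11)
    return rk.render_scene(params, pixel_noise_sigma=0.3)


def random_rig(rng):
    """A random, valid stereo rig for oracle tests."""
    from scipy.spatial.transform import Rotation

    intr = rk.CameraIntrinsics(
        focal_x=rng.uniform(800, 3000),
        focal_y=rng.uniform(800, 3000),
        principal_x=rng.uniform(900, 1000),
        principal_y=rng.uniform(500, 580),
    )
    R = Rotation.from_rotvec(rng.normal(0, 0.05, 3)).as_matrix()
    t = np.array([rng.uniform(-150, -50), rng.normal(0, 5), rng.normal(0, 5)])
    return rk.StereoRig(left=intr, right=intr, right_pose_in_left=rk.CameraPose(R, t))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
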