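"""Growth-trend extraction and kinematic feature computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rootkin as rk
from rootkin.kinematics import GrowthInterval


def make_traj(points, dt=3.0):
    points = np.atleast_2d(points)
    times = np.arange(len(points)) * dt
    return rk.Trajectory3D(times=times, points=points, sampling_interval=dt)


def line_plus_oscillation(n=2000, dt=3.0, period_min=60.0, amp=1.0, slope=0.02):
    t = np.arange(n) * dt
    theta = 2 * np.pi * t / period_min
    pts = np.column_stack(
        [slope * t + amp * np.cos(theta), amp * np.sin(theta), 300.0 + 0.01 * t]
    )
    line = np.column_stack([slope * t, np.zeros(n), 300.0 + 0.01 * t])
    return make_traj(pts, dt), line


class TestMainGrowthComponent:
    def test_window_is_80_samples_at_protocol_settings(self):
        traj = make_traj(np.zeros((200, 3)), dt=3.0)
        mgc = rk.main_growth_component(traj, window_hours=4.0)
        assert mgc.window_samples == 80

    def test_constant_trajectory_unchanged(self):
        traj = make_traj(np.full((100, 3), 7.0))
        mgc = rk.main_growth_component(traj)
        np.testing.assert_allclose(mgc.points, traj.points)

    def test_integer_cycle_oscillation_cancels_exactly(self):
        """A 60-min sinusoid averaged over a 240-min window (4 full cycles)
        must leave the underlying straight line, to 1e-9 mm, in the interior."""
        traj, line = line_plus_oscillation()
        mgc = rk.main_growth_component(traj, window_hours=4.0)
        h = mgc.window_samples // 2
        np.testing.assert_allclose(mgc.points[h:-h], line[h:-h], atol=1e-9)

    def test_trim_edge_policy_drops_half_windows(self):
        traj, line = line_plus_oscillation()
        mgc = rk.main_growth_component(traj, window_hours=4.0, edge="trim")
        assert len(mgc) == len(traj) - 2 * (mgc.window_samples // 2)
        np.testing.assert_allclose(mgc.points, line[40:-40], atol=1e-9)

    def test_commutes_with_rigid_translation(self, rng):
        pts = rng.normal(0, 5, (300, 3)).cumsum(axis=0)
        shift = np.array([10.0, -3.0, 42.0])
        a = rk.main_growth_component(make_traj(pts)).points + shift
        b = rk.main_growth_component(make_traj(pts + shift)).points
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_rejects_nonpositive_window(self):
        with pytest.raises(ValueError):
            rk.main_growth_component(make_traj(np.zeros((10, 3))), window_hours=0)


class TestOverallLength:
    def mgc_of(self, points):
        points = np.atleast_2d(points)
        return rk.MainGrowthComponent(
            times=np.arange(len(points)) * 3.0, points=points, window_samples=1
        )

    def test_two_points_one_mm_apart(self):
        assert rk.overall_length(self.mgc_of([[0, 0, 0], [1, 0, 0]])) == 1.0

    def test_single_point_has_zero_length(self):
        assert rk.overall_length(self.mgc_of([[1, 2, 3]])) == 0.0

    def test_helix_matches_closed_form(self):
        """Arc length of k turns of a helix = k * sqrt((2 pi A)^2 + q^2)."""
        A, q, k, n = 1.5, 3.0, 5, 40000
        s = np.linspace(0, k * 2 * np.pi, n)
        pts = np.column_stack([A * np.cos(s), A * np.sin(s), q * s / (2 * np.pi)])
        expected = k * np.sqrt((2 * np.pi * A) ** 2 + q**2)
        assert rk.overall_length(self.mgc_of(pts)) == pytest.approx(expected, rel=1e-3)

    def test_invariant_under_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.normal(0, 2, (500, 3)).cumsum(axis=0)
        R = Rotation.from_rotvec(rng.normal(0, 1, 3)).as_matrix()
        moved = pts @ R.T + rng.normal(0, 100, 3)
        assert rk.overall_length(self.mgc_of(moved)) == pytest.approx(
            rk.overall_length(self.mgc_of(pts)), rel=1e-12
        )


class TestGrowthRates:
    def mgc_of(self, points, dt=3.0):
        points = np.atleast_2d(points)
        return rk.MainGrowthComponent(
            times=np.arange(len(points)) * dt, points=points, window_samples=1
        )

    def test_empty_interval_rate_is_zero(self):
        mgc = self.mgc_of(np.random.default_rng(0).normal(size=(10, 3)))
        assert rk.absolute_growth_rate(mgc, GrowthInterval(2, 0)) == 0.0

    def test_uniform_steps_one_day(self):
        pts = np.column_stack([0.05 * np.arange(481), np.zeros(481), np.zeros(481)])
        mgc = self.mgc_of(pts)
        assert rk.absolute_growth_rate(mgc, GrowthInterval(0, 480)) == pytest.approx(24.0)

    def test_matches_brute_force_sum(self, rng):
        pts = rng.normal(0, 1, (200, 3)).cumsum(axis=0)
        mgc = self.mgc_of(pts)
        a, d = 37, 101
        expected = sum(
            float(np.linalg.norm(pts[i + 1] - pts[i])) for i in range(a, a + d)
        )
        assert rk.absolute_growth_rate(mgc, GrowthInterval(a, d)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_whole_trajectory_relative_rate_is_one(self, rng):
        pts = rng.normal(0, 1, (50, 3)).cumsum(axis=0)
        mgc = self.mgc_of(pts)
        assert rk.relative_growth_rate(mgc, GrowthInterval(0, 49)) == pytest.approx(1.0)

    def test_second_of_two_equal_days_is_half(self):
        pts = np.column_stack([np.arange(961) * 0.05, np.zeros(961), np.zeros(961)])
        mgc = self.mgc_of(pts)
        assert rk.relative_growth_rate(mgc, GrowthInterval(480, 480)) == pytest.approx(0.5)

    def test_relative_matches_two_pass_oracle(self, rng):
        pts = rng.normal(0, 1, (300, 3)).cumsum(axis=0)
        mgc = self.mgc_of(pts)
        a, d = 50, 120
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert rk.relative_growth_rate(mgc, GrowthInterval(a, d)) == pytest.approx(
            seg[a : a + d].sum() / seg[: a + d].sum(), abs=1e-12
        )

    def test_out_of_bounds_interval_rejected(self):
        mgc = self.mgc_of(np.zeros((10, 3)))
        with pytest.raises(IndexError):
            rk.absolute_growth_rate(mgc, GrowthInterval(5, 10))

    def test_rate_times_cumulative_length_identity(self, rng):
        """relative rate * trend length at interval end == absolute rate."""
        pts = rng.normal(0, 1, (250, 3)).cumsum(axis=0)
        mgc = self.mgc_of(pts)
        iv = GrowthInterval(30, 77)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum_end = seg[: iv.start + iv.span].sum()
        assert rk.relative_growth_rate(mgc, iv) * cum_end == pytest.approx(
            rk.absolute_growth_rate(mgc, iv), abs=1e-9
        )


class TestDailyRates:
    def test_seven_day_record_gives_seven_days(self):
        pts = np.column_stack([np.arange(3361) * 0.05, np.zeros(3361), np.zeros(3361)])
        mgc = rk.MainGrowthComponent(np.arange(3361) * 3.0, pts, window_samples=1)
        absolute, relative = rk.daily_growth_rates(mgc)
        assert len(absolute) == len(relative) == 7

    def test_constant_speed_growth_has_equal_daily_rates(self):
        pts = np.column_stack([np.arange(1441) * 0.05, np.zeros(1441), np.zeros(1441)])
        mgc = rk.MainGrowthComponent(np.arange(1441) * 3.0, pts, window_samples=1)
        absolute, _ = rk.daily_growth_rates(mgc)
        np.testing.assert_allclose(absolute, absolute[0])

    def test_matches_per_day_brute_force(self, rng):
        pts = rng.normal(0, 0.2, (1500, 3)).cumsum(axis=0)
        mgc = rk.MainGrowthComponent(np.arange(1500) * 3.0, pts, window_samples=1)
        absolute, _ = rk.daily_growth_rates(mgc)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        for j in range(len(absolute)):
            assert absolute[j] == pytest.approx(seg[480 * j : 480 * (j + 1)].sum())

    def test_daily_sum_conserves_path_length(self, rng):
        """Sum of absolute daily rates == overall length over the complete days."""
        pts = rng.normal(0, 0.2, (1500, 3)).cumsum(axis=0)
        mgc = rk.MainGrowthComponent(np.arange(1500) * 3.0, pts, window_samples=1)
        absolute, _ = rk.daily_growth_rates(mgc)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert absolute.sum() == pytest.approx(seg[: 480 * len(absolute)].sum(), abs=1e-9)

    def test_sub_day_record_warns_and_returns_empty(self):
        mgc = rk.MainGrowthComponent(np.arange(100) * 3.0, np.zeros((100, 3)), window_samples=1)
        with pytest.warns(UserWarning, match="less than one day"):
            absolute, relative = rk.daily_growth_rates(mgc)
        assert absolute.size == relative.size == 0


class TestAverageTipVelocity:
    def test_stationary_tip_has_zero_velocity(self):
        traj = make_traj(np.full((100, 3), 5.0))
        assert rk.average_tip_velocity(traj) == 0.0

    def test_straight_motion_at_1mm_per_h(self):
        t = np.arange(200) * 3.0
        traj = make_traj(np.column_stack([t / 60.0, np.zeros_like(t), np.zeros_like(t)]))
        assert rk.average_tip_velocity(traj) == pytest.approx(1.0)

    def test_circular_motion_matches_chord_sum_oracle(self):
        r, period = 2.0, 120.0
        t = np.arange(2000) * 3.0
        theta = 2 * np.pi * t / period
        traj = make_traj(np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(t)]))
        v = rk.average_tip_velocity(traj)
        chord_per_step = 2 * r * np.sin(np.pi * 3.0 / period)
        assert v == pytest.approx(chord_per_step * 20.0, rel=1e-9)  # 20 steps/hour
        assert v == pytest.approx(2 * np.pi * r / (period / 60.0), rel=0.01)

    def test_record_shorter_than_window_rejected(self):
        with pytest.raises(rk.SchemaError):
            rk.average_tip_velocity(make_traj(np.zeros((5, 3))))


class TestNutationDistance:
    def test_trajectory_equal_to_trend_gives_zeros(self, rng):
        pts = rng.normal(0, 1, (50, 3)).cumsum(axis=0)
        traj = make_traj(pts)
        mgc = rk.MainGrowthComponent(traj.times, pts.copy(), window_samples=1)
        assert rk.nutation_distance_series(traj, mgc).distances.max() == 0.0

    def test_pure_depth_offset_is_invisible_in_xy(self, rng):
        pts = rng.normal(0, 1, (50, 3)).cumsum(axis=0)
        traj = make_traj(pts)
        shifted = pts + np.array([0.0, 0.0, 5.0])
        mgc = rk.MainGrowthComponent(traj.times, shifted, window_samples=1)
        assert rk.nutation_distance_series(traj, mgc).distances.max() < 1e-12

    def test_xy_circle_amplitude_recovered_in_interior(self):
        traj, _ = line_plus_oscillation(amp=1.5)
        mgc = rk.main_growth_component(traj, window_hours=4.0)
        d = rk.nutation_distance_series(traj, mgc).distances
        np.testing.assert_allclose(d[40:-40], 1.5, atol=1e-6)

    def test_max_amplitude_of_zeros_and_singleton(self):
        zeros = rk.NutationDistanceSeries(np.arange(5) * 3.0, np.zeros(5))
        assert rk.max_nutation_amplitude(zeros) == 0.0
        single = rk.NutationDistanceSeries(np.array([0.0]), np.array([2.0]), 3.0)
        assert rk.max_nutation_amplitude(single) == 2.0

    def test_mismatched_grids_rejected(self):
        traj = make_traj(np.zeros((50, 3)))
        mgc = rk.MainGrowthComponent(traj.times + 1.5, np.zeros((50, 3)), window_samples=1)
        with pytest.raises(rk.GridMismatchError):
            rk.nutation_distance_series(traj, mgc)


class TestSmoothingProperties:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_smoothing_contracts_arc_length_of_oscillating_roots(self, seed):
        """Averaging an oscillation-on-a-line trajectory never adds path length."""
        rng = np.random.default_rng(seed)
        comp = rk.OscillationComponent(
            amplitude=rng.uniform(0.5, 2.0),
            period_min=rng.uniform(30, 120),
            phase_rad=rng.uniform(0, 2 * np.pi),
        )
        params = rk.RootSimParams(
            growth_speed=rng.uniform(0.5, 2.0),
            circ_components=(comp,),
            drift_components=(),
            duration_h=24.0,
            seed=int(seed),
        )
        traj = rk.simulate_root_trajectory(params)
        raw = rk.MainGrowthComponent(traj.times, traj.points, window_samples=1)
        smooth = rk.main_growth_component(traj, window_hours=4.0)
        assert rk.overall_length(smooth) <= rk.overall_length(raw) + 1e-9


class TestParameterRecovery:
    def test_length_and_amplitude_recovered_from_noisy_simulation(self):
        """v and A of a simulated root are recovered from its own features
        (2% on length, 10% on amplitude at 0.05 mm tracking noise)."""
        v, A = 1.5, 2.0
        params = rk.RootSimParams(
            growth_speed=v,
            # centered circular loop: its true max deviation from the trend is A
            circ_components=(rk.OscillationComponent(A, 60.0, radial_modulation=0.0),),
            drift_components=(),
            noise_sigma=0.05,
            duration_h=96.0,
            seed=21,
        )
        traj = rk.simulate_root_trajectory(params)
        feats = rk.extract_features(traj)
        mgc_span_h = (len(traj) - 1 - 2 * (feats.provenance["window_samples"] // 2)) * 3.0 / 60.0
        assert feats.overall_length == pytest.approx(v * mgc_span_h, rel=0.02)
        assert feats.max_nutation_amplitude == pytest.approx(A, rel=0.10)
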