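"""Areal velocity, rotation frequency, and event-aligned averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lfpdyn
from lfpdyn import (
    StateTrajectory,
    SubmovementEvent,
    areal_velocity,
    average_event_trajectories,
    bin_events_by_direction,
    bin_events_by_speed,
    event_areal_velocity_vector,
    rotation_frequency,
)

from .conftest import circle_trajectory


class TestArealVelocity:
    def test_unit_circle_at_3hz_magnitude(self):
        """|v| = 1/2 r^2 omega = 3 pi for a unit circle at 3 Hz."""
        traj = circle_trajectory(freq=3.0, radius=1.0)
        v = areal_velocity(traj)
        np.testing.assert_allclose(v.magnitude, 3 * np.pi, rtol=1e-12)
        assert np.all(v.signed_z > 0)  # anticlockwise

    def test_parallel_position_and_velocity_vanish(self):
        t = np.linspace(0, 1, 100)[:, None]
        x = np.hstack([t, 2 * t])
        traj = StateTrajectory(x, 3 * x, 488.0)
        np.testing.assert_allclose(areal_velocity(traj).v, 0, atol=1e-12)

    @given(radius=st.floats(0.1, 10), freq=st.floats(0.5, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_magnitude_identity_on_circles(self, radius, freq):
        """|v| = 1/2 |x|^2 * 2 pi f holds to machine precision."""
        traj = circle_trajectory(freq=freq, radius=radius, duration=1.0)
        v = areal_velocity(traj).magnitude
        expected = 0.5 * radius**2 * 2 * np.pi * freq
        np.testing.assert_allclose(v, expected, rtol=1e-10)

    def test_rotation_invariance(self):
        traj = circle_trajectory(freq=3.0, radius=2.0, duration=2.0)
        ang = 0.83
        R = np.array([[np.cos(ang), -np.sin(ang)],
                      [np.sin(ang), np.cos(ang)]])
        rotated = StateTrajectory(traj.x @ R.T, traj.xdot @ R.T,
                                  traj.sample_rate)
        np.testing.assert_allclose(areal_velocity(rotated).magnitude,
                                   areal_velocity(traj).magnitude, rtol=1e-10)

    def test_high_dimensional_input_rejected(self):
        x = np.zeros((100, 4))
        traj = StateTrajectory(x + 1, x, 488.0)
        with pytest.raises(ValueError, match="d in"):
            areal_velocity(traj)


class TestRotationFrequency:
    def test_circle_recovers_frequency_everywhere(self):
        traj = circle_trajectory(freq=3.0, radius=0.7)
        np.testing.assert_allclose(rotation_frequency(traj), 3.0, rtol=1e-10)

    def test_ellipse_matches_unwrapped_phase_oracle(self):
        """Time-varying f(t) on an ellipse agrees with the independent
        d/dt-of-unwrapped-polar-angle estimate."""
        fs, f0 = 488.0, 3.0
        t = np.arange(int(4 * fs)) / fs
        w = 2 * np.pi * f0
        x = np.column_stack([2.0 * np.cos(w * t), 0.5 * np.sin(w * t)])
        xdot = np.column_stack([-2.0 * w * np.sin(w * t),
                                0.5 * w * np.cos(w * t)])
        traj = StateTrajectory(x, xdot, fs)
        f_est = rotation_frequency(traj)
        phase = np.unwrap(np.arctan2(x[:, 1], x[:, 0]))
        f_oracle = np.gradient(phase) * fs / (2 * np.pi)
        np.testing.assert_allclose(f_est[5:-5], f_oracle[5:-5], rtol=0.01)
        # orbit average returns the carrier frequency
        assert np.mean(f_est) == pytest.approx(f0, rel=0.01)

    def test_static_point_masked(self):
        x = np.zeros((100, 2))
        traj = StateTrajectory(x, x, 488.0)
        assert np.all(np.isnan(rotation_frequency(traj)))


def make_events(speeds, times=None, directions=None):
    times = times if times is not None else np.arange(len(speeds), dtype=float)
    directions = directions if directions is not None else np.zeros(len(speeds))
    return [SubmovementEvent(t, s, d)
            for t, s, d in zip(times, speeds, directions)]


class TestSpeedBinning:
    def test_equal_counts(self):
        groups = bin_events_by_speed(make_events(np.arange(18.0) + 1), 9)
        assert [np.sum(groups == g) for g in range(9)] == [2] * 9

    def test_ties_broken_by_time(self):
        events = make_events(np.full(9, 50.0), times=np.arange(9.0))
        groups = bin_events_by_speed(events, 9)
        np.testing.assert_array_equal(groups, np.arange(9))

    def test_monotone_in_speed(self):
        rng = np.random.default_rng(1)
        speeds = rng.uniform(30, 200, 40)
        groups = bin_events_by_speed(make_events(speeds), 9)
        order = np.argsort(speeds)
        assert np.all(np.diff(groups[order]) >= 0)

    def test_group_areal_velocity_increases_with_speed(self, task_products):
        """On a synthetic session, group-mean |v| grows monotonically with
        the speed-group index (speed is encoded in areal velocity)."""
        groups = bin_events_by_speed(task_products["usable"], 9)
        means = [np.mean(np.linalg.norm(task_products["v"][groups == g],
                                        axis=1)) for g in range(9)]
        assert np.all(np.diff(means) > 0)

    def test_direction_bins_centered_on_zero(self):
        events = make_events(np.full(4, 50.0),
                             directions=np.deg2rad([0, 10, 70, -70]))
        groups = bin_events_by_direction(events, 6)
        assert groups[0] == groups[1] == 0
        assert groups[2] == 1
        assert groups[3] == 5


class TestEventAverages:
    def test_single_event_average_is_its_window(self):
        traj = circle_trajectory(duration=2.0)
        ev = [SubmovementEvent(1.0, 50.0, 0.0)]
        (avg,) = average_event_trajectories(traj, ev)
        c = int(round(1.0 * traj.sample_rate))
        h = (avg.mean_x.shape[0] - 1) // 2
        np.testing.assert_array_equal(avg.mean_x, traj.x[c - h:c + h + 1])
        assert avg.n_events == 1

    def test_phase_locked_events_preserve_amplitude(self):
        traj = circle_trajectory(freq=3.0, radius=1.0, duration=30.0)
        times = np.arange(1, 29, 1 / 3)  # every cycle: identical windows
        ev = [SubmovementEvent(t, 50.0, 0.0) for t in times]
        (avg,) = average_event_trajectories(traj, ev)
        # event times round to samples (up to ~0.04 rad of phase jitter),
        # but there is no systematic phase cancellation
        np.testing.assert_allclose(np.hypot(*avg.mean_x.T), 1.0, rtol=0.01)

    def test_random_phase_events_shrink_as_sqrt_n(self):
        rng = np.random.default_rng(5)
        traj = circle_trajectory(freq=3.0, radius=1.0, duration=400.0)
        amps = []
        for n in (25, 100):
            times = rng.uniform(1, 399, n)
            ev = [SubmovementEvent(t, 50.0, 0.0) for t in times]
            (avg,) = average_event_trajectories(traj, ev)
            amps.append(np.hypot(*avg.mean_x.T).mean())
        assert amps[1] / amps[0] == pytest.approx(0.5, abs=0.25)

    def test_empty_group_errors(self):
        traj = circle_trajectory(duration=2.0)
        ev = [SubmovementEvent(1.9999, 50.0, 0.0)]  # window clipped
        with pytest.raises(ValueError, match="no events"):
            average_event_trajectories(traj, ev)


class TestEventArealVelocityVector:
    def test_planar_circle_points_along_z(self):
        traj = circle_trajectory(freq=3.0, radius=2.0, duration=2.0, d=3)
        vec = event_areal_velocity_vector(traj, SubmovementEvent(1.0, 50, 0))
        np.testing.assert_allclose(vec[:2], 0, atol=1e-10)
        assert vec[2] == pytest.approx(0.5 * 4 * 2 * np.pi * 3, rel=1e-6)

    def test_time_reversal_negates_vector(self):
        traj = circle_trajectory(freq=3.0, radius=2.0, duration=2.0, d=3)
        rev = StateTrajectory(traj.x[::-1], -traj.xdot[::-1],
                              traj.sample_rate)
        ev = SubmovementEvent(1.0, 50, 0)
        np.testing.assert_allclose(event_areal_velocity_vector(rev, ev),
                                   -event_areal_velocity_vector(traj, ev),
                                   rtol=1e-8)

    def test_tilt_angle_recovered_from_ground_truth_mixing(self):
        """Noise-free, baseline-free session: the per-event areal-velocity
        vector is tilted from the rotation-plane normal by the configured
        direction tilt (within 10%)."""
        cfg = lfpdyn.SimulationConfig(duration=60, seed=13, noise_sd=0,
                                      pink_noise_sd=0,
                                      baseline_amplitude_frac=0)
        rec, _, _, _, gt = lfpdyn.simulate_task_session(cfg)
        # invert the known mixing to recover the latent trajectory exactly
        lat = np.linalg.pinv(gt.mixing_matrix) @ rec.select_area("M1").samples
        x = lat.T
        xdot = np.gradient(x, axis=0) * cfg.sample_rate
        traj = StateTrajectory(x, xdot, cfg.sample_rate)
        tilts = []
        for time, speed, _ in gt.true_submovements:
            vec = event_areal_velocity_vector(
                traj, SubmovementEvent(time, speed, 0.0))
            tilts.append(np.arccos(abs(vec[2]) / np.linalg.norm(vec)))
        assert np.mean(tilts) == pytest.approx(cfg.direction_tilt, rel=0.1)

    def test_clipped_window_errors(self):
        traj = circle_trajectory(duration=1.0, d=3)
        with pytest.raises(ValueError, match="edge"):
            event_areal_velocity_vector(traj, SubmovementEvent(0.05, 50, 0))
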