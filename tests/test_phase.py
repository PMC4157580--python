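"""Event-relative phases, circular statistics, spectra, firing rates."""

import numpy as np
import pytest

from lfpdyn import (
    SpikeTrain,
    StateTrajectory,
    circular_circular_correlation,
    coherence_spectrum,
    event_relative_phase,
    event_triggered_average,
    normalized_firing_rate,
    power_spectrum,
    preferred_phase_and_rayleigh,
    rotate_plane_to_speed_phase,
    spike_triggered_trajectory,
    wrap_angle,
)

from .conftest import circle_trajectory

FS = 488.0


class TestEventTriggeredAverage:
    def test_single_event_returns_its_window(self):
        sig = np.sin(np.arange(4880) / FS * 2 * np.pi * 3)
        avg, n = event_triggered_average(sig, [5.0], FS)
        c = int(5.0 * FS)
        h = (avg.size - 1) // 2
        np.testing.assert_array_equal(avg, sig[c - h:c + h + 1])
        assert n == 1

    def test_random_times_shrink_as_sqrt_n(self):
        rng = np.random.default_rng(0)
        t = np.arange(int(400 * FS)) / FS
        sig = np.cos(2 * np.pi * 3 * t)
        amps = []
        for n in (25, 100):
            avg, _ = event_triggered_average(sig, rng.uniform(1, 399, n), FS)
            amps.append(np.abs(avg).max())
        assert amps[1] / amps[0] == pytest.approx(0.5, abs=0.3)

    def test_no_usable_events_errors(self):
        with pytest.raises(ValueError, match="full window"):
            event_triggered_average(np.zeros(100), [0.01], FS)


class TestEventRelativePhase:
    def test_cosine_window_zero_phase(self):
        tau = (np.arange(195) - 97) / FS
        assert event_relative_phase(np.cos(2 * np.pi * 3 * tau)) == (
            pytest.approx(0.0, abs=0.02))

    def test_sine_window_minus_half_pi(self):
        tau = (np.arange(195) - 97) / FS
        assert event_relative_phase(np.sin(2 * np.pi * 3 * tau)) == (
            pytest.approx(-np.pi / 2, abs=0.05))

    def test_flat_window_flagged(self):
        with pytest.raises(ValueError, match="unreliable"):
            event_relative_phase(np.zeros(195))

    def test_channel_phases_recovered_on_synthetic_session(
            self, task_products):
        """Submovement-triggered average phases reproduce the configured
        per-channel offsets within 5 degrees."""
        delta = task_products["delta"]
        times = np.array([e.peak_time for e in task_products["usable"]])
        psi = 2 * np.pi * np.arange(delta.n_channels) / delta.n_channels
        errs = []
        for ch in range(delta.n_channels):
            eta, _ = event_triggered_average(delta.samples[ch], times, FS)
            phi = event_relative_phase(eta)
            errs.append(wrap_angle(phi - psi[ch]))
        errs = np.rad2deg(np.abs(np.array(errs) - np.mean(errs)))
        assert errs.max() < 5.0


class TestCircularCircularCorrelation:
    def test_identity_and_reflection(self):
        rng = np.random.default_rng(1)
        a = rng.vonmises(0.5, 2.0, 20)
        # the mean-centered form is exactly +-1 for identical/reflected
        # phases; the uniform-corrected form approaches it from below
        r, _ = circular_circular_correlation(a, a, correction_uniform=False)
        assert r == pytest.approx(1.0)
        r, _ = circular_circular_correlation(a, -a, correction_uniform=False)
        assert r == pytest.approx(-1.0)
        r, _ = circular_circular_correlation(a, a)
        assert r > 0.9
        r, _ = circular_circular_correlation(a, -a)
        assert r < -0.9

    def test_uncorrected_form_matches_explicit_formula(self):
        rng = np.random.default_rng(2)
        a = rng.vonmises(0.0, 1.5, 30)
        b = rng.vonmises(1.0, 1.5, 30)
        r, _ = circular_circular_correlation(a, b, correction_uniform=False)
        abar = np.angle(np.mean(np.exp(1j * a)))
        bbar = np.angle(np.mean(np.exp(1j * b)))
        sa, sb = np.sin(a - abar), np.sin(b - bbar)
        expected = np.sum(sa * sb) / np.sqrt(np.sum(sa**2) * np.sum(sb**2))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_uniform_marginals_error_without_correction(self):
        psi = 2 * np.pi * np.arange(10) / 10
        with pytest.raises(ValueError, match="zero resultant"):
            circular_circular_correlation(psi, psi, correction_uniform=False)

    def test_null_calibration_of_analytic_p(self):
        """Independent uniform phases, n=10: rho averages ~0, large
        |rho| (>= 0.81) is a rare event, and the analytic p-value rejects
        at the nominal rate (Monte-Carlo oracle for the p machinery)."""
        rng = np.random.default_rng(3)
        n_reps = 2000
        rs = np.empty(n_reps)
        rejections = 0
        for k in range(n_reps):
            a = rng.uniform(-np.pi, np.pi, 10)
            b = rng.uniform(-np.pi, np.pi, 10)
            rs[k], p = circular_circular_correlation(
                a, b, correction_uniform=False)
            rejections += p < 0.05
        assert abs(np.mean(rs)) < 0.03
        assert np.mean(np.abs(rs) >= 0.81) < 0.03
        assert rejections / n_reps == pytest.approx(0.05, abs=0.02)

    def test_sm_vs_kc_phases_agree_across_states(self, task_products,
                                                 sedation_products):
        """Paired task/sedation sessions share channel phases: per-channel
        submovement-relative vs K-complex-relative phase correlates with
        rho_CC > 0.7, p < 0.05."""
        delta_task = task_products["delta"]
        delta_sed = sedation_products["delta"]
        sm = np.array([e.peak_time for e in task_products["usable"]])
        kc = np.array([k.peak_time
                       for k in sedation_products["kcomplexes"]])
        phi_sm, phi_kc = [], []
        for ch in range(delta_task.n_channels):
            eta, _ = event_triggered_average(delta_task.samples[ch], sm, FS)
            phi_sm.append(event_relative_phase(eta))
            eta, _ = event_triggered_average(delta_sed.samples[ch], kc, FS)
            phi_kc.append(event_relative_phase(eta))
        rho, p = circular_circular_correlation(phi_sm, phi_kc)
        assert rho > 0.7
        assert p < 0.05


class TestPlaneRotation:
    def test_zero_phase_trajectory_identity(self):
        traj = circle_trajectory(duration=10.0)
        # events at integer cycles: trajectory at angle 0
        times = np.arange(1, 9, 1 / 3.0)
        rotated, angle = rotate_plane_to_speed_phase(traj, times)
        assert angle == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(rotated.x, traj.x, atol=1e-9)

    def test_quarter_cycle_phase_rotated_back(self):
        traj = circle_trajectory(duration=10.0, phase0=np.pi / 2)
        times = np.arange(1, 9, 1 / 3.0)
        rotated, angle = rotate_plane_to_speed_phase(traj, times)
        assert angle == pytest.approx(-np.pi / 2, abs=1e-6)
        c = int(times[0] * traj.sample_rate)
        assert np.arctan2(rotated.x[c, 1], rotated.x[c, 0]) == (
            pytest.approx(0.0, abs=1e-6))


class TestPreferredPhase:
    def test_identical_phases_maximal_resultant(self):
        traj = circle_trajectory(freq=3.0, duration=30.0)
        times = np.arange(1, 29, 1 / 3.0)[:20]  # same phase every cycle
        spikes = SpikeTrain(times)
        mu, r, p = preferred_phase_and_rayleigh(spikes, traj)
        # spike times round to samples, so phases agree to ~1 sample
        assert r == pytest.approx(1.0, abs=1e-3)
        assert p < 1e-8

    def test_uniform_phases_reject_at_nominal_rate(self):
        traj = circle_trajectory(freq=3.0, duration=120.0)
        rng = np.random.default_rng(4)
        rejections = 0
        for _ in range(200):
            spikes = SpikeTrain(np.sort(rng.uniform(1, 119, 50)))
            _, _, p = preferred_phase_and_rayleigh(spikes, traj)
            rejections += p < 0.05
        assert rejections / 200 < 0.10

    def test_locked_units_recover_configured_phase(self, task_products):
        """Preferred phase of kappa-locked units matches the generator's
        per-unit phase within 10 degrees (measured on the latent phase)."""
        gt = task_products["gt"]
        errs = []
        for train, pref in zip(task_products["trains"],
                               gt.true_preferred_phases):
            idx = np.clip((train.spike_times * FS).astype(int), 0,
                          gt.latent_phase.size - 1)
            mu = np.angle(np.mean(np.exp(1j * gt.latent_phase[idx])))
            errs.append(np.rad2deg(abs(wrap_angle(mu - pref))))
        assert np.mean(errs) < 10

    def test_population_phase_precedes_peak_speed(self, task_products):
        """In the rotated plane (zero phase at peak speed), units
        configured to lead peak speed cluster at negative phase."""
        times = np.array([e.peak_time for e in task_products["usable"]])
        rotated, _ = rotate_plane_to_speed_phase(task_products["traj2"],
                                                 times)
        prefs = []
        for train in task_products["trains"]:
            mu, _, p = preferred_phase_and_rayleigh(train, rotated)
            if p < 0.05:
                prefs.append(mu)
        assert len(prefs) >= 6
        cluster_mean = np.angle(np.mean(np.exp(1j * np.array(prefs))))
        assert -np.pi / 2 < cluster_mean < 0

    def test_too_few_spikes_errors(self):
        traj = circle_trajectory(duration=10.0)
        with pytest.raises(ValueError, match="at least 10"):
            preferred_phase_and_rayleigh(SpikeTrain(np.arange(5) + 1.0), traj)


class TestSpikeTriggeredTrajectory:
    def test_locked_unit_rotational_average(self, task_products):
        rotated_avg, n = spike_triggered_trajectory(
            task_products["trains"][0], task_products["traj2"])
        assert n >= 50
        radius = np.hypot(rotated_avg[:, 0], rotated_avg[:, 1])
        # unlocked surrogate: same trajectory, uniform random spike times
        rng = np.random.default_rng(5)
        surrogate = SpikeTrain(np.sort(rng.uniform(
            1, task_products["traj2"].n_samples / FS - 1, n)))
        surr_avg, _ = spike_triggered_trajectory(surrogate,
                                                 task_products["traj2"])
        surr_radius = np.hypot(surr_avg[:, 0], surr_avg[:, 1])
        assert radius.max() > 3 * surr_radius.max()

    def test_empty_train_errors(self):
        traj = circle_trajectory(duration=10.0)
        with pytest.raises(ValueError, match="spikes"):
            spike_triggered_trajectory(SpikeTrain(np.empty(0)), traj)


class TestSpectra:
    def test_self_coherence_is_unity(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(6 * 2048)
        f, coh, _ = coherence_spectrum(a, a, FS)
        np.testing.assert_allclose(coh, 1.0, atol=1e-8)

    def test_independent_noise_coherence_bias_is_one_over_l(self):
        """Magnitude-squared coherence of independent noise has mean ~1/L
        for L segments (estimator bias)."""
        rng = np.random.default_rng(7)
        L = 20
        a = rng.standard_normal(L * 2048)
        b = rng.standard_normal(L * 2048)
        _, coh, floor = coherence_spectrum(a, b, FS)
        assert coh.mean() == pytest.approx(1 / L, rel=0.3)
        assert 0 < floor < 1

    def test_speed_lfp_coherence_peaks_at_oscillator_frequency(
            self, task_products, default_config):
        kin = task_products["kin"]
        pc2 = task_products["traj2"].x[:, 1]
        f, coh, _ = coherence_spectrum(kin.radial_speed, pc2, FS)
        peak_f = f[np.argmax(coh)]
        df = FS / 2048
        assert abs(peak_f - default_config.oscillator_freq) <= 2 * df

    def test_too_short_signals_error(self):
        with pytest.raises(ValueError, match="segments"):
            coherence_spectrum(np.zeros(3000), np.zeros(3000), FS)

    def test_sinusoid_power_concentrated_in_one_bin(self):
        t = np.arange(4 * 2048) / FS
        f, p = power_spectrum(np.sin(2 * np.pi * 20.0 * t), FS)
        assert abs(f[np.argmax(p)] - 20.0) <= FS / 2048

    def test_white_noise_spectrum_integrates_to_variance(self):
        rng = np.random.default_rng(8)
        x = 2.5 * rng.standard_normal(30 * 2048)
        f, p = power_spectrum(x, FS)
        assert np.trapezoid(p, f) == pytest.approx(x.var(), rel=0.05)

    def test_sedation_delta_power_exceeds_task(self, task_products,
                                               sedation_products):
        f, p_task = power_spectrum(task_products["delta"].samples[0], FS)
        _, p_sed = power_spectrum(sedation_products["delta"].samples[0], FS)
        delta_band = f <= 5
        assert p_sed[delta_band].sum() > 3 * p_task[delta_band].sum()


class TestNormalizedFiringRate:
    def test_zero_mean_unit_sd(self, task_products):
        train = task_products["trains"][0]
        rate, sd = normalized_firing_rate(train, 120.0)
        assert rate.mean() == pytest.approx(0.0, abs=1e-10)
        assert rate.std() == pytest.approx(1.0, rel=1e-10)
        assert sd > 0

    def test_homogeneous_poisson_rate_is_flat_noise(self):
        rng = np.random.default_rng(9)
        times = np.sort(rng.uniform(0, 120, 1200))
        rate, _ = normalized_firing_rate(SpikeTrain(times), 120.0)
        assert abs(rate.mean()) < 1e-10
        # no rhythmic structure: the 3 Hz bins carry no more than their
        # share of the (low-passed) spectrum
        f, p = power_spectrum(rate, FS)
        near_3hz = (f >= 2.75) & (f <= 3.25)
        in_band = (f > 0) & (f <= 5)
        share = p[near_3hz].sum() / p[in_band].sum()
        assert share < 0.25

    def test_empty_train_errors(self):
        with pytest.raises(ValueError, match="empty"):
            normalized_firing_rate(SpikeTrain(np.empty(0)), 10.0)
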