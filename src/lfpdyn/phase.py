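"""Event-relative phases, circular statistics, spectra, and firing rates.

Phase conventions
-----------------
Event-relative LFP phase is the analytic-signal (Hilbert) angle of the
event-triggered average at the event time, with phase 0 at the peak of a
cosine-like oscillation. Spike phases in the PC plane default to the polar
angle of the plane rotated so the average submovement-triggered trajectory
has zero phase at the moment of peak cursor speed; with anticlockwise
rotation, activity that leads peak speed therefore has negative phase.

Circular statistics (circular-circular correlation, Rayleigh test) follow
the standard Jammalamadaka-SenGupta definitions.
"""

from __future__ import annotations

import numpy as np
import pingouin as pg
from scipy import signal as _sig
from scipy.signal import hilbert

from .containers import SpikeTrain, StateTrajectory, wrap_angle
from .preprocess import lowpass_delta
from .containers import MultichannelRecording

__all__ = [
    "event_triggered_average",
    "event_relative_phase",
    "circular_circular_correlation",
    "spike_triggered_trajectory",
    "rotate_plane_to_speed_phase",
    "preferred_phase_and_rayleigh",
    "coherence_spectrum",
    "power_spectrum",
    "normalized_firing_rate",
]

_NPERSEG = 2048  # rectangular window, no overlap


def event_triggered_average(sig: np.ndarray, event_times: np.ndarray,
                            sample_rate: float,
                            half_window: float = 0.2) -> tuple[np.ndarray, int]:
    """Pointwise mean of ``sig`` in windows aligned to ``event_times``.

    ``sig`` may be 1D (samples,) or 2D (samples, d). Events whose window is
    clipped by the recording edge are skipped.

    Returns
    -------
    average : ndarray, (window,) or (window, d)
    n_used : int
    """
    sig = np.asarray(sig, dtype=float)
    h = int(round(half_window * sample_rate))
    rel = np.arange(-h, h + 1)
    n = sig.shape[0]
    windows = []
    for t in np.atleast_1d(event_times):
        c = int(round(t * sample_rate))
        if c - h < 0 or c + h >= n:
            continue
        windows.append(sig[c + rel])
    if not windows:
        raise ValueError("no events with a full window inside the recording")
    return np.mean(windows, axis=0), len(windows)


def event_relative_phase(eta: np.ndarray, min_amplitude_frac: float = 0.05
                         ) -> float:
    """Hilbert phase of an event-triggered average at its center sample.

    Phase 0 corresponds to a local maximum of a cosine-like oscillation at
    the event; a pure sine window returns -pi/2. Raises if the analytic
    amplitude at the center is negligible relative to the window's peak
    amplitude (phase unreliable).
    """
    eta = np.asarray(eta, dtype=float)
    analytic = hilbert(eta - eta.mean())
    c = eta.size // 2
    amp = np.abs(analytic)
    if amp[c] <= min_amplitude_frac * amp.max():
        raise ValueError("near-zero analytic amplitude at event time; "
                         "phase unreliable")
    return float(np.angle(analytic[c]))


def circular_circular_correlation(phi_a, phi_b,
                                  correction_uniform: bool = True
                                  ) -> tuple[float, float]:
    """Circular-circular correlation coefficient with asymptotic p-value.

    The Jammalamadaka-SenGupta coefficient
    ``rho = sum sin(a - abar) sin(b - bbar) /
    sqrt(sum sin^2(a - abar) sum sin^2(b - bbar))`` (circular means
    ``abar``, ``bbar``) is undefined when a marginal is spread uniformly
    around the circle (zero resultant, e.g. travelling-wave electrode
    phases). With ``correction_uniform`` (default) the equivalent
    pairwise-difference form ``sum_{i<j} sin(a_i - a_j) sin(b_i - b_j) /
    sqrt(...)`` is used instead, which needs no circular mean and reduces
    to the same quantity for concentrated marginals. Both return +1 for
    identical and -1 for reflected phase vectors; the p-value uses the
    standard normal approximation.
    """
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.size != phi_b.size:
        raise ValueError("phase vectors must have equal length")
    if phi_a.size < 5:
        raise ValueError("need at least 5 phase pairs")
    if not correction_uniform:
        for phi in (phi_a, phi_b):
            if np.abs(np.mean(np.exp(1j * phi))) < 1e-12:
                raise ValueError("zero resultant: circular mean undefined; "
                                 "use correction_uniform=True")
    r, p = pg.circ_corrcc(phi_a, phi_b, correction_uniform=correction_uniform)
    return float(r), float(p)


def normalized_firing_rate(spikes: SpikeTrain, duration: float,
                           sample_rate: float = 488.0):
    """Smoothed, z-normalized firing-rate series.

    Spike events are binned at ``sample_rate`` bins/s, low-pass filtered at
    5 Hz (4-pole, zero-phase), and normalized to zero mean and unit SD over
    the whole recording.

    Returns
    -------
    rate : ndarray
        Normalized rate series.
    rate_sd : float
        SD of the smoothed rate before normalization, spikes/s.
    """
    if spikes.n_spikes < 1:
        raise ValueError("empty spike train")
    n = int(round(duration * sample_rate))
    idx = np.clip((spikes.spike_times * sample_rate).astype(int), 0, n - 1)
    counts = np.bincount(idx, minlength=n).astype(float) * sample_rate
    rec = MultichannelRecording(counts[None, :], sample_rate, ["M1"])
    smooth = lowpass_delta(rec).samples[0]
    sd = smooth.std()
    if sd <= 0:
        raise ValueError("zero-variance firing rate; cannot normalize")
    return (smooth - smooth.mean()) / sd, float(sd)


def spike_triggered_trajectory(spikes: SpikeTrain, traj: StateTrajectory,
                               half_window: float = 0.2,
                               min_spikes: int = 50):
    """Spike-triggered average trajectory, normalized by firing-rate SD.

    The average of the PC trajectory in +-200 ms windows around each spike,
    divided by the SD of the unit's smoothed firing rate so that units with
    different rate modulations are comparable.
    """
    if spikes.n_spikes < min_spikes:
        raise ValueError(f"need at least {min_spikes} spikes")
    duration = traj.n_samples / traj.sample_rate
    avg, n_used = event_triggered_average(traj.x, spikes.spike_times,
                                          traj.sample_rate, half_window)
    if n_used < min_spikes:
        raise ValueError("too few spikes with full windows")
    _, rate_sd = normalized_firing_rate(spikes, duration, traj.sample_rate)
    return avg / rate_sd, n_used


def rotate_plane_to_speed_phase(traj: StateTrajectory,
                                event_times: np.ndarray,
                                half_window: float = 0.2):
    """Rotate PC1-PC2 so the submovement-triggered average has zero phase
    at peak speed.

    Returns the rotated trajectory and the rotation angle applied
    (radians). With this convention, spike phases are directly comparable
    across sessions: 0 means firing at the trajectory phase of peak cursor
    speed, negative phases lead it.
    """
    avg, _ = event_triggered_average(traj.x[:, :2], event_times,
                                     traj.sample_rate, half_window)
    c = avg.shape[0] // 2
    radius = np.hypot(avg[c, 0], avg[c, 1])
    if radius < 1e-6 * np.abs(avg).max():
        raise ValueError("average trajectory has near-zero radius at the "
                         "event time; rotation undefined")
    alpha = np.arctan2(avg[c, 1], avg[c, 0])
    rot = np.array([[np.cos(-alpha), -np.sin(-alpha)],
                    [np.sin(-alpha), np.cos(-alpha)]])
    x = traj.x.copy()
    xdot = traj.xdot.copy()
    x[:, :2] = traj.x[:, :2] @ rot.T
    xdot[:, :2] = traj.xdot[:, :2] @ rot.T
    rotated = StateTrajectory(x, xdot, traj.sample_rate, traj.band,
                              traj.basis_tag)
    return rotated, float(-alpha)


def _instantaneous_phase(traj: StateTrajectory, method: str) -> np.ndarray:
    if method == "polar":
        return np.arctan2(traj.x[:, 1], traj.x[:, 0])
    if method == "hilbert":
        return np.angle(hilbert(traj.x[:, 0] - traj.x[:, 0].mean()))
    raise ValueError("method must be 'polar' or 'hilbert'")


def preferred_phase_and_rayleigh(spikes: SpikeTrain, traj: StateTrajectory,
                                 method: str = "polar",
                                 min_radius_frac: float = 0.25):
    """Preferred firing phase in the (rotated) PC plane with a Rayleigh test.

    Spike phases are the instantaneous plane phase at spike times; samples
    where the trajectory radius is below ``min_radius_frac`` of the RMS
    radius are masked (phase undefined near the origin). Errors if more
    than half the spikes fall on masked samples or fewer than 10 remain.

    Returns
    -------
    mean_phase : float, radians
    resultant_length : float in [0, 1]
    p_value : float (Rayleigh test of circular uniformity)
    """
    phase = _instantaneous_phase(traj, method)
    radius = np.hypot(traj.x[:, 0], traj.x[:, 1])
    floor = min_radius_frac * np.sqrt(np.mean(radius**2))
    idx = np.clip((spikes.spike_times * traj.sample_rate).astype(int),
                  0, traj.n_samples - 1)
    ok = radius[idx] >= floor
    if spikes.n_spikes and ok.mean() < 0.5:
        raise ValueError("more than half the spike phases are undefined "
                         "(trajectory near the origin)")
    phases = phase[idx[ok]]
    if phases.size < 10:
        raise ValueError("need at least 10 spikes with defined phase")
    resultant = np.mean(np.exp(1j * phases))
    z, p = pg.circ_rayleigh(phases)
    return (float(np.angle(resultant)), float(np.abs(resultant)), float(p))


def _check_segments(n_samples: int, min_segments: int):
    if n_samples < min_segments * _NPERSEG:
        raise ValueError(
            f"need at least {min_segments} full {_NPERSEG}-sample segments"
        )


def coherence_spectrum(a: np.ndarray, b: np.ndarray, sample_rate: float):
    """Magnitude-squared coherence, 2048-point rectangular segments.

    Returns frequencies, coherence in [0, 1], and the 95% confidence floor
    ``1 - 0.05**(1/(L-1))`` for L segments (independent signals exceed it
    with 5% probability per bin).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("signals must have equal length")
    _check_segments(a.size, 2)
    f, coh = _sig.coherence(a, b, fs=sample_rate, window="boxcar",
                            nperseg=_NPERSEG, noverlap=0)
    n_seg = a.size // _NPERSEG
    floor = 1 - 0.05 ** (1 / (n_seg - 1))
    return f, coh, float(floor)


def power_spectrum(x: np.ndarray, sample_rate: float):
    """Welch power spectral density (uV^2/Hz), same segmentation as the
    coherence estimator."""
    x = np.asarray(x, dtype=float)
    _check_segments(x.size, 1)
    return _sig.welch(x, fs=sample_rate, window="boxcar",
                      nperseg=_NPERSEG, noverlap=0)
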