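"""Synthetic session generator with known ground truth.

The generator is phenomenological: it emulates the statistical structure of
motor-cortical recordings during an isometric wrist-torque task and under
ketamine sedation, so that every downstream analysis stage can be validated
against known parameters. No biophysical (conductance / thalamocortical)
mechanism is modelled.

Generative model (task mode)
----------------------------
A single latent oscillator with constant frequency f (default 3 Hz) and phase
``phi(t) = 2*pi*f*t`` drives a 2D latent plane

    L1(t) = A(t) cos(phi),   L2(t) = A(t) sin(phi),

whose squared amplitude is a sum of raised-cosine bursts, one per
submovement, scaled by that submovement's peak speed ``s_i``:

    A(t)^2  proportional to  sum_i s_i g(t - t_i).

Because the areal velocity of ``(A cos phi, A sin phi)`` equals
``A(t)^2 * pi * f`` regardless of how A varies, the areal velocity during
each burst is *exactly* proportional to the event's peak speed.

Submovements occur as a phase-locked renewal process: one candidate per
oscillator cycle, emitted with probability ``submovement_rate /
oscillator_freq``, so intersubmovement intervals cluster at multiples of the
~333 ms cycle with a dominant mode at one cycle.

Direction is encoded by tilting the rotation axis: a third latent dimension
receives ``tan(direction_tilt) * A(t) cos(phi - theta_i)`` during event i,
which places the trajectory in a plane whose normal is tilted away from the
z axis by exactly ``direction_tilt`` radians, in the direction ``theta_i``.
The resulting areal-velocity vector is

    v_i = coupling * s_i * (-tan(tilt) cos(theta_i), -tan(tilt) sin(theta_i), 1),

a pure first-harmonic Fourier series in theta -- the form the kinematic
decoder assumes.

Each latent dimension is mixed into channels with a fixed phase ``psi_c`` per
channel (evenly spaced around the cycle by default, i.e. a travelling-wave
pattern), plus pink (1/f) and white sensor noise. Channel mixing norms are
chosen so that PCA scores reproduce the latent areal-velocity calibration.

Sedation mode reuses the same oscillator and the same channel phases, but
the oscillation appears as 1-3 cycle bursts flanking large positive
K-complex transients (>250 uV, common across channels), with delta-band
power an order of magnitude above task mode and spiking concentrated on the
K-complex rising phase and peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    EMGTraces,
    KinematicsTrace,
    MultichannelRecording,
    SpikeTrain,
    wrap_angle,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_task_session",
    "simulate_sedation_session",
    "simulate_white_noise",
]

# burst shape: raised cosine with +-200 ms support (~1.2 cycles at 3 Hz);
# adjacent-cycle bursts overlap only in their far tails
_BURST_HALF_WIDTH_S = 0.2
# decoder window over which areal velocity is averaged
_DECODE_HALF_WINDOW_S = 0.2


@dataclass
class SimulationConfig:
    """Parameters of the synthetic session generator.

    Attributes
    ----------
    n_channels_m1, n_channels_pmv : int
        Electrode counts per cortical area.
    sample_rate : float
        Hz (default 488, the recording rate of the emulated system).
    duration : float
        Session length in seconds.
    oscillator_freq : float
        Latent oscillation frequency in Hz (default 3).
    channel_phases : ndarray or None
        Fixed phase offset per M1 channel (radians). Default: evenly spaced
        over the cycle (travelling-wave pattern).
    submovement_rate : float
        Mean submovement rate in events/s. Must not exceed
        ``oscillator_freq`` (at most one event per cycle).
    speed_coupling : float
        Areal velocity (PC-score units^2/s) per unit peak speed (%/s):
        the window-averaged areal velocity of event i is
        ``speed_coupling * s_i``.
    direction_tilt : float
        Tilt (radians) of the rotation axis per unit direction harmonic.
    spike_kappa : float
        Von Mises concentration of spike phase locking (0 = unlocked).
    spike_phase_lead : float
        Radians by which preferred firing phase precedes the peak-speed
        phase (positive = firing leads peak speed).
    noise_sd : float
        White sensor-noise SD per channel, uV.
    pink_noise_sd : float
        1/f background-noise SD per channel, uV.
    speed_median, speed_sigma : float
        Log-normal peak-speed distribution (%/s; median and log-SD).
    kcomplex_rate : float
        K-complex rate in events/s (sedation mode).
    kcomplex_amplitude : float
        K-complex peak amplitude, uV; must exceed the 250 uV detection
        threshold to be recoverable.
    sedation_amplitude_ratio : float
        Ratio of sedation-mode to task-mode delta-band variance
        (mean-referenced), ~10 for an order-of-magnitude increase.
    n_units : int
        Number of simulated single units.
    seed : int
        Seed for all randomness.
    """

    n_channels_m1: int = 10
    n_channels_pmv: int = 8
    sample_rate: float = 488.0
    duration: float = 120.0
    oscillator_freq: float = 3.0
    channel_phases: np.ndarray | None = None
    submovement_rate: float = 1.5
    speed_coupling: float = 400.0
    direction_tilt: float = 0.3
    spike_kappa: float = 1.5
    spike_phase_lead: float = 0.52
    noise_sd: float = 5.0
    pink_noise_sd: float = 5.0
    speed_median: float = 70.0
    speed_sigma: float = 0.35
    baseline_amplitude_frac: float = 0.7
    kcomplex_rate: float = 0.25
    kcomplex_amplitude: float = 400.0
    sedation_amplitude_ratio: float = 10.0
    n_units: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 2 * self.oscillator_freq:
            raise ValueError("sample_rate must exceed twice oscillator_freq")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("submovement_rate", "kcomplex_rate", "spike_kappa",
                     "noise_sd", "pink_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.submovement_rate > self.oscillator_freq:
            raise ValueError(
                "submovement_rate exceeds oscillator_freq: cannot lock one "
                "event per oscillator cycle"
            )
        if self.channel_phases is None:
            self.channel_phases = (
                2 * np.pi * np.arange(self.n_channels_m1) / self.n_channels_m1
            )
        else:
            self.channel_phases = np.asarray(self.channel_phases, dtype=float)
            if self.channel_phases.size != self.n_channels_m1:
                raise ValueError("channel_phases must have one entry per M1 channel")

    @property
    def mean_speed(self) -> float:
        """Mean of the log-normal peak-speed distribution, %/s."""
        return self.speed_median * np.exp(self.speed_sigma**2 / 2)

    @property
    def mean_square_speed(self) -> float:
        """Second moment of the peak-speed distribution, (%/s)^2."""
        return self.speed_median**2 * np.exp(2 * self.speed_sigma**2)


@dataclass
class GroundTruth:
    """Hidden state of a simulated session, for validating the pipeline."""

    latent_phase: np.ndarray            # radians over time
    latent_amplitude: np.ndarray        # sqrt(uV^2) envelope over time
    true_submovements: np.ndarray       # structured: time, speed, direction
    true_kcomplexes: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_preferred_phases: np.ndarray = field(default_factory=lambda: np.empty(0))
    mixing_matrix: np.ndarray | None = None  # channels x latent dims


_SM_DTYPE = np.dtype([("time", float), ("speed", float), ("direction", float)])


def _burst(tau: np.ndarray, half_width: float) -> np.ndarray:
    """Raised-cosine bump, unit peak, compact support |tau| < half_width."""
    out = np.zeros_like(tau)
    m = np.abs(tau) < half_width
    out[m] = np.cos(np.pi * tau[m] / (2 * half_width)) ** 2
    return out


def _pink_noise(rng, shape, sample_rate):
    """Unit-SD 1/f-amplitude noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1 / sample_rate)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _mixing_matrix(cfg: SimulationConfig) -> np.ndarray:
    """M1 channel loadings for the three latent dimensions.

    Row c is ``(cos psi_c, -sin psi_c, cos 2 psi_c)``: the first two columns
    mix the rotation plane so channel c carries ``A(t) cos(phi + psi_c)``;
    the third carries the direction-tilt latent with a spatial pattern
    orthogonal to the plane columns for evenly spaced phases.
    """
    psi = cfg.channel_phases
    return np.column_stack([np.cos(psi), -np.sin(psi), np.cos(2 * psi)])


def _draw_locked_events(rng, cfg: SimulationConfig, rate: float,
                        min_separation: float = 0.0):
    """Phase-locked renewal process: one candidate per cycle, emitted with
    probability rate/oscillator_freq; optional refractory spacing."""
    cycle = 1.0 / cfg.oscillator_freq
    margin = _DECODE_HALF_WINDOW_S + _BURST_HALF_WIDTH_S
    candidates = np.arange(np.ceil(margin / cycle) * cycle,
                           cfg.duration - margin, cycle)
    p = min(rate / cfg.oscillator_freq, 1.0)
    keep = rng.random(candidates.size) < p
    times = candidates[keep]
    if min_separation > 0 and times.size:
        accepted = [times[0]]
        for t in times[1:]:
            if t - accepted[-1] >= min_separation:
                accepted.append(t)
        times = np.asarray(accepted)
    return times


def _neighbor_tail_integral(cfg: SimulationConfig) -> float:
    """Integral of an adjacent-cycle burst over the +-200 ms decode window."""
    w = _BURST_HALF_WIDTH_S
    delta = 1.0 / cfg.oscillator_freq
    lo, hi = max(-w, -_DECODE_HALF_WINDOW_S - delta), min(w, _DECODE_HALF_WINDOW_S - delta)
    if hi <= lo:
        return 0.0
    u = np.linspace(lo, hi, 201)
    return float(np.trapezoid(_burst(u, w), u))


def _calibration_constant(cfg: SimulationConfig) -> float:
    """Latent scale making the regression-recovered |b0| equal speed_coupling.

    The window-mean areal velocity of event i is
    ``pi f c [s_i g_wm + neighbors + baseline]``; the constant-term
    coefficient recovered by regressing it on s_i therefore carries a known
    inflation from the baseline rotation offset and from adjacent-cycle
    burst tails inside the window. c is chosen so the recovered coefficient
    equals the configured coupling in expectation.
    """
    w = _BURST_HALF_WIDTH_S
    g_wm = w / (2 * _DECODE_HALF_WINDOW_S)
    p_neighbor = cfg.submovement_rate / cfg.oscillator_freq
    tail_wm = _neighbor_tail_integral(cfg) / (2 * _DECODE_HALF_WINDOW_S)
    offset = 2 * p_neighbor * cfg.mean_speed * tail_wm + _baseline_speed_units(cfg)
    inflation = g_wm + offset * cfg.mean_speed / cfg.mean_square_speed
    return cfg.speed_coupling / (np.pi * cfg.oscillator_freq * inflation)


def _baseline_speed_units(cfg: SimulationConfig) -> float:
    """Squared baseline amplitude in the generator's speed-burst units.

    The ongoing (between-burst) rotation carries
    ``baseline_amplitude_frac**2`` times the time-averaged burst-driven
    squared amplitude, whose expectation is ``rate * E[s] * w``.
    """
    return (cfg.baseline_amplitude_frac**2 * cfg.submovement_rate
            * cfg.mean_speed * _BURST_HALF_WIDTH_S)


def _latent_amplitude_sq(cfg: SimulationConfig, t: np.ndarray,
                         times: np.ndarray, speeds: np.ndarray) -> np.ndarray:
    """Squared latent envelope: baseline rotation plus one burst per event.

    Calibrated (see ``_calibration_constant``) so the +-200 ms window-mean
    areal velocity of the PC-score trajectory regresses onto peak speed
    with coefficient ``speed_coupling``.
    """
    w = _BURST_HALF_WIDTH_S
    c_cal = _calibration_constant(cfg)
    a2 = np.full_like(t, _baseline_speed_units(cfg))
    for ti, si in zip(times, speeds):
        m = np.abs(t - ti) < w
        a2[m] += si * _burst(t[m] - ti, w)
    # PCA scores scale the latent by sqrt(n/2) for unit-gain mixing, so the
    # latent itself carries a 2/n factor
    return (2.0 / cfg.n_channels_m1) * c_cal * a2


def _spike_trains(rng, cfg: SimulationConfig, phase: np.ndarray,
                  gate: np.ndarray | None, area: str = "M1"):
    """Inhomogeneous point processes with von Mises phase modulation."""
    from scipy.special import i0

    dt = 1.0 / cfg.sample_rate
    prefs = wrap_angle(-cfg.spike_phase_lead
                       + 0.2 * rng.standard_normal(cfg.n_units))
    base_rate = 10.0  # spikes/s
    trains = []
    for u in range(cfg.n_units):
        lam = base_rate * np.exp(cfg.spike_kappa * np.cos(phase - prefs[u]))
        lam = lam / i0(cfg.spike_kappa)
        if gate is not None:
            lam = lam * gate
        spikes = np.nonzero(rng.random(lam.size) < lam * dt)[0] * dt
        # bin-edge draws are already strictly increasing
        trains.append(SpikeTrain(spikes, unit_id=u, area=area))
    return trains, prefs


def _kinematics(cfg: SimulationConfig, t: np.ndarray, times: np.ndarray,
                speeds: np.ndarray, directions: np.ndarray) -> KinematicsTrace:
    """Torque trace whose radial speed peaks at exactly s_i toward theta_i.

    Each submovement is an outward displacement bump followed, 130 ms later,
    by an equal return to center, so the cursor comes back to baseline before
    the next cycle's candidate event.
    """
    w = 0.06      # half-width of the speed bump, s
    d_ret = 0.13  # delay of the return stroke, s
    dt = t[1] - t[0]
    # displacement profile: integral of (bump - delayed bump)
    tau = np.arange(-w, d_ret + w + dt, dt)
    prof = np.cumsum(_burst(tau, w) - _burst(tau - d_ret, w)) * dt
    torque = np.zeros((t.size, 2))
    for ti, si, thi in zip(times, speeds, directions):
        i0_ = int(round((ti - w) / dt))
        sl = slice(max(i0_, 0), min(i0_ + tau.size, t.size))
        seg = prof[sl.start - i0_: sl.stop - i0_]
        torque[sl, 0] += si * seg * np.cos(thi)
        torque[sl, 1] += si * seg * np.sin(thi)
    radial = np.linalg.norm(torque, axis=1)
    rspeed = np.gradient(radial) * cfg.sample_rate
    return KinematicsTrace(torque, radial, rspeed, cfg.sample_rate)


def _pmv_channels(rng, cfg: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """PMv channels: an independent oscillator (same frequency, own bursts,
    own travelling-wave phases), not locked to submovements."""
    n = cfg.n_channels_pmv
    if n == 0:
        return np.zeros((0, t.size))
    psi = 2 * np.pi * np.arange(n) / n
    cycle = 1.0 / cfg.oscillator_freq
    offs = rng.uniform(0, cycle)
    candidates = np.arange(offs, cfg.duration, cycle)
    keep = rng.random(candidates.size) < min(
        cfg.submovement_rate / cfg.oscillator_freq, 1.0)
    times = candidates[keep]
    speeds = cfg.speed_median * np.exp(cfg.speed_sigma
                                       * rng.standard_normal(times.size))
    a2 = np.full_like(t, _baseline_speed_units(cfg))
    for ti, si in zip(times, speeds):
        m = np.abs(t - ti) < _BURST_HALF_WIDTH_S
        a2[m] += si * _burst(t[m] - ti, _BURST_HALF_WIDTH_S)
    amp = np.sqrt((2.0 / max(n, 1)) * _calibration_constant(cfg) * a2)
    phase = 2 * np.pi * cfg.oscillator_freq * t + rng.uniform(0, 2 * np.pi)
    return amp * np.cos(phase[None, :] + psi[:, None])


def _add_noise(rng, cfg: SimulationConfig, lfp: np.ndarray) -> np.ndarray:
    out = lfp
    if cfg.pink_noise_sd > 0:
        out = out + cfg.pink_noise_sd * _pink_noise(rng, lfp.shape,
                                                    cfg.sample_rate)
    if cfg.noise_sd > 0:
        out = out + cfg.noise_sd * rng.standard_normal(lfp.shape)
    return out


def simulate_task_session(config: SimulationConfig):
    """Simulate an isometric-task session.

    Returns
    -------
    (MultichannelRecording, KinematicsTrace, list[SpikeTrain], EMGTraces,
    GroundTruth)
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 1])
    n = int(round(cfg.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    phase = 2 * np.pi * cfg.oscillator_freq * t

    times = _draw_locked_events(rng, cfg, cfg.submovement_rate)
    speeds = cfg.speed_median * np.exp(cfg.speed_sigma
                                       * rng.standard_normal(times.size))
    target_angles = wrap_angle(2 * np.pi * np.arange(8) / 8)
    directions = rng.choice(target_angles, size=times.size)

    a2 = _latent_amplitude_sq(cfg, t, times, speeds)
    amp = np.sqrt(a2)
    lat = np.zeros((3, n))
    lat[0] = amp * np.cos(phase)
    lat[1] = amp * np.sin(phase)
    tilt = np.tan(cfg.direction_tilt)
    for ti, thi in zip(times, directions):
        m = np.abs(t - ti) < _BURST_HALF_WIDTH_S
        lat[2, m] += tilt * amp[m] * np.cos(phase[m] - thi)

    mix = _mixing_matrix(cfg)
    m1 = mix @ lat
    pmv = _pmv_channels(rng, cfg, t)
    lfp = _add_noise(rng, cfg, np.vstack([m1, pmv]))
    areas = ["M1"] * cfg.n_channels_m1 + ["PMv"] * cfg.n_channels_pmv
    rec = MultichannelRecording(lfp, cfg.sample_rate, areas, "surface")

    kin = _kinematics(cfg, t, times, speeds, directions)
    trains, prefs = _spike_trains(rng, cfg, phase, gate=None)

    env = a2 / max(a2.max(), 1e-12)
    emg = np.abs(rng.standard_normal((2, n))) * (0.3 + env) * 50.0
    emg_tr = EMGTraces(emg, cfg.sample_rate, ["ECU", "ECR"])

    events = np.zeros(times.size, dtype=_SM_DTYPE)
    events["time"], events["speed"], events["direction"] = times, speeds, directions
    gt = GroundTruth(phase, amp, events, np.empty(0), prefs, mix)
    return rec, kin, trains, emg_tr, gt


def simulate_sedation_session(config: SimulationConfig):
    """Simulate a ketamine-sedation session with K complexes.

    The latent oscillator and the per-channel phase pattern are identical to
    task mode; only the amplitude statistics differ (burst envelopes flanking
    each K complex, delta power scaled by ``sedation_amplitude_ratio``).

    Returns
    -------
    (MultichannelRecording, list[SpikeTrain], GroundTruth)
    """
    cfg = config
    if cfg.kcomplex_amplitude <= 250.0:
        raise ValueError(
            "kcomplex_amplitude must exceed 250 uV; smaller events are "
            "undetectable by the standard threshold"
        )
    rng = np.random.default_rng([cfg.seed, 2])
    n = int(round(cfg.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    phase = 2 * np.pi * cfg.oscillator_freq * t

    k_times = _draw_locked_events(rng, cfg, cfg.kcomplex_rate,
                                  min_separation=1.5)

    # burst envelope: 1-3 cycles of the oscillator around each K complex
    cycle = 1.0 / cfg.oscillator_freq
    n_cycles = rng.integers(1, 4, size=k_times.size)
    b2 = np.zeros_like(t)
    for ti, nc in zip(k_times, n_cycles):
        hw = nc * cycle / 2
        m = np.abs(t - ti) < hw
        b2[m] += _burst(t[m] - ti, hw)

    # calibrate delta-band variance to `ratio` x the task-mode expectation
    # (burst-driven plus baseline rotation)
    c_cal = _calibration_constant(cfg)
    task_a2_mean = ((2.0 / cfg.n_channels_m1) * c_cal
                    * (cfg.submovement_rate * cfg.mean_speed
                       * _BURST_HALF_WIDTH_S + _baseline_speed_units(cfg)))
    target_b2_mean = cfg.sedation_amplitude_ratio * task_a2_mean
    b2_mean = b2.mean()
    if b2_mean > 0:
        b2 *= target_b2_mean / b2_mean
    amp = np.sqrt(b2)

    lat = np.vstack([amp * np.cos(phase), amp * np.sin(phase),
                     np.zeros_like(t)])
    mix = _mixing_matrix(cfg)
    m1 = mix @ lat

    # common-mode K-complex transient (difference of Gaussians, unit peak)
    tau = np.arange(-1.0, 1.0, 1 / cfg.sample_rate)
    dog = np.exp(-tau**2 / (2 * 0.12**2)) - 0.4 * np.exp(-tau**2 / (2 * 0.3**2))
    dog = dog / dog.max() * cfg.kcomplex_amplitude
    kwave = np.zeros_like(t)
    for ti in k_times:
        i0_ = int(round((ti - 1.0) * cfg.sample_rate))
        sl = slice(max(i0_, 0), min(i0_ + tau.size, n))
        kwave[sl] += dog[sl.start - i0_: sl.stop - i0_]
    m1 = m1 + kwave[None, :]

    pmv = np.zeros((cfg.n_channels_pmv, n)) + kwave[None, :] * 0.8
    lfp = _add_noise(rng, cfg, np.vstack([m1, pmv]))
    areas = ["M1"] * cfg.n_channels_m1 + ["PMv"] * cfg.n_channels_pmv
    rec = MultichannelRecording(lfp, cfg.sample_rate, areas, "surface")

    gate = 0.05 + b2 / max(b2.max(), 1e-12)  # spiking rides the bursts
    trains, prefs = _spike_trains(rng, cfg, phase, gate=gate)

    gt = GroundTruth(phase, amp, np.zeros(0, dtype=_SM_DTYPE),
                     k_times, prefs, mix)
    return rec, trains, gt


def simulate_white_noise(n_channels: int, duration: float,
                         sample_rate: float, seed: int) -> MultichannelRecording:
    """Independent unit-variance Gaussian noise per channel (seeded)."""
    if n_channels <= 0 or duration <= 0 or sample_rate <= 0:
        raise ValueError("all arguments must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    samples = rng.standard_normal((n_channels, n))
    return MultichannelRecording(samples, sample_rate,
                                 ["M1"] * n_channels, "surface")
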