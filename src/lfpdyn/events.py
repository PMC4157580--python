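"""Detection of submovements and K complexes, and interval rhythmicity.

Submovements are discrete peaks in radial cursor speed (> 30 %/s); K
complexes are large positive LFP deflections (> 250 uV) on a single
surface-referenced channel. Rhythmicity is quantified by the pairwise
interval histogram normalized by the expectation under a homogeneous
Poisson process of the same rate.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import (
    KComplexEvent,
    KinematicsTrace,
    MultichannelRecording,
    SubmovementEvent,
    wrap_angle,
)

__all__ = [
    "compute_radial_speed",
    "detect_submovements",
    "detect_k_complexes",
    "interval_autocorrelation",
]

SUBMOVEMENT_THRESHOLD = 30.0       # %/s
KCOMPLEX_THRESHOLD = 250.0         # uV
_SUBMOVEMENT_REFRACTORY_S = 0.1    # below the ~300 ms cycle
_KCOMPLEX_REFRACTORY_S = 1.0


def compute_radial_speed(torque_xy: np.ndarray,
                         sample_rate: float) -> KinematicsTrace:
    """Radial position (|torque|) and its signed time derivative.

    Speed is positive for movements away from the screen center, negative on
    the return stroke; derivatives are central differences (one-sided at the
    endpoints).
    """
    torque_xy = np.asarray(torque_xy, dtype=float)
    if torque_xy.ndim != 2 or torque_xy.shape[1] != 2:
        raise ValueError("torque_xy must be time x 2")
    if not np.isfinite(torque_xy).all():
        raise ValueError("torque trace contains non-finite values")
    radial = np.linalg.norm(torque_xy, axis=1)
    rspeed = np.gradient(radial) * sample_rate
    return KinematicsTrace(torque_xy, radial, rspeed, sample_rate)


def detect_submovements(kin: KinematicsTrace,
                        threshold: float = SUBMOVEMENT_THRESHOLD
                        ) -> list[SubmovementEvent]:
    """Local speed maxima strictly exceeding ``threshold``.

    Peaks closer than 100 ms are merged, keeping the larger. Direction is
    the angle of the instantaneous torque-velocity vector at the peak.
    """
    rspeed = kin.radial_speed
    if rspeed.size < 3:
        return []
    distance = max(int(round(_SUBMOVEMENT_REFRACTORY_S * kin.sample_rate)), 1)
    idx, _ = signal.find_peaks(rspeed, height=threshold, distance=distance)
    idx = idx[rspeed[idx] > threshold]  # strict exceedance
    vel = np.gradient(kin.torque_xy, axis=0) * kin.sample_rate
    out = []
    for i in idx:
        direction = float(wrap_angle(np.arctan2(vel[i, 1], vel[i, 0])))
        out.append(SubmovementEvent(peak_time=i / kin.sample_rate,
                                    peak_speed=float(rspeed[i]),
                                    direction=direction))
    return out


def detect_k_complexes(rec: MultichannelRecording, channel: int = 0,
                       threshold: float = KCOMPLEX_THRESHOLD
                       ) -> list[KComplexEvent]:
    """Peaks of positive deflections exceeding ``threshold`` on one
    surface-referenced channel, with 1 s minimum separation."""
    x = rec.samples[channel]
    distance = max(int(round(_KCOMPLEX_REFRACTORY_S * rec.sample_rate)), 1)
    idx, _ = signal.find_peaks(x, height=threshold, distance=distance)
    idx = idx[x[idx] > threshold]
    return [KComplexEvent(peak_time=i / rec.sample_rate,
                          peak_amplitude=float(x[i])) for i in idx]


def interval_autocorrelation(event_times: np.ndarray,
                             trial_bounds: list[tuple[float, float]],
                             bin_width: float = 0.05,
                             max_lag: float = 1.0):
    """Pairwise-interval histogram normalized by the Poisson expectation.

    All ordered within-trial event pairs contribute their interval. The
    histogram is divided bin-wise by the analytic expectation for a
    homogeneous Poisson process with the same per-trial event counts over
    the same trial windows: for a trial of duration T holding n events, the
    expected number of pairs at lag u has the triangular density
    ``n(n-1)/2 * 2(T-u)/T^2`` (the edge correction for a finite window).
    A flat profile at 1 indicates Poisson timing; peaks at multiples of a
    period indicate rhythmicity.

    Returns
    -------
    bin_centers : ndarray, s
    normalized : ndarray
        Observed / expected pair counts per bin.
    """
    event_times = np.asarray(event_times, dtype=float)
    edges = np.arange(0.0, max_lag + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    observed = np.zeros(centers.size)
    expected = np.zeros(centers.size)
    n_pairs = 0
    for (t0, t1) in trial_bounds:
        T = t1 - t0
        if T <= 0:
            raise ValueError("trial bounds must satisfy start < end")
        ev = np.sort(event_times[(event_times >= t0) & (event_times <= t1)])
        m = ev.size
        if m < 2:
            continue
        lags = (ev[None, :] - ev[:, None])[np.triu_indices(m, k=1)]
        observed += np.histogram(lags, bins=edges)[0]
        n_pairs += lags.size
        # analytic triangular-window expectation per bin
        lo, hi = edges[:-1], np.minimum(edges[1:], T)
        width = np.clip(hi - lo, 0, None)
        integral = width * (T - 0.5 * (lo + hi)) / T**2 * 2
        expected += m * (m - 1) / 2 * np.clip(integral, 0, None)
    if n_pairs == 0:
        raise ValueError("no within-trial event pairs")
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(expected > 0, observed / expected, np.nan)
    return centers, normalized
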