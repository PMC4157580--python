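"""Preprocessing chain for multichannel LFP.

The canonical order is: band filtering (4-pole zero-phase Butterworth),
within-area mean referencing, PCA with a rotational orientation convention,
and projection of any condition onto task-derived axes.

The orientation convention exists because PCA leaves component signs
arbitrary: the PC1-PC2 plane is oriented so the predominant rotation of the
projected trajectory is anticlockwise (positive areal velocity), which makes
rotation-sense comparisons across conditions meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import MultichannelRecording, PCBasis, StateTrajectory

__all__ = [
    "lowpass_delta",
    "bandpass_beta",
    "mean_reference",
    "fit_pca",
    "project",
]

DELTA_CUTOFF_HZ = 5.0
BETA_BAND_HZ = (10.0, 30.0)
_FILTER_ORDER = 4  # poles per pass; applied forward-backward (zero phase)


def _zero_phase(sos: np.ndarray, rec: MultichannelRecording,
                band: str) -> MultichannelRecording:
    # filtfilt pads by reflection ('even') so edges stay finite-length clean
    ntaps = 3 * (2 * _FILTER_ORDER + 1)
    if rec.n_samples <= 3 * ntaps:
        raise ValueError(
            f"recording too short ({rec.n_samples} samples) for zero-phase "
            f"filtering; need > {3 * ntaps}"
        )
    out = signal.sosfiltfilt(sos, rec.samples, axis=1, padtype="even")
    filtered = MultichannelRecording(out, rec.sample_rate,
                                     list(rec.channel_area), rec.reference)
    filtered.band = band
    return filtered


def lowpass_delta(rec: MultichannelRecording,
                  cutoff_hz: float = DELTA_CUTOFF_HZ) -> MultichannelRecording:
    """Delta-band extraction: 4-pole zero-phase Butterworth low-pass at 5 Hz.

    Forward-backward application squares the magnitude response (8 effective
    poles) and cancels phase lag, so a 3 Hz component passes essentially
    untouched while 20 Hz is attenuated by far more than 40 dB.
    """
    if rec.sample_rate <= 2 * cutoff_hz:
        raise ValueError("sample rate too low for the requested cutoff")
    sos = signal.butter(_FILTER_ORDER, cutoff_hz, btype="low",
                        fs=rec.sample_rate, output="sos")
    return _zero_phase(sos, rec, "delta")


def bandpass_beta(rec: MultichannelRecording,
                  band_hz: tuple[float, float] = BETA_BAND_HZ
                  ) -> MultichannelRecording:
    """Beta-band extraction: 4-pole zero-phase Butterworth band-pass 10-30 Hz."""
    if rec.sample_rate <= 2 * band_hz[1]:
        raise ValueError("sample rate too low for the requested band")
    # order 2 per edge -> 4 poles total for the band-pass, mirroring the
    # 4-pole low-pass used for the delta band
    sos = signal.butter(2, band_hz, btype="bandpass",
                        fs=rec.sample_rate, output="sos")
    return _zero_phase(sos, rec, "beta")


def mean_reference(rec: MultichannelRecording) -> MultichannelRecording:
    """Subtract, per sample, the mean across channels of the same area.

    Removes the component common to all electrodes of an area (volume-
    conducted/reference activity), leaving the spatial pattern that PCA
    decomposes. Errors on single-channel areas, where the reference would
    annihilate the channel.
    """
    out = rec.samples.copy()
    for area in dict.fromkeys(rec.channel_area):
        idx = [i for i, a in enumerate(rec.channel_area) if a == area]
        if len(idx) < 2:
            raise ValueError(
                f"area {area!r} has a single channel; within-area mean "
                "reference is undefined"
            )
        out[idx] -= out[idx].mean(axis=0, keepdims=True)
    ref = MultichannelRecording(out, rec.sample_rate,
                                list(rec.channel_area), "area-mean")
    if hasattr(rec, "band"):
        ref.band = rec.band
    return ref


def _mean_areal_velocity_2d(scores: np.ndarray, sample_rate: float) -> float:
    xdot = np.gradient(scores, axis=0) * sample_rate
    return float(np.mean(0.5 * (scores[:, 0] * xdot[:, 1]
                                - scores[:, 1] * xdot[:, 0])))


def fit_pca(rec: MultichannelRecording, n_components: int,
            source_condition: str = "task") -> PCBasis:
    """PCA of the channel covariance with the rotational orientation fix.

    Sign conventions (PCA signs are otherwise arbitrary):

    1. every component's largest-magnitude loading is made positive
       (reproducibility);
    2. if the projected trajectory's mean areal velocity in the PC1-PC2 plane
       is clockwise (negative), PC2 is negated so the predominant rotation is
       anticlockwise.
    """
    if n_components > rec.n_channels:
        raise ValueError("n_components exceeds channel count")
    X = rec.samples.T  # time x channels
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD of the centered data == eigendecomposition of covariance
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (Xc.shape[0] - 1)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if n_components > rank:
        raise ValueError(
            f"covariance rank {rank} < requested {n_components} components"
        )
    loadings = Vt[:n_components].T  # channels x components
    total_var = float(var.sum())
    explained = var[:n_components] / total_var if total_var > 0 else var[:n_components]

    # sign rule 1: largest-|loading| positive
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]

    # sign rule 2: anticlockwise predominant rotation in the PC1-PC2 plane
    if n_components >= 2:
        scores = Xc @ loadings[:, :2]
        if _mean_areal_velocity_2d(scores, rec.sample_rate) < 0:
            loadings[:, 1] = -loadings[:, 1]

    band = getattr(rec, "band", "delta")
    return PCBasis(loadings, explained, source_condition=source_condition,
                   orientation_fixed=True, channel_mean=mean, band=band)


def project(rec: MultichannelRecording, basis: PCBasis) -> StateTrajectory:
    """Project a recording onto a PC basis, with central-difference derivative.

    Any condition (sedation, sleep, free reach) is projected onto the SAME
    task-derived axes, so rotation sense and dynamics are directly comparable
    across behavioral states. The basis's channel means are subtracted before
    projection.
    """
    if rec.n_channels != basis.loadings.shape[0]:
        raise ValueError(
            f"channel count {rec.n_channels} does not match basis "
            f"({basis.loadings.shape[0]} channels)"
        )
    x = (rec.samples.T - basis.channel_mean) @ basis.loadings
    xdot = np.gradient(x, axis=0) * rec.sample_rate
    return StateTrajectory(x, xdot, rec.sample_rate,
                           band=getattr(rec, "band", basis.band),
                           basis_tag=basis.source_condition)
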