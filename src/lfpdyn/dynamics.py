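"""Trace-zero first-order linear dynamical model of 2D trajectories.

The model is ``xdot(t) = A x(t)`` with a 2x2 matrix A constrained to
``trace(A) = 0`` (three free parameters: the fourth entry is fixed by the
constraint). When additionally ``det(A) > 0``, solutions are closed
elliptical orbits with constant frequency ``sqrt(det A) / 2 pi`` and a fixed
sense of rotation, which makes the model a minimal description of rotational
population dynamics. The off-diagonal entries are NOT constrained to be the
only nonzero ones: when data from another condition are projected onto the
same axes, the components need not stay uncorrelated.

Fit quality is the vector coefficient of determination

    CoD = 1 - sum |A x - xdot|^2 / sum |xdot|^2,

summed over all samples of the recording; it can be negative when the
model is worse than predicting zero derivative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .containers import StateTrajectory
from .preprocess import fit_pca, lowpass_delta, mean_reference, project
from .simulate import simulate_white_noise

__all__ = [
    "TraceZeroDynamics",
    "TraceZeroDynamicsResults",
    "white_noise_null",
    "correlation_frequency",
]


class TraceZeroDynamics:
    """Least-squares fit of ``xdot = A x`` with ``trace(A) = 0``.

    Parameters
    ----------
    traj : StateTrajectory
        2-component trajectory with derivative (length >= 100 samples).
    """

    MIN_SAMPLES = 100

    def __init__(self, traj: StateTrajectory):
        if traj.d != 2:
            raise ValueError("the dynamics model is defined for 2 components")
        if traj.n_samples < self.MIN_SAMPLES:
            raise ValueError(
                f"need at least {self.MIN_SAMPLES} samples to fit"
            )
        if np.allclose(traj.x.std(axis=0), 0):
            raise ValueError("degenerate trajectory: zero variance")
        self.traj = traj

    def fit(self) -> "TraceZeroDynamicsResults":
        """Closed-form least squares over A = [[a, b], [c, -a]].

        Stacking both components gives a linear system in (a, b, c):
        ``xdot1 = a x1 + b x2`` and ``xdot2 = c x1 - a x2``.
        """
        x1, x2 = self.traj.x[:, 0], self.traj.x[:, 1]
        z = np.zeros_like(x1)
        D = np.block([[np.column_stack([x1, x2, z])],
                      [np.column_stack([-x2, z, x1])]])
        y = np.concatenate([self.traj.xdot[:, 0], self.traj.xdot[:, 1]])
        (a, b, c), *_ = np.linalg.lstsq(D, y, rcond=None)
        A = np.array([[a, b], [c, -a]])
        res = TraceZeroDynamicsResults(
            A=A, band=self.traj.band, source_condition=self.traj.basis_tag,
            cod_fit=np.nan, nobs=self.traj.n_samples,
        )
        res.cod_fit = res.score(self.traj, check_tags=False)
        return res


@dataclass
class TraceZeroDynamicsResults:
    """Fitted trace-zero matrix with band/condition metadata."""

    A: np.ndarray
    band: str
    source_condition: str
    cod_fit: float
    nobs: int

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        tr = abs(np.trace(self.A))
        scale = max(np.abs(self.A).max(), 1e-300)
        if tr > 1e-10 * scale:
            raise ValueError("matrix violates the trace-zero constraint")

    @property
    def n_parameters(self) -> int:
        """Free parameters: a, b, c (the fourth entry is -a)."""
        return 3

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.A))

    @property
    def frequency_hz(self) -> float:
        """Orbit frequency ``sqrt(det A) / 2 pi`` when det(A) > 0.

        With trace zero the eigenvalues are ``+-i sqrt(det A)`` (rotational
        regime) or a ``+-real`` pair (det < 0, saddle: NaN returned).
        """
        d = self.det
        return float(np.sqrt(d) / (2 * np.pi)) if d > 0 else float("nan")

    def predict(self, traj: StateTrajectory) -> np.ndarray:
        """Model derivative ``A x(t)``."""
        return traj.x @ self.A.T

    def score(self, traj: StateTrajectory, check_tags: bool = True) -> float:
        """Vector CoD of the model on a trajectory (no refitting).

        Used for cross-condition generalization: a model fitted on task
        data can be scored on sedation/sleep data projected onto the SAME
        task-derived PC basis, so ``check_tags`` enforces matching basis
        and band tags by default.
        """
        if check_tags:
            if traj.basis_tag != self.source_condition:
                raise ValueError(
                    f"basis tag mismatch: model from {self.source_condition!r}"
                    f", trajectory from {traj.basis_tag!r} basis"
                )
        energy = np.sum(traj.xdot**2)
        if energy <= 0:
            raise ValueError("zero-energy derivative: CoD undefined")
        resid = np.sum((self.predict(traj) - traj.xdot) ** 2)
        return float(1 - resid / energy)

    def summary(self) -> str:
        lines = ["Trace-zero linear dynamics",
                 "=" * 40,
                 f"band: {self.band}   basis: {self.source_condition}   "
                 f"samples: {self.nobs}",
                 f"A = [[{self.A[0, 0]: .4g}, {self.A[0, 1]: .4g}],",
                 f"     [{self.A[1, 0]: .4g}, {self.A[1, 1]: .4g}]]  (1/s)",
                 f"det(A) = {self.det:.4g}",
                 f"model frequency = {self.frequency_hz:.3f} Hz",
                 f"CoD(fit) = {self.cod_fit:.4f}"]
        return "\n".join(lines)


def white_noise_null(n_channels: int = 10, duration: float = 600.0,
                     sample_rate: float = 488.0, n_reps: int = 200,
                     seed: int = 0):
    """Null distribution of the dynamics CoD on preprocessed white noise.

    Each replicate runs the complete analysis chain on independent white
    noise: 5 Hz zero-phase low-pass -> within-set mean referencing -> PCA to
    2 components -> trace-zero dynamics fit -> vector CoD. Because
    preprocessing alone creates smooth, orthogonal components, the null
    quantifies how much apparent 'rotational fit' the pipeline can produce
    from structureless input.

    Returns
    -------
    cods : ndarray, shape (n_reps,)
    percentile_95 : float
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates for a percentile")
    rng = np.random.default_rng(seed)
    cods = np.empty(n_reps)
    for r in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rec = simulate_white_noise(n_channels, duration, sample_rate, rep_seed)
        rec = mean_reference(lowpass_delta(rec))
        traj = project(rec, fit_pca(rec, 2, source_condition="white-noise"))
        cods[r] = TraceZeroDynamics(traj).fit().cod_fit
    return cods, float(np.percentile(cods, 95))


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample extremum location by parabolic interpolation."""
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def correlation_frequency(traj: StateTrajectory, max_lag_s: float = 1.0,
                          min_amplitude: float = 0.1) -> float:
    """Oscillation frequency from the PC1-PC2 cross-correlogram.

    The cross-correlation of two components in quadrature is an odd-ish
    oscillation of the same period; the nearest peak and trough flanking
    zero lag are half a period apart, so
    ``f = 1 / (2 |lag_peak - lag_trough|)``. Extremum lags are refined by
    parabolic interpolation. Raises if no flanking extrema exist or their
    amplitude is below ``min_amplitude`` of the normalized correlogram
    (unreliable, e.g. independent noise).
    """
    x1 = traj.x[:, 0] - traj.x[:, 0].mean()
    x2 = traj.x[:, 1] - traj.x[:, 1].mean()
    norm = np.sqrt(np.sum(x1**2) * np.sum(x2**2))
    if norm <= 0:
        raise ValueError("degenerate components")
    cc = _sig.correlate(x1, x2, mode="full") / norm
    lags = _sig.correlation_lags(x1.size, x2.size, mode="full")
    h = int(round(max_lag_s * traj.sample_rate))
    keep = np.abs(lags) <= h
    cc, lags = cc[keep], lags[keep]
    peaks, _ = _sig.find_peaks(cc)
    troughs, _ = _sig.find_peaks(-cc)
    if peaks.size == 0 or troughs.size == 0:
        raise ValueError("no local extrema in the cross-correlogram")
    center = np.searchsorted(lags, 0)
    i_pk = peaks[np.argmin(np.abs(peaks - center))]
    i_tr = troughs[np.argmin(np.abs(troughs - center))]
    if max(abs(cc[i_pk]), abs(cc[i_tr])) < min_amplitude:
        raise ValueError("cross-correlation extrema below amplitude floor; "
                         "frequency estimate unreliable")
    lag_pk = _parabolic_refine(cc, i_pk) - center + lags[center]
    lag_tr = _parabolic_refine(-cc, i_tr) - center + lags[center]
    dt = abs(lag_pk - lag_tr) / traj.sample_rate
    if dt == 0:
        raise ValueError("degenerate peak/trough pair")
    return float(1.0 / (2.0 * dt))
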