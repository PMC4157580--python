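"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Multichannel signals are stored ``channels x time`` in microvolts.
* Trajectories (principal-component projections) are ``time x d``.
* All angles are radians wrapped to ``[-pi, pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultichannelRecording",
    "PCBasis",
    "StateTrajectory",
    "KinematicsTrace",
    "SubmovementEvent",
    "KComplexEvent",
    "SpikeTrain",
    "EMGTraces",
    "ArealVelocitySeries",
    "EventTrajectoryAverage",
    "wrap_angle",
]


def wrap_angle(theta):
    """Wrap angles (radians) to ``[-pi, pi)``."""
    return np.mod(np.asarray(theta, dtype=float) + np.pi, 2 * np.pi) - np.pi


@dataclass
class MultichannelRecording:
    """Uniformly sampled multichannel signal block.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sample_rate : float
        Sampling rate in Hz.
    channel_area : list of str
        Cortical area label per channel (e.g. ``"M1"``, ``"PMv"``).
    reference : str
        Referencing tag: ``"surface"`` (as recorded) or ``"area-mean"``.
    """

    samples: np.ndarray
    sample_rate: float
    channel_area: list[str] = field(default_factory=list)
    reference: str = "surface"

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains non-finite samples")
        if not self.channel_area:
            self.channel_area = ["M1"] * self.samples.shape[0]
        if len(self.channel_area) != self.samples.shape[0]:
            raise ValueError("channel_area length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def select_area(self, area: str) -> "MultichannelRecording":
        """Return the sub-recording for one cortical area."""
        idx = [i for i, a in enumerate(self.channel_area) if a == area]
        if not idx:
            raise ValueError(f"no channels labelled {area!r}")
        return MultichannelRecording(
            self.samples[idx], self.sample_rate,
            [self.channel_area[i] for i in idx], self.reference,
        )


@dataclass
class PCBasis:
    """Principal-component loadings with orientation metadata.

    ``loadings`` columns are orthonormal; ``channel_mean`` holds the per-channel
    means subtracted before projection so other conditions can be projected onto
    the same axes.
    """

    loadings: np.ndarray  # channels x components
    variance_explained: np.ndarray
    source_condition: str = "task"
    orientation_fixed: bool = False
    channel_mean: np.ndarray | None = None
    band: str = "delta"

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        if self.channel_mean is None:
            self.channel_mean = np.zeros(self.loadings.shape[0])

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class StateTrajectory:
    """Trajectory of LFP principal-component scores and its time derivative."""

    x: np.ndarray       # time x d
    xdot: np.ndarray    # time x d, units per second
    sample_rate: float
    band: str = "delta"
    basis_tag: str = "task"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.xdot = np.asarray(self.xdot, dtype=float)
        if self.x.ndim != 2 or self.x.shape[1] < 2:
            raise ValueError("trajectory must be time x d with d >= 2")
        if self.xdot.shape != self.x.shape:
            raise ValueError("xdot must match x in shape")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def slice_components(self, k: int) -> "StateTrajectory":
        """Keep the first ``k`` components."""
        return StateTrajectory(self.x[:, :k], self.xdot[:, :k],
                               self.sample_rate, self.band, self.basis_tag)


@dataclass
class KinematicsTrace:
    """2D isometric torque and derived radial kinematics (% of screen)."""

    torque_xy: np.ndarray    # time x 2
    radial_position: np.ndarray
    radial_speed: np.ndarray  # %/s, signed (positive = away from center)
    sample_rate: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.radial_position)) / self.sample_rate


@dataclass(frozen=True)
class SubmovementEvent:
    """A discrete peak in radial cursor speed."""

    peak_time: float       # s
    peak_speed: float      # %/s
    direction: float       # radians in [-pi, pi)
    trial_id: int | None = None


@dataclass(frozen=True)
class KComplexEvent:
    """A large positive LFP deflection during sedation/sleep."""

    peak_time: float       # s
    peak_amplitude: float  # uV


@dataclass
class SpikeTrain:
    """Sorted spike times for one unit."""

    spike_times: np.ndarray  # s, strictly increasing
    unit_id: int = 0
    area: str = "M1"

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class EMGTraces:
    """Rectified EMG envelopes, muscles x time."""

    samples: np.ndarray
    sample_rate: float
    muscle_names: list[str] = field(default_factory=list)


@dataclass
class ArealVelocitySeries:
    """Instantaneous areal velocity, always stored as a 3-vector series.

    For 2D trajectories only the z component is nonzero; its sign encodes the
    sense of rotation (anticlockwise positive).
    """

    v: np.ndarray  # time x 3
    sample_rate: float

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.v, axis=1)

    @property
    def signed_z(self) -> np.ndarray:
        return self.v[:, 2]


@dataclass
class EventTrajectoryAverage:
    """Pointwise mean trajectory over aligned event windows."""

    group_label: int
    mean_x: np.ndarray      # window x d
    window_times: np.ndarray  # s relative to anchor
    n_events: int
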