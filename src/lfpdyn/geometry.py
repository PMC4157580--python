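"""Areal velocity and rotation frequency of state-space trajectories.

The areal velocity ``v(t) = 1/2 x(t) x xdot(t)`` (vector cross product) is
the area swept per unit time about the origin. For a circular orbit of
radius r at frequency f, ``|v| = 1/2 r^2 * 2 pi f``, so the instantaneous
rotation frequency can be read off as ``f = |v| / (pi |x|^2)``.

2D trajectories are embedded with a zero third component; their areal
velocity is the signed z component (anticlockwise positive, matching the
PCA orientation convention).
"""

from __future__ import annotations

import numpy as np

from .containers import (
    ArealVelocitySeries,
    EventTrajectoryAverage,
    StateTrajectory,
    SubmovementEvent,
)

__all__ = [
    "areal_velocity",
    "rotation_frequency",
    "bin_events_by_speed",
    "bin_events_by_direction",
    "average_event_trajectories",
    "event_areal_velocity_vector",
]

EVENT_HALF_WINDOW_S = 0.2
N_SPEED_GROUPS = 9
N_DIRECTION_GROUPS = 6


def _embed3(a: np.ndarray) -> np.ndarray:
    if a.shape[1] == 3:
        return a
    out = np.zeros((a.shape[0], 3))
    out[:, :2] = a
    return out


def areal_velocity(traj: StateTrajectory) -> ArealVelocitySeries:
    """Instantaneous areal velocity ``1/2 x x xdot`` as a 3-vector series."""
    if traj.d > 3:
        raise ValueError("areal velocity requires d in {2, 3}")
    v = 0.5 * np.cross(_embed3(traj.x), _embed3(traj.xdot))
    return ArealVelocitySeries(v, traj.sample_rate)


def rotation_frequency(traj: StateTrajectory,
                       radius_tol: float | None = None) -> np.ndarray:
    """Instantaneous rotation frequency ``f(t) = |v| / (pi |x|^2)``, Hz.

    Signed by the sense of rotation (z component of areal velocity for 2D;
    sign of the dominant z term for 3D). Samples where the radius falls
    below ``radius_tol`` (default: 1e-6 of the RMS radius) are masked NaN.
    """
    v = areal_velocity(traj)
    r2 = np.sum(_embed3(traj.x) ** 2, axis=1)
    if radius_tol is None:
        radius_tol = 1e-6 * np.sqrt(np.mean(r2))
    mask = r2 <= radius_tol**2
    sign = np.sign(v.v[:, 2])
    sign[sign == 0] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = sign * v.magnitude / (np.pi * r2)
    f[mask] = np.nan
    return f


def _event_array(events) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    times = np.array([e.peak_time for e in events])
    speeds = np.array([e.peak_speed for e in events])
    dirs = np.array([e.direction for e in events])
    return times, speeds, dirs


def bin_events_by_speed(events: list[SubmovementEvent],
                        n_groups: int = N_SPEED_GROUPS) -> np.ndarray:
    """Assign events to ``n_groups`` equal-count groups of increasing speed.

    Returns a group index (0-based) per event, in the original event order.
    Ties across a boundary are broken by event time (earlier -> lower
    group); when the count does not divide evenly, the lower groups take
    the extra events.
    """
    if len(events) < n_groups:
        raise ValueError("fewer events than groups")
    times, speeds, _ = _event_array(events)
    order = np.lexsort((times, speeds))  # speed asc, then time asc
    groups = np.empty(len(events), dtype=int)
    for g, chunk in enumerate(np.array_split(order, n_groups)):
        groups[chunk] = g
    return groups


def bin_events_by_direction(events: list[SubmovementEvent],
                            n_groups: int = N_DIRECTION_GROUPS) -> np.ndarray:
    """Assign events to equal-width direction bins; the first bin is
    centered at 0 rad."""
    _, _, dirs = _event_array(events)
    width = 2 * np.pi / n_groups
    return (np.floor_divide(np.mod(dirs + width / 2, 2 * np.pi), width)
            .astype(int))


def _window_indices(traj: StateTrajectory, half_window: float):
    h = int(round(half_window * traj.sample_rate))
    rel = np.arange(-h, h + 1)
    return h, rel


def average_event_trajectories(traj: StateTrajectory,
                               events: list[SubmovementEvent],
                               groups: np.ndarray | None = None,
                               half_window: float = EVENT_HALF_WINDOW_S
                               ) -> list[EventTrajectoryAverage]:
    """Pointwise mean trajectory per group over aligned event windows.

    Events whose window extends past the recording edge are skipped (and
    counted against ``n_events``); a group with no usable events errors.
    """
    if groups is None:
        groups = np.zeros(len(events), dtype=int)
    groups = np.asarray(groups)
    h, rel = _window_indices(traj, half_window)
    out = []
    for g in np.unique(groups):
        windows = []
        for e, gi in zip(events, groups):
            if gi != g:
                continue
            c = int(round(e.peak_time * traj.sample_rate))
            if c - h < 0 or c + h >= traj.n_samples:
                continue
            windows.append(traj.x[c + rel])
        if not windows:
            raise ValueError(f"group {g} has no events with full windows")
        out.append(EventTrajectoryAverage(
            group_label=int(g),
            mean_x=np.mean(windows, axis=0),
            window_times=rel / traj.sample_rate,
            n_events=len(windows),
        ))
    return out


def event_areal_velocity_vector(traj: StateTrajectory,
                                event: SubmovementEvent,
                                half_window: float = EVENT_HALF_WINDOW_S
                                ) -> np.ndarray:
    """Time-averaged 3D areal-velocity vector over the +-200 ms event window.

    This is the per-event feature the kinematic decoder consumes: its
    magnitude tracks submovement speed and its orientation the tilt of the
    rotation axis.
    """
    h, rel = _window_indices(traj, half_window)
    c = int(round(event.peak_time * traj.sample_rate))
    if c - h < 0 or c + h >= traj.n_samples:
        raise ValueError("event window extends past the recording edge")
    x = _embed3(traj.x[c + rel])
    xdot = _embed3(traj.xdot[c + rel])
    return np.mean(0.5 * np.cross(x, xdot), axis=0)
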