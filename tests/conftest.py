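"""Shared fixtures: one synthetic task/sedation session pair at default
generator settings, preprocessed once per test run."""

import numpy as np
import pytest

import lfpdyn
from lfpdyn import (
    SimulationConfig,
    TraceZeroDynamics,
    detect_submovements,
    fit_pca,
    lowpass_delta,
    mean_reference,
    project,
    simulate_sedation_session,
    simulate_task_session,
)
from lfpdyn.geometry import event_areal_velocity_vector

SESSION_SEED = 11


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def task_session(default_config):
    """(rec, kin, trains, emg, gt) at default generator settings."""
    return simulate_task_session(default_config)


@pytest.fixture(scope="session")
def sedation_session(default_config):
    """Paired sedation session sharing the task session's channel phases."""
    return simulate_sedation_session(default_config)


@pytest.fixture(scope="session")
def task_products(task_session):
    """Preprocessed task outputs: dict with delta recording, bases,
    trajectories, detected events, and per-event areal-velocity vectors."""
    rec, kin, trains, emg, gt = task_session
    m1 = rec.select_area("M1")
    delta = mean_reference(lowpass_delta(m1))
    basis3 = fit_pca(delta, 3, source_condition="task")
    traj3 = project(delta, basis3)
    traj2 = traj3.slice_components(2)
    events = detect_submovements(kin)
    usable = [e for e in events
              if 0.21 <= e.peak_time <= rec.duration - 0.21]
    v = np.array([event_areal_velocity_vector(traj3, e) for e in usable])
    return {
        "rec": rec, "kin": kin, "trains": trains, "gt": gt,
        "delta": delta, "basis3": basis3, "traj3": traj3, "traj2": traj2,
        "events": events, "usable": usable, "v": v,
        "speeds": np.array([e.peak_speed for e in usable]),
        "directions": np.array([e.direction for e in usable]),
    }


@pytest.fixture(scope="session")
def dynamics_fit(task_products):
    return TraceZeroDynamics(task_products["traj2"]).fit()


@pytest.fixture(scope="session")
def sedation_products(sedation_session, task_products):
    """Sedation recording projected onto the task-derived PC basis."""
    rec, trains, gt = sedation_session
    delta = mean_reference(lowpass_delta(rec.select_area("M1")))
    traj2 = project(delta, task_products["basis3"]).slice_components(2)
    kcs = lfpdyn.detect_k_complexes(rec)
    return {"rec": rec, "trains": trains, "gt": gt, "delta": delta,
            "traj2": traj2, "kcomplexes": kcs}


def circle_trajectory(freq=3.0, radius=1.0, sample_rate=488.0,
                      duration=10.0, d=2, phase0=0.0):
    """Analytic circular orbit with exact derivative (test helper)."""
    t = np.arange(int(duration * sample_rate)) / sample_rate
    w = 2 * np.pi * freq
    x = np.zeros((t.size, d))
    xdot = np.zeros((t.size, d))
    x[:, 0] = radius * np.cos(w * t + phase0)
    x[:, 1] = radius * np.sin(w * t + phase0)
    xdot[:, 0] = -radius * w * np.sin(w * t + phase0)
    xdot[:, 1] = radius * w * np.cos(w * t + phase0)
    return lfpdyn.StateTrajectory(x, xdot, sample_rate)
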