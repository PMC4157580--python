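"""End-to-end orchestration: simulate -> preprocess -> detect -> geometry ->
decode -> dynamics -> phase, with a machine-readable run report.

The pipeline is driven by a YAML/dict config; every stage contributes a
numeric summary (or a skip reason) to the :class:`RunReport`, and all
randomness derives from the single configured seed, so a config fully
determines the report.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import decoder as _decoder
from . import dynamics as _dynamics
from . import events as _events
from . import geometry as _geometry
from . import phase as _phase
from . import preprocess as _prep
from .session_io import SessionContainer, config_hash, events_to_csv, write_session
from .simulate import SimulationConfig, simulate_sedation_session, simulate_task_session

__all__ = ["RunReport", "run_pipeline", "default_config", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "preprocess", "detect", "geometry",
                  "decode", "dynamics", "phase")

_KNOWN_KEYS = {"simulation", "stages", "seed", "sedation", "output_dir",
               "n_shuffles", "null", "n_pca_components"}


@dataclass
class RunReport:
    """Per-stage numeric summaries, timings, and warnings."""

    summaries: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add(self, stage: str, summary: dict, elapsed: float):
        self.summaries[stage] = summary
        self.timings_s[stage] = round(elapsed, 3)

    def skip(self, stage: str, reason: str):
        self.summaries[stage] = {"skipped": reason}

    def to_dict(self) -> dict:
        return {"summaries": _jsonable(self.summaries),
                "timings_s": self.timings_s,
                "warnings": self.warnings}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def default_config() -> dict:
    """Desk-scale demo configuration exercising every stage."""
    return {
        "seed": 0,
        "simulation": {"duration": 120.0},
        "stages": list(DEFAULT_STAGES),
        "sedation": True,
        "n_shuffles": 200,
        "null": {"n_reps": 50, "duration": 120.0, "n_channels": 10},
    }


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as f:
            cfg = yaml.safe_load(f)
    else:
        cfg = dict(config)
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"invalid config keys: {sorted(unknown)}")
    sim_keys = set(cfg.get("simulation", {}) or {})
    valid_sim = set(SimulationConfig.__dataclass_fields__)
    bad = sim_keys - valid_sim
    if bad:
        raise ValueError(f"invalid simulation keys: {sorted(bad)}")
    return cfg


def run_pipeline(config, out_dir=None) -> RunReport:
    """Run the configured stages end to end.

    Parameters
    ----------
    config : path or dict
        YAML config path or equivalent mapping. Keys: ``seed``,
        ``simulation`` (SimulationConfig overrides), ``stages``,
        ``sedation`` (bool: also simulate/analyse a paired sedation
        session), ``n_shuffles``, ``null`` (white-noise null parameters or
        None to skip).
    out_dir : path, optional
        Where to write session containers, event tables, and report.json.

    Returns
    -------
    RunReport
    """
    cfg = _load_config(config)
    stages = tuple(cfg.get("stages", DEFAULT_STAGES))
    seed = int(cfg.get("seed", 0))
    sim_cfg = SimulationConfig(seed=seed, **(cfg.get("simulation") or {}))
    report = RunReport()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    rec, kin, trains, emg, gt = simulate_task_session(sim_cfg)
    sed = None
    if cfg.get("sedation", False):
        sed = simulate_sedation_session(sim_cfg)
    if "simulate" in stages:
        report.add("simulate", {
            "n_channels": rec.n_channels,
            "duration_s": rec.duration,
            "n_true_submovements": int(gt.true_submovements.size),
            "n_true_kcomplexes": int(sed[2].true_kcomplexes.size) if sed else 0,
        }, time.perf_counter() - t0)
        if out is not None:
            write_session(out / "task_session.h5", SessionContainer(
                lfp=rec, condition="task", kinematics=kin, emg=emg,
                spikes=trains, seed=seed, config_hash=config_hash(sim_cfg)))

    # --- preprocess -----------------------------------------------------
    t0 = time.perf_counter()
    m1 = rec.select_area("M1")
    delta = _prep.mean_reference(_prep.lowpass_delta(m1))
    basis3 = _prep.fit_pca(delta, 3, source_condition="task")
    traj3 = _prep.project(delta, basis3)
    traj2 = traj3.slice_components(2)
    if "preprocess" in stages:
        report.add("preprocess", {
            "variance_explained": basis3.variance_explained,
            "n_components": basis3.n_components,
        }, time.perf_counter() - t0)

    # --- detect ---------------------------------------------------------
    t0 = time.perf_counter()
    kin = _events.compute_radial_speed(kin.torque_xy, kin.sample_rate)
    submovements = _events.detect_submovements(kin)
    kcomplexes = []
    if sed is not None:
        kcomplexes = _events.detect_k_complexes(sed[0])
    if "detect" in stages:
        summary = {"n_submovements": len(submovements),
                   "n_kcomplexes": len(kcomplexes)}
        if len(submovements) >= 2:
            intervals = np.diff([e.peak_time for e in submovements])
            counts, edges = np.histogram(intervals,
                                         bins=np.arange(0, 1.05, 0.05))
            summary["interval_mode_s"] = float(
                0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]))
        report.add("detect", summary, time.perf_counter() - t0)
        if out is not None:
            events_to_csv(out / "submovements.csv", submovements)
            if kcomplexes:
                events_to_csv(out / "kcomplexes.csv", kcomplexes, "kcomplex")

    # --- geometry -------------------------------------------------------
    usable = [e for e in submovements
              if 0.2 <= e.peak_time <= rec.duration - 0.21]
    n_excluded = len(submovements) - len(usable)
    if n_excluded:
        report.warnings.append(
            f"{n_excluded} submovements dropped (window clipped)")
    t0 = time.perf_counter()
    if "geometry" in stages:
        if len(usable) < _geometry.N_SPEED_GROUPS:
            report.skip("geometry", "too few submovements for speed groups")
        else:
            groups = _geometry.bin_events_by_speed(usable)
            group_v = []
            for g in range(_geometry.N_SPEED_GROUPS):
                vs = [np.linalg.norm(
                    _geometry.event_areal_velocity_vector(traj3, e))
                    for e, gi in zip(usable, groups) if gi == g]
                group_v.append(float(np.mean(vs)))
            freq = _geometry.rotation_frequency(traj2)
            report.add("geometry", {
                "group_mean_areal_velocity": group_v,
                "monotone_with_speed": bool(np.all(np.diff(group_v) > 0)),
                "median_rotation_frequency_hz": float(
                    np.nanmedian(np.abs(freq))),
            }, time.perf_counter() - t0)

    # --- decode ---------------------------------------------------------
    t0 = time.perf_counter()
    if "decode" in stages:
        if len(usable) < 16:
            report.skip("decode", "need >= 16 submovements")
        else:
            v = np.array([_geometry.event_areal_velocity_vector(traj3, e)
                          for e in usable])
            s = np.array([e.peak_speed for e in usable])
            th = np.array([e.direction for e in usable])
            model = _decoder.ArealVelocityDecoder(v, s, th)
            loo = model.fit_loo()
            n_shuffles = int(cfg.get("n_shuffles", 200))
            thr = model.shuffle_significance(n_shuffles, seed=seed + 1)
            loo.shuffle_threshold_speed = thr["shuffle_threshold_speed"]
            loo.shuffle_threshold_direction = thr["shuffle_threshold_direction"]
            report.add("decode", {
                "cod_speed": loo.cod_speed,
                "cod_direction": loo.cod_direction,
                "mean_abs_angular_error_deg":
                    loo.mean_absolute_angular_error_deg,
                "shuffle_threshold_speed": loo.shuffle_threshold_speed,
                "shuffle_threshold_direction": loo.shuffle_threshold_direction,
                "n_events": loo.n_events,
                "n_undecoded": loo.n_undecoded,
            }, time.perf_counter() - t0)
            if out is not None:
                loo.to_frame().to_csv(out / "decoding.csv", index=False)

    # --- dynamics -------------------------------------------------------
    t0 = time.perf_counter()
    fit = _dynamics.TraceZeroDynamics(traj2).fit()
    if "dynamics" in stages:
        summary = {
            "cod_fit": fit.cod_fit,
            "model_frequency_hz": fit.frequency_hz,
            "correlation_frequency_hz": _dynamics.correlation_frequency(traj2),
        }
        if sed is not None:
            sed_delta = _prep.mean_reference(
                _prep.lowpass_delta(sed[0].select_area("M1")))
            sed_traj = _prep.project(sed_delta, basis3).slice_components(2)
            summary["cod_generalize_sedation"] = fit.score(sed_traj)
        null_cfg = cfg.get("null")
        if null_cfg:
            _, p95 = _dynamics.white_noise_null(
                n_channels=int(null_cfg.get("n_channels", 10)),
                duration=float(null_cfg.get("duration", 600.0)),
                sample_rate=sim_cfg.sample_rate,
                n_reps=int(null_cfg.get("n_reps", 200)),
                seed=seed + 2)
            summary["white_noise_null_p95"] = p95
        report.add("dynamics", summary, time.perf_counter() - t0)

    # --- phase ----------------------------------------------------------
    t0 = time.perf_counter()
    if "phase" in stages:
        sm_times = np.array([e.peak_time for e in usable])
        rotated, angle = _phase.rotate_plane_to_speed_phase(traj2, sm_times)
        prefs, pvals = [], []
        for tr in trains:
            try:
                mu, _, p = _phase.preferred_phase_and_rayleigh(tr, rotated)
            except ValueError:
                continue
            prefs.append(mu)
            pvals.append(p)
        summary = {
            "plane_rotation_rad": angle,
            "n_units_phase_locked_p05": int(np.sum(np.array(pvals) < 0.05)),
            "n_units_tested": len(prefs),
            "mean_preferred_phase_rad": (
                float(np.angle(np.mean(np.exp(1j * np.array(prefs)))))
                if prefs else None),
        }
        if sed is not None and kcomplexes:
            phi_sm, phi_kc = [], []
            kc_times = np.array([e.peak_time for e in kcomplexes])
            sed_delta_rec = _prep.mean_reference(
                _prep.lowpass_delta(sed[0].select_area("M1")))
            for ch in range(delta.n_channels):
                eta_sm, _ = _phase.event_triggered_average(
                    delta.samples[ch], sm_times, rec.sample_rate)
                eta_kc, _ = _phase.event_triggered_average(
                    sed_delta_rec.samples[ch], kc_times, rec.sample_rate)
                phi_sm.append(_phase.event_relative_phase(eta_sm))
                phi_kc.append(_phase.event_relative_phase(eta_kc))
            rho, p = _phase.circular_circular_correlation(phi_sm, phi_kc)
            summary["sm_kc_phase_rho_cc"] = rho
            summary["sm_kc_phase_p"] = p
        report.add("phase", summary, time.perf_counter() - t0)

    if out is not None:
        with open(out / "report.json", "w") as f:
            json.dump(report.to_dict(), f, indent=2)
    return report
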