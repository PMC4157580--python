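"""Session container serialization (HDF5) and delimited-text exports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .containers import (
    EMGTraces,
    KinematicsTrace,
    MultichannelRecording,
    SpikeTrain,
)

__all__ = [
    "SessionContainer",
    "write_session",
    "read_session",
    "read_nwb_like",
    "events_to_csv",
]

FORMAT_VERSION = 1
CONDITIONS = ("task", "reach", "sleep", "sedation")


@dataclass
class SessionContainer:
    """Time-aligned arrays of one recording session plus provenance."""

    lfp: MultichannelRecording
    condition: str
    kinematics: KinematicsTrace | None = None
    emg: EMGTraces | None = None
    spikes: list[SpikeTrain] = field(default_factory=list)
    seed: int | None = None
    config_hash: str | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


def config_hash(config) -> str:
    """Stable hash of a simulation config (provenance tag)."""
    d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in vars(config).items()}
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def write_session(path, session: SessionContainer) -> None:
    from . import __version__

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["software_version"] = __version__
        f.attrs["condition"] = session.condition
        if session.seed is not None:
            f.attrs["seed"] = session.seed
        if session.config_hash is not None:
            f.attrs["config_hash"] = session.config_hash
        g = f.create_group("lfp")
        g.create_dataset("samples", data=session.lfp.samples)
        g.attrs["sample_rate"] = session.lfp.sample_rate
        g.attrs["reference"] = session.lfp.reference
        g.create_dataset("channel_area",
                         data=np.array(session.lfp.channel_area, dtype="S"))
        if session.kinematics is not None:
            g = f.create_group("torque")
            g.create_dataset("xy", data=session.kinematics.torque_xy)
            g.attrs["sample_rate"] = session.kinematics.sample_rate
        if session.emg is not None:
            g = f.create_group("emg")
            g.create_dataset("samples", data=session.emg.samples)
            g.attrs["sample_rate"] = session.emg.sample_rate
            g.create_dataset("muscles",
                             data=np.array(session.emg.muscle_names, dtype="S"))
        if session.spikes:
            g = f.create_group("spikes")
            for tr in session.spikes:
                ds = g.create_dataset(f"unit_{tr.unit_id:03d}",
                                      data=tr.spike_times)
                ds.attrs["unit_id"] = tr.unit_id
                ds.attrs["area"] = tr.area


def read_session(path) -> SessionContainer:
    from .events import compute_radial_speed

    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"container format version {version} not supported "
                f"(expected {FORMAT_VERSION}); migrate the file first"
            )
        if "lfp" not in f:
            raise ValueError("schema error: required array 'lfp' missing")
        g = f["lfp"]
        lfp = MultichannelRecording(
            g["samples"][()], float(g.attrs["sample_rate"]),
            [a.decode() for a in g["channel_area"][()]],
            str(g.attrs["reference"]),
        )
        kin = None
        if "torque" in f:
            kin = compute_radial_speed(f["torque/xy"][()],
                                       float(f["torque"].attrs["sample_rate"]))
        emg = None
        if "emg" in f:
            emg = EMGTraces(f["emg/samples"][()],
                            float(f["emg"].attrs["sample_rate"]),
                            [m.decode() for m in f["emg/muscles"][()]])
        spikes = []
        if "spikes" in f:
            for name in sorted(f["spikes"]):
                ds = f["spikes"][name]
                spikes.append(SpikeTrain(ds[()], int(ds.attrs["unit_id"]),
                                         str(ds.attrs["area"])))
        return SessionContainer(
            lfp=lfp, condition=str(f.attrs["condition"]), kinematics=kin,
            emg=emg, spikes=spikes,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            config_hash=(str(f.attrs["config_hash"])
                         if "config_hash" in f.attrs else None),
        )


def read_nwb_like(path, series_name: str = "ElectricalSeries",
                  condition: str = "task") -> SessionContainer:
    """Map an NWB-style HDF5 layout into a SessionContainer.

    Minimal reader for files laid out as ``acquisition/<series>/data``
    (time x channels) with a ``starting_time`` dataset carrying a ``rate``
    attribute, as produced by NWB writers. Not a full NWB implementation:
    only the raw electrical series is read, and channels default to a
    single area.
    """
    with h5py.File(path, "r") as f:
        if "acquisition" not in f or series_name not in f["acquisition"]:
            raise ValueError(f"no acquisition/{series_name} in {path}")
        g = f["acquisition"][series_name]
        data = g["data"][()]
        rate = float(g["starting_time"].attrs["rate"])
    lfp = MultichannelRecording(np.asarray(data).T, rate)
    return SessionContainer(lfp=lfp, condition=condition)


def events_to_csv(path, events, kind: str = "submovement") -> pd.DataFrame:
    """Write detected events as a delimited table; returns the frame."""
    if kind == "submovement":
        df = pd.DataFrame({
            "peak_time": [e.peak_time for e in events],
            "peak_speed": [e.peak_speed for e in events],
            "direction": [e.direction for e in events],
            "trial_id": [e.trial_id for e in events],
        })
    elif kind == "kcomplex":
        df = pd.DataFrame({
            "peak_time": [e.peak_time for e in events],
            "peak_amplitude": [e.peak_amplitude for e in events],
        })
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    df.to_csv(path, index=False)
    return df
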