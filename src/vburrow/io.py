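"""Session persistence and configuration.

Sessions are stored in a single HDF5 container: the four sampled channels
under ``/channels`` (with unit attributes), controller events and the
ground-truth log (when simulated) as structured datasets, and mandatory
metadata (schema version, sample rate, seed) as root attributes.  Round
trips are bitwise lossless.  Trial tables are RFC-4180 CSV with stable
headers; spike times read from one-float-per-line text files; configs from
JSON or YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .controller import ControllerConfig, ControllerEvent
from .core import SessionTrace, SpikeData
from .mouse import GroundTruthEvent, GroundTruthLog, MouseParams, StimulusResponse

__all__ = [
    "SCHEMA_VERSION",
    "write_session",
    "read_session",
    "write_trial_table",
    "read_trial_table",
    "read_spike_times",
    "load_config",
    "mouse_params_from_dict",
    "controller_config_from_dict",
]

SCHEMA_VERSION = 1

_UNITS = {"position": "mm", "force": "mN", "actuator": "mm", "stimulus": "id"}


def write_session(path, trace: SessionTrace,
                  ground_truth: GroundTruthLog | None = None,
                  events: list[ControllerEvent] | None = None) -> None:
    """Write a session container (schema v1)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sample_rate"] = trace.sample_rate
        for key, val in trace.metadata.items():
            f.attrs[f"meta_{key}"] = val
        ch = f.create_group("channels")
        for name in ("position", "force", "actuator", "stimulus"):
            d = ch.create_dataset(name, data=getattr(trace, name))
            d.attrs["unit"] = _UNITS[name]
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            if ground_truth.seed is not None:
                g.attrs["seed"] = ground_truth.seed
            ev = ground_truth.events
            g.create_dataset("trial_index",
                             data=np.array([e.trial_index for e in ev], dtype=np.int64))
            g.create_dataset("stimulus_id",
                             data=np.array([e.stimulus_id for e in ev], dtype=np.int64))
            g.create_dataset("onset_time",
                             data=np.array([e.onset_time for e in ev]))
            g.create_dataset("kind", data=np.array(
                [e.kind.encode() for e in ev], dtype="S16"))
            g.create_dataset("latency", data=np.array([e.latency for e in ev]))
            g.create_dataset("peak_displacement",
                             data=np.array([e.peak_displacement for e in ev]))
        if events is not None:
            g = f.create_group("controller_events")
            g.create_dataset("name", data=np.array(
                [e.name.encode() for e in events], dtype="S24"))
            g.create_dataset("time", data=np.array([e.time for e in events]))
            g.create_dataset("info", data=np.array(
                [json.dumps(e.info).encode() for e in events], dtype="S256"))


def read_session(path) -> tuple[SessionTrace, GroundTruthLog | None,
                                list[ControllerEvent] | None]:
    """Read a session container; rejects unknown schema versions."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported session schema version {version} "
                f"(this reader supports {SCHEMA_VERSION})")
        if "channels" not in f or "sample_rate" not in f.attrs:
            raise ValueError("corrupt session file: missing channels/metadata")
        meta = {k[5:]: _to_py(v) for k, v in f.attrs.items()
                if k.startswith("meta_")}
        ch = f["channels"]
        trace = SessionTrace(
            sample_rate=float(f.attrs["sample_rate"]),
            position=ch["position"][:],
            force=ch["force"][:],
            actuator=ch["actuator"][:],
            stimulus=ch["stimulus"][:],
            metadata=meta,
        )
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = GroundTruthLog(seed=_to_py(g.attrs.get("seed")))
            for i in range(len(g["trial_index"])):
                gt.events.append(GroundTruthEvent(
                    trial_index=int(g["trial_index"][i]),
                    stimulus_id=int(g["stimulus_id"][i]),
                    onset_time=float(g["onset_time"][i]),
                    kind=g["kind"][i].decode(),
                    latency=float(g["latency"][i]),
                    peak_displacement=float(g["peak_displacement"][i]),
                ))
        events = None
        if "controller_events" in f:
            g = f["controller_events"]
            events = [ControllerEvent(
                name=g["name"][i].decode(),
                time=float(g["time"][i]),
                info=json.loads(g["info"][i].decode()),
            ) for i in range(len(g["name"]))]
    return trace, gt, events


def _to_py(v):
    if v is None:
        return None
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


def write_trial_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_spike_times(paths) -> SpikeData:
    """Spike times from one-timestamp-per-line text files (one per unit)."""
    units = []
    for p in paths:
        txt = Path(p).read_text().split()
        units.append(np.array([float(x) for x in txt]))
    return SpikeData(units=units)


def load_config(path) -> dict:
    """Load a JSON or YAML configuration file by extension."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def mouse_params_from_dict(d: dict) -> MouseParams:
    d = dict(d)
    responses = {}
    for key, r in (d.pop("responses", None) or {}).items():
        responses[int(key)] = StimulusResponse(**r)
    default = d.pop("default_response", None)
    kwargs = dict(d)
    if responses:
        kwargs["responses"] = responses
    if default is not None:
        kwargs["default_response"] = StimulusResponse(**default)
    return MouseParams(**kwargs)


def controller_config_from_dict(d: dict) -> ControllerConfig:
    return ControllerConfig(**d)


def mouse_params_to_dict(p: MouseParams) -> dict:
    d = asdict(p)
    d["responses"] = {str(k): asdict(v) for k, v in p.responses.items()}
    d["default_response"] = asdict(p.default_response)
    return d
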