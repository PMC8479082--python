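"""Delimited-text I/O for events, traces, and trajectories.

No domain standard exists for CTC counter data, so everything is plain text:
event tables and trajectories as CSV, traces as a single column of voltages
with a JSON metadata sidecar (sampling rate, start time, units), and run
metadata as YAML.  Round trips are lossless at the written precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ExchangeParams
from .pmt import PMTTrace
from .simulate import EventLog, InjectionParams

__all__ = [
    "write_events",
    "read_events",
    "write_trace",
    "read_trace",
    "write_trajectory",
    "read_trajectory",
    "params_to_dict",
    "params_from_dict",
]


def params_to_dict(params) -> dict:
    """Serialize a params dataclass to a plain dict with its type tag."""
    d = dataclasses.asdict(params)
    d["__type__"] = type(params).__name__
    return d


def params_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("__type__", "ExchangeParams")
    cls = {"ExchangeParams": ExchangeParams, "InjectionParams": InjectionParams}[kind]
    return cls(**d)


def write_events(log: EventLog, path: str | Path) -> None:
    """Write an event table as CSV plus a ``.meta.yaml`` sidecar."""
    path = Path(path)
    log.events.to_csv(path, index=False, float_format="%.6f")
    meta: dict = {"seed": log.seed}
    params = log.truth.get("params")
    if params is not None:
        meta["params"] = params_to_dict(params)
    for key in (
        "n_generated",
        "n_cleared",
        "n_pool1_end",
        "n_pool2_end",
        "n_in_transit_end",
        "n_injected",
    ):
        if key in log.truth:
            meta[key] = int(log.truth[key])
    path.with_suffix(path.suffix + ".meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=True)
    )


def read_events(path: str | Path) -> EventLog:
    """Read an event table, enforcing the per-counter time ordering."""
    path = Path(path)
    events = pd.read_csv(path)
    required = {"time_min", "counter_id"}
    if not required.issubset(events.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if events["time_min"].isna().any() or events["counter_id"].isna().any():
        bad = int(events.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}: malformed row at line {bad}")
    for c, grp in events.groupby("counter_id"):
        d = np.diff(grp["time_min"].to_numpy())
        if np.any(d < 0):
            row = grp.index[int(np.argmax(d < 0)) + 1] + 2
            raise ValueError(
                f"{path}: out-of-order event time for counter {c} at line {row}"
            )
    truth: dict = {}
    seed = None
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}
        seed = meta.pop("seed", None)
        if "params" in meta:
            meta["params"] = params_from_dict(meta["params"])
        truth = meta
    return EventLog(events=events, seed=seed, truth=truth)


def write_trace(trace: PMTTrace, path: str | Path) -> None:
    """Write a trace as one voltage per line plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, trace.samples, fmt="%.9g")
    sidecar = {"fs": trace.fs, "t0": trace.t0, "units": "V"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_trace(path: str | Path) -> PMTTrace:
    path = Path(path)
    samples = np.loadtxt(path, ndmin=1)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = {"fs": 30_000.0, "t0": 0.0}
    if sidecar_path.exists():
        meta.update(json.loads(sidecar_path.read_text()))
    return PMTTrace(samples=samples, fs=float(meta["fs"]), t0=float(meta["t0"]))


def write_trajectory(traj: pd.DataFrame, path: str | Path) -> None:
    traj.to_csv(path, index=False)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    traj = pd.read_csv(path)
    if "time_min" not in traj.columns:
        raise ValueError(f"{path}: trajectory file must have a time_min column")
    return traj
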