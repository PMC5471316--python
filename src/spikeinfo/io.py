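"""Text-first file formats for traces, spike trains, populations and reports.

Traces and spike trains are single-column text with ``# key = value``
header lines; floats are printed with 17 significant digits so a
write/read round trip is bit-exact.  Long traces can optionally be stored
in a compact binary container (.npz) with identical semantics.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decoding import InfoReport
from .population import CurrentTrace, PresynapticPopulation, SpikeTrain

__all__ = [
    "read_trace",
    "write_trace",
    "read_spike_train",
    "write_spike_train",
    "write_population",
    "read_population",
    "write_reports",
    "load_config",
    "save_config",
    "config_hash",
]

_FLOAT_FMT = "%.17g"


def _write_header(fh, kind: str, meta: dict) -> None:
    fh.write(f"# spikeinfo {kind} v1\n")
    for key, value in meta.items():
        if isinstance(value, float):
            value = _FLOAT_FMT % value
        elif isinstance(value, (dict, list, tuple)):
            value = json.dumps(value)
        fh.write(f"# {key} = {value}\n")


def _read_header(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta, n_header


def write_trace(trace: CurrentTrace, path) -> None:
    """Serialize a sampled trace; format chosen by suffix (.npz = binary)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            values=trace.values,
            dt=trace.dt,
            units=trace.units,
            offset_theta=trace.offset_theta,
            meta=json.dumps(trace.meta),
        )
        return
    with open(path, "w") as fh:
        _write_header(
            fh,
            "trace",
            {
                "dt": trace.dt,
                "units": trace.units,
                "offset_theta": trace.offset_theta,
                "meta": trace.meta,
            },
        )
        np.savetxt(fh, trace.values, fmt=_FLOAT_FMT)


def read_trace(path) -> CurrentTrace:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return CurrentTrace(
                z["values"],
                float(z["dt"]),
                str(z["units"]),
                float(z["offset_theta"]),
                json.loads(str(z["meta"])),
            )
    meta, n_header = _read_header(path)
    values = np.loadtxt(path, skiprows=n_header, ndmin=1)
    return CurrentTrace(
        values,
        float(meta["dt"]),
        meta.get("units", "dimensionless"),
        float(meta.get("offset_theta", 0.0)),
        json.loads(meta["meta"]) if "meta" in meta else {},
    )


def write_spike_train(train: SpikeTrain, path, dt: float | None = None) -> None:
    """Spike times in seconds, one per line, with a window header."""
    path = Path(path)
    meta = {"window": [train.window[0], train.window[1]]}
    if dt is not None:
        meta["dt"] = dt
    with open(path, "w") as fh:
        _write_header(fh, "spikes", meta)
        np.savetxt(fh, train.times, fmt=_FLOAT_FMT)


def read_spike_train(path) -> SpikeTrain:
    """Read a spike-time file, reporting offending line numbers on error."""
    path = Path(path)
    meta, n_header = _read_header(path)
    if "window" not in meta:
        raise ValueError(f"{path}: missing '# window = [t0, t1]' header")
    t0, t1 = json.loads(meta["window"])
    times = np.loadtxt(path, skiprows=n_header, ndmin=1)
    for j, t in enumerate(times):
        line = n_header + 1 + j
        if t < t0:
            raise ValueError(f"{path}:{line}: spike time {t} before window start {t0}")
        if t >= t1:
            raise ValueError(f"{path}:{line}: spike time {t} at/after window end {t1}")
        if j and t <= times[j - 1]:
            raise ValueError(f"{path}:{line}: spike times not strictly increasing")
    return SpikeTrain(times, (float(t0), float(t1)))


def write_population(pop: PresynapticPopulation, path) -> None:
    """Population audit table: per-neuron rates and weights as CSV with a
    commented metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(
            fh,
            "population",
            {"N": pop.N, "mu_q": pop.mu_q, "sigma_q": pop.sigma_q, "theta": pop.theta},
        )
        pd.DataFrame({"q_on": pop.q_on, "q_off": pop.q_off, "w": pop.w}).to_csv(
            fh, index=False, float_format=_FLOAT_FMT
        )


def read_population(path) -> PresynapticPopulation:
    meta, n_header = _read_header(Path(path))
    df = pd.read_csv(path, comment="#")
    return PresynapticPopulation(
        df.q_on.to_numpy(),
        df.q_off.to_numpy(),
        df.w.to_numpy(),
        float(meta["mu_q"]),
        float(meta["sigma_q"]),
        float(meta["theta"]),
    )


def write_reports(reports, path, extra: dict | None = None) -> None:
    """Flat key-value table, one row per analysis window, as CSV."""
    if isinstance(reports, pd.DataFrame):
        df = reports.copy()
    else:
        df = pd.DataFrame([r.as_dict() for r in reports])
    if extra:
        for key, value in extra.items():
            df[key] = value
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash identifying an effective configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
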