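"""Trace and result serialization.

Traces round-trip through plain CSV (time, V_m, [Ca]_sub, plus any
requested state/current columns) with a JSON sidecar carrying metadata,
or through a compressed binary container holding every state variable.
``write_outputs`` serializes a mixed bag of results and returns a manifest
with a content hash per artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import _indices as ix
from .model import Trace

__all__ = ["save_trace_csv", "load_trace_csv", "save_trace_npz",
           "load_trace_npz", "write_outputs"]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def save_trace_csv(trace: Trace, path, extra_signals=()) -> Path:
    """Write t_ms, V_m_mV, Ca_sub_mM (+ extra signal columns) and a JSON
    metadata sidecar next to the CSV."""
    path = Path(path)
    cols = {"t_ms": trace.t, "V_m_mV": trace.V_m, "Ca_sub_mM": trace.Ca_sub}
    for name in extra_signals:
        cols[name] = trace.signal(name)
    pd.DataFrame(cols).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(_jsonable(trace.meta), indent=1))
    return path


def load_trace_csv(path) -> Trace:
    """Rebuild a (reduced) Trace from CSV + sidecar; only the stored
    columns are populated."""
    path = Path(path)
    df = pd.read_csv(path)
    n = len(df)
    states = np.zeros((n, ix.NSTATE))
    currents = np.zeros((n, ix.NCUR))
    states[:, ix.IV] = df["V_m_mV"].to_numpy()
    states[:, ix.ICASL] = df["Ca_sub_mM"].to_numpy()
    states[:, ix.ICAJ] = df["Ca_sub_mM"].to_numpy()
    for col in df.columns:
        if col in ix.STATE_NAMES:
            states[:, ix.STATE_NAMES.index(col)] = df[col].to_numpy()
        elif col in ix.CURRENT_NAMES:
            currents[:, ix.CURRENT_NAMES.index(col)] = df[col].to_numpy()
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Trace(t=df["t_ms"].to_numpy(), states=states, currents=currents,
                 meta=meta)


def save_trace_npz(trace: Trace, path) -> Path:
    """Compressed binary container with the full state/current matrices."""
    path = Path(path)
    np.savez_compressed(path, t=trace.t, states=trace.states,
                        currents=trace.currents,
                        meta=json.dumps(_jsonable(trace.meta)))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_trace_npz(path) -> Trace:
    with np.load(path, allow_pickle=False) as z:
        return Trace(t=z["t"], states=z["states"], currents=z["currents"],
                     meta=json.loads(str(z["meta"])))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(results: dict, outdir) -> dict:
    """Serialize a dict of results and return a content-hash manifest.

    Values are dispatched on type: Trace -> CSV (+ sidecar), DataFrame ->
    CSV, dict/list/dataclass -> JSON.  The manifest itself is written as
    ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, obj in results.items():
        if isinstance(obj, Trace):
            p = save_trace_csv(obj, outdir / f"{name}.csv")
            entries[f"{name}.csv"] = _sha256(p)
            side = p.with_suffix(p.suffix + ".meta.json")
            entries[side.name] = _sha256(side)
        elif isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.csv"
            obj.to_csv(p, index=False)
            entries[p.name] = _sha256(p)
        else:
            p = outdir / f"{name}.json"
            p.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))
            entries[p.name] = _sha256(p)
    manifest = {"artifacts": dict(sorted(entries.items()))}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
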