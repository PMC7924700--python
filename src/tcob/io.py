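"""File I/O: CSV traces, plain-text spike-time files, configs, manifests.

Spike files hold one spike time (ms, float) per line — nothing else.  Trace
CSVs have a fixed ``time,...`` header with time printed to 6 decimal places.
Configuration is JSON (YAML accepted by extension); every run can be echoed
into a manifest capturing the fully resolved parameters and seed so that a
run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine.errors import CobIOError
from .engine.trace import TraceTable
from .neurons import SpikeTrain

__all__ = ["write_trace", "read_trace", "write_spikes", "read_spikes",
           "load_config", "write_manifest"]


def write_trace(table: TraceTable | Mapping[str, np.ndarray] | pd.DataFrame,
                path: str | Path) -> None:
    """Write a trace as CSV (header ``time,...``; time to 6 decimals).

    Accepts a :class:`TraceTable`, a plain DataFrame, or a dict of equal
    length arrays containing a ``t`` or ``time`` key.
    """
    path = Path(path)
    if isinstance(table, TraceTable):
        table.to_csv(path)
        return
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        data = {k: np.asarray(v) for k, v in table.items()}
        tkey = "t" if "t" in data else "time"
        if tkey not in data:
            raise CobIOError("trace has no time column")
        t = data.pop(tkey)
        cols = {"time": t}
        cols.update((k, v) for k, v in data.items() if v.shape == t.shape)
        df = pd.DataFrame(cols)
    if len(df) == 0:
        raise CobIOError("refusing to write an empty trace")
    df["time"] = df["time"].map(lambda t: f"{float(t):.6f}")
    df.to_csv(path, index=False)


def read_trace(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise CobIOError(f"{path}: not a trace file (no time column)")
    return df


def write_spikes(train: SpikeTrain | Sequence[float], path: str | Path) -> None:
    """One spike time (ms) per line; an empty train writes an empty file."""
    times = train.times if isinstance(train, SpikeTrain) else list(train)
    Path(path).write_text("".join(f"{float(t):.6f}\n" for t in times))


def read_spikes(path: str | Path, source: str = "") -> SpikeTrain:
    """Read a spike-time file; blank lines are ignored, anything
    non-numeric raises naming the offending line."""
    times: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                times.append(float(text))
            except ValueError:
                raise CobIOError(
                    f"{path}: line {lineno} is not a spike time: {text!r}",
                    line=lineno) from None
    return SpikeTrain(times, source=source or str(path))


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a JSON (.json) or YAML (.yml/.yaml) configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        cfg = yaml.safe_load(text)
    else:
        try:
            cfg = json.loads(text)
        except json.JSONDecodeError as e:
            raise CobIOError(f"{path}: invalid JSON ({e})",
                             line=e.lineno) from None
    if not isinstance(cfg, dict):
        raise CobIOError(f"{path}: configuration must be a mapping")
    return cfg


def write_manifest(resolved: Mapping[str, Any], path: str | Path) -> None:
    """Echo the fully resolved run parameters (defaults included) to JSON."""
    Path(path).write_text(json.dumps(_jsonable(resolved), indent=2,
                                     sort_keys=True) + "\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__}
    return obj
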