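"""Tabular run results: one row per tick, one column per series variable."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .store import ConstraintStore

__all__ = ["TraceTable"]


@dataclass
class TraceTable:
    """A per-tick table of every series variable plus model time.

    ``df`` is indexed by tick; the first column is ``time`` (tick × dt, ms)
    followed by one column per dotted ``object.attribute`` path.
    """

    df: pd.DataFrame

    @classmethod
    def from_store(cls, store: "ConstraintStore") -> "TraceTable":
        grid = store.grid
        ticks = list(grid.ticks())
        data: dict[str, list] = {"time": [grid.time(k) for k in ticks]}
        for path in sorted(store.series):
            d = store.series[path]
            data[path] = [d.get(k, math.nan) for k in ticks]
        df = pd.DataFrame(data, index=pd.Index(ticks, name="tick"))
        return cls(df)

    @property
    def columns(self) -> list[str]:
        return [c for c in self.df.columns if c != "time"]

    @property
    def time(self) -> np.ndarray:
        return self.df["time"].to_numpy(dtype=float)

    def column(self, path: str) -> np.ndarray:
        return self.df[path].to_numpy()

    def to_csv(self, path) -> None:
        """Serialize with the fixed header ``time,<object.attribute>...``;
        time is printed in ms with 6 decimal places."""
        out = self.df.copy()
        out["time"] = out["time"].map(lambda t: f"{t:.6f}")
        out.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)
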