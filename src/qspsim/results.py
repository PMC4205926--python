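"""Sampled simulation output.

A :class:`TimeSeriesResult` is the single exchange format between the
simulator, the endpoint calculator and the results store: a strictly
increasing time grid (h), named output series of equal length, and run
metadata (solver settings, code version).  It round-trips losslessly through
plain CSV whose first column is time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, SerializationError


@dataclass
class TimeSeriesResult:
    task_id: str
    times: np.ndarray
    series: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise DomainError("times must be one-dimensional")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0.0):
            raise DomainError("times must be strictly increasing")
        for name, s in self.series.items():
            s = np.asarray(s, dtype=float)
            if s.shape != self.times.shape:
                raise DomainError(
                    f"series {name!r} has length {s.shape}, times {self.times.shape}")
            self.series[name] = s

    def __contains__(self, name: str) -> bool:
        return name in self.series

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.series[name]
        except KeyError as exc:
            raise DomainError(f"output variable {name!r} not in result") from exc

    def interp(self, name: str, t: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation of one series; times outside the grid error."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if t_arr.min() < self.times[0] - 1e-9 or t_arr.max() > self.times[-1] + 1e-9:
            raise DomainError(
                f"time {t} outside simulated range "
                f"[{self.times[0]}, {self.times[-1]}]")
        out = np.interp(t_arr, self.times, self[name])
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, **self.series})

    # -- text persistence ----------------------------------------------------
    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# task_id: {self.task_id}\n")
        for k in sorted(self.metadata):
            buf.write(f"# meta {k}: {self.metadata[k]}\n")
        self.to_frame().to_csv(buf, index=False, float_format="%.12g")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "TimeSeriesResult":
        task_id = ""
        metadata: dict = {}
        lines = text.splitlines(keepends=True)
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            stripped = line[1:].strip()
            if stripped.startswith("task_id:"):
                task_id = stripped.split(":", 1)[1].strip()
            elif stripped.startswith("meta "):
                k, _, v = stripped[5:].partition(":")
                metadata[k.strip()] = v.strip()
        else:
            raise SerializationError("result document has no data section")
        try:
            df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
        except Exception as exc:
            raise SerializationError(f"unparseable result document: {exc}") from exc
        if "time_h" not in df.columns:
            raise SerializationError("result document lacks a time_h column")
        times = df["time_h"].to_numpy()
        series = {c: df[c].to_numpy() for c in df.columns if c != "time_h"}
        return cls(task_id=task_id, times=times, series=series, metadata=metadata)

    def plot(self, names=None, ax=None):
        """Quick-look line plot of selected series (requires matplotlib)."""
        import matplotlib.pyplot as plt

        names = list(names) if names is not None else list(self.series)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        for name in names:
            ax.plot(self.times, self[name], label=name)
        ax.set_xlabel("time (h)")
        ax.legend(loc="best", fontsize="small")
        return ax
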