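"""Uniformly sampled time-series container and CSV round-trip.

All signals handled by the toolkit (strain, volume, flow, velocity,
pressure) share this representation: a strictly increasing, uniform time
grid in seconds and one value column whose unit is carried by ``kind``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TraceError

#: Recognized trace kinds and their value units.
KINDS = {
    "strain_pct": "%",
    "volume_mL": "mL",
    "flow_mL_per_s": "mL/s",
    "accel_mL_per_s2": "mL/s^2",
    "velocity_m_per_s": "m/s",
    "pressure_mmHg": "mmHg",
}

_MIN_SAMPLES = 8
_UNIFORM_RTOL = 1e-9


@dataclass(frozen=True)
class Trace:
    """One uniformly sampled signal.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing, uniform spacing.
    v : array of float
        Sample values; unit set by ``kind``.
    kind : str
        One of :data:`KINDS`.
    """

    t: np.ndarray
    v: np.ndarray
    kind: str = "pressure_mmHg"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if self.kind not in KINDS:
            raise TraceError(f"unknown trace kind {self.kind!r}")
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise TraceError("t and v must be matching 1-D arrays")
        if t.size < _MIN_SAMPLES:
            raise TraceError(f"trace needs >= {_MIN_SAMPLES} samples, got {t.size}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise TraceError("trace contains non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise TraceError("time grid must be strictly increasing")
        if np.ptp(dt) > _UNIFORM_RTOL * max(dt.mean(), 1e-30):
            raise TraceError("time grid is not uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return int(self.t.size)

    def interp(self, times) -> np.ndarray:
        """Linear interpolation of the values at arbitrary times."""
        return np.interp(np.asarray(times, dtype=float), self.t, self.v)

    def index_of(self, time: float) -> int:
        """Index of the grid sample nearest to ``time``."""
        i = int(round((time - self.t[0]) / self.dt))
        return min(max(i, 0), len(self) - 1)

    def window_mask(self, t_start: float, t_end: float) -> np.ndarray:
        return (self.t >= t_start - 1e-12) & (self.t <= t_end + 1e-12)

    def with_values(self, v, kind: str | None = None) -> "Trace":
        return replace(self, v=np.asarray(v, dtype=float), kind=kind or self.kind)

    # -- CSV interface: header "time_s,value", one trace per file ----------
    def to_csv(self, path: str | Path) -> None:
        # repr() emits the shortest string that round-trips float64 exactly
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("time_s,value\n")
            for ti, vi in zip(self.t.tolist(), self.v.tolist()):
                fh.write(f"{ti!r},{vi!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path, kind: str) -> "Trace":
        df = pd.read_csv(path, float_precision="round_trip")
        cols = [c.strip() for c in df.columns]
        if cols[:2] != ["time_s", "value"]:
            raise TraceError(f"{path}: expected header 'time_s,value', got {cols[:2]}")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), kind)


def kind_from_name(name: str) -> str | None:
    """Infer a trace kind from a filename stem suffix (e.g. '*_strain.csv')."""
    stem = Path(name).stem.lower()
    for key, kind in (
        ("strain", "strain_pct"),
        ("volume", "volume_mL"),
        ("flow", "flow_mL_per_s"),
        ("velocity", "velocity_m_per_s"),
        ("pressure", "pressure_mmHg"),
    ):
        if stem.endswith(key):
            return kind
    return None
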