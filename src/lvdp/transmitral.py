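"""Transmitral pressure difference by a simplified momentum balance.

The atrio-ventricular pressure difference is approximated from the mitral
inflow velocity v, the flow rate Q and its change dQ as

    dP = (rho / 2) * v^2 * (1 + Q / dQ)        [Pa]

which keeps both the convective (v^2) and the inertial (Q/dQ) terms that
matter across an unrestricted mitral valve.  Results are in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PA_PER_MMHG
from .errors import GradientError, InvalidParameterError
from .traces import Trace

__all__ = ["BloodProperties", "WaveWindow", "transmitral_dp", "max_dp_over_wave"]


@dataclass(frozen=True)
class BloodProperties:
    """Blood density in kg/m^3 (default 1060)."""

    rho: float = 1060.0

    def __post_init__(self) -> None:
        if not 900 < self.rho < 1200:
            raise InvalidParameterError(f"rho {self.rho} outside (900, 1200) kg/m^3")


@dataclass(frozen=True)
class WaveWindow:
    """Time window of one filling wave (E or A)."""

    t_start: float
    t_end: float
    label: str = "E"

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise InvalidParameterError(
                f"window start {self.t_start} must precede end {self.t_end}"
            )
        if self.label not in ("E", "A"):
            raise InvalidParameterError(f"window label must be 'E' or 'A', got {self.label!r}")


def transmitral_dp(
    v_mv: float,
    q: float,
    delta_q: float,
    blood: BloodProperties = BloodProperties(),
) -> float:
    """Instantaneous transmitral pressure difference (mmHg).

    ``q`` and ``delta_q`` enter only as their dimensionless ratio, so any
    consistent flow unit works.
    """
    if v_mv < 0:
        raise InvalidParameterError(f"velocity must be non-negative, got {v_mv}")
    if delta_q == 0:
        raise GradientError(
            "delta_q is zero; use the convective-only form (q=0) "
            "or a nonzero flow increment"
        )
    dp_pa = 0.5 * blood.rho * v_mv**2 * (1.0 + q / delta_q)
    return dp_pa / PA_PER_MMHG


def _delta_q_series(q: np.ndarray, t: np.ndarray, rule: str, floor_frac: float) -> np.ndarray:
    """Per-sample flow increment under the configured convention."""
    if rule == "onset":
        dq = q - q[0]
    elif rule == "fixed":
        dq = np.full_like(q, float(np.max(q) - q[0]))
    elif rule == "diff":
        dq = np.empty_like(q)
        dq[1:] = np.diff(q)
        dq[0] = dq[1] if q.size > 1 else 0.0
    else:
        raise InvalidParameterError(f"unknown delta-Q rule {rule!r}")
    floor = floor_frac * float(np.max(np.abs(q)))
    if floor > 0:
        sign = np.where(dq >= 0, 1.0, -1.0)
        dq = sign * np.maximum(np.abs(dq), floor)
    return dq


def max_dp_over_wave(
    v_trace: Trace,
    q_trace: Trace,
    window: WaveWindow,
    blood: BloodProperties = BloodProperties(),
    *,
    dq_rule: str = "onset",
    dq_floor_frac: float = 0.05,
) -> tuple[float, float]:
    """Maximum transmitral pressure difference over one filling wave.

    Evaluates the simplified momentum expression at every sample of the
    window and returns ``(dp_max_mmHg, t_at_max)``.  The flow trace is
    interpolated onto the velocity grid if the two differ.
    """
    mask = v_trace.window_mask(window.t_start, window.t_end)
    if not np.any(mask):
        raise InvalidParameterError(
            f"window [{window.t_start}, {window.t_end}] s contains no samples"
        )
    t = v_trace.t[mask]
    v = v_trace.v[mask]
    q = q_trace.interp(t)
    if np.all(v == 0):
        return 0.0, float(window.t_start)

    dq = _delta_q_series(q, t, dq_rule, dq_floor_frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dq != 0, q / dq, 0.0)
    dp = 0.5 * blood.rho * v**2 * (1.0 + ratio) / PA_PER_MMHG
    i = int(np.argmax(dp))
    return float(dp[i]), float(t[i])
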