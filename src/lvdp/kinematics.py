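"""Strain-to-volume kinematics and diastolic event detection.

The LV volume trace is inferred by scaling the global longitudinal strain
(GLS) trace between the measured end-systolic and end-diastolic volumes.
Transmitral flow rate is the time derivative of volume, and the timing of
the diastolic events (mitral valve opening/closure, pressure minimum, E/A
peaks, atrial contraction onset) is read off the volume curve and its
derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    EventDetectionError,
    EventOrderError,
    InsufficientDataError,
    InvalidStrainError,
    InvalidVolumesError,
)
from .traces import Trace

__all__ = [
    "DiastolicEvents",
    "gls_to_volume",
    "flow_and_acceleration",
    "detect_events",
    "measure_ivrt",
]


@dataclass(frozen=True)
class DiastolicEvents:
    """Timestamps (s) of the key diastolic events of one cardiac cycle.

    ``t_a_start``/``t_peak_a`` are ``None`` when the record shows E/A
    fusion (single filling wave); ``has_a_wave`` reflects that.
    """

    t_avc: float
    t_mvo: float
    t_minp: float
    t_peak_e: float
    t_a_start: float | None
    t_peak_a: float | None
    t_mvc: float

    def __post_init__(self) -> None:
        seq = [self.t_avc, self.t_mvo, self.t_minp, self.t_peak_e]
        if self.t_a_start is not None and self.t_peak_a is not None:
            if not (self.t_peak_e <= self.t_a_start < self.t_peak_a < self.t_mvc):
                raise EventOrderError(
                    f"A-wave events out of order: peak_e={self.t_peak_e}, "
                    f"a_start={self.t_a_start}, peak_a={self.t_peak_a}, mvc={self.t_mvc}"
                )
        seq.append(self.t_mvc)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise EventOrderError(f"events out of order: {seq}")

    @property
    def has_a_wave(self) -> bool:
        return self.t_a_start is not None and self.t_peak_a is not None

    def as_dict(self) -> dict:
        return {
            "t_avc": self.t_avc,
            "t_mvo": self.t_mvo,
            "t_minp": self.t_minp,
            "t_peak_e": self.t_peak_e,
            "t_a_start": self.t_a_start,
            "t_peak_a": self.t_peak_a,
            "t_mvc": self.t_mvc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiastolicEvents":
        return cls(**{k: d.get(k) for k in (
            "t_avc", "t_mvo", "t_minp", "t_peak_e", "t_a_start", "t_peak_a", "t_mvc")})


def gls_to_volume(strain: Trace, edv: float, esv: float) -> Trace:
    """Scale a GLS trace (negative %) into an LV volume trace (mL).

    The volume curve is assumed to mirror the GLS curve: zero strain maps
    to EDV and the most negative strain value maps to ESV, linearly in
    between::

        V(t) = EDV + (GLS(t) / GLS_min) * (ESV - EDV)
    """
    if not (edv > esv > 0):
        raise InvalidVolumesError(f"need edv > esv > 0, got edv={edv}, esv={esv}")
    gls_min = float(strain.v.min())
    if gls_min >= 0:
        raise InvalidStrainError("strain trace has no negative minimum")
    v = edv + (strain.v / gls_min) * (esv - edv)
    return Trace(strain.t, v, "volume_mL")


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the first/last half-window samples are
    left untouched so endpoint derivatives stay one-sided on raw data."""
    if window <= 1:
        return y
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    smoothed = np.convolve(y, kernel, mode="same")
    half = window // 2
    smoothed[:half] = y[:half]
    smoothed[-half:] = y[-half:]
    return smoothed


def flow_and_acceleration(volume: Trace, smooth_window: int = 1) -> tuple[Trace, Trace]:
    """First and second time derivatives of the volume trace.

    Q = dV/dt (mL/s) and dQ/dt = d2V/dt2 (mL/s^2), central differences at
    interior samples and one-sided at the endpoints.  An optional moving
    average is applied to the volume before differentiating.
    """
    if len(volume) < 3:
        raise InsufficientDataError("need at least 3 samples to differentiate")
    v = _moving_average(volume.v, smooth_window)
    q = np.gradient(v, volume.t)
    dq = np.gradient(q, volume.t)
    return (
        Trace(volume.t, q, "flow_mL_per_s"),
        Trace(volume.t, dq, "accel_mL_per_s2"),
    )


def _first_upward_crossing(q: np.ndarray, start: int, eps: float) -> int | None:
    """First index j > start with q[j] > eps and q[j-1] <= eps."""
    above = q > eps
    for j in range(max(start, 1), len(q)):
        if above[j] and not above[j - 1]:
            return j
    return None


def detect_events(
    volume: Trace,
    flow: Trace,
    accel: Trace,
    *,
    q_eps_frac: float = 1e-9,
    peak_prominence_frac: float = 0.02,
    min_separation: int = 2,
) -> DiastolicEvents:
    """Locate the diastolic events on one cardiac cycle.

    The cycle must start at end-diastole.  AVC is taken at the (first)
    volume minimum, MVO at the first upward zero-crossing of Q after it,
    E/A peaks from the flow maxima, atrial-contraction onset at the end of
    the inter-peak flow minimum plateau, minimum-pressure time at the
    flow-acceleration maximum on the E upstroke, and MVC at the end of the
    cycle.  With a single filling wave the A-dependent events are ``None``.
    """
    t, q = flow.t, flow.v
    i_avc = int(np.argmin(volume.v))  # ties break toward the earlier sample
    qmax = float(np.max(q))
    if qmax <= 0:
        raise EventDetectionError("no filling upstroke: flow never positive")
    eps = q_eps_frac * qmax

    i_mvo = _first_upward_crossing(q, i_avc, eps)
    if i_mvo is None:
        raise EventDetectionError("no upward flow crossing after minimum volume")

    peaks, _ = find_peaks(q[i_mvo:], prominence=peak_prominence_frac * qmax)
    peaks = peaks + i_mvo
    if peaks.size >= 2:
        i_pe, i_pa = int(peaks[0]), int(peaks[1])
        has_a = True
    elif peaks.size == 1:
        i_pe, i_pa = int(peaks[0]), None
        has_a = False
    else:
        # degenerate: single monotone filling hump peaking at/near the edge
        i_pe = i_mvo + int(np.argmax(q[i_mvo:]))
        i_pa = None
        has_a = False
        if i_pe <= i_mvo:
            raise EventDetectionError("no filling peak after mitral valve opening")

    i_astart = None
    if has_a:
        seg = q[i_pe : i_pa + 1]
        qmin = float(seg.min())
        # end of the minimum plateau == onset of the A upstroke
        plateau = np.flatnonzero(seg <= qmin + eps)
        i_astart = i_pe + int(plateau[-1])

    i_mvc = len(t) - 1

    i_minp = i_mvo + int(np.argmax(accel.v[i_mvo : i_pe + 1]))
    i_minp = max(i_minp, i_mvo + min_separation)
    i_minp = min(i_minp, i_pe - min_separation)
    if i_minp <= i_mvo or i_minp >= i_pe:
        raise EventDetectionError("E-wave too short to place the pressure minimum")

    return DiastolicEvents(
        t_avc=float(t[i_avc]),
        t_mvo=float(t[i_mvo]),
        t_minp=float(t[i_minp]),
        t_peak_e=float(t[i_pe]),
        t_a_start=float(t[i_astart]) if i_astart is not None else None,
        t_peak_a=float(t[i_pa]) if i_pa is not None else None,
        t_mvc=float(t[i_mvc]),
    )


def measure_ivrt(
    strain: Trace,
    flow: Trace,
    *,
    avc_rule: str = "strain_min",
    q_eps_frac: float = 1e-9,
) -> float:
    """Isovolumic relaxation time (s): AVC to mitral valve opening.

    AVC is approximated from the strain signal (peak negative GLS by
    default, or the strain-rate zero crossing), MVO as the first upward
    zero-crossing of the transmitral flow after AVC.
    """
    if avc_rule == "strain_min":
        i_avc = int(np.argmin(strain.v))
    elif avc_rule == "strain_rate_zero":
        rate = np.gradient(strain.v, strain.t)
        i_min = int(np.argmin(strain.v))
        after = np.flatnonzero(rate[i_min:] >= 0)
        i_avc = i_min + (int(after[0]) if after.size else 0)
    else:
        raise ValueError(f"unknown avc_rule {avc_rule!r}")
    t_avc = float(strain.t[i_avc])

    qmax = float(np.max(flow.v))
    if qmax <= 0:
        raise EventDetectionError("no filling upstroke in flow trace")
    start = flow.index_of(t_avc)
    j = _first_upward_crossing(flow.v, start, q_eps_frac * qmax)
    if j is None:
        raise EventDetectionError("no mitral opening found after AVC")
    t_mvo = float(flow.t[j])
    if t_avc >= t_mvo:
        raise EventOrderError(f"AVC at {t_avc} s not before MVO at {t_mvo} s")
    return t_mvo - t_avc
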