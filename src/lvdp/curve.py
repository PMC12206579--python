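"""Reference diastolic pressure curve and patient-specific curve generation.

A reference curve is built by annotating measured diastolic pressure
recordings with six key events (MVO, pressure minimum, peak E, atrial
contraction onset, peak A, MVC), normalizing the duration of each
inter-event segment to [0, 1], and averaging pointwise across recordings.
A patient-specific curve then shifts the reference vertically so it passes
through the patient's estimated event pressures and maps each segment onto
the patient's own event times.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PA_PER_MMHG
from .errors import AnchorOrderWarning, InvalidParameterError, ReferenceCurveError
from .kinematics import DiastolicEvents
from .pressures import PressureEstimates
from .traces import Trace

__all__ = [
    "ANCHOR_EVENTS",
    "AnnotatedPressureCurve",
    "ReferenceCurve",
    "build_reference",
    "generate_patient_curve",
    "event_pressure_table",
    "mean_diastolic_pressure",
]

log = logging.getLogger(__name__)

#: Anchor names in temporal order and the event field each maps to.
ANCHOR_EVENTS: tuple[tuple[str, str], ...] = (
    ("mvo", "t_mvo"),
    ("min_plv", "t_minp"),
    ("peak_e", "t_peak_e"),
    ("a_start", "t_a_start"),
    ("peak_a", "t_peak_a"),
    ("mvc", "t_mvc"),
)


@dataclass(frozen=True)
class AnnotatedPressureCurve:
    """A measured pressure trace with its diastolic event annotations."""

    trace: Trace
    events: DiastolicEvents

    def anchor_times(self) -> list[float] | None:
        """Times of the six curve anchors, or None if any is missing."""
        times = []
        for _, attr in ANCHOR_EVENTS:
            t = getattr(self.events, attr)
            if t is None:
                return None
            times.append(float(t))
        t0, t1 = self.trace.t[0], self.trace.t[-1]
        if times[0] < t0 - 1e-9 or times[-1] > t1 + 1e-9:
            return None
        return times


@dataclass(frozen=True)
class ReferenceCurve:
    """Time-normalized averaged diastolic pressure template.

    ``segments[k]`` holds the mean pressure over the k-th inter-anchor
    segment on the shared ``fractions`` grid; ``anchors[k]`` is the mean
    pressure at the k-th event.
    """

    fractions: np.ndarray           # (n,), 0..1 strictly increasing
    segments: np.ndarray            # (n_anchors-1, n)
    anchors: np.ndarray             # (n_anchors,)
    n_sources: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, float)
        s = np.asarray(self.segments, float)
        a = np.asarray(self.anchors, float)
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "segments", s)
        object.__setattr__(self, "anchors", a)
        if np.any(np.diff(f) <= 0):
            raise InvalidParameterError("fractions must be strictly increasing")
        if s.shape != (a.size - 1, f.size):
            raise InvalidParameterError("segments shape inconsistent with anchors/fractions")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fractions": self.fractions.tolist(),
            "segments": self.segments.tolist(),
            "anchors": self.anchors.tolist(),
            "anchor_names": [name for name, _ in ANCHOR_EVENTS],
            "n_sources": self.n_sources,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["fractions"], float),
            np.asarray(d["segments"], float),
            np.asarray(d["anchors"], float),
            int(d["n_sources"]),
        )


def build_reference(
    curves: list[AnnotatedPressureCurve], n_per_segment: int = 100
) -> ReferenceCurve:
    """Average annotated curves on a per-segment normalized time grid.

    Curves with incomplete annotations are excluded with a warning; at
    least one usable curve is required.
    """
    frac = np.linspace(0.0, 1.0, n_per_segment)
    n_seg = len(ANCHOR_EVENTS) - 1
    stacks: list[np.ndarray] = []
    anchor_stacks: list[np.ndarray] = []
    for i, curve in enumerate(curves):
        times = curve.anchor_times()
        if times is None:
            log.warning("curve %d excluded: incomplete event annotations", i)
            continue
        segs = np.empty((n_seg, n_per_segment))
        for k in range(n_seg):
            ts = times[k] + frac * (times[k + 1] - times[k])
            segs[k] = curve.trace.interp(ts)
        stacks.append(segs)
        anchor_stacks.append(curve.trace.interp(times))
    if not stacks:
        raise ReferenceCurveError("no usable annotated curves")
    return ReferenceCurve(
        fractions=frac,
        segments=np.mean(stacks, axis=0),
        anchors=np.mean(anchor_stacks, axis=0),
        n_sources=len(stacks),
    )


def event_pressure_table(
    estimates: PressureEstimates,
    dp_at_peak_e: float = 0.0,
    max_dp_a: float | None = None,
    *,
    peak_a_rule: str = "midpoint",
) -> dict[str, float]:
    """Target pressures (mmHg) at the six curve anchors.

    MVO sits at P_MVO, the minimum at the estimated minimum pressure, the
    peak-E anchor dips below pre-A by the instantaneous (convective)
    gradient at peak velocity, the A-start anchor is pre-A, MVC is the
    end-diastolic pressure and peak A defaults to the A-start/MVC midpoint.
    """
    pre_a = estimates.pre_a
    mvc = estimates.edp
    if mvc is None:
        if max_dp_a is not None:
            mvc = pre_a + max_dp_a
            warnings.warn(
                "EDP missing; MVC anchor set to pre_a + max_dp_a", AnchorOrderWarning
            )
        else:
            mvc = pre_a
            warnings.warn("EDP missing; MVC anchor set to pre_a", AnchorOrderWarning)
    if peak_a_rule == "midpoint":
        peak_a = 0.5 * (pre_a + mvc)
    else:
        raise InvalidParameterError(f"unknown peak_a_rule {peak_a_rule!r}")
    table = {
        "mvo": estimates.p_mvo,
        "min_plv": estimates.min_plv,
        "peak_e": pre_a - dp_at_peak_e,
        "a_start": pre_a,
        "peak_a": peak_a,
        "mvc": mvc,
    }
    if table["min_plv"] > table["a_start"] or table["peak_e"] < table["min_plv"]:
        warnings.warn(f"anchor pressures out of order: {table}", AnchorOrderWarning)
    return table


def convective_dp_mmhg(v_peak_m_s: float, rho: float = 1060.0) -> float:
    """Convective-only pressure difference (rho/2) v^2, in mmHg."""
    return 0.5 * rho * v_peak_m_s**2 / PA_PER_MMHG


def generate_patient_curve(
    ref: ReferenceCurve,
    events: DiastolicEvents,
    event_pressures: dict[str, float],
    *,
    dt: float = 0.005,
    estimates: PressureEstimates | None = None,
) -> Trace:
    """Patient-specific diastolic pressure curve from the reference template.

    Within each segment the reference pressures are shifted by a blend,
    linear in normalized fraction, of the offsets at the two bounding
    anchors (offset = target pressure - reference anchor pressure), then
    mapped to the patient's absolute event times and resampled at ``dt``.
    """
    names = [name for name, _ in ANCHOR_EVENTS]
    missing = [n for n in names if n not in event_pressures]
    if missing:
        raise InvalidParameterError(f"missing event pressures: {missing}")
    times = []
    for _, attr in ANCHOR_EVENTS:
        t = getattr(events, attr)
        if t is None:
            raise InvalidParameterError(f"event {attr} required for curve generation")
        times.append(float(t))
    if any(b <= a for a, b in zip(times, times[1:])):
        raise InvalidParameterError(f"event times must be strictly increasing: {times}")

    targets = np.array([event_pressures[n] for n in names], float)
    if targets[1] > targets[3]:
        warnings.warn("min pressure anchor above pre-A anchor", AnchorOrderWarning)

    offsets = targets - ref.anchors
    ts, ps = [], []
    frac = ref.fractions
    for k in range(len(names) - 1):
        blend = (1.0 - frac) * offsets[k] + frac * offsets[k + 1]
        seg_t = times[k] + frac * (times[k + 1] - times[k])
        seg_p = ref.segments[k] + blend
        if k > 0:  # drop duplicated anchor sample
            seg_t, seg_p = seg_t[1:], seg_p[1:]
        ts.append(seg_t)
        ps.append(seg_p)
    t_all = np.concatenate(ts)
    p_all = np.concatenate(ps)

    # uniform grid ending exactly at MVC (dt nudged down if needed)
    n_out = max(int(np.ceil((times[-1] - times[0]) / dt)), 7)
    t_out = np.linspace(times[0], times[-1], n_out + 1)
    p_out = np.interp(t_out, t_all, p_all)
    return Trace(t_out, p_out, "pressure_mmHg")


def mean_diastolic_pressure(curve: Trace, t_mvo: float, t_mvc: float) -> float:
    """Time-averaged pressure (trapezoidal) over [t_mvo, t_mvc]."""
    if not (curve.t[0] - 1e-9 <= t_mvo < t_mvc <= curve.t[-1] + 1e-9):
        raise InvalidParameterError(
            f"window [{t_mvo}, {t_mvc}] outside curve span "
            f"[{curve.t[0]}, {curve.t[-1]}]"
        )
    inner = curve.t[(curve.t > t_mvo) & (curve.t < t_mvc)]
    ts = np.concatenate([[t_mvo], inner, [t_mvc]])
    ps = curve.interp(ts)
    return float(np.trapezoid(ps, ts) / (t_mvc - t_mvo))
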