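"""Forward simulator of self-consistent synthetic patients.

Each patient is generated backwards from ground-truth diastolic
pressures: the linear minimum-pressure model fixes min P at the chosen
tau, the difference to the chosen pre-A pressure fixes the E-wave
transmitral maximum (and hence peak E velocity), and the exponential
relaxation model fixes the isovolumic relaxation time.  Raised-cosine
E/A flow waves are integrated into a volume trace, mirrored into a GLS
trace, and divided by an effective orifice area into a mitral velocity
trace.  At zero noise the estimation pipeline applied to these
observables recovers the truth to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.integrate import cumulative_trapezoid

from .agreement import AgreementStats, agreement_report
from .config import PA_PER_MMHG
from .errors import CohortMismatchError, ParameterRejectionError
from .kinematics import DiastolicEvents
from .pressures import MinPlvModel, PressureEstimates
from .traces import Trace

__all__ = [
    "NoiseSD",
    "SimParams",
    "SyntheticPatient",
    "simulate_patient",
    "simulate_cohort",
    "recovery_report",
]


class NoiseSD(BaseModel):
    """Gaussian noise SDs per observable (0 = noiseless)."""

    model_config = {"frozen": True}

    strain_pct: float = Field(0.0, ge=0)
    velocity_m_s: float = Field(0.0, ge=0)
    pressure_mmhg: float = Field(0.0, ge=0)
    lars_pct: float = Field(0.0, ge=0)


class SimParams(BaseModel):
    """Ground-truth physiology and acquisition settings for one patient."""

    model_config = {"frozen": True}

    psys: float = Field(ge=80, le=200)
    bmi: float = Field(gt=10, lt=60)
    lars: float = Field(ge=5, le=60)
    tau_true: float = Field(ge=20, le=90, description="ms")
    pre_a_true: float = Field(ge=4, le=30, description="mmHg")
    edv: float = Field(gt=0)
    esv: float = Field(gt=0)
    hr: float = Field(ge=35, le=110, description="bpm")
    a_peak_vel: float = Field(0.5, gt=0, le=1.5, description="m/s")
    gls_min: float = Field(-20.0, lt=0, description="peak negative GLS, %")
    a_volume_frac: float = Field(0.25, gt=0.05, lt=0.6)
    diastasis_s: float = Field(0.05, ge=0.0)
    orifice_area_cm2: float = Field(4.0, gt=0)
    rho: float = Field(1060.0, gt=900, lt=1200)
    dt: float = Field(5e-4, gt=0, le=0.005, description="nominal sample step, s")
    noise_sd: NoiseSD = NoiseSD()
    seed: int = 0

    @model_validator(mode="after")
    def _check_volumes(self):
        if not self.edv > self.esv:
            raise ValueError(f"edv {self.edv} must exceed esv {self.esv}")
        return self


@dataclass(frozen=True)
class SyntheticPatient:
    """One simulated patient: truth, observable traces and scalar record."""

    patient_id: str
    params: SimParams
    true_values: dict            # tau, min_plv, pre_a, p_mvo, edp, ivrt_ms, ...
    strain: Trace
    velocity: Trace
    pressure_curve: Trace
    events_true: DiastolicEvents
    scalars: dict                # observable scalars fed to the estimator


def _raised_half(n: int, rising: bool) -> np.ndarray:
    """Half raised-cosine over n intervals (n+1 samples), 0->1 or 1->0."""
    u = np.arange(n + 1) / n
    shape = 0.5 * (1.0 - np.cos(np.pi * u))
    return shape if rising else shape[::-1]


def simulate_patient(
    params: SimParams, model: MinPlvModel = MinPlvModel(), patient_id: str = "sim"
) -> SyntheticPatient:
    """Build one self-consistent synthetic patient (deterministic per seed)."""
    p = params
    min_plv = model.predict(p.psys, p.bmi, p.lars, p.tau_true)
    max_dp_e = p.pre_a_true - min_plv
    if max_dp_e <= 0.05:
        raise ParameterRejectionError(
            f"pre_a_true {p.pre_a_true:.2f} mmHg does not exceed model "
            f"min_plv {min_plv:.2f} mmHg; no consistent E-wave gradient"
        )
    p_mvo = p.pre_a_true + 5.0
    p0 = 0.65 * p.psys
    if p_mvo >= p0:
        raise ParameterRejectionError(
            f"P_MVO {p_mvo:.2f} >= 0.65*Psys {p0:.2f} mmHg; no consistent IVRT"
        )
    ivrt_ms = p.tau_true / 0.85 * np.log(p0 / p_mvo)
    ivrt_s = ivrt_ms / 1000.0

    # peak velocities / flows pinned by the E-wave gradient target
    v_e = float(np.sqrt(max_dp_e * PA_PER_MMHG / p.rho))
    qp_e = v_e * 100.0 * p.orifice_area_cm2       # mL/s
    qp_a = p.a_peak_vel * 100.0 * p.orifice_area_cm2
    max_dp_a = p.rho * p.a_peak_vel**2 / PA_PER_MMHG
    edp = p.pre_a_true + max_dp_a

    # wave durations from the volume budget (raised cosine: mean = peak/2)
    dv = p.edv - p.esv
    d_a = 2.0 * p.a_volume_frac * dv / qp_a
    d_e = 2.0 * (1.0 - p.a_volume_frac) * dv / qp_e
    cycle = 60.0 / p.hr
    t_avc = cycle - ivrt_s - d_e - p.diastasis_s - d_a
    d_dia = p.diastasis_s
    if t_avc > 0.45 * cycle:
        d_dia += t_avc - 0.45 * cycle
        t_avc = 0.45 * cycle
    if t_avc < 0.10 * cycle:
        raise ParameterRejectionError(
            f"filling waves (E {d_e * 1e3:.0f} ms, A {d_a * 1e3:.0f} ms) plus IVRT "
            f"{ivrt_ms:.0f} ms do not fit a {cycle * 1e3:.0f} ms cycle"
        )

    # snap all phase boundaries to a grid that represents IVRT exactly
    n_ivrt = max(int(round(ivrt_s / p.dt)), 8)
    dt = ivrt_s / n_ivrt
    n_sys = max(int(round(t_avc / dt)), 8)
    n_e = max(int(round(d_e / dt)), 16)
    n_up = max(int(round(0.4 * n_e)), 4)
    n_up += n_up % 2                      # even: acceleration peak on-grid
    n_down = max(n_e - n_up, 4)
    n_dia = max(int(round(d_dia / dt)), 4) if d_dia > 0 else 0
    n_a = max(int(round(d_a / dt)), 16)
    n_a += n_a % 2                        # even: A peak on-grid

    i_avc = n_sys
    i_mvo = i_avc + n_ivrt
    i_pe = i_mvo + n_up
    i_e_end = i_pe + n_down
    i_astart = i_e_end + n_dia
    i_mvc = i_astart + n_a
    n = i_mvc + 1
    t = np.arange(n) * dt

    # analytic filling flow (mL/s); zero in systole, IVRT and diastasis
    q_fill = np.zeros(n)
    q_fill[i_mvo : i_pe + 1] = qp_e * _raised_half(n_up, rising=True)
    q_fill[i_pe : i_e_end + 1] = qp_e * _raised_half(n_down, rising=False)
    u_a = np.arange(n_a + 1) / n_a
    q_fill[i_astart:] = qp_a * 0.5 * (1.0 - np.cos(2.0 * np.pi * u_a))

    # volume: cosine ejection, flat isovolumic phase, then integrated inflow
    volume = np.empty(n)
    u_sys = t[: i_avc + 1] / t[i_avc]
    volume[: i_avc + 1] = p.esv + 0.5 * dv * (1.0 + np.cos(np.pi * u_sys))
    volume[i_avc:i_mvo] = p.esv
    volume[i_mvo:] = p.esv + cumulative_trapezoid(q_fill[i_mvo:], dx=dt, initial=0.0)

    gls = p.gls_min * (p.edv - volume) / dv
    velocity = np.clip(q_fill, 0.0, None) / (100.0 * p.orifice_area_cm2)

    # ground-truth event times
    events = DiastolicEvents(
        t_avc=float(t[i_avc]),
        t_mvo=float(t[i_mvo]),
        t_minp=float(t[i_mvo + n_up // 2]),
        t_peak_e=float(t[i_pe]),
        t_a_start=float(t[i_astart]),
        t_peak_a=float(t[i_astart + n_a // 2]),
        t_mvc=float(t[i_mvc]),
    )

    pressure = _true_pressure_curve(
        t[i_avc:], events, p0, p.tau_true / 1000.0, ivrt_s,
        p_mvo, min_plv, p.pre_a_true, max_dp_e, edp,
    )

    rng = np.random.default_rng(p.seed)
    ns = p.noise_sd
    gls_obs = gls + rng.normal(0.0, ns.strain_pct, n) if ns.strain_pct else gls
    vel_obs = velocity + rng.normal(0.0, ns.velocity_m_s, n) if ns.velocity_m_s else velocity
    pres_obs = pressure + rng.normal(0.0, ns.pressure_mmhg, pressure.size) if ns.pressure_mmhg else pressure
    lars_obs = p.lars + (rng.normal(0.0, ns.lars_pct) if ns.lars_pct else 0.0)

    true_values = {
        "tau_ms": p.tau_true,
        "min_plv_mmhg": min_plv,
        "pre_a_mmhg": p.pre_a_true,
        "p_mvo_mmhg": p_mvo,
        "edp_mmhg": edp,
        "max_dp_e_mmhg": max_dp_e,
        "max_dp_a_mmhg": max_dp_a,
        "ivrt_ms": ivrt_ms,
        "e_peak_vel_m_s": v_e,
    }
    scalars = {
        "psys_mmhg": p.psys,
        "bmi_kg_m2": p.bmi,
        "lars_pct": float(lars_obs),
        "edv_ml": p.edv,
        "esv_ml": p.esv,
        "hr_bpm": 60.0 / t[-1],
    }
    return SyntheticPatient(
        patient_id=patient_id,
        params=p,
        true_values=true_values,
        strain=Trace(t, gls_obs, "strain_pct"),
        velocity=Trace(t, vel_obs, "velocity_m_per_s"),
        pressure_curve=Trace(t[i_avc:], pres_obs, "pressure_mmHg"),
        events_true=events,
        scalars=scalars,
    )


def _true_pressure_curve(
    t, events, p0, tau_s, ivrt_s, p_mvo, min_plv, pre_a, max_dp_e, edp
) -> np.ndarray:
    """Piecewise diastolic pressure hitting every anchor exactly.

    Exponential decay over the isovolumic phase (decay onset 15% of IVRT
    after AVC, so the exponential spans 85% of IVRT down to P_MVO), then
    zero-slope cosine blends between consecutive anchor pressures.
    """
    p = np.empty_like(t)
    t0 = events.t_avc + 0.15 * ivrt_s
    iso = t <= events.t_mvo + 1e-12
    p[iso] = p0 * np.exp(-(t[iso] - t0) / tau_s)

    peak_e_p = pre_a - 0.5 * max_dp_e  # convective-only dip at peak velocity
    peak_a_p = 0.5 * (pre_a + edp)
    anchors = [
        (events.t_mvo, p_mvo),
        (events.t_minp, min_plv),
        (events.t_peak_e, peak_e_p),
        (events.t_a_start, pre_a),
        (events.t_peak_a, peak_a_p),
        (events.t_mvc, edp),
    ]
    for (ta, pa), (tb, pb) in zip(anchors, anchors[1:]):
        seg = (t >= ta - 1e-12) & (t <= tb + 1e-12)
        u = (t[seg] - ta) / (tb - ta)
        p[seg] = pa + (pb - pa) * 0.5 * (1.0 - np.cos(np.pi * u))
    return p


#: Default uniform sampling ranges for cohort draws.  ``max_dp_e`` is drawn
#: and added to the model minimum pressure to obtain ``pre_a_true``.
DEFAULT_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "psys": (100.0, 160.0),
    "bmi": (20.0, 34.0),
    "lars": (22.0, 45.0),
    "tau_true": (28.0, 60.0),
    "max_dp_e": (1.5, 5.0),
    "edv": (100.0, 160.0),
    "esv_frac": (0.38, 0.52),
    "hr": (55.0, 75.0),
    "a_peak_vel": (0.35, 0.65),
}

_MAX_DRAW_ATTEMPTS = 500


def simulate_cohort(
    n: int,
    param_distributions: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    noise_sd: NoiseSD = NoiseSD(),
    model: MinPlvModel = MinPlvModel(),
) -> list[SyntheticPatient]:
    """Draw ``n`` independent, self-consistent synthetic patients."""
    if n < 1:
        raise ParameterRejectionError(f"cohort size must be >= 1, got {n}")
    dists = dict(DEFAULT_DISTRIBUTIONS)
    if param_distributions:
        unknown = set(param_distributions) - set(dists)
        if unknown:
            raise ParameterRejectionError(f"unknown distribution keys: {sorted(unknown)}")
        dists.update(param_distributions)
    for name, (lo, hi) in dists.items():
        if not lo < hi:
            raise ParameterRejectionError(f"invalid bounds for {name}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    cohort: list[SyntheticPatient] = []
    for i in range(n):
        for _ in range(_MAX_DRAW_ATTEMPTS):
            draw = {k: rng.uniform(*b) for k, b in dists.items()}
            min_plv = model.predict(
                draw["psys"], draw["bmi"], draw["lars"], draw["tau_true"]
            )
            pre_a = min_plv + draw["max_dp_e"]
            if not 4.0 <= pre_a <= 30.0:
                continue
            try:
                params = SimParams(
                    psys=draw["psys"], bmi=draw["bmi"], lars=draw["lars"],
                    tau_true=draw["tau_true"], pre_a_true=pre_a,
                    edv=draw["edv"], esv=draw["esv_frac"] * draw["edv"],
                    hr=draw["hr"], a_peak_vel=draw["a_peak_vel"],
                    noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)),
                )
                cohort.append(simulate_patient(params, model, patient_id=f"sim{i:03d}"))
                break
            except (ParameterRejectionError, ValueError):
                continue
        else:
            raise ParameterRejectionError(
                f"could not draw a valid patient in {_MAX_DRAW_ATTEMPTS} attempts"
            )
    return cohort


def recovery_report(
    cohort: list[SyntheticPatient], estimates: list[PressureEstimates]
) -> dict[str, AgreementStats]:
    """Agreement of estimated vs. true parameters across a cohort."""
    if not cohort:
        raise CohortMismatchError("empty cohort")
    if len(cohort) != len(estimates):
        raise CohortMismatchError(
            f"cohort has {len(cohort)} patients but {len(estimates)} estimates"
        )
    for pat, est in zip(cohort, estimates):
        if est.patient_id is not None and est.patient_id != pat.patient_id:
            raise CohortMismatchError(
                f"estimate for {est.patient_id!r} paired with patient {pat.patient_id!r}"
            )
    report: dict[str, AgreementStats] = {}
    pairs = {
        "tau": ("tau_ms", lambda e: e.tau),
        "min_plv": ("min_plv_mmhg", lambda e: e.min_plv),
        "pre_a": ("pre_a_mmhg", lambda e: e.pre_a),
        "edp": ("edp_mmhg", lambda e: e.edp),
    }
    for name, (key, getter) in pairs.items():
        truth, est_vals = [], []
        for pat, est in zip(cohort, estimates):
            v = getter(est)
            if v is None:
                continue
            truth.append(pat.true_values[key])
            est_vals.append(v)
        if len(est_vals) >= 2:
            report[name] = agreement_report(est_vals, truth)
    return report
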