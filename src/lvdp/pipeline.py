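"""End-to-end estimation pipeline for one patient record.

Order of operations: strain -> volume -> flow/acceleration -> event
detection -> IVRT -> transmitral maxima (E and A windows) -> coupled
solver -> end-diastolic pressure -> optional pressure curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, PA_PER_MMHG
from .cohort import SyntheticPatient
from .curve import ReferenceCurve, event_pressure_table, generate_patient_curve
from .errors import LvdpError
from .kinematics import (
    DiastolicEvents,
    detect_events,
    flow_and_acceleration,
    gls_to_volume,
    measure_ivrt,
)
from .patient import PatientRecord, RecordScalars
from .pressures import (
    MinPlvModel,
    PatientScalars,
    PressureEstimates,
    estimate_edp,
    solve_coupled,
)
from .traces import Trace
from .transmitral import BloodProperties, WaveWindow, max_dp_over_wave

__all__ = ["EstimateResult", "run_estimate", "synthesize_velocity", "record_from_synthetic"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EstimateResult:
    """Pressure estimates plus per-stage diagnostics."""

    estimates: PressureEstimates
    events: DiastolicEvents
    diagnostics: dict
    curve: Trace | None = None

    def as_dict(self) -> dict:
        return {
            "estimates": self.estimates.as_dict(),
            "events": self.events.as_dict(),
            "diagnostics": self.diagnostics,
        }


def synthesize_velocity(
    flow: Trace,
    events: DiastolicEvents,
    e_peak: float,
    a_peak: float | None,
) -> Trace:
    """Triangular E/A mitral velocity reconstruction (fixture behaviour).

    Used when no measured Doppler trace is supplied: triangles peak at the
    detected E/A flow peaks and return to zero at the wave boundaries.
    """
    t = flow.t
    v = np.zeros_like(t)
    e_end = events.t_a_start if events.t_a_start is not None else events.t_mvc

    def _triangle(t0, tp, t1, peak):
        up = (t >= t0) & (t <= tp)
        down = (t > tp) & (t <= t1)
        if tp > t0:
            v[up] = peak * (t[up] - t0) / (tp - t0)
        if t1 > tp:
            v[down] = peak * (t1 - t[down]) / (t1 - tp)

    _triangle(events.t_mvo, events.t_peak_e, e_end, e_peak)
    if events.has_a_wave and a_peak is not None:
        _triangle(events.t_a_start, events.t_peak_a, events.t_mvc, a_peak)
    return Trace(t, v, "velocity_m_per_s")


def run_estimate(
    record: PatientRecord,
    config: ModelConfig = ModelConfig(),
    model: MinPlvModel = MinPlvModel(),
    reference: ReferenceCurve | None = None,
) -> EstimateResult:
    """Run the full estimation pipeline on one patient record."""
    diag: dict = {"config_hash": config.config_hash(), "patient_id": record.id}
    s = record.scalars

    volume = gls_to_volume(record.strain, s.edv_ml, s.esv_ml)
    flow, accel = flow_and_acceleration(volume, smooth_window=config.smooth_window)
    # zero crossings come from unsmoothed flow: the moving average leaks the
    # filling upstroke across phase boundaries and biases MVO/A-onset by
    # a couple of samples; the smoothed acceleration still places min P
    flow_raw, _ = flow_and_acceleration(volume, smooth_window=1)
    events = detect_events(
        volume, flow_raw, accel,
        q_eps_frac=config.q_eps_frac,
        peak_prominence_frac=config.peak_prominence_frac,
    )
    diag["events"] = events.as_dict()

    ivrt_ms = 1000.0 * measure_ivrt(
        record.strain, flow_raw, avc_rule=config.avc_rule, q_eps_frac=config.q_eps_frac
    )
    diag["ivrt_ms"] = ivrt_ms

    velocity = record.velocity
    if velocity is None:
        if s.e_peak_m_s is None:
            raise LvdpError(
                "stage transmitral: no velocity trace and no e_peak_m_s scalar "
                "to reconstruct one"
            )
        velocity = synthesize_velocity(flow, events, s.e_peak_m_s, s.a_peak_m_s)
        diag["velocity_source"] = "triangular_reconstruction"
    else:
        diag["velocity_source"] = "measured"

    blood = BloodProperties(rho=config.rho_kg_m3)
    e_end = events.t_a_start if events.t_a_start is not None else events.t_mvc
    max_dp_e, t_dp_e = max_dp_over_wave(
        velocity, flow, WaveWindow(events.t_mvo, e_end, "E"), blood,
        dq_rule=config.dq_rule, dq_floor_frac=config.dq_floor_frac,
    )
    max_dp_e = max(max_dp_e, 0.0)
    diag["max_dp_e_mmhg"] = max_dp_e
    diag["t_max_dp_e_s"] = t_dp_e

    max_dp_a = None
    if events.has_a_wave:
        max_dp_a, t_dp_a = max_dp_over_wave(
            velocity, flow, WaveWindow(events.t_a_start, events.t_mvc, "A"), blood,
            dq_rule=config.dq_rule, dq_floor_frac=config.dq_floor_frac,
        )
        max_dp_a = max(max_dp_a, 0.0)
        diag["max_dp_a_mmhg"] = max_dp_a
        diag["t_max_dp_a_s"] = t_dp_a
    else:
        diag["missing_a_wave"] = True

    scalars = PatientScalars(
        psys=s.psys_mmhg, bmi=s.bmi_kg_m2, lars=s.lars_pct,
        ivrt=ivrt_ms, max_dp_e=max_dp_e, max_dp_a=max_dp_a,
    )
    est = solve_coupled(
        scalars, model,
        max_iter=config.solver_max_iter,
        tol_mmhg=config.solver_tol_mmhg,
        init_pre_a=config.init_pre_a_mmhg,
        p_mvo_offset=config.p_mvo_offset_mmhg,
        ivrt_factor=config.ivrt_factor,
        p0_fraction=config.p0_fraction,
    )
    diag["iterations"] = est.iterations
    diag["converged"] = est.converged

    edp = None
    if max_dp_a is not None:
        edp = estimate_edp(est.pre_a, max_dp_a, config.passive_rise_mmhg)
    else:
        diag["edp_unavailable"] = "missing A wave (E/A fusion)"

    est = PressureEstimates(
        tau=est.tau, min_plv=est.min_plv, pre_a=est.pre_a, p_mvo=est.p_mvo,
        edp=edp, iterations=est.iterations, converged=est.converged,
        patient_id=record.id,
    )

    curve = None
    if reference is not None and events.has_a_wave:
        v_peak_e = float(velocity.interp([events.t_peak_e])[0])
        dp_conv = 0.5 * config.rho_kg_m3 * v_peak_e**2 / PA_PER_MMHG
        anchors = event_pressure_table(
            est, dp_at_peak_e=dp_conv, max_dp_a=max_dp_a,
            peak_a_rule=config.peak_a_anchor_rule,
        )
        curve = generate_patient_curve(
            reference, events, anchors, dt=config.curve_dt_s, estimates=est
        )
        diag["anchor_pressures"] = anchors
    diag["curve_generated"] = curve is not None

    return EstimateResult(estimates=est, events=events, diagnostics=diag, curve=curve)


def record_from_synthetic(patient: SyntheticPatient) -> PatientRecord:
    """Wrap a simulated patient's observables as an estimator input record."""
    sc = patient.scalars
    return PatientRecord(
        id=patient.patient_id,
        scalars=RecordScalars(
            psys_mmhg=sc["psys_mmhg"], bmi_kg_m2=sc["bmi_kg_m2"],
            lars_pct=sc["lars_pct"], edv_ml=sc["edv_ml"], esv_ml=sc["esv_ml"],
            hr_bpm=sc.get("hr_bpm"),
        ),
        strain=patient.strain,
        velocity=patient.velocity,
        pressure=patient.pressure_curve,
    )
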