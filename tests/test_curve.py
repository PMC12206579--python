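import numpy as np
import pytest

from lvdp.curve import (
    ANCHOR_EVENTS,
    AnnotatedPressureCurve,
    ReferenceCurve,
    build_reference,
    event_pressure_table,
    generate_patient_curve,
    mean_diastolic_pressure,
)
from lvdp.errors import AnchorOrderWarning, InvalidParameterError, ReferenceCurveError
from lvdp.kinematics import DiastolicEvents
from lvdp.pressures import PressureEstimates
from lvdp.traces import Trace


@pytest.fixture(scope="module")
def template(sim_patient):
    return AnnotatedPressureCurve(sim_patient.pressure_curve, sim_patient.events_true)


def _anchor_times(events):
    return [getattr(events, attr) for _, attr in ANCHOR_EVENTS]


def _warped_copy(template: AnnotatedPressureCurve, rng) -> AnnotatedPressureCurve:
    """Time-warp each inter-event segment by a random factor, preserving the
    per-segment pressure shape in normalized time."""
    ev = template.events
    old = [ev.t_avc, ev.t_mvo, ev.t_minp, ev.t_peak_e, ev.t_a_start, ev.t_peak_a, ev.t_mvc]
    gaps = np.diff(old) * rng.uniform(0.7, 1.4, len(old) - 1)
    new = np.concatenate([[old[0]], old[0] + np.cumsum(gaps)])
    dt = template.trace.dt
    n = int(np.ceil((new[-1] - new[0]) / dt))
    t_new = np.linspace(new[0], new[-1], n + 1)  # spans exactly through MVC
    p_new = np.empty_like(t_new)
    for k in range(len(old) - 1):
        seg = (t_new >= new[k] - 1e-12) & (t_new <= new[k + 1] + 1e-12)
        frac = (t_new[seg] - new[k]) / (new[k + 1] - new[k])
        p_new[seg] = template.trace.interp(old[k] + frac * (old[k + 1] - old[k]))
    events = DiastolicEvents(*[float(x) for x in new])
    return AnnotatedPressureCurve(Trace(t_new, p_new, "pressure_mmHg"), events)


class TestBuildReference:
    def test_single_curve_identity(self, template):
        ref = build_reference([template], n_per_segment=100)
        assert ref.n_sources == 1
        times = _anchor_times(template.events)
        for k in range(5):
            ts = times[k] + ref.fractions * (times[k + 1] - times[k])
            np.testing.assert_allclose(
                ref.segments[k], template.trace.interp(ts), atol=1e-9
            )
        np.testing.assert_allclose(ref.anchors, template.trace.interp(times), atol=1e-9)

    def test_offset_pair_averages(self, template):
        shifted = AnnotatedPressureCurve(
            template.trace.with_values(template.trace.v + 2.0), template.events
        )
        ref1 = build_reference([template], 80)
        ref2 = build_reference([template, shifted], 80)
        np.testing.assert_allclose(ref2.segments, ref1.segments + 1.0, atol=1e-9)
        np.testing.assert_allclose(ref2.anchors, ref1.anchors + 1.0, atol=1e-9)

    def test_warped_sources_recover_template(self, template):
        rng = np.random.default_rng(3)
        sources = [_warped_copy(template, rng) for _ in range(8)]
        ref = build_reference(sources, n_per_segment=100)
        assert ref.n_sources == 8
        times = _anchor_times(template.events)
        for k in range(5):
            ts = times[k] + ref.fractions * (times[k + 1] - times[k])
            np.testing.assert_allclose(
                ref.segments[k], template.trace.interp(ts), atol=0.1
            )

    def test_incomplete_curve_excluded(self, template):
        incomplete = AnnotatedPressureCurve(
            template.trace,
            DiastolicEvents(
                t_avc=template.events.t_avc, t_mvo=template.events.t_mvo,
                t_minp=template.events.t_minp, t_peak_e=template.events.t_peak_e,
                t_a_start=None, t_peak_a=None, t_mvc=template.events.t_mvc,
            ),
        )
        ref = build_reference([template, incomplete], 50)
        assert ref.n_sources == 1

    def test_zero_usable_curves_errors(self, template):
        incomplete = AnnotatedPressureCurve(
            template.trace,
            DiastolicEvents(
                t_avc=template.events.t_avc, t_mvo=template.events.t_mvo,
                t_minp=template.events.t_minp, t_peak_e=template.events.t_peak_e,
                t_a_start=None, t_peak_a=None, t_mvc=template.events.t_mvc,
            ),
        )
        with pytest.raises(ReferenceCurveError):
            build_reference([incomplete], 50)

    def test_json_roundtrip(self, template, tmp_path):
        ref = build_reference([template], 60)
        path = tmp_path / "ref.json"
        ref.to_json(path)
        back = ReferenceCurve.from_json(path)
        np.testing.assert_allclose(back.segments, ref.segments)
        np.testing.assert_allclose(back.anchors, ref.anchors)
        assert back.n_sources == ref.n_sources


class TestGeneratePatientCurve:
    def test_identity_map(self, template):
        ref = build_reference([template], 100)
        names = [n for n, _ in ANCHOR_EVENTS]
        pressures = dict(zip(names, ref.anchors))
        out = generate_patient_curve(ref, template.events, pressures, dt=0.002)
        expected = template.trace.interp(out.t)
        assert np.max(np.abs(out.v - expected)) < 0.1

    def test_uniform_offset(self, template):
        ref = build_reference([template], 100)
        names = [n for n, _ in ANCHOR_EVENTS]
        base = dict(zip(names, ref.anchors))
        up = {k: v + 2.0 for k, v in base.items()}
        c0 = generate_patient_curve(ref, template.events, base, dt=0.002)
        c2 = generate_patient_curve(ref, template.events, up, dt=0.002)
        np.testing.assert_allclose(c2.v, c0.v + 2.0, atol=1e-9)

    def test_passes_through_anchor_pressures(self, template):
        ref = build_reference([template], 200)
        names = [n for n, _ in ANCHOR_EVENTS]
        pressures = dict(zip(names, ref.anchors + np.array([1, -0.5, 0.3, 0.8, 1.1, 2.0])))
        out = generate_patient_curve(ref, template.events, pressures, dt=0.001)
        times = _anchor_times(template.events)
        got = out.interp(times)
        np.testing.assert_allclose(got, [pressures[n] for n in names], atol=0.05)

    def test_continuity_at_boundaries(self, template):
        ref = build_reference([template], 100)
        names = [n for n, _ in ANCHOR_EVENTS]
        pressures = dict(zip(names, ref.anchors + 1.5))
        out = generate_patient_curve(ref, template.events, pressures, dt=0.001)
        # no jumps beyond what the local slope explains
        steps = np.abs(np.diff(out.v))
        slope = np.max(np.abs(np.gradient(out.v, out.t)))
        assert np.max(steps) <= slope * out.dt * 2 + 1e-9

    def test_anchor_order_warning(self, template):
        ref = build_reference([template], 50)
        names = [n for n, _ in ANCHOR_EVENTS]
        pressures = dict(zip(names, ref.anchors))
        pressures["min_plv"] = pressures["a_start"] + 5.0  # violates ordering
        with pytest.warns(AnchorOrderWarning):
            generate_patient_curve(ref, template.events, pressures, dt=0.002)

    def test_missing_anchor_pressure_rejected(self, template):
        ref = build_reference([template], 50)
        with pytest.raises(InvalidParameterError, match="missing"):
            generate_patient_curve(ref, template.events, {"mvo": 10.0}, dt=0.002)

    def test_simulator_rms_under_1mmhg(self, sim_patient, template):
        # reference built from the patient's own cohort template; anchors set
        # to the true event pressures must reproduce the true curve closely
        ref = build_reference([template], 150)
        tv = sim_patient.true_values
        names = [n for n, _ in ANCHOR_EVENTS]
        pressures = {
            "mvo": tv["p_mvo_mmhg"],
            "min_plv": tv["min_plv_mmhg"],
            "peak_e": tv["pre_a_mmhg"] - 0.5 * tv["max_dp_e_mmhg"],
            "a_start": tv["pre_a_mmhg"],
            "peak_a": 0.5 * (tv["pre_a_mmhg"] + tv["edp_mmhg"]),
            "mvc": tv["edp_mmhg"],
        }
        out = generate_patient_curve(ref, sim_patient.events_true, pressures, dt=0.002)
        truth = sim_patient.pressure_curve.interp(out.t)
        rms = float(np.sqrt(np.mean((out.v - truth) ** 2)))
        assert rms < 1.0


class TestEventPressureTable:
    EST = PressureEstimates(tau=40.0, min_plv=5.0, pre_a=8.0, p_mvo=13.0, edp=10.0)

    def test_rule_arithmetic(self):
        table = event_pressure_table(self.EST)
        assert table["mvo"] == pytest.approx(13.0)
        assert table["min_plv"] == pytest.approx(5.0)
        assert table["a_start"] == pytest.approx(8.0)
        assert table["mvc"] == pytest.approx(10.0)
        assert table["peak_a"] == pytest.approx(9.0)

    def test_zero_gradients(self):
        est = PressureEstimates(tau=40.0, min_plv=5.0, pre_a=8.0, p_mvo=13.0, edp=8.0)
        table = event_pressure_table(est, dp_at_peak_e=0.0)
        assert table["peak_e"] == pytest.approx(8.0)
        assert table["peak_a"] == pytest.approx(8.0)
        assert table["mvc"] == pytest.approx(8.0)

    def test_missing_edp_fallback_warns(self):
        est = PressureEstimates(tau=40.0, min_plv=5.0, pre_a=8.0, p_mvo=13.0, edp=None)
        with pytest.warns(AnchorOrderWarning):
            table = event_pressure_table(est, max_dp_a=2.0)
        assert table["mvc"] == pytest.approx(10.0)

    def test_order_violation_warns(self):
        est = PressureEstimates(tau=40.0, min_plv=9.0, pre_a=8.0, p_mvo=13.0, edp=10.0)
        with pytest.warns(AnchorOrderWarning):
            event_pressure_table(est)


class TestMeanDiastolicPressure:
    def test_constant(self):
        t = np.linspace(0, 1, 51)
        tr = Trace(t, np.full(51, 8.0), "pressure_mmHg")
        assert mean_diastolic_pressure(tr, 0.1, 0.9) == pytest.approx(8.0)

    def test_linear_ramp_midpoint(self, linear_ramp_pressure):
        assert mean_diastolic_pressure(linear_ramp_pressure, 0.0, 1.0) == pytest.approx(8.0)

    def test_piecewise_halves(self):
        # 4 mmHg first half, 12 mmHg second half, jump centred on the grid:
        # hand trapezoid = 4*0.495 + (4+8)/2*0.01 + (8+12)/2*0.01 + 12*0.485... = 8
        t = np.linspace(0, 1, 101)
        v = np.where(t < 0.5, 4.0, 12.0)
        v[50] = 8.0  # symmetric jump keeps the trapezoid integral exact
        tr = Trace(t, v, "pressure_mmHg")
        assert mean_diastolic_pressure(tr, 0.0, 1.0) == pytest.approx(8.0, abs=1e-9)

    def test_window_outside_span_errors(self, linear_ramp_pressure):
        with pytest.raises(InvalidParameterError):
            mean_diastolic_pressure(linear_ramp_pressure, -0.5, 0.5)

    def test_resampling_invariance(self, template):
        ref = build_reference([template], 100)
        names = [n for n, _ in ANCHOR_EVENTS]
        pressures = dict(zip(names, ref.anchors + 0.7))
        ev = template.events
        vals = []
        for dt in (0.005, 0.001):
            curve = generate_patient_curve(ref, ev, pressures, dt=dt)
            vals.append(mean_diastolic_pressure(curve, ev.t_mvo, ev.t_mvc))
        assert abs(vals[1] - vals[0]) / abs(vals[1]) < 0.005
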