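# lvdp

Non-invasive estimation of left-ventricular (LV) diastolic pressures from
echocardiography-derived inputs, plus reconstruction of the patient-specific
LV diastolic pressure curve.

From a global longitudinal strain (GLS) trace, a mitral inflow velocity
trace and a handful of scalar measurements (systolic cuff pressure, BMI,
left-atrial reservoir strain, end-diastolic/end-systolic volumes), the
toolkit estimates:

- **tau** — the time constant of isovolumic relaxation (exponential decay
  model, decay onset at 65% of systolic pressure, spanning 85% of IVRT),
- **minimum LV pressure** — a fixed linear model in systolic pressure, BMI,
  LA reservoir strain and tau,
- **pre-atrial-contraction LV pressure** (surrogate for mean left-atrial
  pressure) — minimum pressure plus the maximum early-diastolic transmitral
  pressure difference from a simplified Navier–Stokes momentum balance,
- **end-diastolic LV pressure** — pre-A pressure plus the A-wave transmitral
  maximum (plus an optional passive-filling term).

Because tau depends on the pressure at mitral valve opening (pre-A + 5 mmHg),
the system is closed by a fixed-point iteration (`solve_coupled`).

A time-normalized **reference diastolic pressure curve** can be built from
annotated measured pressure recordings and adapted to a patient by shifting
it through the estimated event pressures and remapping it onto the patient's
detected event times.

## Layout

| module | contents |
|---|---|
| `lvdp.traces` | uniform time-series container, CSV round-trip |
| `lvdp.kinematics` | GLS→volume scaling, flow `dV/dt` and acceleration, diastolic event detection, IVRT |
| `lvdp.relaxation` | exponential relaxation model, non-invasive tau estimate, sensitivity scans |
| `lvdp.transmitral` | simplified momentum-balance transmitral pressure difference, per-wave maxima |
| `lvdp.pressures` | linear minimum-pressure model, coupled fixed-point solver, EDP |
| `lvdp.curve` | reference-curve building, patient-specific curve generation, mean diastolic pressure |
| `lvdp.agreement` | Bland–Altman limits of agreement, least-squares correlation |
| `lvdp.cohort` | self-consistent synthetic-patient simulator and recovery reports |
| `lvdp.patient` / `lvdp.pipeline` / `lvdp.cli` | record I/O, end-to-end pipeline, command line |

## CLI

```sh
# synthetic cohort with ground truth
lvdp simulate -n 10 --seed 1 --out cohort/

# estimate pressures for one patient record (manifest.json + trace CSVs)
lvdp estimate cohort/sim000 --out est.json

# build a reference curve from annotated pressure recordings
lvdp reference-build curves/ --out reference.json

# patient-specific diastolic pressure curve
lvdp curve cohort/sim000 --reference reference.json --out curve.csv

# agreement statistics (and optional figure) for an estimated/measured table
lvdp validate table.csv --out agreement.json --plot agreement.png
```

All model constants (the 0.85 IVRT factor, 0.65 systolic-pressure fraction,
+5 mmHg mitral-opening offset, blood density, solver tolerances, delta-Q
convention, curve anchor rules) live in `lvdp.config.ModelConfig`, can be
overridden via `--config config.yaml`, and a hash of the resolved
configuration is embedded in every result JSON.

## Patient record format

`manifest.json`:

```json
{
  "id": "p001",
  "scalars": {"psys_mmhg": 120, "bmi_kg_m2": 25, "lars_pct": 35,
              "edv_ml": 120, "esv_ml": 50},
  "units": {"psys_mmhg": "mmHg", "bmi_kg_m2": "kg/m^2", "lars_pct": "%",
            "edv_ml": "mL", "esv_ml": "mL"},
  "traces": {"strain": "strain.csv", "velocity": "velocity.csv"}
}
```

Trace CSVs have the header `time_s,value` and one uniformly sampled signal
per file. If no Doppler velocity trace is available, a triangular E/A
reconstruction from `e_peak_m_s`/`a_peak_m_s` scalars is used instead.
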