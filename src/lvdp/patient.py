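"""Patient record manifest: validated scalar inputs plus trace file refs.

A patient is a directory (or manifest path) with a ``manifest.json``
declaring the scalar measurements, their units, and relative paths to the
trace CSV files (``time_s,value`` columns).
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, ValidationError

from .errors import UnitError, TraceError
from .traces import Trace

__all__ = ["PatientRecord", "RecordScalars", "load_patient", "save_patient"]

#: Expected unit string per scalar field.
EXPECTED_UNITS = {
    "psys_mmhg": "mmHg",
    "bmi_kg_m2": "kg/m^2",
    "lars_pct": "%",
    "edv_ml": "mL",
    "esv_ml": "mL",
    "hr_bpm": "bpm",
    "e_peak_m_s": "m/s",
    "a_peak_m_s": "m/s",
}


class RecordScalars(BaseModel):
    """Scalar echo/clinical measurements of one patient."""

    model_config = {"frozen": True}

    psys_mmhg: float = Field(gt=0)
    bmi_kg_m2: float = Field(gt=0)
    lars_pct: float = Field(ge=0)
    edv_ml: float = Field(gt=0)
    esv_ml: float = Field(gt=0)
    hr_bpm: float | None = Field(None, gt=0)
    e_peak_m_s: float | None = Field(None, ge=0)
    a_peak_m_s: float | None = Field(None, ge=0)


class PatientRecord(BaseModel):
    """One fully loaded, validated patient."""

    model_config = {"frozen": True, "arbitrary_types_allowed": True}

    id: str
    scalars: RecordScalars
    strain: Trace
    velocity: Trace | None = None
    pressure: Trace | None = None


def _check_units(units: dict, path: Path) -> None:
    for field_name, unit in units.items():
        expected = EXPECTED_UNITS.get(field_name)
        if expected is None:
            raise UnitError(f"{path}: unknown field {field_name!r} in units block")
        if unit != expected:
            raise UnitError(
                f"{path}: field {field_name!r} declares unit {unit!r}, expected {expected!r}"
            )


def load_patient(path: str | Path) -> PatientRecord:
    """Load and validate a patient manifest (JSON file or directory)."""
    path = Path(path)
    manifest_path = path / "manifest.json" if path.is_dir() else path
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    data = json.loads(manifest_path.read_text())
    base = manifest_path.parent

    _check_units(data.get("units", {}), manifest_path)
    try:
        scalars = RecordScalars(**data["scalars"])
    except (KeyError, ValidationError) as exc:
        raise TraceError(f"{manifest_path}: invalid scalars block: {exc}") from exc

    traces_block = data.get("traces", {})
    if "strain" not in traces_block:
        raise TraceError(f"{manifest_path}: a 'strain' trace is required")

    def _load(key: str, kind: str) -> Trace | None:
        rel = traces_block.get(key)
        if rel is None:
            return None
        fp = base / rel
        if not fp.exists():
            raise TraceError(f"{manifest_path}: trace file {fp} does not exist")
        return Trace.from_csv(fp, kind)

    return PatientRecord(
        id=str(data.get("id", manifest_path.parent.name)),
        scalars=scalars,
        strain=_load("strain", "strain_pct"),
        velocity=_load("velocity", "velocity_m_per_s"),
        pressure=_load("pressure", "pressure_mmHg"),
    )


def save_patient(record: PatientRecord, directory: str | Path) -> Path:
    """Write a patient record as manifest + trace CSVs; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    traces = {"strain": "strain.csv"}
    record.strain.to_csv(directory / "strain.csv")
    if record.velocity is not None:
        record.velocity.to_csv(directory / "velocity.csv")
        traces["velocity"] = "velocity.csv"
    if record.pressure is not None:
        record.pressure.to_csv(directory / "pressure.csv")
        traces["pressure"] = "pressure.csv"
    scalars = {k: v for k, v in record.scalars.model_dump().items() if v is not None}
    manifest = {
        "id": record.id,
        "scalars": scalars,
        "units": {k: EXPECTED_UNITS[k] for k in scalars},
        "traces": traces,
    }
    out = directory / "manifest.json"
    out.write_text(json.dumps(manifest, indent=1))
    return out
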