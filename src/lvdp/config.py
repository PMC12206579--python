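"""Model constants and pipeline configuration.

Every tunable of the method lives here with its default value, so that a
result file can embed a hash of the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

#: Pa per mmHg; fixed physical constant, deliberately not configurable.
PA_PER_MMHG = 133.322


class ModelConfig(BaseModel):
    """All method constants and numerical settings."""

    model_config = {"frozen": True}

    # tau estimate
    ivrt_factor: float = Field(0.85, gt=0, description="fraction of IVRT spanned by the exponential decay")
    p0_fraction: float = Field(0.65, gt=0, lt=1, description="decay onset pressure as fraction of systolic pressure")

    # filling-pressure composition
    p_mvo_offset_mmhg: float = Field(5.0, description="P at mitral valve opening minus mean atrial pressure")
    passive_rise_mmhg: float = Field(0.0, ge=0, description="passive-filling pressure rise added to EDP")

    # transmitral gradient
    rho_kg_m3: float = Field(1060.0, gt=900, lt=1200, description="blood density")
    dq_rule: str = Field("onset", description="delta-Q convention: onset | fixed | diff")
    dq_floor_frac: float = Field(0.05, ge=0, description="|delta Q| floor as fraction of max |Q| in window")

    # coupled solver
    solver_tol_mmhg: float = 0.01
    solver_max_iter: int = 10
    init_pre_a_mmhg: float = 10.0

    # kinematics
    smooth_window: int = Field(3, ge=1, description="moving-average window (samples) applied before differentiation")
    avc_rule: str = Field("strain_min", description="AVC surrogate: strain_min | strain_rate_zero")
    minp_rule: str = Field("max_accel", description="min-pressure timing rule during E upstroke")
    q_eps_frac: float = Field(1e-9, ge=0, description="zero-crossing threshold as fraction of max |Q|")
    peak_prominence_frac: float = Field(0.02, ge=0, description="find_peaks prominence as fraction of max Q")

    # pressure-curve construction
    n_per_segment: int = Field(100, ge=2)
    curve_dt_s: float = Field(0.005, gt=0)
    peak_e_anchor_rule: str = Field("convective", description="pressure rule at the peak-E anchor")
    peak_a_anchor_rule: str = Field("midpoint", description="pressure rule at the peak-A anchor")

    # velocity reconstruction
    orifice_area_cm2: float = Field(4.0, gt=0, description="effective mitral orifice area for Q<->v mapping")

    def config_hash(self) -> str:
        """Short stable hash of the resolved configuration."""
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a YAML config; missing keys fall back to defaults."""
    if path is None:
        return ModelConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return ModelConfig(**data)


def save_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)
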