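"""Core diastolic-pressure estimation.

Minimum LV pressure comes from a fixed linear model in systolic pressure,
BMI, atrial reservoir strain and tau.  Pre-atrial-contraction pressure is
minimum pressure plus the maximum early-diastolic transmitral difference.
Because tau itself depends on the mitral-opening pressure (pre-A + 5 mmHg),
the system is closed by a fixed-point iteration.  End-diastolic pressure
adds the A-wave transmitral maximum and an optional passive-filling rise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import DivergenceError, GradientError, MissingAWaveError
from .relaxation import estimate_tau

__all__ = [
    "MinPlvModel",
    "PatientScalars",
    "PressureEstimates",
    "estimate_min_plv",
    "estimate_pre_a",
    "solve_coupled",
    "estimate_edp",
    "fit_min_plv_model",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MinPlvModel:
    """Linear model for minimum LV pressure (mmHg).

    min_PLV = intercept + coef_psys*Psys + coef_bmi*BMI
              + coef_lars*LARS + coef_tau*tau
    """

    intercept: float = -6.885
    coef_psys: float = 0.025   # mmHg per mmHg
    coef_bmi: float = 0.243    # mmHg per kg/m^2
    coef_lars: float = -0.097  # mmHg per %
    coef_tau: float = 0.158    # mmHg per ms

    def predict(self, psys: float, bmi: float, lars: float, tau: float) -> float:
        return (
            self.intercept
            + self.coef_psys * psys
            + self.coef_bmi * bmi
            + self.coef_lars * lars
            + self.coef_tau * tau
        )


class PatientScalars(BaseModel):
    """Scalar inputs of the pressure estimation for one patient."""

    model_config = {"frozen": True}

    psys: float = Field(gt=0, description="systolic cuff pressure, mmHg")
    bmi: float = Field(gt=0, description="body mass index, kg/m^2")
    lars: float = Field(ge=0, description="LA reservoir strain, % (positive)")
    ivrt: float = Field(gt=0, description="isovolumic relaxation time, ms")
    max_dp_e: float = Field(ge=0, description="max transmitral dP, E wave, mmHg")
    max_dp_a: float | None = Field(None, ge=0, description="max transmitral dP, A wave, mmHg")
    passive_rise: float | None = Field(None, ge=0, description="passive-filling pressure rise, mmHg")


@dataclass(frozen=True)
class PressureEstimates:
    """Converged diastolic pressure estimates for one patient."""

    tau: float            # ms
    min_plv: float        # mmHg
    pre_a: float          # mmHg
    p_mvo: float          # mmHg
    edp: float | None = None
    iterations: int = 0
    converged: bool = True
    patient_id: str | None = None

    def as_dict(self) -> dict:
        return {
            "tau_ms": self.tau,
            "min_plv_mmhg": self.min_plv,
            "pre_a_mmhg": self.pre_a,
            "p_mvo_mmhg": self.p_mvo,
            "edp_mmhg": self.edp,
            "iterations": self.iterations,
            "converged": self.converged,
            "patient_id": self.patient_id,
        }


def estimate_min_plv(
    scalars: PatientScalars, tau: float, model: MinPlvModel = MinPlvModel()
) -> float:
    """Minimum LV pressure (mmHg) from the linear model at the given tau (ms)."""
    return model.predict(scalars.psys, scalars.bmi, scalars.lars, tau)


def estimate_pre_a(min_plv: float, max_dp_e: float) -> float:
    """Pre-atrial-contraction pressure: minimum pressure plus E-wave dP max."""
    if max_dp_e < 0:
        raise GradientError(f"max_dp_e must be non-negative, got {max_dp_e}")
    return min_plv + max_dp_e


def solve_coupled(
    scalars: PatientScalars,
    model: MinPlvModel = MinPlvModel(),
    *,
    max_iter: int = 10,
    tol_mmhg: float = 0.01,
    init_pre_a: float = 10.0,
    p_mvo_offset: float = 5.0,
    ivrt_factor: float = 0.85,
    p0_fraction: float = 0.65,
) -> PressureEstimates:
    """Fixed-point solution of the coupled (tau, min P, pre-A, P_MVO) system.

    Each sweep updates, in order::

        p_mvo  <- pre_a + offset
        tau    <- tau(IVRT, Psys, p_mvo)
        min_p  <- linear model at tau
        pre_a  <- min_p + max_dp_e

    and stops when the largest change across the four unknowns is below
    ``tol_mmhg`` (tau compared numerically in ms) or at ``max_iter``.
    """
    p0 = p0_fraction * scalars.psys
    if p0 <= init_pre_a + p_mvo_offset:
        raise DivergenceError(
            f"initial P_MVO {init_pre_a + p_mvo_offset:.2f} mmHg already >= "
            f"{p0_fraction}*Psys = {p0:.2f} mmHg (psys={scalars.psys})"
        )

    pre_a = float(init_pre_a)
    tau = min_plv = p_mvo = np.nan
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        prev = (tau, min_plv, pre_a, p_mvo)
        p_mvo = pre_a + p_mvo_offset
        if p_mvo >= p0:
            raise DivergenceError(
                f"iteration {iterations}: P_MVO {p_mvo:.2f} mmHg reached "
                f"{p0_fraction}*Psys = {p0:.2f} mmHg "
                f"(psys={scalars.psys}, ivrt={scalars.ivrt}, max_dp_e={scalars.max_dp_e})"
            )
        tau = estimate_tau(
            scalars.ivrt, scalars.psys, p_mvo,
            ivrt_factor=ivrt_factor, p0_fraction=p0_fraction,
        )
        min_plv = estimate_min_plv(scalars, tau, model)
        pre_a = estimate_pre_a(min_plv, scalars.max_dp_e)
        log.info(
            "iter %d: tau=%.4f ms, min_plv=%.4f, pre_a=%.4f mmHg",
            iterations, tau, min_plv, pre_a,
        )
        changes = [abs(n - p) for n, p in zip((tau, min_plv, pre_a, p_mvo), prev)
                   if np.isfinite(p)]
        if changes and max(changes) < tol_mmhg:
            converged = True
            break

    return PressureEstimates(
        tau=float(tau),
        min_plv=float(min_plv),
        pre_a=float(pre_a),
        p_mvo=float(pre_a + p_mvo_offset),
        iterations=iterations,
        converged=converged,
    )


def estimate_edp(
    pre_a: float, max_dp_a: float | None, passive_rise: float = 0.0
) -> float:
    """End-diastolic pressure: pre-A + A-wave dP max + passive-filling rise."""
    if max_dp_a is None:
        raise MissingAWaveError("A-wave transmitral maximum unavailable (E/A fusion)")
    if max_dp_a < 0 or passive_rise < 0:
        raise GradientError("max_dp_a and passive_rise must be non-negative")
    return pre_a + max_dp_a + passive_rise


def fit_min_plv_model(
    psys, bmi, lars, tau, min_plv
) -> MinPlvModel:
    """Refit the linear minimum-pressure model on (synthetic) cohort data.

    Ordinary least squares on the four predictors; intended for synthetic
    cohorts, not for re-deriving the published coefficients.
    """
    X = np.column_stack([
        np.ones(len(np.atleast_1d(psys))),
        np.atleast_1d(psys), np.atleast_1d(bmi),
        np.atleast_1d(lars), np.atleast_1d(tau),
    ])
    beta, *_ = np.linalg.lstsq(X, np.atleast_1d(min_plv), rcond=None)
    return MinPlvModel(*[float(b) for b in beta])
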