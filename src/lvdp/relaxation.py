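"""Exponential isovolumic-relaxation model and non-invasive tau estimate.

Pressure during isovolumic relaxation decays as P(t) = P0 * exp(-t/tau).
Non-invasively, the decay is assumed to start at a fixed fraction (65%)
of systolic pressure and to span 85% of the isovolumic relaxation time,
ending at the mitral-valve-opening pressure, which pins down tau:

    tau = 0.85 * IVRT / (ln(0.65 * Psys) - ln(P_MVO))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NonPhysiologicalPressuresError

__all__ = ["RelaxationParams", "weiss_pressure", "estimate_tau", "tau_sensitivity"]


@dataclass(frozen=True)
class RelaxationParams:
    """Exponential decay parameters: onset pressure (mmHg) and tau (ms)."""

    p0: float
    tau: float

    def __post_init__(self) -> None:
        if not self.p0 > 0:
            raise InvalidParameterError(f"p0 must be positive, got {self.p0}")
        if not self.tau > 0:
            raise InvalidParameterError(f"tau must be positive, got {self.tau}")


def weiss_pressure(params: RelaxationParams, t_ms):
    """Pressure (mmHg) of the exponential decay at time t (ms) after onset."""
    t = np.asarray(t_ms, dtype=float)
    p = params.p0 * np.exp(-t / params.tau)
    return float(p) if np.isscalar(t_ms) else p


def estimate_tau(
    ivrt_ms: float,
    psys_mmhg: float,
    p_mvo_mmhg: float,
    *,
    ivrt_factor: float = 0.85,
    p0_fraction: float = 0.65,
) -> float:
    """Non-invasive tau (ms) from IVRT, systolic pressure and P at MVO."""
    if not ivrt_ms > 0:
        raise InvalidParameterError(f"ivrt must be positive, got {ivrt_ms}")
    p0 = p0_fraction * psys_mmhg
    if not 0 < p_mvo_mmhg < p0:
        raise NonPhysiologicalPressuresError(
            f"need 0 < p_mvo < {p0_fraction}*psys ({p0:.2f} mmHg), got {p_mvo_mmhg}"
        )
    return ivrt_factor * ivrt_ms / (np.log(p0) - np.log(p_mvo_mmhg))


def tau_sensitivity(
    base: dict,
    deltas: dict,
    *,
    ivrt_factor: float = 0.85,
    p0_fraction: float = 0.65,
) -> pd.DataFrame:
    """Perturbation scan of the tau estimate.

    Parameters
    ----------
    base : dict
        Valid inputs ``{"ivrt_ms": ..., "psys_mmhg": ..., "p_mvo_mmhg": ...}``.
    deltas : dict
        Mapping input name -> iterable of additive perturbations.

    Returns
    -------
    DataFrame with columns ``input_name, delta, tau_base_ms,
    tau_perturbed_ms, delta_tau_ms, valid``.  Perturbations that cross the
    physiological boundary are flagged invalid rather than raising.
    """
    kw = dict(ivrt_factor=ivrt_factor, p0_fraction=p0_fraction)
    tau_base = estimate_tau(base["ivrt_ms"], base["psys_mmhg"], base["p_mvo_mmhg"], **kw)
    rows = []
    for name, dvals in deltas.items():
        if name not in base:
            raise InvalidParameterError(f"unknown input {name!r}")
        for d in np.atleast_1d(dvals):
            pert = dict(base)
            pert[name] = pert[name] + float(d)
            try:
                tau_p = estimate_tau(
                    pert["ivrt_ms"], pert["psys_mmhg"], pert["p_mvo_mmhg"], **kw
                )
                rows.append((name, float(d), tau_base, tau_p, tau_p - tau_base, True))
            except (NonPhysiologicalPressuresError, InvalidParameterError):
                rows.append((name, float(d), tau_base, np.nan, np.nan, False))
    return pd.DataFrame(
        rows,
        columns=[
            "input_name", "delta", "tau_base_ms",
            "tau_perturbed_ms", "delta_tau_ms", "valid",
        ],
    )
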