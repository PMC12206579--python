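"""Bland-Altman agreement and least-squares correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError

__all__ = ["AgreementStats", "bland_altman", "linfit", "agreement_report"]


@dataclass(frozen=True)
class AgreementStats:
    """Bias, limits of agreement and (optionally) regression of two series."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int
    slope: float | None = None
    intercept: float | None = None
    r: float | None = None
    r2: float | None = None

    def as_dict(self) -> dict:
        return {
            "bias": self.bias, "sd": self.sd,
            "loa_low": self.loa_low, "loa_high": self.loa_high, "n": self.n,
            "slope": self.slope, "intercept": self.intercept,
            "r": self.r, "r2": self.r2,
        }


def bland_altman(estimated, measured) -> AgreementStats:
    """Bias and 95% limits of agreement of estimated minus measured.

    The SD uses the sample (n-1) denominator; limits are bias +/- 1.96*SD.
    """
    est = np.asarray(estimated, float)
    mea = np.asarray(measured, float)
    if est.shape != mea.shape or est.ndim != 1:
        raise InsufficientDataError("estimated and measured must be equal-length 1-D")
    if est.size < 2:
        raise InsufficientDataError(f"need n >= 2, got {est.size}")
    d = est - mea
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        bias=bias, sd=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n=int(est.size),
    )


def linfit(x, y) -> tuple[float, float, float, float]:
    """Ordinary least-squares fit of y on x: (slope, intercept, r, r2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise InsufficientDataError(f"need n >= 3, got {x.size}")
    if np.var(x) == 0:
        raise DegenerateFitError("zero variance in x")
    if np.var(y) == 0:
        return 0.0, float(y[0]), 0.0, 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.rvalue**2)


def agreement_report(estimated, measured) -> AgreementStats:
    """Bland-Altman stats plus the regression of estimated on measured."""
    ba = bland_altman(estimated, measured)
    try:
        slope, intercept, r, r2 = linfit(measured, estimated)
    except (DegenerateFitError, InsufficientDataError):
        slope = intercept = r = r2 = None
    return AgreementStats(
        bias=ba.bias, sd=ba.sd, loa_low=ba.loa_low, loa_high=ba.loa_high,
        n=ba.n, slope=slope, intercept=intercept, r=r, r2=r2,
    )
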