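"""Dose-response fitting and drug-combination synergy analysis.

The median-effect model describes a dose-response curve by

    fa/(1 − fa) = (D/Dm)^m,

with ``fa`` the fraction affected (1 − viability), ``Dm`` the
median-effect dose (the IC50) and ``m`` the curve's sigmoidicity.  Its
log-linearisation gives the fit; inverting it gives the dose producing
any effect level.  For a two-agent mixture at a fixed dose ratio the
(mutually exclusive) combination index at effect level ``fa`` is

    CI = d_a/D_x,a + d_b/D_x,b,

where ``(d_a, d_b)`` are the mixture components producing ``fa`` and
``D_x,·`` the single-agent doses producing the same effect.  By the
convention used here CI < 0.9 is synergy, 0.9–1.1 additivity, and
> 1.1 antagonism.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "DoseResponse",
    "MedianEffectFit",
    "SynergyResult",
    "median_effect_fit",
    "ic50",
    "dose_for_effect",
    "combination_index",
    "classify_ci",
]


@dataclass
class DoseResponse:
    """Dose (J/m² for UV, µM for drugs) vs viability fraction."""

    dose: np.ndarray
    viability: np.ndarray     # fraction of untreated control
    agent: str = ""

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if len(self.dose) != len(self.viability):
            raise ValueError("dose/viability length mismatch")
        if np.any(self.dose < 0):
            raise ValueError("doses must be non-negative")
        if np.any(np.diff(self.dose) <= 0):
            raise ValueError("doses must be strictly increasing")

    @property
    def fraction_affected(self) -> np.ndarray:
        return 1.0 - self.viability


@dataclass
class MedianEffectFit:
    """Fitted median-effect parameters."""

    dm: float          # median-effect dose (IC50), dose units
    m: float           # sigmoidicity (slope)
    r_squared: float
    agent: str = ""


@dataclass
class SynergyResult:
    ci: float
    effect_level: float
    classification: str


def median_effect_fit(dr: DoseResponse) -> MedianEffectFit:
    """Fit (Dm, m) by regressing log10(fa/(1−fa)) on log10(D).

    Points at fa = 0 or fa = 1 (and zero dose) carry no information for
    the log-linear form; they are excluded with a warning.  At least 3
    usable points are required.
    """
    fa = dr.fraction_affected
    usable = (dr.dose > 0) & (fa > 0) & (fa < 1)
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} point(s) with fa in {{0,1}} "
                      "or zero dose from the median-effect fit")
    if np.sum(usable) < 3:
        raise ValueError("need at least 3 points with 0 < fa < 1")
    x = np.log10(dr.dose[usable])
    y = np.log10(fa[usable] / (1.0 - fa[usable]))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError("non-positive median-effect slope: response does "
                         "not increase with dose")
    dm = 10.0 ** (-res.intercept / m)
    return MedianEffectFit(dm=dm, m=m, r_squared=float(res.rvalue ** 2),
                           agent=dr.agent)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing fraction affected ``fa``: Dm·(fa/(1−fa))^(1/m)."""
    if not (0.0 < fa < 1.0):
        raise ValueError("effect level must be strictly between 0 and 1")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def ic50(dr: DoseResponse, method: str = "median-effect") -> float:
    """Dose at 50 % viability.

    ``median-effect`` returns the fitted Dm; ``interpolation`` returns
    the log-linear crossing of viability = 0.5 between the bracketing
    observations.
    """
    if method == "median-effect":
        return median_effect_fit(dr).dm
    if method != "interpolation":
        raise ValueError(f"unknown method {method!r}")
    v = dr.viability
    below = np.flatnonzero(v <= 0.5)
    if len(below) == 0 or below[0] == 0:
        raise ValueError("viability does not cross 0.5 from above")
    lo = int(below[0])      # first point at or below 50 % viability
    hi = lo - 1             # bracketing point above 50 %
    d1, d2 = dr.dose[hi], dr.dose[lo]
    v1, v2 = v[hi], v[lo]
    if d1 <= 0:
        # linear in dose when the bracket includes zero dose
        return float(d1 + (v1 - 0.5) * (d2 - d1) / (v1 - v2))
    t = (v1 - 0.5) / (v1 - v2)
    return float(10 ** (math.log10(d1) + t * (math.log10(d2) - math.log10(d1))))


def classify_ci(ci: float, synergy_below: float = 0.9,
                antagonism_above: float = 1.1) -> str:
    """CI < 0.9 synergy, 0.9 ≤ CI ≤ 1.1 additivity, CI > 1.1 antagonism."""
    if ci < synergy_below:
        return "synergy"
    if ci > antagonism_above:
        return "antagonism"
    return "additivity"


def combination_index(single_a: MedianEffectFit, single_b: MedianEffectFit,
                      combo: DoseResponse, ratio: Tuple[float, float],
                      effect_level: float = 0.95,
                      combo_fit: Optional[MedianEffectFit] = None
                      ) -> SynergyResult:
    """Mutually-exclusive combination index at one effect level.

    ``combo`` holds total mixture dose vs viability at the fixed dose
    ratio ``ratio = (parts_a, parts_b)``.  The mixture's median-effect
    fit gives the total dose producing ``effect_level``; splitting it by
    the ratio and comparing with the single-agent doses for the same
    effect yields CI.  CI_95 (the default) is the index at fa = 0.95.
    """
    if not (0.0 < effect_level < 1.0):
        raise ValueError("effect level must be strictly between 0 and 1")
    ra, rb = float(ratio[0]), float(ratio[1])
    if ra < 0 or rb < 0 or ra + rb == 0:
        raise ValueError("invalid dose ratio")
    fit_combo = combo_fit if combo_fit is not None else median_effect_fit(combo)
    d_total = dose_for_effect(fit_combo, effect_level)
    d_a = d_total * ra / (ra + rb)
    d_b = d_total * rb / (ra + rb)
    dx_a = dose_for_effect(single_a, effect_level)
    dx_b = dose_for_effect(single_b, effect_level)
    ci = d_a / dx_a + d_b / dx_b
    return SynergyResult(ci=float(ci), effect_level=effect_level,
                         classification=classify_ci(ci))
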