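"""Fluorescence-quenching titration analysis.

Tryptophan fluorescence of a peptide (fixed concentration, 20 µM in the
reference protocol) is quenched by incremental ligand additions.  With
a 1:1 saturable binding event the intensity drop follows

    ΔFI = ΔFI_max · K_b [L] / (1 + K_b [L]),

whose double-reciprocal (linear) form

    1/ΔFI = 1/ΔFI_max + 1/(K_b · ΔFI_max · [L])

yields the binding constant K_b from the fitted slope and intercept:
K_b = intercept/slope, K_d = 1/K_b.  The apparent bimolecular quenching
rate constant K_Q = K_b/τ0 (fluorophore lifetime τ0 = 1e−8 s) diagnoses
the mechanism: values above the maximum scatter limit of ~2×10¹⁰
M⁻¹s⁻¹ indicate static quenching via a non-fluorescent ground-state
complex.

Inner-filter attenuation is corrected empirically with a parallel
tryptophan-solution control titrated with the same ligand: the control
intensity ratio divides out the non-binding attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TitrationSeries",
    "QuenchFit",
    "inner_filter_correct",
    "fit_binding",
    "quenching_rate",
    "classify_quenching",
    "SCATTER_LIMIT",
]

#: maximum scatter quenching constant of quenchers with biopolymers, M⁻¹s⁻¹
SCATTER_LIMIT = 2e10


@dataclass
class TitrationSeries:
    """One titration: ligand concentrations (µM) vs emission intensity."""

    ligand_conc: np.ndarray          # µM, strictly increasing, first may be 0
    intensity: np.ndarray            # arbitrary units
    peptide_conc: float = 20.0       # µM
    control_intensity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.control_intensity is not None:
            self.control_intensity = np.asarray(self.control_intensity,
                                                dtype=float)
            if len(self.control_intensity) != len(self.ligand_conc):
                raise ValueError("control series length mismatch")
        if len(self.ligand_conc) != len(self.intensity):
            raise ValueError("concentration/intensity length mismatch")
        if np.any(self.ligand_conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.ligand_conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class QuenchFit:
    """Titration-derived binding parameters."""

    dfi_max: float     # a.u.
    k_b: float         # M⁻¹
    k_d: float         # M
    k_q: float         # M⁻¹s⁻¹
    tau0: float        # s
    r_squared: float
    quenching_class: str   # "static" or "below-scatter-limit"


def inner_filter_correct(series: TitrationSeries) -> TitrationSeries:
    """Divide out ligand-induced attenuation of the non-binding control.

    ``corrected_i = intensity_i × control_0 / control_i`` where
    ``control_0`` is the ligand-free control reading.  Idempotent when
    the control is flat (no inner-filter effect).
    """
    if series.control_intensity is None:
        raise ValueError("inner-filter correction needs a control series")
    control = series.control_intensity
    if np.any(control <= 0):
        raise ValueError("control intensities must be positive")
    corrected = series.intensity * (control[0] / control)
    return replace(series, intensity=corrected,
                   control_intensity=np.full_like(control, control[0]))


def fit_binding(series: TitrationSeries, tau0: float = 1e-8) -> QuenchFit:
    """Estimate (ΔFI_max, K_b, K_d, K_Q) by the double-reciprocal fit.

    Ordinary least squares of 1/ΔFI against 1/[L] over the nonzero-
    ligand points, with ΔFI_i = FI_0 − FI_i and concentrations in M.
    Needs a ligand-free reference point and, for an overdetermined fit,
    at least 3 nonzero-ligand points (exactly 2 give the exact line).
    """
    conc_uM = series.ligand_conc
    fi = series.intensity
    if conc_uM[0] != 0:
        raise ValueError("series must start with a ligand-free reference")
    fi0 = fi[0]
    mask = conc_uM > 0
    dfi = fi0 - fi[mask]
    conc_M = conc_uM[mask] * 1e-6
    if len(conc_M) < 2:
        raise ValueError("need at least 2 nonzero-ligand points")
    if np.any(dfi <= 0):
        raise ValueError("all fitted points must show quenching (ΔFI > 0)")
    x = 1.0 / conc_M
    y = 1.0 / dfi
    if np.allclose(dfi, dfi[0], rtol=1e-12, atol=0.0):
        raise ValueError("fit inconsistent with saturable binding: "
                         "ΔFI shows no concentration dependence")
    res = stats.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    if slope <= 0 or intercept <= 0:
        raise ValueError("fit inconsistent with saturable binding")
    dfi_max = 1.0 / intercept
    k_b = intercept / slope
    k_q = quenching_rate(k_b, tau0)
    return QuenchFit(
        dfi_max=dfi_max, k_b=k_b, k_d=1.0 / k_b, k_q=k_q, tau0=tau0,
        r_squared=float(res.rvalue ** 2) if len(x) > 2 else 1.0,
        quenching_class=classify_quenching(k_q))


def fit_binding_nonlinear(series: TitrationSeries, tau0: float = 1e-8,
                          depletion: bool = True) -> QuenchFit:
    """Depletion-corrected nonlinear fit of the 1:1 binding isotherm.

    Alternative to the double-reciprocal fit that drops the free-ligand
    ≈ total-ligand approximation: the free ligand concentration solves
    the 1:1 mass-balance quadratic against the fixed peptide
    concentration.
    """
    from scipy.optimize import curve_fit

    conc_uM = series.ligand_conc
    fi = series.intensity
    if conc_uM[0] != 0:
        raise ValueError("series must start with a ligand-free reference")
    fi0 = fi[0]
    mask = conc_uM > 0
    dfi = fi0 - fi[mask]
    lt = conc_uM[mask] * 1e-6
    pt = series.peptide_conc * 1e-6

    def model(ltot, dfi_max, k_b):
        if depletion:
            kd = 1.0 / k_b
            b = ltot + pt + kd
            bound = (b - np.sqrt(b * b - 4 * ltot * pt)) / 2.0
            free = ltot - bound
        else:
            free = ltot
        return dfi_max * k_b * free / (1.0 + k_b * free)

    p0 = (float(dfi.max()) * 1.2, 1.0 / (lt.mean()))
    popt, _ = curve_fit(model, lt, dfi, p0=p0, maxfev=20000)
    dfi_max, k_b = float(popt[0]), float(popt[1])
    resid = dfi - model(lt, *popt)
    ss_tot = float(np.sum((dfi - dfi.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    k_q = quenching_rate(k_b, tau0)
    return QuenchFit(dfi_max=dfi_max, k_b=k_b, k_d=1.0 / k_b, k_q=k_q,
                     tau0=tau0, r_squared=r2,
                     quenching_class=classify_quenching(k_q))


def bootstrap_kb(series: TitrationSeries, n_boot: int = 1000,
                 seed: int = 0) -> float:
    """Bootstrap standard deviation of K_b (resampling titration points)."""
    rng = np.random.default_rng(seed)
    conc = series.ligand_conc
    fi = series.intensity
    nz = np.flatnonzero(conc > 0)
    values: List[float] = []
    for _ in range(n_boot):
        pick = np.sort(rng.choice(nz, size=len(nz), replace=True))
        if len(np.unique(conc[pick])) < 2:
            continue
        sub_conc = np.concatenate(([0.0], conc[pick]))
        sub_fi = np.concatenate(([fi[0]], fi[pick]))
        # collapse duplicate concentrations by averaging intensities
        sc, si = [], []
        for c in np.unique(sub_conc):
            sc.append(c)
            si.append(float(np.mean(sub_fi[sub_conc == c])))
        if len(sc) < 3:
            continue
        try:
            fit = fit_binding(TitrationSeries(
                ligand_conc=np.array(sc), intensity=np.array(si),
                peptide_conc=series.peptide_conc))
            values.append(fit.k_b)
        except ValueError:
            continue
    if len(values) < 2:
        raise ValueError("bootstrap produced too few successful fits")
    return float(np.std(values, ddof=1))


def quenching_rate(k_a: float, tau0: float = 1e-8) -> float:
    """Bimolecular quenching rate constant K_Q = K_A/τ0 (M⁻¹s⁻¹)."""
    if k_a < 0:
        raise ValueError("K_A must be non-negative")
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    return k_a / tau0


def classify_quenching(k_q: float, scatter_limit: float = SCATTER_LIMIT) -> str:
    """Classify the quenching mechanism from K_Q.

    Strictly above the scatter limit implies a ground-state complex
    ("static"); at or below it the diagnosis is "below-scatter-limit".
    """
    if k_q < 0:
        raise ValueError("K_Q must be non-negative")
    return "static" if k_q > scatter_limit else "below-scatter-limit"
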