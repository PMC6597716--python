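"""Two-state thermal unfolding fits of CD melt curves.

Ellipticity-vs-temperature scans are fit to the two-state van't Hoff model
with linear native/unfolded baselines,

    theta(T) = (1-f)(aN + bN*T) + f(aU + bU*T)
    f(T)     = 1 / (1 + exp(dG_unf / (R*T_K)))
    dG_unf   = dHvH * (1 - T_K / Tm_K)        (dCp = 0)

yielding the midpoint Tm and the van't Hoff unfolding enthalpy. Thermophilic
protein melts are frequently irreversible and asymmetric, so a model-free
fallback (the extremum of a Savitzky-Golay smoothed derivative) is also
provided.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .constants import CONST, celsius_to_kelvin

__all__ = ["MeltCurve", "MeltFit", "fit_melt", "delta_tm",
           "derivative_tm", "read_melt_csv", "write_melt_csv",
           "fraction_unfolded_curve"]


@dataclass
class MeltCurve:
    enzyme: str
    temperatures_C: list[float]
    ellipticities_mdeg: list[float]
    scan_rate_C_min: float = 1.0
    truth: dict | None = None

    def validate(self) -> None:
        T = np.asarray(self.temperatures_C)
        if len(T) < 20:
            raise ValueError("melt curve needs >= 20 points")
        if len(T) != len(self.ellipticities_mdeg):
            raise ValueError("length mismatch")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltFit:
    enzyme: str
    Tm_C: float
    Tm_se: float
    dHvH_kJ: float
    dHvH_se: float
    baselines: tuple[float, float, float, float]  # aN, bN, aU, bU
    converged: bool
    no_transition: bool = False
    rss: float = math.nan

    def validate(self, curve: MeltCurve | None = None) -> None:
        if self.converged and curve is not None:
            if not (min(curve.temperatures_C) <= self.Tm_C
                    <= max(curve.temperatures_C)):
                raise ValueError("converged Tm outside the data range")


def _two_state(T_C, Tm_C, dHvH_kJ, aN, bN, aU, bU):
    T_K = T_C + 273.15
    Tm_K = Tm_C + 273.15
    dg = dHvH_kJ * 1000.0 * (1.0 - T_K / Tm_K)
    f = 1.0 / (1.0 + np.exp(np.clip(dg / (CONST.R * T_K), -500, 500)))
    return (1.0 - f) * (aN + bN * T_C) + f * (aU + bU * T_C)


def _noise_estimate(theta: np.ndarray) -> float:
    """Robust per-point noise sigma from second differences.

    For iid Gaussian noise the second difference has sd sigma*sqrt(6) and
    median absolute value sigma*sqrt(6)*0.6745.
    """
    return float(np.median(np.abs(np.diff(theta, 2)))) / (0.6745 * 6 ** 0.5) + 1e-12


def derivative_tm(curve: MeltCurve, window: int = 11, order: int = 3) -> float:
    """Model-free midpoint: extremum of the smoothed d(theta)/dT."""
    T = np.asarray(curve.temperatures_C)
    theta = np.asarray(curve.ellipticities_mdeg)
    window = min(window if window % 2 else window + 1, len(T) - (len(T) + 1) % 2)
    smooth = savgol_filter(theta, window, min(order, window - 1))
    dtheta = np.gradient(smooth, T)
    return float(T[np.argmax(np.abs(dtheta))])


def fit_melt(curve: MeltCurve) -> MeltFit:
    """Least-squares two-state fit; flat curves give a no-transition result."""
    curve.validate()
    T = np.asarray(curve.temperatures_C, dtype=float)
    theta = np.asarray(curve.ellipticities_mdeg, dtype=float)

    # iid noise alone spans ~6 sigma over a typical scan length, so a real
    # transition must clear a 10-sigma bar
    span = float(theta.max() - theta.min())
    if span < 10.0 * _noise_estimate(theta) or span == 0.0:
        return MeltFit(curve.enzyme, math.nan, math.nan, math.nan, math.nan,
                       (math.nan,) * 4, converged=False, no_transition=True)

    tm0 = derivative_tm(curve)
    k = max(3, len(T) // 10)
    bN0, aN0 = np.polyfit(T[:k], theta[:k], 1)
    bU0, aU0 = np.polyfit(T[-k:], theta[-k:], 1)
    p0 = [tm0, 400.0, aN0, bN0, aU0, bU0]
    lo = [T.min(), 10.0, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [T.max(), 5000.0, np.inf, np.inf, np.inf, np.inf]
    try:
        popt, pcov = curve_fit(_two_state, T, theta, p0=p0, bounds=(lo, hi),
                               maxfev=40000)
    except RuntimeError:
        return MeltFit(curve.enzyme, math.nan, math.nan, math.nan, math.nan,
                       (math.nan,) * 4, converged=False)
    perr = np.sqrt(np.diag(pcov))
    rss = float(np.sum((theta - _two_state(T, *popt)) ** 2))
    fit = MeltFit(curve.enzyme, float(popt[0]), float(perr[0]),
                  float(popt[1]), float(perr[1]),
                  tuple(float(x) for x in popt[2:]),
                  converged=bool(np.all(np.isfinite(perr))), rss=rss)
    fit.validate(curve)
    return fit


def delta_tm(mutant: MeltFit, reference: MeltFit) -> tuple[float, float]:
    """Tm(mutant) - Tm(reference) in degC, with propagated standard error."""
    if not (mutant.converged and reference.converged):
        raise ValueError("both fits must be converged")
    d = mutant.Tm_C - reference.Tm_C
    se = math.sqrt(mutant.Tm_se ** 2 + reference.Tm_se ** 2)
    return d, se


def fraction_unfolded_curve(fit: MeltFit, temperatures_C) -> np.ndarray:
    T_K = np.asarray(temperatures_C, dtype=float) + 273.15
    Tm_K = celsius_to_kelvin(fit.Tm_C)
    dg = fit.dHvH_kJ * 1000.0 * (1.0 - T_K / Tm_K)
    return 1.0 / (1.0 + np.exp(np.clip(dg / (CONST.R * T_K), -500, 500)))


def read_melt_csv(path, enzyme: str = "unknown") -> MeltCurve:
    df = pd.read_csv(path)
    return MeltCurve(enzyme=enzyme,
                     temperatures_C=df["temperature_C"].tolist(),
                     ellipticities_mdeg=df["ellipticity_mdeg"].tolist())


def write_melt_csv(curve: MeltCurve, path) -> None:
    pd.DataFrame({"temperature_C": curve.temperatures_C,
                  "ellipticity_mdeg": curve.ellipticities_mdeg}).to_csv(
        path, index=False)
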