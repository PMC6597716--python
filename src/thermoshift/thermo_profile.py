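"""Transition-state-theory energy profiles along the reaction coordinate.

Three states are tracked relative to the initial (free enzyme + ligands)
state: the Michaelis complex (MS) and the transition state (TS).

    dG_act = -R*T*ln(kcat*h/(kB*T))        (Eyring, MS -> TS)
    dG_m   = R*T*ln(Km/c0)                 (association convention, IS -> MS)
    dG_T   = dG_act + dG_m                 (IS -> TS)
    dH_act = -R * d ln kcat / d(1/T) - R*T_ref   (Arrhenius slope)
    dH_m   = +R * d ln Km / d(1/T)         (van't Hoff slope, association)
    -T*dS_X = dG_X - dH_X                  for X in {act, m, T}

Sign convention: read literally, reporting dG_m = -RT ln Km for a sub-molar
Km yields a large positive "binding" energy and breaks the expected equality
of dG_T between a thermophilic enzyme and its mesophilic homologue at 25
degC. The default "association" convention (dG_m = RT ln(Km/c0), dH_m = +R
times the van't Hoff slope) restores thermodynamic meaning; "as_printed"
flips the signs of both binding terms for comparison with literature tables
that use the literal form. Both are exposed and audited side by side.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import CONST, PhysicalConstants

__all__ = [
    "ThermoProfile", "TemperatureSeries", "RegressionResult",
    "eyring_dg_act", "binding_dg", "dg_total",
    "arrhenius_dh_act", "vanthoff_dhm",
    "assemble_profile", "compare_profiles", "convention_audit",
    "profile_to_tsv",
]

CONVENTIONS = ("association", "as_printed")


@dataclass(frozen=True)
class TemperatureSeries:
    """(T, value) pairs for kcat (s^-1) or Km (M) across temperatures."""

    temperatures_K: tuple[float, ...]
    values: tuple[float, ...]

    def validate(self, minimum: int = 3) -> None:
        T = np.asarray(self.temperatures_K)
        v = np.asarray(self.values)
        if len(T) != len(v):
            raise ValueError("length mismatch")
        if len(set(self.temperatures_K)) < 2:
            raise ValueError("need at least 2 distinct temperatures")
        if len(set(self.temperatures_K)) < minimum:
            import warnings
            warnings.warn("fewer than 3 distinct temperatures; slope is "
                          "poorly constrained", stacklevel=3)
        if np.any(T <= 0) or np.any(v <= 0):
            raise ValueError("temperatures and values must be positive")


@dataclass(frozen=True)
class RegressionResult:
    value_kJ: float  # the derived enthalpy
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class ThermoProfile:
    """State energies (kJ/mol) relative to the initial state at T_ref."""

    enzyme: str
    T_ref: float  # Kelvin
    dG_act: float
    dG_m: float
    dG_T: float
    dH_act: float
    dH_m: float
    dH_T: float
    mTdS_act: float
    mTdS_m: float
    mTdS_T: float
    convention: str = "association"

    def validate(self, tol: float = 1e-9) -> None:
        if abs(self.dG_T - self.dG_act - self.dG_m) > tol:
            raise ValueError("dG_T != dG_act + dG_m")
        if abs(self.dH_T - self.dH_act - self.dH_m) > tol:
            raise ValueError("dH_T != dH_act + dH_m")
        for g, h, s in [(self.dG_act, self.dH_act, self.mTdS_act),
                        (self.dG_m, self.dH_m, self.mTdS_m),
                        (self.dG_T, self.dH_T, self.mTdS_T)]:
            if abs(s - (g - h)) > tol:
                raise ValueError("-TdS != dG - dH")

    def as_array(self) -> np.ndarray:
        return np.array([self.dG_act, self.dG_m, self.dG_T,
                         self.dH_act, self.dH_m, self.dH_T,
                         self.mTdS_act, self.mTdS_m, self.mTdS_T])


def eyring_dg_act(kcat_per_s: float, T_kelvin: float,
                  constants: PhysicalConstants = CONST) -> float:
    """Activation free energy (kJ/mol) from the turnover number."""
    if kcat_per_s <= 0 or T_kelvin <= 0:
        raise ValueError("kcat and T must be positive")
    return (-constants.R * T_kelvin
            * math.log(kcat_per_s * constants.h / (constants.k_B * T_kelvin))
            / 1000.0)


def binding_dg(Km_M: float, T_kelvin: float, convention: str = "association",
               constants: PhysicalConstants = CONST) -> float:
    """Coenzyme-binding free energy (kJ/mol) from the Michaelis constant."""
    if Km_M <= 0:
        raise ValueError("Km must be positive")
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    val = constants.R * T_kelvin * math.log(Km_M / constants.c_standard) / 1000.0
    return val if convention == "association" else -val


def dg_total(dG_act: float, dG_m: float) -> float:
    """Free energy from initial state to transition state."""
    return dG_act + dG_m


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def arrhenius_dh_act(series: TemperatureSeries, T_ref: float = 298.15,
                     constants: PhysicalConstants = CONST) -> RegressionResult:
    """Activation enthalpy from the Arrhenius slope of ln kcat vs 1/T.

    dH_act = -R * slope - R * T_ref, with the -RT term evaluated at the
    reference temperature of the profile.
    """
    series.validate()
    T = np.asarray(series.temperatures_K, dtype=float)
    slope, intercept, r2 = _ols(1.0 / T, np.log(np.asarray(series.values)))
    dh = (-constants.R * slope - constants.R * T_ref) / 1000.0
    return RegressionResult(value_kJ=dh, slope=slope, intercept=intercept,
                            r_squared=r2)


def vanthoff_dhm(series: TemperatureSeries, convention: str = "association",
                 constants: PhysicalConstants = CONST) -> RegressionResult:
    """Binding enthalpy from the van't Hoff slope of ln Km vs 1/T."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    series.validate()
    T = np.asarray(series.temperatures_K, dtype=float)
    km = np.asarray(series.values) / constants.c_standard
    slope, intercept, r2 = _ols(1.0 / T, np.log(km))
    dh = constants.R * slope / 1000.0
    if convention == "as_printed":
        dh = -dh
    return RegressionResult(value_kJ=dh, slope=slope, intercept=intercept,
                            r_squared=r2)


def assemble_profile(enzyme: str, kcat_per_s: float, Km_M: float,
                     arrhenius: RegressionResult, vanthoff: RegressionResult,
                     T_ref: float = 298.15, convention: str = "association",
                     constants: PhysicalConstants = CONST) -> ThermoProfile:
    """All nine state energies at T_ref; invariants hold by construction."""
    dg_act = eyring_dg_act(kcat_per_s, T_ref, constants)
    dg_m = binding_dg(Km_M, T_ref, convention, constants)
    dg_t = dg_total(dg_act, dg_m)
    dh_act = arrhenius.value_kJ
    dh_m = vanthoff.value_kJ
    dh_t = dh_act + dh_m
    profile = ThermoProfile(
        enzyme=enzyme, T_ref=T_ref, dG_act=dg_act, dG_m=dg_m, dG_T=dg_t,
        dH_act=dh_act, dH_m=dh_m, dH_T=dh_t,
        mTdS_act=dg_act - dh_act, mTdS_m=dg_m - dh_m, mTdS_T=dg_t - dh_t,
        convention=convention)
    profile.validate()
    return profile


def profile_from_constants(enzyme: str, temps_C, kcats_per_s, kms_M,
                           T_ref: float = 298.15,
                           convention: str = "association",
                           constants: PhysicalConstants = CONST) -> ThermoProfile:
    """Convenience: profile straight from per-temperature kcat/Km triples.

    kcat and Km at T_ref are interpolated exactly when T_ref is one of the
    measured temperatures (the usual case: profiles are reported at 25 degC).
    """
    temps_K = tuple(float(t) + 273.15 for t in temps_C)
    if not any(abs(t - T_ref) < 1e-9 for t in temps_K):
        raise ValueError("T_ref must be one of the measured temperatures")
    i_ref = int(np.argmin(np.abs(np.asarray(temps_K) - T_ref)))
    arr = arrhenius_dh_act(TemperatureSeries(temps_K, tuple(kcats_per_s)),
                           T_ref, constants)
    vh = vanthoff_dhm(TemperatureSeries(temps_K, tuple(kms_M)), convention,
                      constants)
    return assemble_profile(enzyme, kcats_per_s[i_ref], kms_M[i_ref],
                            arr, vh, T_ref, convention, constants)


def compare_profiles(profiles: list[ThermoProfile]) -> dict:
    """Pairwise RMS distance over the nine state energies.

    Returns the distance matrix plus, for every profile, the name of its
    nearest other profile (the "pattern similarity" classification).
    """
    if len({p.convention for p in profiles}) > 1:
        raise ValueError("profiles mix sign conventions")
    if len({round(p.T_ref, 6) for p in profiles}) > 1:
        raise ValueError("profiles mix reference temperatures")
    names = [p.enzyme for p in profiles]
    arrays = np.stack([p.as_array() for p in profiles])
    n = len(profiles)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = math.sqrt(float(np.mean((arrays[i] - arrays[j]) ** 2)))
    nearest = {}
    for i, name in enumerate(names):
        others = [(dist[i, j], names[j]) for j in range(n) if j != i]
        nearest[name] = min(others)[1] if others else None
    return {"names": names, "distance_matrix": dist, "nearest": nearest}


def convention_audit(kcat_tt: float, km_tt: float, kcat_other: float,
                     km_other: float, T_ref: float = 298.15,
                     constants: PhysicalConstants = CONST) -> dict:
    """|dG_T difference| between two enzymes under both sign conventions."""
    out = {}
    for conv in CONVENTIONS:
        g1 = dg_total(eyring_dg_act(kcat_tt, T_ref, constants),
                      binding_dg(km_tt, T_ref, conv, constants))
        g2 = dg_total(eyring_dg_act(kcat_other, T_ref, constants),
                      binding_dg(km_other, T_ref, conv, constants))
        out[conv] = {"dG_T_a": g1, "dG_T_b": g2, "gap": abs(g1 - g2)}
    return out


def profile_to_tsv(profile: ThermoProfile) -> str:
    """Three-state (IS/MS/TS) levels for plotting reaction-coordinate diagrams."""
    lines = ["state\tdG_kJ\tdH_kJ\tmTdS_kJ",
             "IS\t0.0\t0.0\t0.0",
             f"MS\t{profile.dG_m:.1f}\t{profile.dH_m:.1f}\t{profile.mTdS_m:.1f}",
             f"TS\t{profile.dG_T:.1f}\t{profile.dH_T:.1f}\t{profile.mTdS_T:.1f}"]
    return "\n".join(lines) + "\n"
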