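"""Michaelis-Menten fitting, specific activities and relative-value tables.

Steady-state initial velocities v(S) for a single varied ligand (NAD+ or
D-3-IPM) are fit by unweighted nonlinear least squares to

    v = Vmax * S / (Km + S),        kcat = Vmax / [E]

with standard errors taken from the covariance of the fit. Relative-value
tables mirror the convention of reporting each enzyme's constant alongside
its fold-change versus a reference enzyme, rounded to two significant
figures.
"""
from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "KineticSeries",
    "MMFit",
    "RelativeTable",
    "fit_mm",
    "specific_activity",
    "relative_table",
    "fold_change_report",
    "round_sigfigs",
    "load_printed_constants",
    "read_series_csv",
    "write_series_csv",
]


@dataclass
class KineticSeries:
    """One enzyme x one temperature x one varied-ligand titration."""

    enzyme: str
    temperature_C: float
    varied_ligand: str  # "NAD" or "D-3-IPM"
    fixed_ligand_conc_M: float
    enzyme_conc_M: float
    concentrations_M: list[float] = field(default_factory=list)
    velocities_per_s: list[float] = field(default_factory=list)
    # ground truth carried along by the synthetic generator for recovery tests
    truth: dict | None = None

    def validate(self) -> None:
        conc = np.asarray(self.concentrations_M, dtype=float)
        if len(conc) < 5:
            raise ValueError("kinetic series needs >= 5 points")
        if len(conc) != len(self.velocities_per_s):
            raise ValueError("concentration/velocity length mismatch")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.allclose(conc, conc[0]):
            raise ValueError("concentrations must not all be equal")
        if self.enzyme_conc_M <= 0:
            raise ValueError("enzyme concentration must be positive")


@dataclass
class MMFit:
    enzyme: str
    temperature_C: float
    varied_ligand: str
    kcat_per_s: float
    kcat_se: float
    Km_M: float
    Km_se: float
    converged: bool
    rss: float
    n_points: int

    def validate(self) -> None:
        if self.converged and (self.kcat_per_s <= 0 or self.Km_M <= 0):
            raise ValueError("converged fit must have positive kcat and Km")


def _mm(S: np.ndarray, Vmax: float, Km: float) -> np.ndarray:
    return Vmax * S / (Km + S)


def fit_mm(series: KineticSeries) -> MMFit:
    """Fit kcat and Km for one titration by nonlinear least squares.

    Initialisation: Vmax0 = 1.2 * max(v); Km0 = concentration nearest the
    half-maximal velocity. Parameters are bounded positive. A Km estimate
    pinned near the parameter bounds is reported as non-converged.
    """
    series.validate()
    S = np.asarray(series.concentrations_M, dtype=float)
    v = np.asarray(series.velocities_per_s, dtype=float)

    if np.max(v) <= 0:
        return MMFit(series.enzyme, series.temperature_C, series.varied_ligand,
                     math.nan, math.nan, math.nan, math.nan, False,
                     float(np.sum(v**2)), len(S))
    # normalise both axes so the optimizer works near unit scale; Vmax and Km
    # otherwise differ by many orders of magnitude and stall the fit
    v_scale = float(np.max(np.abs(v)))
    s_scale = float(np.median(S))
    vmax0 = 1.2 * float(np.max(v)) / v_scale
    km0 = float(S[np.argmin(np.abs(v / v_scale - vmax0 / 2.4))]) / s_scale
    lo, hi = [1e-9, 1e-7], [1e9, 1e9]
    try:
        popt, pcov = curve_fit(_mm, S / s_scale, v / v_scale, p0=[vmax0, km0],
                               bounds=(lo, hi), maxfev=20000)
        converged = np.all(np.isfinite(pcov))
    except RuntimeError:
        return MMFit(series.enzyme, series.temperature_C, series.varied_ligand,
                     math.nan, math.nan, math.nan, math.nan, False,
                     math.nan, len(S))
    vmax, km = popt[0] * v_scale, popt[1] * s_scale
    if popt[1] <= 1.01 * lo[1] or popt[1] >= 0.99 * hi[1]:
        warnings.warn(f"Km for {series.enzyme} hit a parameter bound", stacklevel=2)
        converged = False
    perr = (np.sqrt(np.diag(pcov)) * np.array([v_scale, s_scale])
            if np.all(np.isfinite(pcov)) else np.array([math.nan] * 2))
    rss = float(np.sum((v - _mm(S, vmax, km)) ** 2))
    E = series.enzyme_conc_M
    return MMFit(
        enzyme=series.enzyme,
        temperature_C=series.temperature_C,
        varied_ligand=series.varied_ligand,
        kcat_per_s=vmax / E,
        kcat_se=float(perr[0]) / E,
        Km_M=float(km),
        Km_se=float(perr[1]),
        converged=bool(converged),
        rss=rss,
        n_points=len(S),
    )


def specific_activity(slope_dA340_per_min: float, path_cm: float = 1.0,
                      extinction_M_cm: float = 6220.0,
                      assay_volume_L: float = 1e-3,
                      protein_mass_mg: float = 1.0) -> float:
    """Specific activity in U/mg from an A340 time course slope.

    One unit (U) is 1 umol NADH formed per minute; NADH epsilon_340 defaults
    to 6220 M^-1 cm^-1.
    """
    for name, val in [("slope", slope_dA340_per_min), ("path", path_cm),
                      ("extinction", extinction_M_cm),
                      ("volume", assay_volume_L), ("mass", protein_mass_mg)]:
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    umol_per_min = slope_dA340_per_min / (extinction_M_cm * path_cm) * assay_volume_L * 1e6
    return umol_per_min / protein_mass_mg


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (half away from zero)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exponent - sig + 1)
    return math.floor(abs(x) / factor + 0.5) * factor * math.copysign(1.0, x)


@dataclass
class RelativeTable:
    reference: str
    rows: dict[str, tuple[float, float]]  # enzyme -> (value, relative 2 s.f.)

    def validate(self) -> None:
        if abs(self.rows[self.reference][1] - 1.0) > 1e-12:
            raise ValueError("reference relative value must be 1.0")


def relative_table(values: dict[str, float], reference: str) -> RelativeTable:
    """Fold-change of each enzyme's constant versus the reference enzyme.

    Relative values are rounded to two significant figures, matching the
    parenthesized convention of kinetic-constant tables.
    """
    if reference not in values:
        raise KeyError(f"reference enzyme {reference!r} not in table")
    ref = values[reference]
    if ref <= 0 or any(v <= 0 for v in values.values()):
        raise ValueError("all values must be positive")
    rows = {enz: (v, round_sigfigs(v / ref, 2)) for enz, v in values.items()}
    table = RelativeTable(reference=reference, rows=rows)
    table.validate()
    return table


def fold_change_report(tables_by_temperature: dict[float, dict[str, float]],
                       reference: str) -> pd.DataFrame:
    """kcat fold-changes per enzyme across temperatures.

    Returns a DataFrame with one row per enzyme, one column per temperature,
    plus a ``monotone_decreasing`` flag: True when the fold-change does not
    increase with temperature (mutations helping most at low temperature).
    """
    temps = sorted(tables_by_temperature)
    enzymes = set.intersection(*(set(t) for t in tables_by_temperature.values()))
    records = {}
    for enz in sorted(enzymes):
        folds = [tables_by_temperature[t][enz] / tables_by_temperature[t][reference]
                 for t in temps]
        records[enz] = folds + [all(a >= b - 1e-12 for a, b in zip(folds, folds[1:]))]
    return pd.DataFrame.from_dict(
        records, orient="index",
        columns=[f"fold_{t:g}C" for t in temps] + ["monotone_decreasing"])


def load_printed_constants() -> pd.DataFrame:
    """Kinetic constants (with printed fold-changes) shipped with the package."""
    with importlib.resources.files("thermoshift.data").joinpath(
            "printed_constants.csv").open() as fh:
        return pd.read_csv(fh)


SERIES_COLUMNS = ["enzyme", "temperature_C", "ligand", "conc_M",
                  "enzyme_conc_M", "fixed_conc_M", "velocity_per_s"]


def write_series_csv(series_list: list[KineticSeries], path) -> None:
    rows = []
    for s in series_list:
        for c, v in zip(s.concentrations_M, s.velocities_per_s):
            rows.append([s.enzyme, s.temperature_C, s.varied_ligand, c,
                         s.enzyme_conc_M, s.fixed_ligand_conc_M, v])
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def read_series_csv(path) -> list[KineticSeries]:
    df = pd.read_csv(path)
    out = []
    keys = ["enzyme", "temperature_C", "ligand", "enzyme_conc_M", "fixed_conc_M"]
    for (enz, T, lig, E, fixed), grp in df.groupby(keys, sort=False):
        out.append(KineticSeries(
            enzyme=enz, temperature_C=float(T), varied_ligand=lig,
            fixed_ligand_conc_M=float(fixed), enzyme_conc_M=float(E),
            concentrations_M=grp["conc_M"].tolist(),
            velocities_per_s=grp["velocity_per_s"].tolist()))
    return out
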