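"""Stability-activity trade-off regression.

Across natural enzyme homologues, the logarithm of low-temperature specific
activity tends to fall linearly with the unfolding midpoint temperature.
The trade-off line is fit by ordinary least squares of log10(activity at
25 degC) on Tm over the wild-type points; engineered mutants are then scored
by their vertical deviation from that line (positive = more active than the
trade-off predicts at their stability).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TradeoffPoint", "TradeoffFit", "fit_tradeoff",
           "deviation_from_line", "read_points_csv", "fit_to_dataframe"]


@dataclass(frozen=True)
class TradeoffPoint:
    enzyme: str
    specific_activity_U_per_mg: float  # at 25 degC
    Tm_C: float
    group: str = "wild-type"  # or "mutant"

    def __post_init__(self):
        if self.specific_activity_U_per_mg <= 0:
            raise ValueError("activity must be positive (log scale)")


@dataclass(frozen=True)
class TradeoffFit:
    slope: float  # log10(U/mg) per degC
    intercept: float
    r: float  # Pearson correlation, carries the sign of the slope
    slope_se: float
    residuals: dict[str, float]  # enzyme -> vertical residual, log10 units
    n: int


def fit_tradeoff(points: list[TradeoffPoint]) -> TradeoffFit:
    """OLS of log10(specific activity) on Tm with Pearson correlation."""
    if len(points) < 3:
        raise ValueError("need at least 3 points to fit the trade-off line")
    tm = np.array([p.Tm_C for p in points])
    log_act = np.log10([p.specific_activity_U_per_mg for p in points])
    res = stats.linregress(tm, log_act)
    residuals = {p.enzyme: float(la - (res.slope * t + res.intercept))
                 for p, t, la in zip(points, tm, log_act)}
    return TradeoffFit(slope=float(res.slope), intercept=float(res.intercept),
                       r=float(res.rvalue), slope_se=float(res.stderr),
                       residuals=residuals, n=len(points))


def deviation_from_line(fit: TradeoffFit, point: TradeoffPoint) -> float:
    """Observed log10(activity) minus the trade-off line prediction."""
    predicted = fit.slope * point.Tm_C + fit.intercept
    return float(math.log10(point.specific_activity_U_per_mg) - predicted)


def read_points_csv(path) -> list[TradeoffPoint]:
    df = pd.read_csv(path)
    return [TradeoffPoint(enzyme=r.enzyme,
                          specific_activity_U_per_mg=float(r.specific_activity_U_per_mg),
                          Tm_C=float(r.Tm_C), group=str(r.group))
            for r in df.itertuples()]


def fit_to_dataframe(fit: TradeoffFit, points: list[TradeoffPoint]) -> pd.DataFrame:
    rows = []
    for p in points:
        rows.append({"enzyme": p.enzyme, "Tm_C": p.Tm_C,
                     "specific_activity_U_per_mg": p.specific_activity_U_per_mg,
                     "group": p.group,
                     "deviation_log10": deviation_from_line(fit, p)})
    return pd.DataFrame(rows)
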