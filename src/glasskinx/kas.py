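"""Isoconversional Kissinger–Akahira–Sunose (KAS) analysis.

For each conversion level α, the temperatures T_α reached at several heating
rates β obey

    ln(β / T_α²) = −Ea/(R·T_α) + ln(A·R / (Ea·g(α))),

so an ordinary least-squares line of ln(β/T²) on 1/T gives the apparent
activation energy (Ea = −slope·R) and an intercept from which the apparent
frequency factor follows once a reaction model is chosen. Here the
Avrami–Erofeev model g(α) = [−ln(1−α)]^(1/n) is used, with the exponent n
taken from the isothermal Avrami fit of the matching condition.

Units are fixed throughout: β in K/min, T in K, Ea in J/mol, A in 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .types import R_GAS, ConversionCurve

__all__ = [
    "IsoTemperatureTable",
    "KASPoint",
    "AncovaResult",
    "extract_iso_temperatures",
    "KASRegression",
    "kas_regression",
    "frequency_factor",
    "ancova_compare",
    "kas_summary",
]


@dataclass(frozen=True)
class IsoTemperatureTable:
    """T(α, β) in Kelvin: rows follow ``alphas``, columns follow ``rates``."""

    alphas: tuple[float, ...]
    rates_K_min: tuple[float, ...]
    T_K: np.ndarray  # shape (len(alphas), len(rates))

    def row(self, alpha: float) -> np.ndarray:
        idx = self.alphas.index(alpha)
        return self.T_K[idx]


def extract_iso_temperatures(
    curves: Sequence[ConversionCurve], alphas: Sequence[float]
) -> IsoTemperatureTable:
    """Invert each conversion curve at the requested α levels.

    Monotone piecewise-linear interpolation of T(α); raises (naming the
    heating rate) if a level falls outside a curve's range.
    """
    alphas = tuple(float(a) for a in alphas)
    rates = tuple(float(c.heating_rate_K_min) for c in curves)
    T = np.empty((len(alphas), len(curves)))
    for j, c in enumerate(curves):
        T[:, j] = np.asarray(c.temperature_at(list(alphas))) + 273.15
    return IsoTemperatureTable(alphas=alphas, rates_K_min=rates, T_K=T)


@dataclass(frozen=True)
class KASPoint:
    alpha: float
    Ea_J_mol: float
    se_Ea_J_mol: float
    intercept: float
    se_intercept: float
    r2: float
    lnA: float = float("nan")


class KASRegression(BaseEstimator):
    """OLS of ln(β/T²) on 1/T for one conversion level.

    ``fit(rates_K_min, T_K)`` stores ``Ea_``, ``se_Ea_`` (J/mol),
    ``intercept_``, ``se_intercept_`` (ln units) and ``r2_``.
    """

    def fit(self, rates_K_min, T_K) -> "KASRegression":
        beta = np.asarray(rates_K_min, float).ravel()
        T = np.asarray(T_K, float).ravel()
        if len(beta) != len(T):
            raise ValueError("rates and temperatures must align")
        if len(beta) < 3:
            raise ValueError("KAS regression needs at least 3 heating rates")
        x = 1.0 / T
        if np.ptp(x) < 1e-12:
            raise ValueError("degenerate design: all temperatures equal")
        y = np.log(beta / T**2)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.Ea_ = -self.slope_ * R_GAS
        self.se_Ea_ = float(res.bse[1]) * R_GAS
        self.se_intercept_ = float(res.bse[0])
        self.r2_ = float(res.rsquared)
        self.x_ = x
        self.y_ = y
        return self


def kas_regression(table: IsoTemperatureTable, alpha: float) -> KASPoint:
    """KAS line for one conversion level of an iso-temperature table."""
    reg = KASRegression().fit(table.rates_K_min, table.row(alpha))
    return KASPoint(
        alpha=alpha, Ea_J_mol=reg.Ea_, se_Ea_J_mol=reg.se_Ea_,
        intercept=reg.intercept_, se_intercept=reg.se_intercept_, r2=reg.r2_,
    )


def frequency_factor(Ea_J_mol: float, intercept: float, alpha: float,
                     n: float) -> float:
    """Apparent frequency factor ln A (A in 1/min) from a KAS intercept.

    With the Avrami–Erofeev model g(α) = [−ln(1−α)]^(1/n):
    ln A = intercept + ln(Ea·g(α)/R).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n <= 0:
        raise ValueError("Avrami exponent must be > 0")
    if Ea_J_mol <= 0:
        raise ValueError("Ea must be > 0")
    g = (-np.log1p(-alpha)) ** (1.0 / n)
    return float(intercept + np.log(Ea_J_mol * g / R_GAS))


@dataclass(frozen=True)
class AncovaResult:
    """Nested-F comparison of two regression lines.

    ``p_slope`` tests the rate×group interaction in the full model;
    ``p_intercept`` tests the group effect under a common slope.
    """

    p_slope: float
    p_intercept: float
    df_resid_full: int
    df_resid_common: int
    degenerate: bool = False


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), len(y) - rank


def ancova_compare(
    group1: tuple[np.ndarray, np.ndarray],
    group2: tuple[np.ndarray, np.ndarray],
) -> AncovaResult:
    """ANCOVA on two (x, y) point sets.

    F-tests of nested linear models: slope homogeneity from dropping the
    interaction in ``y ~ x * group``; intercept (group) effect from dropping
    the group term in ``y ~ x + group``. Identical groups with zero residual
    variance are flagged degenerate with p-values of 1.
    """
    from scipy.stats import f as f_dist

    x1, y1 = (np.asarray(a, float).ravel() for a in group1)
    x2, y2 = (np.asarray(a, float).ravel() for a in group2)
    if len(x1) < 3 or len(x2) < 3:
        raise ValueError("each group needs at least 3 points")
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(len(x1)), np.ones(len(x2))])

    ones = np.ones_like(x)
    X_full = np.column_stack([ones, x, g, x * g])
    X_common = np.column_stack([ones, x, g])
    X_single = np.column_stack([ones, x])
    if np.linalg.matrix_rank(X_full) < 4:
        raise ValueError("singular ANCOVA design")

    rss_full, df_full = _ols_rss(X_full, y)
    rss_common, df_common = _ols_rss(X_common, y)
    rss_single, df_single = _ols_rss(X_single, y)
    if rss_full <= 1e-12 * max(1.0, float(y @ y)):
        return AncovaResult(1.0, 1.0, df_full, df_common, degenerate=True)

    F_slope = (rss_common - rss_full) / 1 / (rss_full / df_full)
    p_slope = float(f_dist.sf(F_slope, 1, df_full))
    F_int = (rss_single - rss_common) / 1 / (rss_common / df_common)
    p_intercept = float(f_dist.sf(F_int, 1, df_common))
    return AncovaResult(p_slope, p_intercept, df_full, df_common)


def kas_summary(
    curves_by_condition: dict[str, Sequence[ConversionCurve]],
    alphas: Sequence[float],
    n_by_condition: dict[str, float],
    ancova_pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-condition KAS table across α, with pairwise ANCOVA p-values.

    Returns a tidy DataFrame with columns alpha, condition, Ea_kJ_mol,
    se_Ea_kJ_mol, intercept, se_intercept, lnA, r2, p_slope, p_intercept
    (the p-values attach to the second condition of each compared pair).
    """
    tables = {
        cond: extract_iso_temperatures(curves, alphas)
        for cond, curves in curves_by_condition.items()
    }
    regs: dict[tuple[str, float], KASRegression] = {}
    rows = []
    for cond, table in tables.items():
        for alpha in table.alphas:
            reg = KASRegression().fit(table.rates_K_min, table.row(alpha))
            regs[(cond, alpha)] = reg
            lnA = frequency_factor(reg.Ea_, reg.intercept_, alpha,
                                   n_by_condition[cond])
            rows.append({
                "alpha": alpha, "condition": cond,
                "Ea_kJ_mol": reg.Ea_ / 1e3, "se_Ea_kJ_mol": reg.se_Ea_ / 1e3,
                "intercept": reg.intercept_, "se_intercept": reg.se_intercept_,
                "lnA": lnA, "r2": reg.r2_,
                "p_slope": np.nan, "p_intercept": np.nan,
            })
    df = pd.DataFrame(rows)
    if ancova_pairs is None and len(tables) == 2:
        ancova_pairs = [tuple(tables.keys())]
    for pair in ancova_pairs or []:
        c1, c2 = pair
        for alpha in alphas:
            r1, r2_ = regs[(c1, alpha)], regs[(c2, alpha)]
            res = ancova_compare((r1.x_, r1.y_), (r2_.x_, r2_.y_))
            m = (df["condition"] == c2) & (df["alpha"] == alpha)
            df.loc[m, "p_slope"] = res.p_slope
            df.loc[m, "p_intercept"] = res.p_intercept
    return df
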