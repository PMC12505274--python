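"""Closed-form thermodynamics, classical nucleation theory and dissolution
corrections.

Small, unit-explicit helpers: entropy of fusion from the molar fusion
enthalpy and melting point, the critical nucleus radius
r* = 2σTm / (ΔHv (Tm − T)) with ΔHv the volumetric fusion enthalpy, the
first-point concentration correction for in-situ UV dissolution traces, and
replicate summaries for shake-flask solubility.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .types import DissolutionTrace, InvalidParameterError

__all__ = [
    "entropy_of_fusion",
    "CntInput",
    "critical_radius",
    "molar_to_volumetric",
    "correct_concentration",
    "solubility_summary",
]


def entropy_of_fusion(dHf_kJ_mol: float, Tm_C: float) -> float:
    """Entropy of fusion ΔSf = ΔHf / Tm, in J/(mol K).

    ``dHf_kJ_mol`` in kJ/mol, ``Tm_C`` in °C (converted to K internally).
    """
    if dHf_kJ_mol <= 0:
        raise InvalidParameterError("enthalpy of fusion must be > 0")
    Tm_K = Tm_C + 273.15
    if Tm_K <= 0:
        raise InvalidParameterError("melting temperature below absolute zero")
    return dHf_kJ_mol * 1e3 / Tm_K


@dataclass(frozen=True)
class CntInput:
    """Inputs for the critical-radius formula.

    sigma: crystal/amorphous interfacial specific surface energy, J/m².
    Tm_K: melting temperature, K. dHf_vol_J_m3: enthalpy of fusion per unit
    volume, J/m³. T_K: temperature of interest, K (< Tm).
    """

    sigma_J_m2: float
    Tm_K: float
    dHf_vol_J_m3: float
    T_K: float

    def __post_init__(self) -> None:
        for name in ("sigma_J_m2", "Tm_K", "dHf_vol_J_m3", "T_K"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.T_K >= self.Tm_K:
            raise InvalidParameterError("critical radius requires T < Tm")


def molar_to_volumetric(dHf_kJ_mol: float, molar_volume_cm3_mol: float) -> float:
    """Convert a molar fusion enthalpy (kJ/mol) to J/m³ given the molar
    volume in cm³/mol."""
    if molar_volume_cm3_mol <= 0:
        raise InvalidParameterError("molar volume must be > 0")
    return dHf_kJ_mol * 1e3 / (molar_volume_cm3_mol * 1e-6)


def critical_radius(
    inp: CntInput, sigma_of_T: Callable[[float], float] | None = None
) -> float:
    """Classical-nucleation-theory critical radius r* in meters.

    r* = 2σTm / (ΔHv (Tm − T)); nuclei larger than r* can keep growing.
    ``sigma_of_T`` optionally replaces the constant σ with a temperature
    dependence evaluated at ``inp.T_K``.
    """
    sigma = sigma_of_T(inp.T_K) if sigma_of_T is not None else inp.sigma_J_m2
    if sigma <= 0:
        raise InvalidParameterError("sigma must be > 0")
    return 2.0 * sigma * inp.Tm_K / (inp.dHf_vol_J_m3 * (inp.Tm_K - inp.T_K))


def correct_concentration(trace: DissolutionTrace) -> DissolutionTrace:
    """First-point correction of an in-situ UV dissolution trace.

    corrected(t) = nominal / measured(first point) × measured(t), so the
    corrected first point equals the nominal medium concentration exactly
    and all timepoint ratios are preserved.
    """
    first = trace.conc_ug_mL[0]
    if first <= 0:
        raise ValueError("first measured concentration must be > 0")
    factor = trace.nominal_ug_mL / first
    return replace(
        trace,
        conc_ug_mL=trace.conc_ug_mL * factor,
        meta={**trace.meta, "first_point_correction": factor},
    )


def solubility_summary(replicates: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation of solubility replicates (μg/mL)."""
    reps = np.asarray(replicates, float)
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates")
    return float(reps.mean()), float(reps.std(ddof=1))
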