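"""Simulators for every input the analysis pipeline consumes.

The generators emulate the four experiment families of the study design:

* quasi-isothermal modulated DSC — reversing heat capacity decaying from the
  amorphous plateau to the crystalline plateau as the sample crystallizes,
  following the modified Avrami law ``f(t) = 100 · 0.9^((t/t10)^n)``;
* nonisothermal DSC — heat-flow thermograms with a heat-capacity step at the
  glass transition, an Avrami–Erofeev cold-crystallization exotherm driven by
  Arrhenius kinetics along the temperature program, and two overlapping
  melting endotherms for the two polymorphs;
* powder diffraction — sums of split pseudo-Voigt peaks on a polynomial
  background;
* dissolution — a supersaturation rise-and-decay concentration trace with an
  optional first-point probe bias.

Thermograms use the endothermic-up sign convention: the ``Cp·β`` heating
baseline and melting peaks are positive, the crystallization exotherm is a
negative excursion.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .profiles import SplitPVPeak
from .types import (
    ArrheniusAvramiKinetics,
    DissolutionTrace,
    InvalidParameterError,
    ModulatedTrace,
    NoiseSpec,
    PXRDPattern,
    TemperatureProgram,
    ThermoParams,
    Thermogram,
)

__all__ = [
    "avrami_fraction",
    "isothermal_t10",
    "nonisothermal_conversion",
    "simulate_isothermal_trace",
    "simulate_nonisothermal_thermogram",
    "simulate_pxrd",
    "simulate_dissolution",
    "DEFAULT_KINETICS",
]


def avrami_fraction(t_min: np.ndarray | float, t10: float, n: float) -> np.ndarray:
    """Residual amorphous fraction (%) under the modified Avrami law.

    ``f(t) = 100 · 0.9^((t/t10)^n)`` — equal to 90 at ``t = t10`` for every
    parameter pair.
    """
    if t10 <= 0:
        raise InvalidParameterError("t10 must be > 0")
    t = np.asarray(t_min, dtype=float)
    return 100.0 * 0.9 ** ((t / t10) ** n)


def simulate_isothermal_trace(
    t10: float,
    n: float,
    cp_amorphous: float = 2.1,
    cp_crystal: float = 1.5,
    duration: float = 120.0,
    dt: float = 0.01,
    noise: NoiseSpec = NoiseSpec(),
    hold_temp_C: float = 100.0,
) -> ModulatedTrace:
    """Reversing heat capacity during isothermal crystallization.

    The noise-free trace is
    ``Cp(t) = cp_crystal + (cp_amorphous − cp_crystal) · 0.9^((t/t10)^n)``,
    i.e. excess heat capacity over the crystal proportional to the amorphous
    fraction. ``t10`` and ``duration`` in minutes, heat capacities in J/(g K).
    """
    if t10 <= 0 or dt <= 0:
        raise InvalidParameterError("t10 and dt must be > 0")
    if duration <= t10:
        raise InvalidParameterError("duration must exceed t10")
    if cp_amorphous <= cp_crystal:
        raise InvalidParameterError("cp_amorphous must exceed cp_crystal")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    f = avrami_fraction(t, t10, n) / 100.0
    cp = cp_crystal + (cp_amorphous - cp_crystal) * f
    return ModulatedTrace(
        t, noise.apply(cp), hold_temp_C,
        meta={"t10": t10, "n": n, "noise_sd": noise.sd, "seed": noise.seed},
    )


# ---------------------------------------------------------------------------
# nonisothermal kinetics


def _u0(kin: ArrheniusAvramiKinetics) -> float:
    if kin.alpha0 == 0:
        return 0.0
    return (-np.log1p(-kin.alpha0)) ** (1.0 / kin.n)


def isothermal_t10(kin: ArrheniusAvramiKinetics, T_C: float) -> float:
    """Closed-form time (min) to 10% conversion at constant temperature.

    The Avrami–Erofeev rate law linearizes under ``u = [−ln(1−α)]^(1/n)``
    (``du/dt = k``), so ``t10 = ((−ln 0.9)^(1/n) − u0) / k(T)``.
    """
    k = float(kin.rate_constant(T_C + 273.15))
    u_target = (-np.log(0.9)) ** (1.0 / kin.n)
    u0 = _u0(kin)
    if u0 >= u_target:
        raise InvalidParameterError("alpha0 already exceeds 10% conversion")
    return (u_target - u0) / k


def nonisothermal_conversion(
    kin: ArrheniusAvramiKinetics,
    program: TemperatureProgram,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the Avrami–Erofeev conversion along a temperature program.

    Works in the transformed variable ``u = [−ln(1−α)]^(1/n)`` whose ODE is
    simply ``du/dt = k(T(t))`` (adaptively integrated); this removes the
    rate singularity at α = 0 so ``alpha0 = 0`` needs no seeding floor.

    Returns ``(t_min, T_C, alpha, dalpha_dt_per_min)``.
    """
    if t_eval is None:
        t_eval = program.time_grid()
    t_eval = np.asarray(t_eval, dtype=float)

    def du_dt(t, u):
        T_K = program.temperature(t) + 273.15
        return [kin.rate_constant(T_K)]

    sol = solve_ivp(
        du_dt, (t_eval[0], t_eval[-1]), [_u0(kin)], t_eval=t_eval,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:  # pragma: no cover - LSODA on a smooth 1-D ODE
        raise RuntimeError(f"conversion integration failed: {sol.message}")
    u = np.clip(sol.y[0], 0.0, None)
    alpha = 1.0 - np.exp(-(u ** kin.n))
    T_C = np.asarray(program.temperature(t_eval), dtype=float)
    k = np.asarray(kin.rate_constant(T_C + 273.15), dtype=float)
    with np.errstate(invalid="ignore"):
        dalpha_dt = np.exp(-(u ** kin.n)) * kin.n * u ** (kin.n - 1.0) * k
    dalpha_dt = np.nan_to_num(dalpha_dt, nan=0.0)
    return t_eval, T_C, alpha, dalpha_dt


#: Default cold-crystallization kinetics of the well-nucleated glass
#: (40 days at −20 °C): activation energy 134 kJ/mol and Avrami exponent 4.7
#: as estimated for that condition; the frequency factor is calibrated once,
#: on the noise-free curve, so that the extrapolated onset at 1 °C/min falls
#: at 107.4 °C; alpha0 represents the preformed nuclei.
DEFAULT_KINETICS = ArrheniusAvramiKinetics(
    Ea_J_mol=134.0e3, lnA=39.4102, n=4.7, alpha0=1e-4
)


def simulate_nonisothermal_thermogram(
    kin: ArrheniusAvramiKinetics = DEFAULT_KINETICS,
    program: TemperatureProgram | None = None,
    thermo: ThermoParams = ThermoParams(),
    sample_mass_mg: float = 3.0,
    noise: NoiseSpec = NoiseSpec(),
    ratio_II_I: float = 7.4,
    cp_glass_J_gK: float = 1.2,
    tg_width_C: float = 1.5,
    melt_fwhm_C: tuple[float, float] = (1.0, 1.6),
    max_dT_C: float = 0.02,
) -> Thermogram:
    """Simulate a DSC heating thermogram of the annealed glass.

    The heat flow (mW/mg, endothermic up) is the sum of

    * a sensible-heat baseline ``Cp(T)·β`` with a sigmoidal Cp step of height
      ΔCp centered at Tg (width ``tg_width_C``),
    * the cold-crystallization exotherm ``−ΔHc·dα/dt`` with α integrated
      along the program (total exotherm area = ΔHc·Δα),
    * two melting endotherms at Tm_II and Tm_I modeled as split pseudo-Voigt
      peaks in temperature with areas set by the form II / form I enthalpy
      ratio ``ratio_II_I`` and scaled by the crystallized fraction.

    If conversion has not reached 0.999 by 5 °C below Tm_II the output is
    flagged ``incomplete_crystallization`` (melting areas then scale down
    accordingly).
    """
    if program is None:
        program = TemperatureProgram.single_ramp(25.0, 160.0, 1.0)
    if program.T_min_C > thermo.Tg_C or program.T_max_C < thermo.Tm_I_C:
        raise InvalidParameterError(
            "temperature program must cover Tg through Tm_I "
            f"(program spans {program.T_min_C}-{program.T_max_C} °C)"
        )
    if ratio_II_I <= 0:
        raise InvalidParameterError("ratio_II_I must be > 0")

    t, T_C, alpha, dalpha_dt = nonisothermal_conversion(
        kin, program, t_eval=program.time_grid(max_dT_C=max_dT_C)
    )
    beta_K_s = np.asarray(program.rate(t), dtype=float) / 60.0

    # sensible-heat baseline with the glass-transition Cp step
    cp = cp_glass_J_gK + thermo.dCp_J_gK * expit((T_C - thermo.Tg_C) / tg_width_C)
    hf = cp * beta_K_s

    # cold-crystallization exotherm, J/g total = dHc * (alpha_end - alpha0)
    hf = hf - thermo.dHc_J_g * dalpha_dt / 60.0

    # crystallized fraction available for melting
    before_melt = T_C <= thermo.Tm_II_C - 5.0
    alpha_final = float(alpha[before_melt][-1]) if before_melt.any() else float(alpha[-1])
    incomplete = alpha_final < 0.999

    # melting doublet: per-gram fusion enthalpy split by the form ratio
    x_II = ratio_II_I / (1.0 + ratio_II_I)
    dHf_total = alpha_final * (
        x_II * thermo.dHf_II_J_g + (1.0 - x_II) * thermo.dHf_I_J_g
    )
    areas = {
        "II": dHf_total * x_II,
        "I": dHf_total * (1.0 - x_II),
    }
    centers = {"II": thermo.Tm_II_C, "I": thermo.Tm_I_C}
    for form, area in areas.items():
        # Gaussian limit of the split profile: asymmetric via the two FWHMs,
        # with tails that decay fast enough not to leak into the exotherm
        peak = SplitPVPeak(
            center=centers[form], amplitude=1.0,
            fwhm_left=melt_fwhm_C[0], fwhm_right=melt_fwhm_C[1],
            mix_left=0.0, mix_right=0.0,
        )
        # unit-area shape in temperature; power = shape(T) * area * beta
        hf = hf + peak(T_C) / peak.area * area * beta_K_s

    return Thermogram(
        time_min=t, temp_C=T_C, heat_flow=noise.apply(hf),
        mass_mg=sample_mass_mg, program=program,
        incomplete_crystallization=incomplete,
        meta={
            "kinetics": {"Ea_J_mol": kin.Ea_J_mol, "lnA": kin.lnA,
                         "n": kin.n, "alpha0": kin.alpha0},
            "dHc_J_g": thermo.dHc_J_g,
            "dHf_total_J_g": dHf_total,
            "ratio_II_I": ratio_II_I,
            "alpha_final": alpha_final,
            "noise_sd": noise.sd, "seed": noise.seed,
        },
    )


def simulate_pxrd(
    peaks: list[SplitPVPeak],
    background: np.ndarray | list[float] = (50.0, -0.5),
    grid: tuple[float, float, float] = (2.5, 40.0, 0.01),
    noise: NoiseSpec = NoiseSpec(),
) -> PXRDPattern:
    """Powder pattern as split pseudo-Voigt peaks on a polynomial background.

    ``background`` holds polynomial coefficients in increasing degree order;
    ``grid`` is (start °2θ, stop °2θ, step °2θ). Peak centers must lie inside
    the grid.
    """
    lo, hi, step = grid
    if step <= 0 or hi <= lo:
        raise InvalidParameterError("invalid 2theta grid")
    x = np.arange(lo, hi + 0.5 * step, step)
    for p in peaks:
        if not lo <= p.center <= hi:
            raise InvalidParameterError(
                f"peak center {p.center}° outside grid [{lo}, {hi}]°"
            )
    y = np.polynomial.polynomial.polyval(x, np.asarray(background, float))
    for p in peaks:
        y = y + p(x)
    return PXRDPattern(x, noise.apply(y),
                       meta={"noise_sd": noise.sd, "seed": noise.seed})


def simulate_dissolution(
    peak_time: float = 24.0,
    c_max: float = 55.0,
    c_final: float = 18.0,
    first_point_bias: float = 1.0,
    duration: float = 48.0,
    dt: float = 10.0,
    noise: NoiseSpec = NoiseSpec(),
    nominal: float = 40.0,
    decay_h: float | None = None,
) -> DissolutionTrace:
    """Supersaturation rise-and-decay dissolution trace.

    The noise-free nominal trace starts at ``nominal``, rises (sin² shape)
    to ``c_max`` at ``peak_time`` (hours), then decays (Gaussian in time,
    width ``decay_h``) toward ``c_final``; both branches meet with zero slope
    so the trace is unimodal and C¹. The measured trace is the nominal one
    multiplied by ``first_point_bias`` (a probe-scale error), so the first
    measured value is ``nominal · first_point_bias``. ``dt`` is in minutes.
    """
    if not 0 < peak_time < duration:
        raise InvalidParameterError("need 0 < peak_time < duration")
    if c_final >= c_max:
        raise InvalidParameterError("c_final must be below c_max")
    if nominal > c_max:
        raise InvalidParameterError("nominal must not exceed c_max")
    if first_point_bias <= 0:
        raise InvalidParameterError("first_point_bias must be > 0")
    if decay_h is None:
        decay_h = (duration - peak_time) / 2.5
    t = np.arange(0.0, duration + 1e-9, dt / 60.0)
    rise = nominal + (c_max - nominal) * np.sin(np.pi * t / (2.0 * peak_time)) ** 2
    decay = c_final + (c_max - c_final) * np.exp(-(((t - peak_time) / decay_h) ** 2))
    c = np.where(t <= peak_time, rise, decay)
    measured = first_point_bias * c
    return DissolutionTrace(
        t, noise.apply(measured), nominal_ug_mL=nominal,
        meta={"first_point_bias": first_point_bias,
              "noise_sd": noise.sd, "seed": noise.seed},
    )
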