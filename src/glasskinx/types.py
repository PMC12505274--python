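"""Domain containers for thermal, diffraction and dissolution data.

Units are part of the field names wherever a quantity is stored: time in
minutes (hours for dissolution), temperature in degrees Celsius unless a
``_K`` suffix says Kelvin, heat flow in mW/mg (== W/g), heat capacity in
J/(g K), enthalpies per gram in J/g and molar quantities in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

#: Ideal gas constant, J/(mol K).
R_GAS = 8.314

#: Molar mass of terfenadine (C32H41NO2), g/mol. Used to convert the molar
#: thermodynamic parameters to the per-gram scale of a DSC trace.
TFD_MOLAR_MASS = 471.67


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its stated constraints."""


@dataclass(frozen=True)
class NoiseSpec:
    """Additive iid Gaussian noise on a simulated signal.

    Parameters
    ----------
    sd : float
        Standard deviation in the units of the signal it is applied to.
    seed : int
        Seed for an independent ``numpy`` generator; identical seeds give
        bit-identical traces.
    """

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidParameterError(f"noise sd must be >= 0, got {self.sd}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, signal: np.ndarray) -> np.ndarray:
        if self.sd == 0:
            return np.asarray(signal, dtype=float)
        return np.asarray(signal, dtype=float) + self.rng().normal(
            0.0, self.sd, size=np.shape(signal)
        )


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters of the glass and its two polymorphs.

    Defaults are the terfenadine values: glass transition at 58.4 °C with a
    271.4 J/(mol K) heat-capacity step, monotropic melting pair at 149.9 °C
    (form I) / 145.9 °C (form II) with fusion enthalpies 54.4 / 53.3 kJ/mol,
    and a cold-crystallization enthalpy of 95.3 J/g.
    """

    Tg_C: float = 58.4
    dCp_J_molK: float = 271.4
    Tm_I_C: float = 149.9
    Tm_II_C: float = 145.9
    dHf_I_kJ_mol: float = 54.4
    dHf_II_kJ_mol: float = 53.3
    dHc: float = 95.3
    dHc_unit: Literal["J/g", "kJ/mol"] = "J/g"
    molar_mass_g_mol: float = TFD_MOLAR_MASS

    def __post_init__(self) -> None:
        if not self.Tm_II_C < self.Tm_I_C:
            raise InvalidParameterError(
                "monotropic pair requires Tm_II < Tm_I, got "
                f"{self.Tm_II_C} >= {self.Tm_I_C}"
            )
        if not self.Tg_C < self.Tm_II_C:
            raise InvalidParameterError("Tg must be below Tm_II")
        for name in ("dCp_J_molK", "dHf_I_kJ_mol", "dHf_II_kJ_mol", "dHc"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def dCp_J_gK(self) -> float:
        return self.dCp_J_molK / self.molar_mass_g_mol

    @property
    def dHf_I_J_g(self) -> float:
        return self.dHf_I_kJ_mol * 1e3 / self.molar_mass_g_mol

    @property
    def dHf_II_J_g(self) -> float:
        return self.dHf_II_kJ_mol * 1e3 / self.molar_mass_g_mol

    @property
    def dHc_J_g(self) -> float:
        if self.dHc_unit == "J/g":
            return self.dHc
        return self.dHc * 1e3 / self.molar_mass_g_mol


@dataclass(frozen=True)
class ArrheniusAvramiKinetics:
    """Arrhenius + Avrami–Erofeev kinetics of cold crystallization.

    The conversion rate is
    ``dα/dt = A exp(−Ea/RT) · n (1−α) [−ln(1−α)]^((n−1)/n)``
    with ``A = exp(lnA)`` in 1/min. ``alpha0`` is the conversion equivalent
    of preformed crystal nuclei present before heating.
    """

    Ea_J_mol: float
    lnA: float
    n: float
    alpha0: float = 0.0

    def __post_init__(self) -> None:
        if self.Ea_J_mol <= 0:
            raise InvalidParameterError("Ea must be > 0")
        if not 0.5 <= self.n <= 10:
            raise InvalidParameterError(f"Avrami exponent out of [0.5, 10]: {self.n}")
        if not 0 <= self.alpha0 < 0.01:
            raise InvalidParameterError(f"alpha0 out of [0, 0.01): {self.alpha0}")

    def rate_constant(self, T_K: np.ndarray | float) -> np.ndarray | float:
        """Arrhenius rate constant k(T) in 1/min."""
        return np.exp(self.lnA - self.Ea_J_mol / (R_GAS * np.asarray(T_K, float)))


@dataclass(frozen=True)
class Segment:
    """One segment of a DSC temperature program."""

    kind: Literal["ramp", "isothermal"]
    T_start_C: float
    T_end_C: float
    rate_C_min: float = 0.0      # ramps only, signed; nonzero
    duration_min: float = 0.0    # isothermal only

    def __post_init__(self) -> None:
        if self.kind == "ramp":
            if self.rate_C_min == 0:
                raise InvalidParameterError("ramp rate must be nonzero")
            if np.sign(self.T_end_C - self.T_start_C) != np.sign(self.rate_C_min):
                raise InvalidParameterError("ramp rate sign inconsistent with endpoints")
        elif self.kind == "isothermal":
            if self.T_start_C != self.T_end_C:
                raise InvalidParameterError("isothermal segment must hold temperature")
            if self.duration_min <= 0:
                raise InvalidParameterError("isothermal duration must be > 0")
        else:
            raise InvalidParameterError(f"unknown segment kind {self.kind!r}")

    @property
    def length_min(self) -> float:
        if self.kind == "isothermal":
            return self.duration_min
        return (self.T_end_C - self.T_start_C) / self.rate_C_min


@dataclass(frozen=True)
class TemperatureProgram:
    """Contiguous sequence of ramps and isothermal holds."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise InvalidParameterError("program needs at least one segment")
        for prev, cur in zip(self.segments, self.segments[1:]):
            if abs(prev.T_end_C - cur.T_start_C) > 1e-9:
                raise InvalidParameterError(
                    f"segments not contiguous at {prev.T_end_C} -> {cur.T_start_C}"
                )

    @classmethod
    def single_ramp(cls, start_C: float, end_C: float, rate_C_min: float
                    ) -> "TemperatureProgram":
        return cls((Segment("ramp", start_C, end_C, rate_C_min=rate_C_min),))

    @property
    def duration_min(self) -> float:
        return float(sum(s.length_min for s in self.segments))

    @property
    def T_min_C(self) -> float:
        return min(min(s.T_start_C, s.T_end_C) for s in self.segments)

    @property
    def T_max_C(self) -> float:
        return max(max(s.T_start_C, s.T_end_C) for s in self.segments)

    def _breakpoints(self) -> tuple[np.ndarray, np.ndarray]:
        times = [0.0]
        temps = [self.segments[0].T_start_C]
        for s in self.segments:
            times.append(times[-1] + s.length_min)
            temps.append(s.T_end_C)
        return np.asarray(times), np.asarray(temps)

    def temperature(self, t_min: np.ndarray | float) -> np.ndarray | float:
        """Temperature (°C) at program time ``t_min`` (piecewise linear)."""
        times, temps = self._breakpoints()
        return np.interp(t_min, times, temps)

    def rate(self, t_min: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous heating rate (°C/min) at program time ``t_min``."""
        times, _ = self._breakpoints()
        rates = np.array(
            [s.rate_C_min if s.kind == "ramp" else 0.0 for s in self.segments]
        )
        idx = np.clip(np.searchsorted(times, t_min, side="right") - 1, 0,
                      len(rates) - 1)
        return rates[idx]

    def time_grid(self, max_dT_C: float = 0.05, max_dt_min: float = 0.5
                  ) -> np.ndarray:
        """Time grid resolving ramps to ``max_dT_C`` per step."""
        grids = []
        t0 = 0.0
        for s in self.segments:
            if s.kind == "ramp":
                npts = max(int(np.ceil(abs(s.T_end_C - s.T_start_C) / max_dT_C)), 2)
            else:
                npts = max(int(np.ceil(s.length_min / max_dt_min)), 2)
            grids.append(np.linspace(t0, t0 + s.length_min, npts + 1))
            t0 += s.length_min
        out = np.concatenate(grids)
        return np.unique(out)


@dataclass
class Thermogram:
    """A DSC heat-flow trace with its temperature program.

    ``heat_flow`` is specific heat flow in mW/mg (== W/g), endothermic up:
    the heating baseline ``Cp·β`` is positive, melting peaks point up and
    the cold-crystallization exotherm points down.
    """

    time_min: np.ndarray
    temp_C: np.ndarray
    heat_flow: np.ndarray
    mass_mg: float
    program: TemperatureProgram | None = None
    incomplete_crystallization: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, float)
        self.temp_C = np.asarray(self.temp_C, float)
        self.heat_flow = np.asarray(self.heat_flow, float)
        if not (len(self.time_min) == len(self.temp_C) == len(self.heat_flow)):
            raise InvalidParameterError("trace columns must have equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise InvalidParameterError("time must be strictly increasing")
        if self.mass_mg <= 0:
            raise InvalidParameterError("mass must be > 0")

    def local_rate_K_min(self) -> np.ndarray:
        """Pointwise heating rate dT/dt (K/min) from the recorded columns."""
        return np.gradient(self.temp_C, self.time_min)

    def window(self, T_lo: float, T_hi: float) -> "Thermogram":
        """Sub-trace with temperatures inside ``[T_lo, T_hi]`` (heating)."""
        m = (self.temp_C >= T_lo) & (self.temp_C <= T_hi)
        if m.sum() < 4:
            raise ValueError(
                f"window [{T_lo}, {T_hi}] °C covers too little of the trace"
            )
        return Thermogram(self.time_min[m], self.temp_C[m], self.heat_flow[m],
                          self.mass_mg, self.program,
                          self.incomplete_crystallization, dict(self.meta))


@dataclass
class ModulatedTrace:
    """Quasi-isothermal reversing heat capacity versus time."""

    time_min: np.ndarray
    cp_J_gK: np.ndarray
    hold_temp_C: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, float)
        self.cp_J_gK = np.asarray(self.cp_J_gK, float)
        if len(self.time_min) != len(self.cp_J_gK):
            raise InvalidParameterError("trace columns must have equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise InvalidParameterError("time must be strictly increasing")


@dataclass
class PXRDPattern:
    """A powder diffraction pattern (2θ in degrees, intensity in counts)."""

    two_theta_deg: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.two_theta_deg = np.asarray(self.two_theta_deg, float)
        self.intensity = np.asarray(self.intensity, float)
        if len(self.two_theta_deg) != len(self.intensity):
            raise InvalidParameterError("pattern columns must have equal length")
        if np.any(np.diff(self.two_theta_deg) <= 0):
            raise InvalidParameterError("2theta must be strictly increasing")


@dataclass
class DissolutionTrace:
    """Concentration–time trace from an in-situ UV dissolution experiment."""

    time_h: np.ndarray
    conc_ug_mL: np.ndarray
    nominal_ug_mL: float = 40.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, float)
        self.conc_ug_mL = np.asarray(self.conc_ug_mL, float)
        if len(self.time_h) != len(self.conc_ug_mL):
            raise InvalidParameterError("trace columns must have equal length")
        if np.any(np.diff(self.time_h) <= 0):
            raise InvalidParameterError("time must be strictly increasing")
        if self.nominal_ug_mL <= 0:
            raise InvalidParameterError("nominal concentration must be > 0")


@dataclass
class ConversionCurve:
    """Crystallization conversion α(T) for one heating rate."""

    heating_rate_K_min: float
    temp_C: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.temp_C = np.asarray(self.temp_C, float)
        self.alpha = np.asarray(self.alpha, float)
        if len(self.temp_C) != len(self.alpha):
            raise InvalidParameterError("curve columns must have equal length")

    def temperature_at(self, alpha: float | Sequence[float]) -> np.ndarray | float:
        """Inverse-interpolate T(α); monotone piecewise-linear."""
        a = np.asarray(alpha, dtype=float)
        # enforce a strictly increasing abscissa for interpolation
        mono = np.maximum.accumulate(self.alpha)
        keep = np.concatenate(([True], np.diff(mono) > 0))
        aa, tt = mono[keep], self.temp_C[keep]
        if np.any(a < aa[0]) or np.any(a > aa[-1]):
            raise ValueError(
                f"conversion level outside curve range "
                f"[{aa[0]:.4g}, {aa[-1]:.4g}] for rate "
                f"{self.heating_rate_K_min} K/min"
            )
        out = np.interp(a, aa, tt)
        return float(out) if np.isscalar(alpha) else out
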