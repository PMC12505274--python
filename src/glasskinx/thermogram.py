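"""Feature extraction from DSC heating thermograms.

Covers the quantities a stability study reads off each trace: the glass
transition (half-height midpoint of the Cp step), event enthalpies by linear
baseline integration, the extrapolated onset of cold crystallization
(baseline ∩ leading-edge inflection tangent), partial-area conversion
curves, and deconvolution of the overlapping form II / form I melting
doublet by fitting two asymmetric peaks.

All routines assume the endothermic-up sign convention of
:mod:`glasskinx.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.signal import find_peaks, savgol_filter
from scipy.special import expit

from .profiles import SplitPVPeak, split_pseudo_voigt
from .types import ConversionCurve, Thermogram

__all__ = [
    "GlassTransition",
    "OnsetResult",
    "PeakIntegral",
    "MeltingDeconvolution",
    "detect_glass_transition",
    "integrate_peak",
    "onset_temperature",
    "conversion_curve",
    "deconvolve_melting",
    "MeltingDoubletModel",
]


@dataclass(frozen=True)
class GlassTransition:
    """Glass-transition fit result; ``found`` is False when no step exceeds
    three times the local noise level."""

    found: bool
    Tg_C: float = float("nan")
    dCp_J_gK: float = float("nan")


@dataclass(frozen=True)
class OnsetResult:
    found: bool
    T_onset_C: float = float("nan")


@dataclass(frozen=True)
class PeakIntegral:
    """Baseline-corrected event enthalpy, reported positive; ``sign`` records
    whether the event was endothermic (+) or exothermic (−) under the
    endo-up convention."""

    enthalpy_J_g: float
    sign: str  # "endo" or "exo"


def _noise_sd(y: np.ndarray) -> float:
    """Robust noise estimate from first differences (trend-insensitive)."""
    d = np.diff(y)
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) * 1.4826 / np.sqrt(2.0))


def detect_glass_transition(
    tg: Thermogram, search_window: tuple[float, float] = (40.0, 75.0)
) -> GlassTransition:
    """Locate the glass transition as the half-height midpoint of the Cp step.

    The heat flow inside ``search_window`` is converted to an apparent heat
    capacity (heat flow / heating rate) and fitted with a linear baseline
    plus a logistic step; the logistic midpoint is Tg and its height ΔCp.
    Returns ``found=False`` if the fitted step is below 3× the noise level.
    """
    sub = tg.window(*search_window)
    beta = sub.local_rate_K_min() / 60.0  # K/s
    if np.any(np.abs(beta) < 1e-12):
        raise ValueError("glass-transition window must lie on a ramp")
    cp = sub.heat_flow / beta  # J/(g K)
    T = sub.temp_C
    Tc = T - T.mean()

    noise = _noise_sd(cp)
    h0 = cp[-max(3, len(cp) // 10):].mean() - cp[: max(3, len(cp) // 10)].mean()

    def resid(p):
        a, b, h, tmid, w = p
        return a + b * Tc + h * expit((T - tmid) / np.abs(w)) - cp

    p0 = [cp[: max(3, len(cp) // 10)].mean(), 0.0, h0, T.mean(), 1.5]
    lo = [-np.inf, -np.inf, -np.inf, T[0], 0.05]
    hi = [np.inf, np.inf, np.inf, T[-1], (T[-1] - T[0])]
    fit = least_squares(resid, p0, bounds=(lo, hi))
    a, b, h, tmid, w = fit.x
    if abs(h) < 3.0 * max(noise, 1e-12) or not fit.success:
        return GlassTransition(found=False)
    return GlassTransition(found=True, Tg_C=float(tmid), dCp_J_gK=float(abs(h)))


def _linear_baseline(x: np.ndarray, y: np.ndarray, edge: int = 3) -> np.ndarray:
    """Line through the mean of the first/last ``edge`` samples."""
    edge = max(1, min(edge, len(x) // 4))
    x0, y0 = x[:edge].mean(), y[:edge].mean()
    x1, y1 = x[-edge:].mean(), y[-edge:].mean()
    slope = (y1 - y0) / (x1 - x0)
    return y0 + slope * (x - x0)


def integrate_peak(
    tg: Thermogram, limits: tuple[float, float], baseline: str = "linear"
) -> PeakIntegral:
    """Enthalpy of the thermal event inside ``limits`` (°C), J/g.

    The signal minus a linear baseline (anchored at the window edges) is
    integrated over time in seconds; the magnitude is returned with the
    event sign recorded (net positive area → endothermic under endo-up).
    """
    if baseline != "linear":
        raise ValueError("only the linear baseline is supported")
    lo, hi = limits
    if lo < tg.temp_C.min() - 1e-9 or hi > tg.temp_C.max() + 1e-9:
        raise ValueError(f"limits ({lo}, {hi}) outside the recorded trace")
    sub = tg.window(lo, hi)
    base = _linear_baseline(sub.time_min, sub.heat_flow)
    area = float(np.trapezoid(sub.heat_flow - base, sub.time_min * 60.0))
    sign = "endo" if area >= 0 else "exo"
    return PeakIntegral(enthalpy_J_g=abs(area), sign=sign)


def onset_temperature(
    tg: Thermogram,
    peak_region: tuple[float, float],
    kind: str = "exo",
    smooth: int | None = None,
) -> OnsetResult:
    """Extrapolated onset of the event inside ``peak_region``.

    Standard DSC construction: intersection of the pre-peak linear baseline
    with the tangent at the inflection point of the leading edge. ``kind``
    selects the event sign ("exo" events point down under endo-up).
    Returns ``found=False`` when the region holds no resolvable peak.
    """
    sub = tg.window(*peak_region)
    s = -sub.heat_flow if kind == "exo" else sub.heat_flow.copy()
    T = sub.temp_C
    if smooth is None and _noise_sd(s) > 0:
        smooth = min(51, (len(s) // 10) * 2 + 1)
    if smooth and smooth >= 5:
        s = savgol_filter(s, smooth, 3)

    base = _linear_baseline(T, s, edge=max(3, len(s) // 20))
    noise = _noise_sd(s)
    ipk = int(np.argmax(s - base))
    if (s - base)[ipk] < 3.0 * max(noise, 1e-12) or ipk < 3:
        return OnsetResult(found=False)

    grad = np.gradient(s, T)
    lead = slice(0, ipk + 1)
    iinf = int(np.argmax(grad[lead]))
    gi = grad[iinf]
    if gi <= 0:
        return OnsetResult(found=False)
    # tangent: y = s[iinf] + gi (T - T[iinf]); baseline: y = b0 + b1 T
    b1 = (base[-1] - base[0]) / (T[-1] - T[0])
    b0 = base[0] - b1 * T[0]
    T_on = (b0 - (s[iinf] - gi * T[iinf])) / (gi - b1)
    return OnsetResult(found=True, T_onset_C=float(T_on))


def conversion_curve(
    tg: Thermogram,
    limits: tuple[float, float],
    kind: str = "exo",
) -> ConversionCurve:
    """Partial-area conversion α(T) of the event inside ``limits``.

    α(T) is the cumulative baseline-corrected area up to T over the total
    area; the endpoints are exactly 0 and 1.
    """
    sub = tg.window(*limits)
    s = -sub.heat_flow if kind == "exo" else sub.heat_flow
    base = _linear_baseline(sub.time_min, s)
    y = s - base
    cum = cumulative_trapezoid(y, sub.time_min, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise ValueError("total event area is not positive inside the limits")
    alpha = cum / total
    rate = float(np.median(sub.local_rate_K_min()))
    return ConversionCurve(heating_rate_K_min=rate, temp_C=sub.temp_C, alpha=alpha)


@dataclass(frozen=True)
class MeltingDeconvolution:
    """Areas of the two overlapping melting endotherms, ordered by center
    temperature (lower = form II for a monotropic pair)."""

    dHf_II_J_g: float
    dHf_I_J_g: float
    ratio_II_I: float
    center_II_C: float
    center_I_C: float
    converged: bool
    residual_norm: float


class MeltingDoubletModel:
    """Two split pseudo-Voigt endotherms plus a linear baseline.

    scikit-learn style estimator: ``fit(T, heat_flow)`` stores the fitted
    peaks in ``peaks_`` (ordered by center), per-peak enthalpies in
    ``areas_J_g_``, and diagnostics in ``converged_``/``residual_norm_``.
    """

    def __init__(self, heating_rate_K_min: float = 1.0,
                 min_area_fraction: float = 1e-3, max_nfev: int = 4000):
        self.heating_rate_K_min = heating_rate_K_min
        self.min_area_fraction = min_area_fraction
        self.max_nfev = max_nfev

    def get_params(self, deep: bool = True) -> dict:
        return {
            "heating_rate_K_min": self.heating_rate_K_min,
            "min_area_fraction": self.min_area_fraction,
            "max_nfev": self.max_nfev,
        }

    def set_params(self, **params) -> "MeltingDoubletModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _initial_centers(self, T: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        w = max(5, len(y) // 50) | 1
        ys = savgol_filter(y, w, 3) if len(y) > w else y
        pk, props = find_peaks(ys, prominence=0.05 * (ys.max() - ys.min() + 1e-30))
        if len(pk) >= 2:
            top = pk[np.argsort(props["prominences"])[-2:]]
            return tuple(sorted(T[top]))
        span = T[-1] - T[0]
        return (T[0] + 0.4 * span, T[0] + 0.6 * span)

    def fit(self, T, y) -> "MeltingDoubletModel":
        T = np.asarray(T, float)
        y = np.asarray(y, float)
        base = _linear_baseline(T, y)
        yc = y - base
        c1, c2 = self._initial_centers(T, yc)
        amp = max(yc.max(), 1e-12)

        def unpack(p):
            peaks = []
            for i in range(2):
                c, a, wl, wr, ml, mr = p[6 * i: 6 * i + 6]
                peaks.append((c, a, wl, wr, ml, mr))
            b0, b1 = p[12], p[13]
            return peaks, b0, b1

        def model(p):
            peaks, b0, b1 = unpack(p)
            out = b0 + b1 * (T - T.mean())
            for c, a, wl, wr, ml, mr in peaks:
                out = out + split_pseudo_voigt(T, c, a, wl, wr, ml, mr)
            return out

        p0 = [c1, 0.7 * amp, 1.0, 1.0, 0.2, 0.2,
              c2, 0.7 * amp, 1.0, 1.0, 0.2, 0.2,
              float(base.mean()), 0.0]
        lo = [T[0], 0.0, 0.1, 0.1, 0.0, 0.0,
              T[0], 0.0, 0.1, 0.1, 0.0, 0.0, -np.inf, -np.inf]
        hi = [T[-1], np.inf, T[-1] - T[0], T[-1] - T[0], 1.0, 1.0,
              T[-1], np.inf, T[-1] - T[0], T[-1] - T[0], 1.0, 1.0,
              np.inf, np.inf]
        fit = least_squares(lambda p: model(p) - y, p0, bounds=(lo, hi),
                            max_nfev=self.max_nfev)
        peaks, _, _ = unpack(fit.x)
        fitted = sorted(
            (SplitPVPeak(c, a, wl, wr, ml, mr) for c, a, wl, wr, ml, mr in peaks),
            key=lambda p: p.center,
        )
        beta_K_s = self.heating_rate_K_min / 60.0
        self.peaks_ = fitted
        self.areas_J_g_ = [p.area / beta_K_s for p in fitted]
        self.converged_ = bool(fit.success)
        self.residual_norm_ = float(np.sqrt(2.0 * fit.cost))
        if not fit.success:
            raise RuntimeError(
                "melting deconvolution did not converge "
                f"(residual norm {self.residual_norm_:.3g})"
            )
        return self

    def predict(self, T) -> np.ndarray:
        T = np.asarray(T, float)
        out = np.zeros_like(T)
        for p in self.peaks_:
            out = out + p(T)
        return out


def deconvolve_melting(
    tg: Thermogram, limits: tuple[float, float]
) -> MeltingDeconvolution:
    """Split the overlapping melting doublet into per-polymorph enthalpies.

    Fits two asymmetric split pseudo-Voigt peaks plus a linear baseline to
    the endotherm region; areas are reported in J/g ordered by center
    temperature (lower-melting form II first) together with their ratio.
    A vanishing high-temperature peak yields ``ratio_II_I = inf``.
    """
    sub = tg.window(*limits)
    rate = float(np.median(sub.local_rate_K_min()))
    model = MeltingDoubletModel(heating_rate_K_min=rate).fit(
        sub.temp_C, sub.heat_flow
    )
    a_II, a_I = model.areas_J_g_
    total = a_II + a_I
    if total <= 0:
        raise RuntimeError("no endotherm found inside the limits")
    if a_I < model.min_area_fraction * total:
        ratio = float("inf")
    else:
        ratio = a_II / a_I
    return MeltingDeconvolution(
        dHf_II_J_g=a_II, dHf_I_J_g=a_I, ratio_II_I=ratio,
        center_II_C=model.peaks_[0].center, center_I_C=model.peaks_[1].center,
        converged=model.converged_, residual_norm=model.residual_norm_,
    )
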