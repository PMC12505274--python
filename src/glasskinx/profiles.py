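"""Split pseudo-Voigt peak profile (Toraya-style convention).

Each side of the peak is an independent pseudo-Voigt: a linear mix of a
Lorentzian and a Gaussian that share the side's full width at half maximum
(FWHM) and the common peak amplitude, so the profile is continuous at the
center with value equal to the amplitude. Peak areas have a closed form
(half-Gaussian + half-Lorentzian per side), used instead of quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import InvalidParameterError

_LN2 = np.log(2.0)
# area of a unit-amplitude Gaussian with FWHM w is w * sqrt(pi / (4 ln 2))
_GAUSS_AREA = float(np.sqrt(np.pi / (4.0 * _LN2)))


def _side_profile(dx: np.ndarray, fwhm: float, mix: float) -> np.ndarray:
    """Unit-amplitude pseudo-Voigt evaluated at |x - center| = dx."""
    g = np.exp(-4.0 * _LN2 * (dx / fwhm) ** 2)
    lo = 1.0 / (1.0 + 4.0 * (dx / fwhm) ** 2)
    return mix * lo + (1.0 - mix) * g


def split_pseudo_voigt(
    x: np.ndarray | float,
    center: float,
    amplitude: float,
    fwhm_left: float,
    fwhm_right: float,
    mix_left: float,
    mix_right: float,
) -> np.ndarray:
    """Evaluate a split pseudo-Voigt profile.

    Points below ``center`` use ``(fwhm_left, mix_left)``, the rest
    ``(fwhm_right, mix_right)``; both sides take the value ``amplitude`` at
    the center.
    """
    if fwhm_left <= 0 or fwhm_right <= 0:
        raise InvalidParameterError("FWHM values must be > 0")
    x = np.asarray(x, dtype=float)
    dx = x - center
    left = _side_profile(np.abs(dx), fwhm_left, mix_left)
    right = _side_profile(np.abs(dx), fwhm_right, mix_right)
    return amplitude * np.where(dx < 0, left, right)


def side_area(amplitude: float, fwhm: float, mix: float) -> float:
    """Analytic area of one half of a split pseudo-Voigt."""
    half_gauss = 0.5 * _GAUSS_AREA * fwhm
    half_lorentz = np.pi * fwhm / 4.0
    return amplitude * (mix * half_lorentz + (1.0 - mix) * half_gauss)


@dataclass(frozen=True)
class SplitPVPeak:
    """A split pseudo-Voigt peak with analytic area.

    ``center`` and the FWHMs are in the abscissa units (°2θ for powder
    patterns, °C for melting endotherms); ``amplitude`` is in signal units,
    mixing parameters in [0, 1] (0 = Gaussian, 1 = Lorentzian).
    """

    center: float
    amplitude: float
    fwhm_left: float
    fwhm_right: float
    mix_left: float = 0.5
    mix_right: float = 0.5

    def __post_init__(self) -> None:
        if self.fwhm_left <= 0 or self.fwhm_right <= 0:
            raise InvalidParameterError("FWHM values must be > 0")
        for m in (self.mix_left, self.mix_right):
            if not 0.0 <= m <= 1.0:
                raise InvalidParameterError("mixing parameter must lie in [0, 1]")

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        return split_pseudo_voigt(
            x, self.center, self.amplitude, self.fwhm_left, self.fwhm_right,
            self.mix_left, self.mix_right,
        )

    @property
    def area(self) -> float:
        """Analytic integral of the profile over the whole axis."""
        return side_area(self.amplitude, self.fwhm_left, self.mix_left) + side_area(
            self.amplitude, self.fwhm_right, self.mix_right
        )
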