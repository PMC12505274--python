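"""Modified Avrami analysis of quasi-isothermal crystallization.

The reversing heat capacity decays from the amorphous plateau to the
crystalline plateau as the sample crystallizes. The residual amorphous
fraction is

    f(t) = (Cp(t) − Cp_crystal) / (Cp_amorphous − Cp_crystal) × 100,

with the plateau heat capacities taken as the means of the first and last
``edge_count`` samples of the hold. The decay is fitted with the modified
Avrami form f(t) = 100·0.9^((t/t10)^n), parameterized so the curve passes
through 90% at t = t10 for any Avrami exponent n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .synthetic import avrami_fraction
from .types import ModulatedTrace

__all__ = ["amorphous_fraction", "AvramiModel", "AvramiFit", "fit_modified_avrami"]


def amorphous_fraction(
    trace: ModulatedTrace, edge_count: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Residual amorphous fraction (%) from a reversing-heat-capacity trace.

    The amorphous and crystalline plateau heat capacities are the means of
    the first and last ``edge_count`` samples. Values are not clipped to
    [0, 100]; noise may carry them outside. Raises if the two plateaus are
    indistinguishable from the noise.
    """
    cp = trace.cp_J_gK
    if len(cp) < 2 * edge_count + 10:
        raise ValueError(
            f"trace too short for edge_count={edge_count}: {len(cp)} samples"
        )
    first = cp[:edge_count]
    last = cp[-edge_count:]
    cp_am, cp_cr = first.mean(), last.mean()
    sd = max(first.std(ddof=1), last.std(ddof=1))
    if cp_am - cp_cr <= 3.0 * sd / np.sqrt(edge_count):
        raise ValueError(
            "degenerate trace: amorphous and crystalline plateaus are equal "
            "within noise"
        )
    f = (cp - cp_cr) / (cp_am - cp_cr) * 100.0
    return trace.time_min.copy(), f


class AvramiModel(BaseEstimator, RegressorMixin):
    """Modified Avrami decay fitted by bounded nonlinear least squares.

    Parameters
    ----------
    n_starts : sequence of float
        Multistart grid for the Avrami exponent; t10 is always initialized
        at the observed 90% crossing.
    n_bounds : (float, float)
        Box constraint on the exponent.

    Attributes
    ----------
    t10_ : float
        Time (min) at 10% crystallization.
    n_ : float
        Avrami exponent.
    rss_ : float
        Residual sum of squares in squared-percent units.
    converged_ : bool
        Optimizer success for the best start.
    """

    def __init__(self, n_starts=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
                 n_bounds=(0.5, 10.0), max_nfev: int = 2000):
        self.n_starts = n_starts
        self.n_bounds = n_bounds
        self.max_nfev = max_nfev

    def fit(self, t, f) -> "AvramiModel":
        t = np.asarray(t, float).ravel()
        f = np.asarray(f, float).ravel()
        if len(t) != len(f) or len(t) < 4:
            raise ValueError("need matching t/f arrays with >= 4 samples")
        # initial t10: first crossing of 90% (fall back to mid-time)
        below = np.nonzero(f <= 90.0)[0]
        t10_0 = float(t[below[0]]) if len(below) and below[0] > 0 else float(
            t[len(t) // 2]
        )
        t10_0 = max(t10_0, t[1] if t[0] == 0 else t[0])

        span = f.max() - f.min()
        best = None
        for n0 in self.n_starts:
            res = least_squares(
                lambda p: avrami_fraction(t, p[0], p[1]) - f,
                x0=[t10_0, n0],
                bounds=([1e-6, self.n_bounds[0]], [np.inf, self.n_bounds[1]]),
                max_nfev=self.max_nfev,
            )
            if best is None or res.cost < best.cost:
                best = res
        self.t10_ = float(best.x[0])
        self.n_ = float(best.x[1])
        self.rss_ = float(2.0 * best.cost)
        # a fit that never leaves the plateau is degenerate, not converged
        self.converged_ = bool(best.success and span > 1.0)
        return self

    def predict(self, t) -> np.ndarray:
        return avrami_fraction(np.asarray(t, float), self.t10_, self.n_)


@dataclass(frozen=True)
class AvramiFit:
    t10_min: float
    n: float
    rss: float
    converged: bool


def fit_modified_avrami(
    t: np.ndarray,
    f: np.ndarray,
    fit_window: tuple[float, float] | None = None,
) -> AvramiFit:
    """Fit (t10, n) minimizing the residual sum of squares of f(t).

    ``fit_window`` restricts the fitted time range (the plateau-definition
    windows are typically excluded).
    """
    t = np.asarray(t, float)
    f = np.asarray(f, float)
    if fit_window is not None:
        m = (t >= fit_window[0]) & (t <= fit_window[1])
        t, f = t[m], f[m]
    model = AvramiModel().fit(t, f)
    return AvramiFit(t10_min=model.t10_, n=model.n_, rss=model.rss_,
                     converged=model.converged_)


def fit_trace(
    trace: ModulatedTrace, edge_count: int = 100
) -> AvramiFit:
    """Plateau normalization + Avrami fit, excluding the plateau windows."""
    t, f = amorphous_fraction(trace, edge_count=edge_count)
    window = (t[edge_count], t[len(t) - edge_count - 1])
    return fit_modified_avrami(t, f, fit_window=window)
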