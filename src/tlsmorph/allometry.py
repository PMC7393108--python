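"""Power-law allometry: quantile envelopes, through-origin fits, DGVM theory.

The conditional envelopes of the Height-CA-DBH relations are modeled as
power laws y = a * x^b fitted at extreme quantiles (5% as the minimum
necessary value, 95% as the maximum potential value) by minimizing the
pinball loss.  The exponent is found by 1-D search; for fixed b the
optimal coefficient a is an exact weighted quantile, which keeps the
solver stable at extreme quantile levels.

The reference theory is the LPJ allometric module shared by many dynamic
global vegetation models: Height = 40 * DBH^0.5 and CA = 100 * DBH^1.6,
which compose into CA = k * Height^p with p = 1.6/0.5 = 3.2 and
k = 100 * 40^-3.2 (about 7.5e-4).  DBH is in meters throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PowerLawFit",
    "TheoreticalAllometry",
    "LPJ",
    "fit_power_quantile",
    "fit_proportional",
    "combine_theoretical",
    "compare_envelopes",
]


@dataclass
class PowerLawFit:
    """A fitted y = a * x^b relation with its quantile level and loss."""

    a: float
    b: float
    tau: float | str  # quantile level in (0,1), or "ols-origin"
    loss: float
    n: int
    p_value: float | None = None

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(x, dtype=float) ** self.b

    def coverage(self, x: np.ndarray, y: np.ndarray) -> float:
        """Fraction of observations strictly below the fitted curve."""
        return float(np.mean(np.asarray(y) < self.predict(np.asarray(x))))


def _pinball(residuals: np.ndarray, tau: float) -> float:
    return float(np.sum(residuals * (tau - (residuals < 0))))


def _best_a_for_b(x: np.ndarray, y: np.ndarray, b: float, tau: float) -> tuple[float, float]:
    """Exact inner minimizer of sum rho_tau(y - a * x^b) over a.

    With z = x^b > 0, rho_tau(y - a z) = z * rho_tau(y/z - a), so the
    optimal a is the tau-quantile of the ratios y/z weighted by z —
    computed exactly by sorting and cumulative weights.
    """
    z = x ** b
    ratio = y / z
    order = np.argsort(ratio)
    w = z[order]
    cum = np.cumsum(w)
    target = tau * cum[-1]
    idx = int(np.searchsorted(cum, target))
    a = float(ratio[order][min(idx, len(ratio) - 1)])
    loss = _pinball(y - a * z, tau)
    return a, loss


def fit_power_quantile(
    x: np.ndarray,
    y: np.ndarray,
    tau: float,
    b_bounds: tuple[float, float] = (0.05, 8.0),
    n_grid: int = 80,
) -> PowerLawFit:
    """Fit the tau-quantile power-law envelope by pinball-loss minimization.

    The exponent b is searched on ``b_bounds`` with a coarse grid followed
    by golden-section refinement; the coefficient a is solved exactly for
    each candidate b as a weighted quantile.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError(f"need n >= 10 observations, got {len(x)}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law quantile fit requires strictly positive x and y")
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values identical")

    grid = np.linspace(*b_bounds, n_grid)
    losses = np.array([_best_a_for_b(x, y, b, tau)[1] for b in grid])
    k = int(np.argmin(losses))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    result = optimize.minimize_scalar(
        lambda b: _best_a_for_b(x, y, b, tau)[1],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    b_best = float(result.x)
    if losses[k] < result.fun:  # keep the grid point if refinement stalled
        b_best = float(grid[k])
    a_best, loss = _best_a_for_b(x, y, b_best, tau)
    return PowerLawFit(a=a_best, b=b_best, tau=tau, loss=loss, n=len(x))


def fit_proportional(x: np.ndarray, y: np.ndarray) -> PowerLawFit:
    """Through-origin least squares y = b0 * x (exponent fixed at 1).

    The slope is sum(xy)/sum(x^2); the two-sided p-value comes from the t
    statistic of the through-origin regression on n - 1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need n >= 3 observations, got {len(x)}")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("degenerate x: sum of squares is zero")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    df = len(x) - 1
    s2 = float(np.sum(resid ** 2) / df)
    if s2 == 0:
        p = 0.0
    else:
        t = slope / np.sqrt(s2 / sxx)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PowerLawFit(
        a=slope, b=1.0, tau="ols-origin",
        loss=float(np.sum(resid ** 2)), n=len(x), p_value=p,
    )


def combine_theoretical(
    k_h: float, p_h: float, k_ca: float, p_ca: float
) -> tuple[float, float]:
    """Compose Height = k_h * DBH^p_h and CA = k_ca * DBH^p_ca into CA(Height).

    Eliminating DBH gives CA = k_c * Height^p_c with p_c = p_ca / p_h and
    k_c = k_ca * k_h^(-p_c).  The LPJ constants (40, 0.5, 100, 1.6) give
    p_c = 3.2 and k_c about 7.5e-4.
    """
    if min(k_h, k_ca, p_ca) <= 0 or p_h == 0:
        raise ValueError("all parameters must be positive (p_h nonzero)")
    p_c = p_ca / p_h
    k_c = k_ca * k_h ** (-p_c)
    return k_c, p_c


@dataclass
class TheoreticalAllometry:
    """The DGVM reference allometry (LPJ constants by default)."""

    k_h: float = 40.0
    p_h: float = 0.5
    k_ca: float = 100.0
    p_ca: float = 1.6

    @property
    def combined(self) -> tuple[float, float]:
        """(k_c, p_c) of the composed CA = k_c * Height^p_c curve."""
        return combine_theoretical(self.k_h, self.p_h, self.k_ca, self.p_ca)

    def height(self, dbh: np.ndarray | float) -> np.ndarray | float:
        return self.k_h * np.asarray(dbh, dtype=float) ** self.p_h

    def ca_from_dbh(self, dbh: np.ndarray | float) -> np.ndarray | float:
        return self.k_ca * np.asarray(dbh, dtype=float) ** self.p_ca

    def ca_from_height(self, height: np.ndarray | float) -> np.ndarray | float:
        k_c, p_c = self.combined
        return k_c * np.asarray(height, dtype=float) ** p_c


LPJ = TheoreticalAllometry()


def compare_envelopes(
    fit: PowerLawFit,
    theory: tuple[float, float],
    x_grid: np.ndarray,
) -> pd.DataFrame:
    """Evaluate a fitted envelope against a theoretical power law on a grid.

    Returns columns x, fitted, theoretical, difference (fitted minus
    theoretical).  The frame's ``attrs['crossing']`` holds the x where the
    two curves cross (bisection on the log-difference), or None if they do
    not cross on the grid.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if np.any(x_grid <= 0):
        raise ValueError("evaluation grid must be positive")
    k, p = theory
    fitted = fit.predict(x_grid)
    theoretical = k * x_grid ** p

    def log_diff(x: float) -> float:
        return (np.log(fit.a) + fit.b * np.log(x)) - (np.log(k) + p * np.log(x))

    crossing = None
    lo, hi = float(x_grid.min()), float(x_grid.max())
    if lo < hi and log_diff(lo) * log_diff(hi) < 0:
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if log_diff(lo) * log_diff(mid) <= 0:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-12 * max(1.0, hi):
                break
        crossing = 0.5 * (lo + hi)

    out = pd.DataFrame(
        {
            "x": x_grid,
            "fitted": fitted,
            "theoretical": theoretical,
            "difference": fitted - theoretical,
        }
    )
    out.attrs["crossing"] = crossing
    return out
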