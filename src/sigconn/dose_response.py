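"""Hill-equation growth-inhibition fits and GI20 extraction.

The response model is the four-parameter logistic

    y = Bottom + (Top - Bottom) / (1 + 10**((logGI50 - x) * h))

with *x* the log10 concentration.  GI20 is the concentration at which the
fitted response crosses 80% of untreated growth, found by closed-form
inversion of the fitted curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from sigconn.errors import DataError, FitError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Dose-response observations: log10 concentration vs % growth."""

    x: np.ndarray  # log10(concentration), concentration in ug/uL
    y: np.ndarray  # percent growth vs untreated

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise DataError("x and y must be 1-D arrays of equal length")
        if not np.all(np.isfinite(x)):
            raise DataError("x must be finite")
        if np.unique(x).size < 4:
            raise DataError("need at least 4 distinct doses for fitting")
        out_of_range = np.sum((y < -50) | (y > 150))
        if out_of_range:
            logger.warning("%d response value(s) outside [-50, 150]%%", out_of_range)

    @classmethod
    def from_concentrations(cls, conc, y) -> "DoseResponseCurve":
        """Build from linear-scale concentrations (converted to log10)."""
        conc = np.asarray(conc, dtype=float)
        if np.any(conc <= 0):
            raise DataError("concentrations must be positive")
        return cls(x=np.log10(conc), y=np.asarray(y, dtype=float))


@dataclass(frozen=True)
class HillFit:
    bottom: float
    top: float
    loggi50: float
    h: float
    r2: float
    converged: bool = True

    def __post_init__(self):
        if not self.top > self.bottom:
            raise FitError(f"degenerate fit: top ({self.top}) <= bottom ({self.bottom})")

    def predict(self, x) -> np.ndarray:
        return hill(np.asarray(x, dtype=float), self.bottom, self.top, self.loggi50, self.h)


def hill(x, bottom, top, loggi50, h):
    """Four-parameter logistic in log10 dose."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((loggi50 - x) * h))


def fit_hill(curve: DoseResponseCurve) -> HillFit:
    """Least-squares Hill fit; raises on degenerate (flat) data."""
    x, y = curve.x, curve.y
    if np.var(y) < 1e-12:
        raise FitError("flat response: variance of y is ~0, nothing to fit")

    top0, bottom0 = float(np.max(y)), float(np.min(y))
    mid = (top0 + bottom0) / 2.0
    loggi50_0 = float(x[np.argmin(np.abs(y - mid))])
    p0 = [bottom0, top0, loggi50_0, -1.0]
    span = x.max() - x.min()
    lower = [-200.0, -200.0, x.min() - 2 * span - 1, -50.0]
    upper = [200.0, 200.0, x.max() + 2 * span + 1, 50.0]

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                hill, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
    except RuntimeError:
        converged = False
        popt = p0

    bottom, top, loggi50, h = (float(v) for v in popt)
    if top < bottom:  # canonicalise: (B,T,h) -> (T,B,-h) leaves the curve invariant
        bottom, top, h = top, bottom, -h
    if top - bottom < 1e-9:
        raise FitError("degenerate fit: top == bottom")
    resid = y - hill(x, bottom, top, loggi50, h)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if not converged:
        logger.warning("Hill fit did not converge; returning initial parameters")
    return HillFit(bottom=bottom, top=top, loggi50=loggi50, h=h, r2=r2, converged=converged)


def gi20_from_fit(fit: HillFit, y_target: float = 80.0) -> float:
    """Concentration (linear scale, ug/uL) at which the fit crosses *y_target*.

    Closed form: x* = logGI50 - log10((Top-Bottom)/(y_target-Bottom) - 1) / h.
    Raises if *y_target* is not strictly between Bottom and Top.
    """
    if not (fit.bottom < y_target < fit.top):
        raise FitError(
            f"no GI20 in range: target {y_target}% outside fitted response range "
            f"({fit.bottom:.3g}, {fit.top:.3g})"
        )
    ratio = (fit.top - fit.bottom) / (y_target - fit.bottom) - 1.0
    x_star = fit.loggi50 - np.log10(ratio) / fit.h
    return float(10.0**x_star)
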