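"""Gompertz growth-curve fitting for in-vivo tumor radius series.

Uses the classical three-parameter form

    r(t) = a * exp(-b * exp(-c * t))

with asymptote ``a`` (mm), displacement ``b`` (dimensionless, sets the
initial radius a*e^{-b}) and rate ``c`` (day^-1).  The curve is strictly
increasing for t >= 0 and saturates at ``a``.  Treatment effect is
quantified as a growth delay: the difference in time-to-reference-radius
between two fitted curves, via the closed-form inverse

    t(r) = -ln( ln(a/r) / b ) / c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GompertzFit",
    "gompertz_curve",
    "gompertz_inverse",
    "fit_gompertz",
    "growth_delay",
]


def gompertz_curve(t, a: float, b: float, c: float):
    """Evaluate r(t) = a * exp(-b * exp(-c*t))."""
    t = np.asarray(t, dtype=float)
    return a * np.exp(-b * np.exp(-c * t))


def gompertz_inverse(r: float, a: float, b: float, c: float) -> float:
    """Closed-form t(r); defined for 0 < r < a (negative t for r < a*e^-b)."""
    if not (0.0 < r < a):
        raise ValueError("radius must lie strictly between 0 and the asymptote")
    return -math.log(math.log(a / r) / b) / c


@dataclass
class GompertzFit:
    """Result of a nonlinear least-squares Gompertz fit."""

    asymptote_a: float
    displacement_b: float
    rate_c: float
    residual_sse: float
    converged: bool
    message: str = ""

    def predict(self, t):
        return gompertz_curve(t, self.asymptote_a, self.displacement_b, self.rate_c)

    def time_to_radius(self, r: float) -> float:
        return gompertz_inverse(r, self.asymptote_a, self.displacement_b, self.rate_c)


def _initial_guess(times: np.ndarray, radii: np.ndarray) -> tuple[float, float, float]:
    """Heuristic start: a0 slightly above the data maximum, c0 from the slope
    of log(log(a0/r)) vs t (linear in t with slope -c), b0 from r(t0)."""
    a0 = 1.05 * float(radii.max())
    y = np.log(np.log(a0 / np.minimum(radii, 0.999 * a0)))
    slope, intercept = np.polyfit(times, y, 1)
    c0 = max(-slope, 1e-4)
    b0 = max(math.exp(intercept), 1e-6)
    return a0, b0, c0


def fit_gompertz(
    times: Sequence[float],
    radii: Sequence[float],
    init: Optional[Sequence[float]] = None,
) -> GompertzFit:
    """Fit the Gompertz form to (times, radii) by nonlinear least squares.

    Fitting is on the radius scale with uniform weights.  Deterministic
    given data and start values.  Non-convergence (or a degenerate series
    that defeats the start heuristic) returns a flagged fit with
    diagnostics rather than raising.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(radii, dtype=float)
    if t.size < 4:
        raise ValueError("at least 4 data points are required")
    if t.shape != r.shape:
        raise ValueError("times and radii must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(r <= 0):
        raise ValueError("radii must be positive")

    if init is not None:
        x0 = np.asarray(init, dtype=float)
    else:
        try:
            x0 = np.asarray(_initial_guess(t, r), dtype=float)
        except (ValueError, FloatingPointError):
            x0 = np.array([1.05 * r.max(), 1.0, 0.05])

    def residuals(p):
        return gompertz_curve(t, *p) - r

    try:
        sol = least_squares(
            residuals,
            x0,
            bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=5000,
        )
    except Exception as exc:  # pragma: no cover - scipy raises only on bad input
        return GompertzFit(
            asymptote_a=float(x0[0]),
            displacement_b=float(x0[1]),
            rate_c=float(x0[2]),
            residual_sse=float("nan"),
            converged=False,
            message=str(exc),
        )
    a, b, c = (float(v) for v in sol.x)
    sse = float(np.sum(sol.fun**2))
    # a vanishing rate or displacement means the curve degenerates to a
    # constant (e.g. a flat series): flag rather than report a spurious fit
    degenerate = c <= 1e-6 or b <= 1e-6
    return GompertzFit(
        asymptote_a=a,
        displacement_b=b,
        rate_c=c,
        residual_sse=sse,
        converged=bool(sol.success) and not degenerate,
        message="degenerate fit: rate/displacement unidentifiable" if degenerate else sol.message,
    )


def growth_delay(
    fit_ref: GompertzFit, fit_alt: GompertzFit, reference_radius: float
) -> float:
    """Growth delay (days) of ``fit_alt`` relative to ``fit_ref``.

    Defined as t_alt(reference_radius) - t_ref(reference_radius) with the
    closed-form inverse; positive when the alternative (treated) curve
    reaches the reference radius later.  For a pure time shift the delay is
    independent of the reference radius.
    """
    if reference_radius >= fit_ref.asymptote_a or reference_radius >= fit_alt.asymptote_a:
        raise ValueError("reference radius must lie below both asymptotes")
    return fit_alt.time_to_radius(reference_radius) - fit_ref.time_to_radius(reference_radius)
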