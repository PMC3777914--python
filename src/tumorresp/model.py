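"""Dimensionless spherically symmetric continuum tumor-growth model.

The tumor is a compact sphere of radius ``R`` (non-dimensionalized by the
oxygen diffusion length ``L_D``) fed by nutrient diffusing in from a
well-vascularized boundary.  The steady diffusion-uptake balance yields a
nutrient profile that decays toward the core, so proliferation is
oxygen-limited in the interior while apoptosis acts uniformly.  The boundary
velocity, scaled by the mitosis-to-relaxation parameter ``G``, is

    V/G = -A*R/3 + coth(R) - 1/R

with the dimensionless apoptosis strength

    A = (lambda_A/lambda_M - B) / (1 - B)

where ``lambda_A/lambda_M`` is the apoptosis-to-mitosis rate ratio and ``B``
the vascularization parameter.  ``G = lambda_M*(1-B)/lambda_R`` carries the
sign ``sign(1-B)``; only that sign enters the radially symmetric dynamics
(its magnitude sets the time scale, which is why time is reported as the
G-scaled variable ``tau' = |G|*t``).

Three growth regimes follow:

* low vascularization (``B < lambda_A/lambda_M``, ``B < 1``): ``A > 0``,
  growth arrests at a stationary radius ``R_inf``;
* moderate (``lambda_A/lambda_M <= B < 1``): ``A <= 0``, unbounded growth,
  linear for ``A = 0`` (velocity -> G) and exponential for ``A < 0``;
* high (``B > 1``): ``G < 0``; shrinkage, or unbounded growth for large
  enough initial radius when ``A > 0``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "DegenerateVascularizationError",
    "DimensionlessParameters",
    "GrowthTrajectory",
    "apoptosis_strength",
    "classify_regime",
    "nutrient_profile",
    "boundary_velocity_over_G",
    "stationary_radius",
    "integrate_radius",
]

Regime = Literal["low", "moderate", "high"]
GSign = Literal["positive", "negative", "zero"]

#: below this radius the closed form coth(R) - 1/R suffers catastrophic
#: cancellation; the series R/3 - R^3/45 is exact to ~1e-19 there.
SMALL_R_SWITCHOVER = 1e-3

#: default dimensionless radius below which a shrinking tumor is declared
#: extinct and integration stops.
DEFAULT_EXTINCTION_RADIUS = 1e-6


class DegenerateVascularizationError(ValueError):
    """Raised when B == 1: G vanishes and A is undefined."""


def apoptosis_strength(death_mitosis_ratio: float, B: float) -> float:
    """Dimensionless apoptosis strength A = (lambda_A/lambda_M - B)/(1 - B).

    Parameters
    ----------
    death_mitosis_ratio
        Apoptosis-to-mitosis rate ratio lambda_A/lambda_M (>= 0).
    B
        Vascularization parameter (>= 0, != 1).

    A > 0 means death dominates the vascular supply surplus (stationary
    radius exists in the low regime); A < 0 drives unbounded growth.
    """
    if not (np.isfinite(death_mitosis_ratio) and np.isfinite(B)):
        raise ValueError("inputs must be finite")
    if death_mitosis_ratio < 0 or B < 0:
        raise ValueError("rate ratio and B must be non-negative")
    if B == 1.0:
        raise DegenerateVascularizationError(
            "B == 1 makes G vanish and the apoptosis strength A undefined"
        )
    return (death_mitosis_ratio - B) / (1.0 - B)


def classify_regime(death_mitosis_ratio: float, B: float) -> Regime:
    """Classify the vascularization regime from (lambda_A/lambda_M, B).

    ``low`` when B < lambda_A/lambda_M (and B < 1): A > 0, growth arrests.
    ``moderate`` when lambda_A/lambda_M <= B < 1: A <= 0, unbounded growth.
    ``high`` when B > 1: G < 0.

    The tie B == lambda_A/lambda_M (A = 0) is moderate, matching the
    inclusive A <= 0 condition of that regime.
    """
    if not (np.isfinite(death_mitosis_ratio) and np.isfinite(B)):
        raise ValueError("inputs must be finite")
    if death_mitosis_ratio < 0 or B < 0:
        raise ValueError("rate ratio and B must be non-negative")
    if B == 1.0:
        raise DegenerateVascularizationError("B == 1 is a degenerate boundary case")
    if B > 1.0:
        return "high"
    if B < death_mitosis_ratio:
        return "low"
    return "moderate"


@dataclass(frozen=True)
class DimensionlessParameters:
    """Dimensionless parameter set for one (cell line, dose) condition.

    Attributes
    ----------
    apoptosis_strength_A:
        A = (lambda_A/lambda_M - B)/(1 - B).
    vascularization_B:
        Nutrient supply/uptake balance scaled by vascular density.
    death_mitosis_ratio:
        lambda_A/lambda_M.
    g_sign:
        Sign of G = lambda_M*(1-B)/lambda_R; negative iff B > 1.  Its
        magnitude only rescales time and is never needed numerically.
    regime:
        low / moderate / high vascularization label.
    """

    apoptosis_strength_A: float
    vascularization_B: float
    death_mitosis_ratio: float
    g_sign: GSign
    regime: Regime

    @classmethod
    def from_rates(cls, death_mitosis_ratio: float, B: float) -> "DimensionlessParameters":
        """Build the full parameter set from the rate ratio and B."""
        A = apoptosis_strength(death_mitosis_ratio, B)
        regime = classify_regime(death_mitosis_ratio, B)
        g_sign: GSign = "negative" if B > 1.0 else "positive"
        return cls(
            apoptosis_strength_A=A,
            vascularization_B=B,
            death_mitosis_ratio=death_mitosis_ratio,
            g_sign=g_sign,
            regime=regime,
        )


def nutrient_profile(r: float, R: float) -> float:
    """Steady-state nutrient concentration at radius r inside a tumor of radius R.

    Closed-form solution of the spherically symmetric diffusion-uptake
    balance with unit concentration at the boundary:

        sigma(r) = (R / sinh R) * sinh(r) / r,   sigma(0) = R / sinh R.

    Monotonically non-decreasing in r with sigma(R) = 1; deep cores are
    nutrient-starved (sigma(0) ~ 2R e^{-R} for large R).
    """
    if not (np.isfinite(r) and np.isfinite(R)):
        raise ValueError("inputs must be finite")
    if R <= 0:
        raise ValueError("tumor radius R must be positive")
    if r < 0 or r > R:
        raise ValueError("r must lie in [0, R]")
    # overflow-safe: sinh(r)/sinh(R) = e^{r-R} * (1-e^{-2r})/(1-e^{-2R})
    denom = -math.expm1(-2.0 * R)
    if r == 0.0:
        return 2.0 * R * math.exp(-R) / denom
    return (R / r) * math.exp(r - R) * (-math.expm1(-2.0 * r)) / denom


def boundary_velocity_over_G(R: float, A: float) -> float:
    """G-scaled boundary velocity V/G = -A*R/3 + coth(R) - 1/R.

    For R below ``SMALL_R_SWITCHOVER`` the Laurent series
    R*(1-A)/3 - R^3/45 is used to avoid cancellation between coth(R)
    and 1/R.  As R -> inf the velocity tends to 1 - A*R/3, i.e. V -> G
    for A = 0 and |V| -> |A| G R / 3 for A != 0.
    """
    if not (np.isfinite(R) and np.isfinite(A)):
        raise ValueError("inputs must be finite")
    if R <= 0:
        raise ValueError("radius must be positive")
    if R < SMALL_R_SWITCHOVER:
        return R * (1.0 - A) / 3.0 - R**3 / 45.0
    return -A * R / 3.0 + 1.0 / math.tanh(R) - 1.0 / R


def stationary_radius(A: float, rtol: float = 1e-12) -> Optional[float]:
    """Stationary radius R_inf where the boundary velocity vanishes.

    A unique positive root of V/G exists exactly for 0 < A < 1 (the
    low-vascularization regime): the velocity rises from ~R(1-A)/3 at small
    R and falls as -A*R/3 + 1 at large R.  Returns None outside (0, 1):
    for A <= 0 the velocity is positive for all R (unbounded growth); for
    A >= 1 it is negative for all R (monotone shrinkage).
    """
    if not np.isfinite(A):
        raise ValueError("A must be finite")
    if not (0.0 < A < 1.0):
        return None
    lo = 1e-8
    hi = 1.0
    while boundary_velocity_over_G(hi, A) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for A in (0,1)
            raise RuntimeError("failed to bracket stationary radius")
    return brentq(boundary_velocity_over_G, lo, hi, args=(A,), xtol=1e-14, rtol=rtol)


@dataclass
class GrowthTrajectory:
    """Radius trajectory in G-scaled time tau' = |G|*t.

    ``radii`` holds the dimensionless radius (length scale L_D);
    ``length_scale_LD`` (micrometres), when set, enables the millimetre
    column in exports via R_mm = R * L_D / 1000.
    """

    times: np.ndarray
    radii: np.ndarray
    params: DimensionlessParameters
    length_scale_LD: Optional[float] = None
    extinct: bool = False
    extinction_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.times.shape != self.radii.shape:
            raise ValueError("times and radii must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if self.length_scale_LD is not None and self.length_scale_LD <= 0:
            raise ValueError("length scale L_D must be positive")

    @property
    def radii_mm(self) -> Optional[np.ndarray]:
        if self.length_scale_LD is None:
            return None
        return self.radii * self.length_scale_LD / 1000.0

    def to_frame(self):
        import pandas as pd

        data = {"tau": self.times, "R_dimensionless": self.radii}
        if self.length_scale_LD is not None:
            data["R_mm"] = self.radii_mm
        return pd.DataFrame(data)

    def metadata(self) -> dict:
        return {
            "A": self.params.apoptosis_strength_A,
            "B": self.params.vascularization_B,
            "death_mitosis_ratio": self.params.death_mitosis_ratio,
            "g_sign": self.params.g_sign,
            "regime": self.params.regime,
            "L_D_um": self.length_scale_LD,
            "extinct": self.extinct,
            "extinction_time": self.extinction_time,
        }

    def to_csv(self, path, metadata_path=None) -> None:
        """Write tau/R columns as CSV; metadata as a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")
        meta.write_text(json.dumps(self.metadata(), indent=2) + "\n")


def integrate_radius(
    R0: float,
    params: DimensionlessParameters,
    tau_end: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    extinction_radius: float = DEFAULT_EXTINCTION_RADIUS,
    n_points: int = 400,
    length_scale_LD: Optional[float] = None,
) -> GrowthTrajectory:
    """Integrate dR/dtau' = s * [-A*R/3 + coth R - 1/R] from R(0) = R0.

    ``s`` is +1 for g_sign positive (B < 1) and -1 for negative (B > 1):
    reversing the sign of G reverses the direction of the flow at every
    radius.  Adaptive error control (RK45); integration stops early,
    flagged on the trajectory, if R falls below ``extinction_radius``.
    """
    if params.g_sign == "zero":
        raise DegenerateVascularizationError("g_sign zero: no dynamics (G = 0)")
    if not (np.isfinite(R0) and np.isfinite(tau_end)):
        raise ValueError("inputs must be finite")
    if R0 <= 0 or tau_end <= 0:
        raise ValueError("R0 and tau_end must be positive")
    s = 1.0 if params.g_sign == "positive" else -1.0
    A = params.apoptosis_strength_A

    def rhs(t, y):
        return [s * boundary_velocity_over_G(max(y[0], 1e-300), A)]

    def extinction(t, y):
        return y[0] - extinction_radius

    extinction.terminal = True
    extinction.direction = -1

    t_eval = np.linspace(0.0, tau_end, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, tau_end),
        [R0],
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        events=extinction,
        max_step=tau_end,
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"integration failed: {sol.message}")
    times = sol.t
    radii = sol.y[0]
    extinct = sol.status == 1
    t_ext = float(sol.t_events[0][0]) if extinct and sol.t_events[0].size else None
    # the t=0 sample is the (positive) initial condition; drop any trailing
    # sample at/below the extinction floor so the trajectory stays positive
    keep = radii > 0
    return GrowthTrajectory(
        times=times[keep],
        radii=radii[keep],
        params=params,
        length_scale_LD=length_scale_LD,
        extinct=extinct,
        extinction_time=t_ext,
    )
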