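"""Microvessel density and the dimensionless vascularization parameter B.

B measures nutrient supply from vasculature relative to cellular uptake:

    B = [lambda_B / (lambda + lambda_B)] * sigma_B / sigma_inf

with lambda the uptake rate, lambda_B the vasculature-tissue transfer rate,
sigma_B the vascular nutrient level (capillary PO2) and sigma_inf the level
in host tissue.  Only the composite transfer fraction
lambda_B/(lambda+lambda_B) is identifiable from the data used here, so it is
the exposed parameter.  The tumor-tissue B is obtained by scaling the
normal-tissue estimate by the tumor/normal microvessel-density (MVD) ratio,
MVD being the percent of ROI cross-sectional area occupied by vessels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Literal, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MvdMeasurement",
    "VascularizationEstimate",
    "mvd_percent",
    "vascularization_normal",
    "vascularization_tumor",
    "estimate_vascularization",
    "read_roi_csv",
]

TissueLabel = Literal["normal", "tumor"]


@dataclass
class MvdMeasurement:
    """Per-ROI vessel cross-sectional areas for one tissue type.

    Areas may be in any common unit (um^2 or pixel^2); MVD is a ratio and
    is invariant to the unit as long as both vectors share it.
    """

    roi_vessel_areas: np.ndarray
    roi_areas: np.ndarray
    tissue_label: TissueLabel

    def __post_init__(self) -> None:
        self.roi_vessel_areas = np.asarray(self.roi_vessel_areas, dtype=float)
        self.roi_areas = np.asarray(self.roi_areas, dtype=float)
        if self.roi_vessel_areas.shape != self.roi_areas.shape:
            raise ValueError("vessel-area and ROI-area vectors must have equal length")
        if np.any(self.roi_areas <= 0) or np.any(self.roi_vessel_areas <= 0):
            raise ValueError("all areas must be positive")
        if np.any(self.roi_vessel_areas > self.roi_areas):
            raise ValueError("per-ROI vessel area cannot exceed ROI area")
        if self.tissue_label not in ("normal", "tumor"):
            raise ValueError("tissue_label must be 'normal' or 'tumor'")


def mvd_percent(m: MvdMeasurement) -> Tuple[float, float]:
    """Microvessel density as (mean %, sample sd %) across ROIs.

    Per-ROI percentage is 100 * vessel_area / roi_area; the mean is
    unweighted.  A single ROI returns sd 0 by convention, with a warning.
    """
    if m.roi_areas.size == 0:
        raise ValueError("at least one ROI is required")
    pct = 100.0 * m.roi_vessel_areas / m.roi_areas
    if pct.size == 1:
        warnings.warn("single ROI: standard deviation reported as 0", stacklevel=2)
        return float(pct[0]), 0.0
    return float(pct.mean()), float(pct.std(ddof=1))


def vascularization_normal(
    sigma_B: float, sigma_inf: float, transfer_fraction: float
) -> float:
    """Normal-tissue B = transfer_fraction * sigma_B / sigma_inf.

    sigma_B / sigma_inf are the capillary / tissue PO2 in mmHg;
    transfer_fraction = lambda_B/(lambda+lambda_B) in (0, 1) is the
    supply/uptake balance (0.5 when supply balances uptake).
    """
    if sigma_B <= 0 or sigma_inf <= 0:
        raise ValueError("PO2 values must be positive")
    if not (0.0 < transfer_fraction < 1.0):
        raise ValueError("transfer fraction must lie in (0, 1)")
    return transfer_fraction * sigma_B / sigma_inf


def vascularization_tumor(
    B_normal: float, mvd_tumor_pct: float, mvd_normal_pct: float
) -> float:
    """Tumor-tissue B: normal-tissue B scaled by the tumor/normal MVD ratio."""
    if B_normal <= 0 or mvd_tumor_pct <= 0:
        raise ValueError("B_normal and tumor MVD must be positive")
    if mvd_normal_pct <= 0:
        raise ValueError("normal-tissue MVD must be positive")
    return B_normal * (mvd_tumor_pct / mvd_normal_pct)


@dataclass(frozen=True)
class VascularizationEstimate:
    """Full B-estimation chain: PO2 constants -> B_normal -> MVD ratio -> B_tumor."""

    sigma_B: float
    sigma_inf: float
    transfer_fraction: float
    B_normal: float
    mvd_normal_pct: float
    mvd_normal_sd: float
    mvd_tumor_pct: float
    mvd_tumor_sd: float
    mvd_ratio: float
    B_tumor: float
    B_tumor_sd: Optional[float] = None


def estimate_vascularization(
    normal: MvdMeasurement,
    tumor: MvdMeasurement,
    sigma_B: float = 40.0,
    sigma_inf: float = 8.0,
    transfer_fraction: float = 0.5,
    propagate_sd: bool = False,
) -> VascularizationEstimate:
    """Run the full chain from ROI tables and PO2 constants to B_tumor.

    The MVD ratio is computed from the unrounded ROI means.  B is a point
    estimate; ``propagate_sd`` optionally attaches a first-order
    delta-method sd (an extension beyond the point-estimate treatment),
    treating the two MVD means as independent.
    """
    mvd_n, sd_n = mvd_percent(normal)
    mvd_t, sd_t = mvd_percent(tumor)
    B_n = vascularization_normal(sigma_B, sigma_inf, transfer_fraction)
    B_t = vascularization_tumor(B_n, mvd_t, mvd_n)
    B_t_sd = None
    if propagate_sd:
        n_n, n_t = normal.roi_areas.size, tumor.roi_areas.size
        se_n = sd_n / math.sqrt(n_n)
        se_t = sd_t / math.sqrt(n_t)
        rel_var = (se_t / mvd_t) ** 2 + (se_n / mvd_n) ** 2
        B_t_sd = B_t * math.sqrt(rel_var)
    return VascularizationEstimate(
        sigma_B=sigma_B,
        sigma_inf=sigma_inf,
        transfer_fraction=transfer_fraction,
        B_normal=B_n,
        mvd_normal_pct=mvd_n,
        mvd_normal_sd=sd_n,
        mvd_tumor_pct=mvd_t,
        mvd_tumor_sd=sd_t,
        mvd_ratio=mvd_t / mvd_n,
        B_tumor=B_t,
        B_tumor_sd=B_t_sd,
    )


def read_roi_csv(path) -> Dict[str, MvdMeasurement]:
    """Read a histology ROI CSV into per-tissue measurements.

    Schema: optional leading ``# key: value`` metadata (e.g. unit), then
    columns ``roi_id``, ``vessel_area``, ``roi_area``, ``tissue_label``.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"roi_id", "vessel_area", "roi_area", "tissue_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI CSV must contain columns {sorted(required)}")
    out: Dict[str, MvdMeasurement] = {}
    for label, grp in df.groupby("tissue_label"):
        out[str(label)] = MvdMeasurement(
            roi_vessel_areas=grp["vessel_area"].to_numpy(dtype=float),
            roi_areas=grp["roi_area"].to_numpy(dtype=float),
            tissue_label=str(label),  # type: ignore[arg-type]
        )
    return out
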