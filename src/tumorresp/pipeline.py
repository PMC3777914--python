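"""End-to-end orchestration: calibration -> vascularization -> model -> fits.

``run_pipeline`` composes the library stages into a single deterministic
report: per-condition kinetic rates and dimensionless parameters with
regime labels, the B-estimation chain, radius trajectories from the
treatment-start radius, and optional Gompertz fits of in-vivo series with
a growth-delay comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import data as published
from .calibration import KineticRates, ViabilityAssay, calibrate
from .gompertz import GompertzFit, fit_gompertz, growth_delay
from .model import DimensionlessParameters, GrowthTrajectory, integrate_radius, stationary_radius
from .units import CellGeometry, cells_from_signal, radius_from_cells
from .vascular import MvdMeasurement, VascularizationEstimate, estimate_vascularization

__all__ = ["PipelineReport", "run_pipeline", "condition_table", "trajectory_summary"]

logger = logging.getLogger("tumorresp.pipeline")


def condition_table(
    rates_by_line: Mapping[str, KineticRates], B: float
) -> pd.DataFrame:
    """Per-condition table: lambda_A, lambda_A/lambda_M, A, regime.

    One row per (cell line, concentration), everything derived from the
    calibrated rates and the tumor-tissue vascularization parameter B.
    """
    rows = []
    for line, rates in rates_by_line.items():
        ratios = rates.death_mitosis_ratios()
        for conc in sorted(rates.apoptosis_rates):
            ratio = ratios[conc]
            params = DimensionlessParameters.from_rates(ratio, B)
            rows.append(
                {
                    "cell_line": line,
                    "concentration_nM": conc,
                    "lambda_A_per_day": rates.apoptosis_rates[conc],
                    "lambda_M_per_day": rates.mitosis_rate_lambdaM,
                    "death_mitosis_ratio": ratio,
                    "A": params.apoptosis_strength_A,
                    "regime": params.regime,
                }
            )
    return pd.DataFrame(rows)


def trajectory_summary(traj: GrowthTrajectory) -> dict:
    """Compact summary of one integrated trajectory."""
    R_inf = stationary_radius(traj.params.apoptosis_strength_A)
    return {
        "regime": traj.params.regime,
        "A": traj.params.apoptosis_strength_A,
        "R0": float(traj.radii[0]),
        "R_final": float(traj.radii[-1]),
        "tau_final": float(traj.times[-1]),
        "stationary_R": R_inf,
        "extinct": traj.extinct,
    }


@dataclass
class PipelineReport:
    """Full deterministic analysis report.

    ``conditions`` mirrors the per-condition rate table; ``vascularization``
    carries the B chain; ``trajectories`` one summary per condition;
    ``gompertz`` the in-vivo fits and growth delay when series were given.
    """

    conditions: pd.DataFrame
    vascularization: VascularizationEstimate
    trajectories: Dict[str, dict]
    gompertz: Dict[str, dict] = field(default_factory=dict)
    delay_days: Optional[float] = None
    provenance: Dict[str, object] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "conditions": self.conditions.to_dict(orient="records"),
            "vascularization": {
                "sigma_B_mmHg": self.vascularization.sigma_B,
                "sigma_inf_mmHg": self.vascularization.sigma_inf,
                "transfer_fraction": self.vascularization.transfer_fraction,
                "B_normal": self.vascularization.B_normal,
                "mvd_normal_pct": self.vascularization.mvd_normal_pct,
                "mvd_tumor_pct": self.vascularization.mvd_tumor_pct,
                "mvd_ratio": self.vascularization.mvd_ratio,
                "B_tumor": self.vascularization.B_tumor,
            },
            "trajectories": self.trajectories,
            "gompertz": self.gompertz,
            "delay_days": self.delay_days,
            "provenance": self.provenance,
        }

    def write(self, out_dir) -> None:
        """Write the report: conditions CSV + full JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.conditions.to_csv(out / "conditions.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, default=_jsonable) + "\n"
        )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    assays: Mapping[str, ViabilityAssay],
    normal_rois: MvdMeasurement,
    tumor_rois: MvdMeasurement,
    lambda_M: Optional[Mapping[str, float]] = None,
    series: Optional[Mapping[str, pd.DataFrame]] = None,
    series_cell_line: Optional[str] = None,
    signal_per_cell: float = 100.0,
    sigma_B: float = published.SIGMA_B_MMHG,
    sigma_inf: float = published.SIGMA_INF_MMHG,
    transfer_fraction: float = published.TRANSFER_FRACTION,
    treatment_start_radius_mm: float = published.TREATMENT_START_RADIUS_MM,
    L_D_um: float = published.DEFAULT_L_D_UM,
    tau_end: float = 20.0,
    b_decimals: Optional[int] = 2,
    seed: Optional[int] = None,
) -> PipelineReport:
    """Run calibration -> B estimation -> classification -> trajectories -> fits.

    Parameters
    ----------
    assays
        One viability assay per cell line.
    normal_rois, tumor_rois
        Histology ROI measurements for the B chain.
    lambda_M
        Stated mitosis rates per cell line, used when an assay lacks raw
        counts.
    series
        Optional in-vivo measurement series (columns ``day`` and ``signal``
        or ``radius_mm``) keyed by arm name; the arm named ``"untreated"``
        (or the first arm) is the delay reference.
    series_cell_line
        Cell line whose geometry converts signal to radius (defaults to
        the first assay's line).
    treatment_start_radius_mm, L_D_um
        Initial radius and oxygen diffusion length; the dimensionless
        initial radius is their ratio.
    b_decimals
        The B chain reports its point estimate at two decimals and the
        parameter table uses that rounded value (the reporting convention
        of the source analysis); None disables the rounding.
    """
    lambda_M = dict(lambda_M or {})
    rates_by_line: Dict[str, KineticRates] = {}
    for line, assay in assays.items():
        rates_by_line[line] = calibrate(assay, lambda_M.get(line))
        logger.info("calibrated %s: lambda_M=%.4g", line, rates_by_line[line].mitosis_rate_lambdaM)

    vasc = estimate_vascularization(
        normal_rois,
        tumor_rois,
        sigma_B=sigma_B,
        sigma_inf=sigma_inf,
        transfer_fraction=transfer_fraction,
    )
    B = vasc.B_tumor if b_decimals is None else round(vasc.B_tumor, b_decimals)
    logger.info(
        "B chain: B_normal=%.4g, MVD ratio=%.4g, B_tumor=%.4g (using B=%g)",
        vasc.B_normal, vasc.mvd_ratio, vasc.B_tumor, B,
    )

    conditions = condition_table(rates_by_line, B)

    R0 = treatment_start_radius_mm * 1000.0 / L_D_um
    logger.info("trajectory R0 = %.3g (%.2g mm at L_D = %g um)", R0, treatment_start_radius_mm, L_D_um)
    trajectories: Dict[str, dict] = {}
    for _, row in conditions.iterrows():
        params = DimensionlessParameters.from_rates(row["death_mitosis_ratio"], B)
        traj = integrate_radius(R0, params, tau_end, length_scale_LD=L_D_um)
        key = f"{row['cell_line']}@{row['concentration_nM']:g}nM"
        trajectories[key] = trajectory_summary(traj)

    gomp: Dict[str, dict] = {}
    delay: Optional[float] = None
    if series:
        line = series_cell_line or next(iter(assays))
        geom = published.CELL_GEOMETRY.get(line, published.CELL_GEOMETRY["MiaPaCa-2"])
        fits: Dict[str, GompertzFit] = {}
        for arm, df in series.items():
            radii = _series_radius_mm(df, geom, signal_per_cell)
            fit = fit_gompertz(df["day"].to_numpy(dtype=float), radii)
            fits[arm] = fit
            gomp[arm] = {
                "a_mm": fit.asymptote_a,
                "b": fit.displacement_b,
                "c_per_day": fit.rate_c,
                "sse": fit.residual_sse,
                "converged": fit.converged,
            }
        ref_name = "untreated" if "untreated" in fits else next(iter(fits))
        others = [k for k in fits if k != ref_name]
        if others and fits[ref_name].converged and fits[others[0]].converged:
            ref_fit, alt_fit = fits[ref_name], fits[others[0]]
            r0 = ref_fit.predict(0.0)
            reference_radius = 0.5 * (float(r0) + min(ref_fit.asymptote_a, alt_fit.asymptote_a))
            delay = growth_delay(ref_fit, alt_fit, reference_radius)
            gomp["delay"] = {
                "reference_arm": ref_name,
                "alternative_arm": others[0],
                "reference_radius_mm": reference_radius,
                "delay_days": delay,
            }

    provenance = {
        "seed": seed,
        "config_hash": _config_hash(
            {
                "sigma_B": sigma_B,
                "sigma_inf": sigma_inf,
                "transfer_fraction": transfer_fraction,
                "treatment_start_radius_mm": treatment_start_radius_mm,
                "L_D_um": L_D_um,
                "tau_end": tau_end,
                "lambda_M": lambda_M,
                "B_used": B,
            }
        ),
        "version": __import__("tumorresp").__version__,
    }
    return PipelineReport(
        conditions=conditions,
        vascularization=vasc,
        trajectories=trajectories,
        gompertz=gomp,
        delay_days=delay,
        provenance=provenance,
    )


def _series_radius_mm(df: pd.DataFrame, geom: CellGeometry, signal_per_cell: float) -> np.ndarray:
    """Radius series (mm) from a measurement frame (signal or radius_mm column)."""
    if "radius_mm" in df.columns:
        return df["radius_mm"].to_numpy(dtype=float)
    if "signal" not in df.columns:
        raise ValueError("series needs a 'signal' or 'radius_mm' column")
    cells = np.array(
        [cells_from_signal(s, signal_per_cell) for s in df["signal"].to_numpy(dtype=float)]
    )
    return np.array([radius_from_cells(n, geom) for n in cells]) / 1000.0
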