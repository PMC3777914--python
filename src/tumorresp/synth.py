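"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates the three input kinds the analysis consumes — monolayer viability
assays, histology ROI tables, and in-vivo bioluminescence series — from the
same kinetic/geometric model the pipeline inverts, so every stage is
testable end-to-end without external data.

Noise is multiplicative lognormal everywhere (viability, MVD, signal): all
three are positive, skewed measurements reported as percent-of-control or
photon counts.  Draws are mean-one so zero CV reproduces the noise-free
model exactly.  A single global seed is fanned out into fixed per-generator
substreams, so adding one generator never shifts another's draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional

import numpy as np
import pandas as pd

from .calibration import ViabilityAssay
from .gompertz import gompertz_curve
from .model import DimensionlessParameters, integrate_radius
from .units import CellGeometry, cells_from_radius, signal_from_cells
from .vascular import MvdMeasurement

__all__ = [
    "SyntheticConfig",
    "InVivoConfig",
    "synth_viability_assay",
    "synth_mvd_rois",
    "synth_in_vivo_series",
]

# fixed substream indices: adding a generator appends, never reorders
_STREAM_VIABILITY = 0
_STREAM_INVIVO = 1
_STREAM_MVD_NORMAL = 2
_STREAM_MVD_TUMOR = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with coefficient of variation cv."""
    if cv < 0:
        raise ValueError("noise CV must be non-negative")
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


@dataclass(frozen=True)
class InVivoConfig:
    """In-vivo series settings.

    ``mode`` selects the generating radius path: the Gompertz closed form
    (parameters a mm, b, c day^-1) or the continuum model (A, B via the
    parameter set, |G| day^-1 time scale, L_D um length scale).
    """

    mode: Literal["gompertz", "model"] = "gompertz"
    gompertz_a: float = 3.5  # mm
    gompertz_b: float = 2.0
    gompertz_c: float = 0.05  # day^-1
    model_params: Optional[DimensionlessParameters] = None
    model_R0_dimensionless: float = 7.5  # 1.5 mm at L_D = 200 um
    abs_G: float = 1.0  # day^-1
    L_D_um: float = 200.0
    sampling_interval_days: float = 7.0
    horizon_days: float = 50.0
    signal_per_cell: float = 100.0  # photons/s per cell
    signal_noise_cv: float = 0.10


@dataclass(frozen=True)
class SyntheticConfig:
    """Seeded generating conditions for all pipeline inputs.

    Defaults mirror the assay design the pipeline targets: 2000 seeded
    cells per well, doses (0, 3, 30, 300) nM for 1 day with n = 4
    replicates and 5% viability CV; MVD area fractions 1.56% (normal) and
    0.27% (tumor) over 10 ROIs with CV 0.6; weekly in-vivo imaging over
    50 days.
    """

    seed: int = 0
    true_lambdaM: float = 1.23  # day^-1
    kill_model: Dict[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 3.0: 3.14e-2, 30.0: 1.48e-1, 300.0: 4.65e-1}
    )
    exposure_time_T: float = 1.0  # days
    initial_count_NI: float = 2000.0  # cells/well
    replicate_count: int = 4
    viability_noise_cv: float = 0.05
    drug_name: str = "gemcitabine"
    cell_line: str = "MiaPaCa-2"
    mvd_true_fraction: Dict[str, float] = field(
        default_factory=lambda: {"normal": 0.0156, "tumor": 0.0027}
    )
    roi_count: int = 10
    roi_area: float = 1e6  # um^2
    mvd_noise_cv: float = 0.6
    cell_geometry: CellGeometry = field(
        default_factory=lambda: CellGeometry(cell_radius=9.0, packing_fraction=0.761)
    )
    in_vivo: InVivoConfig = field(default_factory=InVivoConfig)

    def __post_init__(self) -> None:
        if self.replicate_count < 1 or self.roi_count < 1:
            raise ValueError("replicate and ROI counts must be >= 1")
        if min(self.viability_noise_cv, self.mvd_noise_cv, self.in_vivo.signal_noise_cv) < 0:
            raise ValueError("noise CVs must be non-negative")
        if self.true_lambdaM <= 0 or self.exposure_time_T <= 0 or self.initial_count_NI <= 0:
            raise ValueError("kinetic constants must be positive")


def synth_viability_assay(cfg: SyntheticConfig) -> ViabilityAssay:
    """Generate a monolayer cytotoxicity assay from exponential kinetics.

    Control grows as N_C = N_I exp(lambda_M T); a treated well holds
    N(d) = N_I exp((lambda_M - lambda_A(d)) T), floored at one cell with a
    warning if the kill rate would drive it below a single cell.  Replicate
    fractions N(d)/N_C are perturbed by mean-one lognormal noise at the
    configured CV; deterministic under the seed.
    """
    rng = _rng(cfg.seed, _STREAM_VIABILITY)
    conc = np.array(sorted(cfg.kill_model), dtype=float)
    T = cfg.exposure_time_T
    N_C = cfg.initial_count_NI * math.exp(cfg.true_lambdaM * T)
    counts = []
    for c in conc:
        n = cfg.initial_count_NI * math.exp((cfg.true_lambdaM - cfg.kill_model[c]) * T)
        if n < 1.0:
            warnings.warn(
                f"kill rate at {c} nM drives the well below one cell; floored at 1",
                stacklevel=2,
            )
            n = 1.0
        counts.append(n)
    fractions = np.array(counts) / N_C
    noise = _lognormal_factors(rng, cfg.viability_noise_cv, (cfg.replicate_count, conc.size))
    reps = fractions[None, :] * noise
    reps[:, conc == 0.0] = 1.0  # control wells define the denominator
    return ViabilityAssay.from_replicates(
        drug_name=cfg.drug_name,
        concentrations=conc,
        replicate_fractions=reps,
        exposure_time_T=T,
        initial_count_NI=cfg.initial_count_NI,
        control_count_NC=N_C,
        cell_line=cfg.cell_line,
    )


def synth_mvd_rois(cfg: SyntheticConfig, tissue: str = "tumor") -> MvdMeasurement:
    """Generate per-ROI vessel areas around the true area fraction.

    Fractions are mean-one lognormal around the configured true fraction,
    truncated to (0, 1); deterministic under the seed, with independent
    substreams per tissue.
    """
    if tissue not in cfg.mvd_true_fraction:
        raise ValueError(f"no true MVD fraction configured for tissue {tissue!r}")
    stream = _STREAM_MVD_NORMAL if tissue == "normal" else _STREAM_MVD_TUMOR
    rng = _rng(cfg.seed, stream)
    true = cfg.mvd_true_fraction[tissue]
    fractions = true * _lognormal_factors(rng, cfg.mvd_noise_cv, cfg.roi_count)
    fractions = np.clip(fractions, 1e-12, 1.0 - 1e-12)
    return MvdMeasurement(
        roi_vessel_areas=fractions * cfg.roi_area,
        roi_areas=np.full(cfg.roi_count, cfg.roi_area),
        tissue_label=tissue,  # type: ignore[arg-type]
    )


def _model_radius_path_mm(iv: InVivoConfig, days: np.ndarray) -> np.ndarray:
    if iv.model_params is None:
        raise ValueError("model mode requires model_params")
    tau_end = iv.abs_G * float(days[-1]) if days[-1] > 0 else 1.0
    traj = integrate_radius(
        iv.model_R0_dimensionless,
        iv.model_params,
        tau_end,
        length_scale_LD=iv.L_D_um,
        n_points=2000,
    )
    taus = iv.abs_G * days
    R = np.interp(taus, traj.times, traj.radii)
    return R * iv.L_D_um / 1000.0


def synth_in_vivo_series(cfg: SyntheticConfig) -> pd.DataFrame:
    """Generate a bioluminescence measurement series for one animal.

    The radius path (Gompertz closed form or integrated continuum model,
    dimensionalized by L_D and |G|) is converted to a cell number via the
    cell geometry, then to photon emission via ``signal_per_cell``, with
    mean-one lognormal signal noise.  Columns: ``day``, ``signal``, and
    ``radius_mm_true`` (the noise-free generating radius, kept for
    recovery checks; readers of real data ignore it).
    """
    iv = cfg.in_vivo
    rng = _rng(cfg.seed, _STREAM_INVIVO)
    days = np.arange(0.0, iv.horizon_days + 1e-9, iv.sampling_interval_days)
    if iv.mode == "gompertz":
        radius_mm = gompertz_curve(days, iv.gompertz_a, iv.gompertz_b, iv.gompertz_c)
    elif iv.mode == "model":
        if iv.model_params is not None and iv.model_params.g_sign == "zero":
            raise ValueError("model mode requires a nonzero G sign")
        radius_mm = _model_radius_path_mm(iv, days)
    else:
        raise ValueError(f"unknown in-vivo mode {iv.mode!r}")
    cells = np.array(
        [cells_from_radius(r * 1000.0, cfg.cell_geometry) for r in radius_mm]
    )
    signal = np.array([signal_from_cells(n, iv.signal_per_cell) for n in cells])
    signal = signal * _lognormal_factors(rng, iv.signal_noise_cv, days.size)
    return pd.DataFrame({"day": days, "signal": signal, "radius_mm_true": radius_mm})
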