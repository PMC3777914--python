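"""Deterministic conversions tying model quantities to measurements.

Covers: tumor radius <-> cell number (sphere-packing), bioluminescent
signal -> cell number (linear, zero intercept), nanomolar drug
concentration -> bolus-equivalent mg/kg dose, and constant-exposure AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "CellGeometry",
    "DoseContext",
    "cells_from_radius",
    "radius_from_cells",
    "cells_from_signal",
    "signal_from_cells",
    "packing_fraction_from_roi",
    "plasma_concentration_equivalent",
    "auc_constant_exposure",
]

#: free-base gemcitabine molecular weight (g/mol); the HCl salt is 299.7.
GEMCITABINE_MW = 263.2


@dataclass(frozen=True)
class CellGeometry:
    """Cell radius (um) and volume packing fraction for a cell line.

    The packing fraction is a single dimensionless factor used for both
    the 2-D (ROI count) estimate and the 3-D radius conversion — an
    approximation mirroring how sphere/circle packing references
    (0.74 in 3-D, 0.813 in 2-D) bracket the measured ~0.761.
    """

    cell_radius: float
    packing_fraction: float

    def __post_init__(self) -> None:
        if self.cell_radius <= 0:
            raise ValueError("cell radius must be positive")
        if not (0.0 < self.packing_fraction <= 1.0):
            raise ValueError("packing fraction must lie in (0, 1]")


@dataclass(frozen=True)
class DoseContext:
    """Drug and animal constants for the nM -> mg/kg bolus conversion."""

    molecular_weight: float = GEMCITABINE_MW  # g/mol
    plasma_volume: float = 1.2  # mL
    body_mass: float = 20.0  # g

    def __post_init__(self) -> None:
        if min(self.molecular_weight, self.plasma_volume, self.body_mass) <= 0:
            raise ValueError("dose-context constants must be positive")


def cells_from_radius(tumor_radius: float, geom: CellGeometry) -> float:
    """Cell number in a spherical tumor: phi * (R / r_cell)^3.

    ``tumor_radius`` in um.  The smallest admissible tumor is one cell.
    """
    if not math.isfinite(tumor_radius):
        raise ValueError("tumor radius must be finite")
    if tumor_radius < geom.cell_radius:
        raise ValueError("tumor radius cannot be smaller than one cell radius")
    return geom.packing_fraction * (tumor_radius / geom.cell_radius) ** 3


def radius_from_cells(cell_count: float, geom: CellGeometry) -> float:
    """Inverse of :func:`cells_from_radius`: R = r_cell * (N / phi)^(1/3) (um)."""
    if cell_count <= 0 or not math.isfinite(cell_count):
        raise ValueError("cell count must be positive and finite")
    return geom.cell_radius * (cell_count / geom.packing_fraction) ** (1.0 / 3.0)


def cells_from_signal(signal: float, signal_per_cell: float) -> float:
    """Cell number from bioluminescent emission, N = signal / k.

    Emission and cell number are linearly proportional with zero intercept;
    ``signal_per_cell`` (photons/s per cell) is the calibration constant.
    """
    if not (math.isfinite(signal) and math.isfinite(signal_per_cell)):
        raise ValueError("inputs must be finite")
    if signal_per_cell <= 0:
        raise ValueError("signal per cell must be positive")
    if signal < 0:
        raise ValueError("signal must be non-negative")
    return signal / signal_per_cell


def signal_from_cells(cell_count: float, signal_per_cell: float) -> float:
    """Forward linear map, exact inverse of :func:`cells_from_signal`."""
    if signal_per_cell <= 0:
        raise ValueError("signal per cell must be positive")
    if cell_count < 0:
        raise ValueError("cell count must be non-negative")
    return cell_count * signal_per_cell


def packing_fraction_from_roi(
    cell_count: int, cell_radius: float, roi_area: float
) -> float:
    """Area packing fraction from a counted circular ROI: N * pi * r^2 / area."""
    if roi_area <= 0:
        raise ValueError("ROI area must be positive")
    if cell_count <= 0 or cell_radius <= 0:
        raise ValueError("cell count and radius must be positive")
    frac = cell_count * math.pi * cell_radius**2 / roi_area
    if frac > 1.0:
        warnings.warn(
            f"packing fraction {frac:.3f} > 1 clipped to 1 (overlapping/miscounted cells)",
            stacklevel=2,
        )
        frac = 1.0
    return frac


def plasma_concentration_equivalent(conc: float, ctx: DoseContext) -> float:
    """Bolus dose (mg drug / kg body mass) giving plasma concentration ``conc`` (nM).

    mass = conc[mol/L] * plasma volume[L] * MW[g/mol]; dose = mass / body mass.
    Linear in conc with zero intercept.
    """
    if conc < 0 or not math.isfinite(conc):
        raise ValueError("concentration must be non-negative and finite")
    mol_per_L = conc * 1e-9
    grams = mol_per_L * (ctx.plasma_volume * 1e-3) * ctx.molecular_weight
    return grams * 1e3 / (ctx.body_mass * 1e-3)


def auc_constant_exposure(
    conc: float, duration: float, molecular_weight: float = GEMCITABINE_MW
) -> float:
    """AUC (ug*hr/mL) of a constant exposure: conc (nM) held for ``duration`` hours.

    conc[nM] * 1e-9 [mol/L] * MW [g/mol] = g/L = mg/mL*1e-3 -> ug/mL via *1e3.
    """
    if conc < 0 or duration < 0 or molecular_weight <= 0:
        raise ValueError("inputs must be non-negative (MW positive)")
    ug_per_ml = conc * 1e-9 * molecular_weight * 1e3
    return ug_per_ml * duration
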