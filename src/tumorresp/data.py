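"""Published experimental constants used as pipeline inputs.

These are measured inputs (rates from monolayer cytotoxicity, PO2 levels,
microvessel densities, cell geometry), not outputs of this package: the
pipeline recomputes every derived quantity (rate ratios, apoptosis
strength A, B chain, regime labels) from them.
"""

from __future__ import annotations

import pandas as pd

from .units import CellGeometry

#: mitosis rates from 24 h monolayer expansion (day^-1), T = 1 day
LAMBDA_M = {"MiaPaCa-2": 1.23, "S2-VP10": 2.63}

#: apoptosis rates per gemcitabine dose (nM -> day^-1) from viability assays
LAMBDA_A = {
    "MiaPaCa-2": {0.0: 0.0, 3.0: 3.14e-2, 30.0: 1.48e-1, 300.0: 4.65e-1},
    "S2-VP10": {0.0: 0.0, 3.0: 2.04e-1, 30.0: 8.25e-1, 300.0: 1.44},
}

#: 24 h viable fractions of control at 300 nM (dose-response endpoints)
VIABLE_FRACTION_300NM = {"MiaPaCa-2": 0.62, "S2-VP10": 0.24}

#: oxygen partial pressures (mmHg): capillary and host tissue
SIGMA_B_MMHG = 40.0
SIGMA_INF_MMHG = 8.0
#: supply/uptake transfer fraction lambda_B/(lambda+lambda_B)
TRANSFER_FRACTION = 0.5

#: microvessel density area percentages (mean, sd) per tissue
MVD_PERCENT = {"normal": (1.56, 0.94), "tumor": (0.27, 0.26)}

#: measured cell geometry (H&E): radius um, shared packing factor
CELL_GEOMETRY = {
    "MiaPaCa-2": CellGeometry(cell_radius=9.0, packing_fraction=0.761),
    "S2-VP10": CellGeometry(cell_radius=7.0, packing_fraction=0.761),
}

#: treatment begins when the tumor reaches this radius (mm)
TREATMENT_START_RADIUS_MM = 1.5

#: conventional oxygen diffusion length (um), default dimensionalization scale
DEFAULT_L_D_UM = 200.0


def kinetic_inputs() -> pd.DataFrame:
    """Long-form table of the measured kinetic inputs per (cell line, dose)."""
    rows = []
    for line, per_dose in LAMBDA_A.items():
        for conc, la in sorted(per_dose.items()):
            rows.append(
                {
                    "cell_line": line,
                    "concentration_nM": conc,
                    "lambda_A_per_day": la,
                    "lambda_M_per_day": LAMBDA_M[line],
                }
            )
    return pd.DataFrame(rows)
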