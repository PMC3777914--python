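"""Kinetic-rate calibration from monolayer cytotoxicity assays.

Monolayer growth/kill is modeled as exponential over the exposure window:
the untreated control expands as N_C = N_I * exp(lambda_M * T) and a
treated well as N(d) = N_I * exp((lambda_M - lambda_A(d)) * T), so

    lambda_M = ln(N_C / N_I) / T
    lambda_A(d) = ln(N_C / N(d)) / T = -ln(viable fraction) / T.

Rates are treated as constants for cells under similar conditions during
the treatment window (optimal-exposure assumption): calibration returns a
single mitosis rate and one apoptosis rate per drug concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ViabilityAssay",
    "KineticRates",
    "mitosis_rate",
    "apoptosis_rate_from_viability",
    "calibrate",
    "read_assay_csv",
]


def mitosis_rate(N_C: float, N_I: float, T: float) -> float:
    """Net mitosis rate lambda_M = ln(N_C/N_I)/T (per day).

    N_C is the untreated viable count at time T, N_I the seeded count.
    Positive iff the control expanded.
    """
    if N_C <= 0 or N_I <= 0 or T <= 0:
        raise ValueError("counts and exposure time must be positive")
    return math.log(N_C / N_I) / T


def apoptosis_rate_from_viability(viable_fraction: float, T: float) -> float:
    """Drug-induced apoptosis rate lambda_A = -ln(viable fraction)/T (per day).

    ``viable_fraction`` is the treated viable count as a fraction of the
    untreated control, in (0, 1].  Fractions above 1 (treated exceeding
    control) must be clipped upstream: the rate is non-negative by model
    definition.
    """
    if T <= 0:
        raise ValueError("exposure time must be positive")
    if not (0.0 < viable_fraction <= 1.0):
        raise ValueError("viable fraction must lie in (0, 1]")
    return -math.log(viable_fraction) / T


@dataclass
class ViabilityAssay:
    """Dose-response table from one monolayer cytotoxicity experiment.

    ``viable_fraction`` is the replicate-mean fraction of untreated control
    per concentration; ``replicate_fractions`` (replicate x concentration)
    keeps the raw replicates when available.  Raw counts ``initial_count_NI``
    / ``control_count_NC`` enable mitosis-rate extraction.
    """

    drug_name: str
    concentrations: np.ndarray
    exposure_time_T: float
    viable_fraction: np.ndarray
    replicate_fractions: Optional[np.ndarray] = None
    initial_count_NI: Optional[float] = None
    control_count_NC: Optional[float] = None
    cell_line: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viable_fraction = np.asarray(self.viable_fraction, dtype=float)
        if self.exposure_time_T <= 0:
            raise ValueError("exposure time must be positive")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be sorted ascending and unique")
        if self.viable_fraction.shape != self.concentrations.shape:
            raise ValueError("viable_fraction length must match concentrations")
        if np.any(self.viable_fraction <= 0) or np.any(self.viable_fraction > 1):
            raise ValueError("viable fractions must lie in (0, 1]")
        zero = self.concentrations == 0
        if np.any(zero) and not np.allclose(self.viable_fraction[zero], 1.0, atol=5e-3):
            raise ValueError("viable fraction at concentration 0 must equal 1")
        if self.replicate_fractions is not None:
            self.replicate_fractions = np.asarray(self.replicate_fractions, dtype=float)
            if self.replicate_fractions.shape[1] != self.concentrations.size:
                raise ValueError("replicate matrix columns must match concentrations")

    @classmethod
    def from_replicates(
        cls,
        drug_name: str,
        concentrations,
        replicate_fractions,
        exposure_time_T: float,
        **kwargs,
    ) -> "ViabilityAssay":
        """Build from raw replicate fractions, clipping values above 1.

        Treated-above-control replicates are clipped to 1 with a warning
        (the apoptosis rate is defined non-negative).
        """
        reps = np.asarray(replicate_fractions, dtype=float)
        if np.any(reps > 1.0):
            warnings.warn(
                "replicate viable fractions above 1 clipped to 1 "
                "(treated exceeded control)",
                stacklevel=2,
            )
            reps = np.minimum(reps, 1.0)
        means = reps.mean(axis=0)
        conc = np.asarray(concentrations, dtype=float)
        means = np.where(conc == 0, 1.0, np.minimum(means, 1.0))
        return cls(
            drug_name=drug_name,
            concentrations=conc,
            exposure_time_T=exposure_time_T,
            viable_fraction=means,
            replicate_fractions=reps,
            **kwargs,
        )

    def fraction_se(self) -> Optional[np.ndarray]:
        """Standard error of the replicate mean per concentration."""
        if self.replicate_fractions is None or self.replicate_fractions.shape[0] < 2:
            return None
        n = self.replicate_fractions.shape[0]
        return self.replicate_fractions.std(axis=0, ddof=1) / math.sqrt(n)


@dataclass
class KineticRates:
    """Calibrated mitosis rate and per-concentration apoptosis rates (day^-1)."""

    mitosis_rate_lambdaM: float
    apoptosis_rates: Dict[float, float]
    exposure_time_T: float
    apoptosis_rate_se: Dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mitosis_rate_lambdaM <= 0:
            raise ValueError("mitosis rate must be positive")
        if 0.0 in self.apoptosis_rates and self.apoptosis_rates[0.0] != 0.0:
            raise ValueError("apoptosis rate at concentration 0 must be 0")
        if any(v < 0 for v in self.apoptosis_rates.values()):
            raise ValueError("apoptosis rates must be non-negative")

    def death_mitosis_ratios(self) -> Dict[float, float]:
        """lambda_A/lambda_M per concentration."""
        lm = self.mitosis_rate_lambdaM
        return {c: la / lm for c, la in self.apoptosis_rates.items()}


def calibrate(assay: ViabilityAssay, lambda_M: Optional[float] = None) -> KineticRates:
    """Extract (lambda_M, lambda_A per concentration) from an assay.

    lambda_M comes from the assay's raw counts when present, otherwise from
    the ``lambda_M`` argument (a stated literature/measured value).
    Apoptosis rates are -ln(mean viable fraction)/T, forced to exactly 0 at
    concentration 0.  First-order standard errors (delta method on the
    replicate-mean SE) are attached when replicates are available.
    """
    if assay.control_count_NC is not None and assay.initial_count_NI is not None:
        lm = mitosis_rate(assay.control_count_NC, assay.initial_count_NI, assay.exposure_time_T)
    elif lambda_M is not None:
        lm = lambda_M
    else:
        raise ValueError(
            "calibration needs either raw counts (N_C, N_I) or a stated lambda_M"
        )
    rates: Dict[float, float] = {}
    ses: Dict[float, float] = {}
    se = assay.fraction_se()
    for i, conc in enumerate(assay.concentrations):
        c = float(conc)
        if c == 0.0:
            rates[c] = 0.0
            continue
        f = float(assay.viable_fraction[i])
        rates[c] = apoptosis_rate_from_viability(f, assay.exposure_time_T)
        if se is not None:
            # delta method: d(-ln f)/df = -1/f
            ses[c] = float(se[i]) / (f * assay.exposure_time_T)
    return KineticRates(
        mitosis_rate_lambdaM=lm,
        apoptosis_rates=rates,
        exposure_time_T=assay.exposure_time_T,
        apoptosis_rate_se=ses,
    )


def read_assay_csv(path) -> ViabilityAssay:
    """Read a viability-assay CSV.

    Schema: leading ``# key: value`` metadata lines (drug, cell_line,
    exposure_days), then columns ``concentration_nM``, ``replicate``, and
    ``viable_fraction`` (or ``viable_count`` normalized by the replicate-mean
    count at concentration 0).
    """
    path = Path(path)
    meta: Dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("#").partition(":")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    required = {"concentration_nM", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"assay CSV must contain columns {sorted(required)}")
    if "viable_fraction" in df.columns:
        values = df.pivot_table(
            index="replicate", columns="concentration_nM", values="viable_fraction"
        )
    elif "viable_count" in df.columns:
        counts = df.pivot_table(
            index="replicate", columns="concentration_nM", values="viable_count"
        )
        if 0.0 not in counts.columns:
            raise ValueError("viable_count schema requires a concentration-0 control column")
        values = counts.div(counts[0.0].mean())
    else:
        raise ValueError("assay CSV needs a viable_fraction or viable_count column")
    conc = np.sort(values.columns.to_numpy(dtype=float))
    reps = values[conc].to_numpy(dtype=float)
    T = float(meta.get("exposure_days", 1.0))
    extra = {}
    if "initial_count" in meta:
        extra["initial_count_NI"] = float(meta["initial_count"])
    if "control_count" in meta:
        extra["control_count_NC"] = float(meta["control_count"])
    return ViabilityAssay.from_replicates(
        drug_name=meta.get("drug", ""),
        concentrations=conc,
        replicate_fractions=reps,
        exposure_time_T=T,
        cell_line=meta.get("cell_line", ""),
        **extra,
    )
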