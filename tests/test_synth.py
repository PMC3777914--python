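"""Synthetic-data generator: determinism, noise structure, pipeline closure."""

import math

import numpy as np
import pytest

from tumorresp.calibration import calibrate
from tumorresp.gompertz import fit_gompertz
from tumorresp.model import DimensionlessParameters, classify_regime, stationary_radius
from tumorresp.synth import (
    InVivoConfig,
    SyntheticConfig,
    synth_in_vivo_series,
    synth_mvd_rois,
    synth_viability_assay,
)
from tumorresp.units import cells_from_radius, radius_from_cells
from tumorresp.vascular import estimate_vascularization, mvd_percent


class TestViabilityGenerator:
    def test_noise_free_fraction_matches_kill_kinetics(self):
        """lambda_A = 1.44, lambda_M = 2.63, T = 1 -> viable fraction e^-1.44 ~ 0.24."""
        cfg = SyntheticConfig(
            seed=0,
            true_lambdaM=2.63,
            kill_model={0.0: 0.0, 300.0: 1.44},
            viability_noise_cv=0.0,
            cell_line="S2-VP10",
        )
        assay = synth_viability_assay(cfg)
        idx = list(assay.concentrations).index(300.0)
        assert assay.viable_fraction[idx] == pytest.approx(math.exp(-1.44), abs=1e-12)
        assert assay.viable_fraction[idx] == pytest.approx(0.24, abs=5e-3)

    def test_control_fraction_exactly_one(self):
        assay = synth_viability_assay(SyntheticConfig(seed=3))
        assert assay.viable_fraction[list(assay.concentrations).index(0.0)] == 1.0
        assert np.all(assay.replicate_fractions[:, assay.concentrations == 0.0] == 1.0)

    def test_determinism_same_seed(self):
        a1 = synth_viability_assay(SyntheticConfig(seed=11))
        a2 = synth_viability_assay(SyntheticConfig(seed=11))
        np.testing.assert_array_equal(a1.replicate_fractions, a2.replicate_fractions)

    def test_different_seeds_differ(self):
        a1 = synth_viability_assay(SyntheticConfig(seed=11))
        a2 = synth_viability_assay(SyntheticConfig(seed=12))
        assert not np.array_equal(a1.replicate_fractions, a2.replicate_fractions)

    def test_overkill_floored_with_warning(self):
        cfg = SyntheticConfig(
            seed=0, kill_model={0.0: 0.0, 300.0: 15.0}, viability_noise_cv=0.0
        )
        with pytest.warns(UserWarning, match="below one cell"):
            assay = synth_viability_assay(cfg)
        assert np.all(assay.viable_fraction > 0)


class TestMvdGenerator:
    def test_noise_free_fixture(self):
        cfg = SyntheticConfig(seed=0, mvd_noise_cv=0.0)
        mean, sd = mvd_percent(synth_mvd_rois(cfg, "tumor"))
        assert mean == pytest.approx(0.27, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_large_sample_mean_near_truth(self):
        """Mean-one noise: sample mean within 3 sd of truth over 1000 ROIs."""
        cfg = SyntheticConfig(seed=5, roi_count=1000, mvd_noise_cv=0.3)
        mean, sd = mvd_percent(synth_mvd_rois(cfg, "normal"))
        se = sd / math.sqrt(1000)
        assert abs(mean - 1.56) < 3 * se

    def test_determinism_and_substream_independence(self):
        m1 = synth_mvd_rois(SyntheticConfig(seed=9), "tumor")
        m2 = synth_mvd_rois(SyntheticConfig(seed=9), "tumor")
        np.testing.assert_array_equal(m1.roi_vessel_areas, m2.roi_vessel_areas)
        # normal-tissue draws come from their own substream
        n1 = synth_mvd_rois(SyntheticConfig(seed=9), "normal")
        assert not np.allclose(
            n1.roi_vessel_areas / 0.0156, m1.roi_vessel_areas / 0.0027
        )


class TestInVivoGenerator:
    def test_gompertz_mode_round_trip(self, noise_free_config):
        df = synth_in_vivo_series(noise_free_config)
        iv = noise_free_config.in_vivo
        geom = noise_free_config.cell_geometry
        radii_mm = np.array(
            [radius_from_cells(s / iv.signal_per_cell, geom) / 1000.0 for s in df["signal"]]
        )
        fit = fit_gompertz(df["day"].to_numpy(), radii_mm)
        assert fit.converged
        assert fit.asymptote_a == pytest.approx(iv.gompertz_a, abs=1e-6)
        assert fit.displacement_b == pytest.approx(iv.gompertz_b, abs=1e-6)
        assert fit.rate_c == pytest.approx(iv.gompertz_c, abs=1e-6)

    def test_zero_noise_signal_consistency(self, noise_free_config):
        """signal/k equals cells_from_radius of the generating path exactly."""
        df = synth_in_vivo_series(noise_free_config)
        iv = noise_free_config.in_vivo
        geom = noise_free_config.cell_geometry
        for _, row in df.iterrows():
            cells = cells_from_radius(row["radius_mm_true"] * 1000.0, geom)
            assert row["signal"] / iv.signal_per_cell == pytest.approx(cells, rel=1e-12)

    def test_model_mode_plateaus_at_stationary_radius(self):
        A = 3 * (1 / math.tanh(2) - 0.5) / 2  # R_inf = 2 exactly
        B = 0.43
        ratio = A * (1 - B) + B
        params = DimensionlessParameters.from_rates(ratio, B)
        iv = InVivoConfig(
            mode="model",
            model_params=params,
            model_R0_dimensionless=0.5,
            abs_G=5.0,
            L_D_um=200.0,
            horizon_days=100.0,
            signal_noise_cv=0.0,
        )
        cfg = SyntheticConfig(seed=0, in_vivo=iv)
        df = synth_in_vivo_series(cfg)
        assert df["radius_mm_true"].iloc[-1] == pytest.approx(2.0 * 200.0 / 1000.0, abs=1e-4)

    def test_series_determinism(self):
        d1 = synth_in_vivo_series(SyntheticConfig(seed=21))
        d2 = synth_in_vivo_series(SyntheticConfig(seed=21))
        np.testing.assert_array_equal(d1["signal"], d2["signal"])


class TestPipelineClosure:
    def test_zero_noise_full_recovery(self, noise_free_config):
        """assay+ROIs through calibrate -> B chain -> classification recovers
        the generating (ratio, B-chain values, regime) exactly."""
        cfg = noise_free_config
        rates = calibrate(synth_viability_assay(cfg))
        est = estimate_vascularization(
            synth_mvd_rois(cfg, "normal"), synth_mvd_rois(cfg, "tumor")
        )
        assert est.B_normal == pytest.approx(2.5)
        assert est.B_tumor == pytest.approx(2.5 * 0.0027 / 0.0156, rel=1e-9)
        ratios = rates.death_mitosis_ratios()
        for conc, true_la in cfg.kill_model.items():
            true_ratio = true_la / cfg.true_lambdaM
            assert ratios[conc] == pytest.approx(true_ratio, abs=1e-12)
            assert classify_regime(ratios[conc], est.B_tumor) == classify_regime(
                true_ratio, est.B_tumor
            )
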