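"""Core dimensionless growth model: parameters, nutrient profile, dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from tumorresp.model import (
    SMALL_R_SWITCHOVER,
    DegenerateVascularizationError,
    DimensionlessParameters,
    GrowthTrajectory,
    apoptosis_strength,
    boundary_velocity_over_G,
    classify_regime,
    integrate_radius,
    nutrient_profile,
    stationary_radius,
)


class TestApoptosisStrength:
    @pytest.mark.parametrize(
        "ratio,B,expected",
        [
            (0.0, 0.43, -0.43 / 0.57),  # untreated: A = -0.754
            (0.43, 0.43, 0.0),  # ratio equals B
            (0.0255, 0.43, (0.0255 - 0.43) / 0.57),  # ~-0.710
        ],
    )
    def test_closed_form(self, ratio, B, expected):
        assert apoptosis_strength(ratio, B) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_vascularization(self):
        with pytest.raises(DegenerateVascularizationError):
            apoptosis_strength(0.5, 1.0)

    @given(
        ratio=st.floats(0, 3, allow_nan=False),
        B=st.floats(0, 3, allow_nan=False).filter(lambda b: abs(b - 1) > 1e-6),
    )
    @settings(derandomize=True, max_examples=100)
    def test_identity_with_parameter_set(self, ratio, B):
        """A == (ratio - B)/(1 - B) holds on the assembled parameter set."""
        p = DimensionlessParameters.from_rates(ratio, B)
        assert p.apoptosis_strength_A == pytest.approx(
            (ratio - B) / (1 - B), abs=1e-12
        )
        assert (p.g_sign == "negative") == (B > 1)


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "ratio,B,expected",
        [
            (0.545, 0.43, "low"),
            (0.313, 0.43, "moderate"),
            (0.5, 1.5, "high"),
            (0.43, 0.43, "moderate"),  # tie A=0 belongs to the inclusive A<=0 side
        ],
    )
    def test_labels(self, ratio, B, expected):
        assert classify_regime(ratio, B) == expected

    def test_degenerate(self):
        with pytest.raises(DegenerateVascularizationError):
            classify_regime(0.5, 1.0)

    def test_published_condition_labels(self):
        """All 8 (cell line, dose) labels from the measured ratios with B=0.43."""
        from tumorresp import data

        B = 0.43
        expected = {
            ("MiaPaCa-2", 0.0): "moderate",
            ("MiaPaCa-2", 3.0): "moderate",
            ("MiaPaCa-2", 30.0): "moderate",
            ("MiaPaCa-2", 300.0): "moderate",
            ("S2-VP10", 0.0): "moderate",
            ("S2-VP10", 3.0): "moderate",
            ("S2-VP10", 30.0): "moderate",
            ("S2-VP10", 300.0): "low",
        }
        for (line, conc), label in expected.items():
            ratio = data.LAMBDA_A[line][conc] / data.LAMBDA_M[line]
            assert classify_regime(ratio, B) == label, (line, conc)


class TestNutrientProfile:
    def test_boundary_is_unity(self):
        for R in (0.3, 1.0, 10.0, 100.0):
            assert nutrient_profile(R, R) == pytest.approx(1.0, abs=1e-12)

    def test_center_closed_form(self):
        assert nutrient_profile(0, 1) == pytest.approx(1 / math.sinh(1), rel=1e-12)
        assert nutrient_profile(0, 10) == pytest.approx(10 / math.sinh(10), rel=1e-12)

    def test_continuity_at_center(self):
        """The r=0 limit matches the r>0 formula evaluated nearby."""
        assert nutrient_profile(1e-9, 5.0) == pytest.approx(
            nutrient_profile(0.0, 5.0), rel=1e-9
        )

    @given(R=st.floats(0.1, 50), frac=st.floats(0, 1))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_and_bounded(self, R, frac):
        r = frac * R
        v = nutrient_profile(r, R)
        assert 0 < v <= 1 + 1e-12
        r2 = min(R, r + 0.01 * R)
        assert nutrient_profile(r2, R) >= v - 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nutrient_profile(2.0, 1.0)
        with pytest.raises(ValueError):
            nutrient_profile(0.0, 0.0)

    def test_no_overflow_large_radius(self):
        assert nutrient_profile(0, 800.0) == pytest.approx(0.0, abs=1e-300)
        assert nutrient_profile(800.0, 800.0) == pytest.approx(1.0)


class TestBoundaryVelocity:
    def test_closed_form_values(self):
        assert boundary_velocity_over_G(1, 0) == pytest.approx(
            1 / math.tanh(1) - 1, rel=1e-12
        )
        assert boundary_velocity_over_G(0.01, 0) == pytest.approx(
            0.01 / 3 - 0.01**3 / 45, rel=1e-10
        )

    def test_large_R_limit_A0(self):
        """V/G -> 1 as R -> inf for A = 0 (the residual is the 1/R term)."""
        assert boundary_velocity_over_G(50.0, 0.0) == pytest.approx(1.0 - 1 / 50, abs=1e-12)
        assert boundary_velocity_over_G(1e4, 0.0) == pytest.approx(1.0, abs=1e-3)

    def test_series_matches_closed_form_at_switchover(self):
        R = SMALL_R_SWITCHOVER
        series = R * (1 - 0.3) / 3 - R**3 / 45
        closed = -0.3 * R / 3 + 1 / math.tanh(R) - 1 / R
        assert series == pytest.approx(closed, abs=1e-10)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            boundary_velocity_over_G(0.0, 0.0)


class TestStationaryRadius:
    def test_constructed_inverse(self):
        # A chosen so that R_inf = 2 exactly: A = 3*(coth 2 - 1/2)/2
        A = 3 * (1 / math.tanh(2) - 0.5) / 2
        assert stationary_radius(A) == pytest.approx(2.0, rel=1e-10)

    @pytest.mark.parametrize("A", [0.0, -0.5, 1.0, 1.5])
    def test_no_root_outside_unit_interval(self, A):
        assert stationary_radius(A) is None

    def test_velocity_sign_for_A_above_one(self):
        """Bracket check: the velocity stays negative for all R when A >= 1."""
        R = np.linspace(1e-3, 100, 2000)
        v = np.array([boundary_velocity_over_G(r, 1.5) for r in R])
        assert np.all(v < 0)

    def test_agrees_with_bisection_oracle(self, rng):
        """Independent bisection over a sign-change scan, 200 random A in (0,1)."""
        for A in rng.uniform(1e-3, 1 - 1e-3, size=200):
            # the root sits near 3/A for small A; scan far enough to bracket it
            upper = max(200.0, 4.0 / A)
            grid = np.logspace(-6, math.log10(upper), 400)
            v = np.array([boundary_velocity_over_G(r, A) for r in grid])
            idx = np.nonzero(np.sign(v[:-1]) != np.sign(v[1:]))[0]
            assert idx.size >= 1
            lo, hi = grid[idx[0]], grid[idx[0] + 1]
            for _ in range(80):  # plain bisection
                mid = 0.5 * (lo + hi)
                if boundary_velocity_over_G(mid, A) > 0:
                    lo = mid
                else:
                    hi = mid
            oracle = 0.5 * (lo + hi)
            assert stationary_radius(A) == pytest.approx(oracle, abs=1e-8, rel=1e-8)


class TestIntegrateRadius:
    def low_params(self, A):
        # reverse-engineer a (ratio, B) pair in the low regime giving this A
        B = 0.43
        ratio = A * (1 - B) + B
        return DimensionlessParameters.from_rates(ratio, B)

    def test_linear_growth_for_A_zero(self):
        """dR/dtau' -> 1 (V -> G) once the radius is large."""
        p = DimensionlessParameters.from_rates(0.43, 0.43)  # A = 0
        traj = integrate_radius(1.5, p, 1500.0, n_points=3000)
        assert traj.radii[-1] > 1000  # 1/R correction now below 1e-3
        late = traj.times > 0.99 * traj.times[-1]
        slope = np.gradient(traj.radii[late], traj.times[late])
        assert slope[-1] == pytest.approx(1.0, abs=1e-3)

    def test_convergence_to_stationary_radius(self):
        A = 3 * (1 / math.tanh(2) - 0.5) / 2  # R_inf = 2
        p = self.low_params(A)
        traj = integrate_radius(0.5, p, 400.0)
        assert traj.radii[-1] == pytest.approx(2.0, abs=1e-6)

    def test_exponential_regime_rate(self):
        """(dR/dtau')/R -> |A|/3 for A < 0 at late times."""
        p = DimensionlessParameters.from_rates(0.0, 0.43)  # A = -0.754
        A = p.apoptosis_strength_A
        traj = integrate_radius(1.5, p, 35.0, n_points=4000)
        assert traj.radii[-1] > 2000  # far into the asymptotic regime
        R_end = traj.radii[-1]
        v_end = boundary_velocity_over_G(R_end, A)
        assert v_end / R_end == pytest.approx(abs(A) / 3, abs=1e-3)
        # and the integrated path agrees with the vector field
        late = traj.times > 0.95 * traj.times[-1]
        slope = np.gradient(traj.radii[late], traj.times[late]) / traj.radii[late]
        assert slope[-1] == pytest.approx(abs(A) / 3, abs=1e-3)

    @pytest.mark.parametrize("A", [0.2, 0.5, 0.8])
    def test_phase_consistency(self, A):
        """Low-regime trajectories converge to R_inf from both sides, monotonically."""
        R_inf = stationary_radius(A)
        p = self.low_params(A)
        below = integrate_radius(0.5 * R_inf, p, 300.0)
        above = integrate_radius(1.5 * R_inf, p, 300.0)
        assert np.all(np.diff(below.radii) >= -1e-9)
        assert np.all(below.radii <= R_inf + 1e-7)
        assert below.radii[-1] == pytest.approx(R_inf, abs=1e-6)
        assert np.all(np.diff(above.radii) <= 1e-9)
        assert above.radii[-1] == pytest.approx(R_inf, abs=1e-6)

    def test_sign_symmetry(self):
        """g_sign negative negates the velocity field pointwise."""
        pos = DimensionlessParameters(0.5, 0.43, 0.715, "positive", "low")
        neg = DimensionlessParameters(0.5, 1.5, 0.715, "negative", "high")
        t_pos = integrate_radius(3.0, pos, 0.2, n_points=100)
        t_neg = integrate_radius(3.0, neg, 0.2, n_points=100)
        # early displacements are equal and opposite (same |A|, reversed field)
        d_pos = np.gradient(t_pos.radii, t_pos.times)
        d_neg = np.gradient(t_neg.radii, t_neg.times)
        v0 = boundary_velocity_over_G(3.0, 0.5)
        assert d_pos[0] == pytest.approx(v0, rel=1e-3)
        assert d_neg[0] == pytest.approx(-v0, rel=1e-3)
        assert (t_pos.radii[-1] - 3.0) * (t_neg.radii[-1] - 3.0) < 0

    def test_extinction_event(self):
        """A shrinking high-regime tumor terminates at the extinction radius."""
        # B>1 (G<0) with 0<A<1: below the unstable radius the tumor shrinks
        p = DimensionlessParameters.from_rates(1.5, 2.0)  # A = 0.5
        traj = integrate_radius(0.5, p, 500.0, extinction_radius=1e-4)
        assert traj.extinct
        assert traj.extinction_time is not None
        assert np.all(traj.radii > 0)

    def test_g_sign_zero_rejected(self):
        p = DimensionlessParameters(0.0, 1.0, 1.0, "zero", "moderate")
        with pytest.raises(DegenerateVascularizationError):
            integrate_radius(1.0, p, 1.0)


class TestGrowthTrajectory:
    def test_invariants_enforced(self):
        p = DimensionlessParameters.from_rates(0.0, 0.43)
        with pytest.raises(ValueError):
            GrowthTrajectory(times=[0, 1, 1], radii=[1, 2, 3], params=p)
        with pytest.raises(ValueError):
            GrowthTrajectory(times=[0, 1], radii=[1, -2], params=p)

    def test_csv_round_trip(self, tmp_path):
        import json

        import pandas as pd

        p = DimensionlessParameters.from_rates(0.0, 0.43)
        traj = integrate_radius(1.5, p, 2.0, length_scale_LD=200.0)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        df = pd.read_csv(out)
        assert list(df.columns) == ["tau", "R_dimensionless", "R_mm"]
        np.testing.assert_allclose(df["R_mm"], df["R_dimensionless"] * 0.2)
        meta = json.loads((tmp_path / "traj.meta.json").read_text())
        assert meta["regime"] == "moderate"
        assert meta["L_D_um"] == 200.0
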