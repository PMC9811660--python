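"""Forward model, inversions, and mass-action arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinpre import (
    BindingContext,
    SpinSystemParams,
    distance_at_ratio,
    gamma2_from_distance,
    gamma2_from_ratio,
    kd_from_population,
    population_from_kd,
    population_from_ratio,
    predicted_pre,
    ratio_from_gamma2,
)
from conftest import bisect_gamma2


class TestGamma2FromDistance:
    def test_reference_rate_at_11A(self, params):
        # hand evaluation: K * (4*tau + 3*tau/(1+(w*tau)^2)) / 11^6
        assert gamma2_from_distance(11.0, params) == pytest.approx(1.11e3, rel=0.01)

    def test_vanishes_at_large_distance(self, params):
        assert gamma2_from_distance(1e6, params) < 1e-20

    @pytest.mark.parametrize("r", [4.0, 8.5, 11.6, 23.0])
    def test_r6_scaling_identity(self, params, r):
        assert gamma2_from_distance(2 * r, params) == pytest.approx(
            gamma2_from_distance(r, params) / 64.0, rel=1e-12
        )

    def test_strictly_decreasing(self, params):
        grid = np.linspace(4, 40, 50)
        vals = gamma2_from_distance(grid, params)
        assert np.all(np.diff(vals) < 0)

    def test_nonpositive_distance_rejected(self, params):
        with pytest.raises(ValueError):
            gamma2_from_distance(0.0, params)
        with pytest.raises(ValueError):
            gamma2_from_distance(-3.0, params)

    def test_high_field_limit_dominates(self, params):
        # at 800 MHz / 40 ns the spectral term beyond 4*tau_c is negligible
        full = params.spectral_factor
        truncated = 4.0 * params.tau_c
        assert abs(full - truncated) / full < 1e-4


class TestRatioFromGamma2:
    def test_unit_ratio_without_broadening(self, params):
        assert ratio_from_gamma2(0.0, params) == 1.0

    def test_full_occupancy_prediction_11A(self, params):
        ratio = ratio_from_gamma2(gamma2_from_distance(11.0, params), params)
        assert ratio == pytest.approx(3e-6, rel=0.5)

    def test_full_occupancy_prediction_10p6A(self, params):
        ratio = ratio_from_gamma2(gamma2_from_distance(10.6, params), params)
        assert ratio == pytest.approx(2e-7, rel=0.5)

    def test_strictly_decreasing_and_bounded(self, params):
        grid = np.logspace(-3, 3, 60)
        vals = ratio_from_gamma2(grid, params)
        assert np.all(np.diff(vals) < 0)
        assert np.all((vals > 0) & (vals < 1))

    def test_negative_gamma2_rejected(self, params):
        with pytest.raises(ValueError):
            ratio_from_gamma2(-1.0, params)


class TestPredictedPre:
    def test_sparse_close_contact_cases(self, params):
        # 0.01% occupancy at 5 A still attenuates to ~0.77
        assert predicted_pre(5.0, 1e-4, params) == pytest.approx(0.77, abs=0.02)
        assert predicted_pre(5.0, 1e-4, params) <= 0.8
        # 10% occupancy at 10 A crushes the peak below 0.2
        assert predicted_pre(10.0, 0.10, params) <= 0.2

    def test_zero_population_is_unity(self, params):
        for r in (4.0, 11.6, 40.0):
            assert predicted_pre(r, 0.0, params) == 1.0

    def test_joint_monotonicity_on_grid(self, params):
        rs = np.linspace(4, 40, 25)
        ps = np.logspace(-5, 0, 25)
        for p in ps:
            vals = predicted_pre(rs, p, params)
            assert np.all(np.diff(vals) >= 0)  # non-decreasing in r
        for r in rs:
            vals = predicted_pre(r, ps, params)
            assert np.all(np.diff(vals) <= 0)  # non-increasing in p

    def test_population_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            predicted_pre(10.0, -0.1, params)
        with pytest.raises(ValueError):
            predicted_pre(10.0, 1.5, params)


class TestGamma2FromRatio:
    def test_unit_ratio_maps_to_zero(self, params):
        assert gamma2_from_ratio(1.0, params) == 0.0
        assert gamma2_from_ratio(1.3, params) == 0.0  # noise above 1 clips

    @pytest.mark.parametrize("ratio,expected", [(0.89, 5.47), (0.77, 12.56)])
    def test_against_bisection_oracle(self, params, ratio, expected):
        got = gamma2_from_ratio(ratio, params)
        assert got == pytest.approx(bisect_gamma2(ratio, params), rel=1e-8)
        assert got == pytest.approx(expected, rel=0.01)

    def test_nonpositive_ratio_rejected(self, params):
        with pytest.raises(ValueError):
            gamma2_from_ratio(0.0, params)

    @given(st.floats(min_value=1e-6, max_value=0.999999))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip(self, ratio):
        params = SpinSystemParams()
        g = gamma2_from_ratio(ratio, params)
        assert ratio_from_gamma2(g, params) == pytest.approx(ratio, rel=1e-9)


class TestPopulationFromRatio:
    def test_worked_case_residue_350(self, params):
        assert population_from_ratio(0.89, 11.6, params) == pytest.approx(0.007, abs=0.001)

    def test_worked_case_residue_354(self, params):
        assert population_from_ratio(0.77, 10.6, params) == pytest.approx(0.009, abs=0.001)

    def test_no_attenuation_means_zero_population(self, params):
        assert population_from_ratio(1.0, 15.0, params) == 0.0

    def test_clipped_to_unit_interval(self, params):
        # tiny ratio at a long distance would imply p > 1; must clip
        assert population_from_ratio(1e-6, 40.0, params) == 1.0


class TestMassAction:
    def test_worked_case_kds(self, ctx, params):
        p1 = population_from_ratio(0.89, 11.6, params)
        p2 = population_from_ratio(0.77, 10.6, params)
        assert kd_from_population(p1, ctx) == pytest.approx(16e-3, abs=2e-3)
        assert kd_from_population(p2, ctx) == pytest.approx(12e-3, abs=2e-3)

    def test_half_occupancy_arithmetic(self, ctx):
        # (110 - 10) * 10 / 10 uM = 100 uM
        assert kd_from_population(0.5, ctx) == pytest.approx(1.00e-4, rel=1e-12)
        assert population_from_kd(1.00e-4, ctx) == pytest.approx(0.5, rel=1e-12)

    def test_quadratic_inverse_at_16mM(self, ctx):
        # quadratic-formula oracle: C^2 - (L+P+KD) C + L P = 0
        L, P, KD = ctx.labeled_total, ctx.partner_total, 16e-3
        b = L + P + KD
        c_oracle = (b - math.sqrt(b * b - 4 * L * P)) / 2
        assert population_from_kd(KD, ctx) == pytest.approx(c_oracle / L, rel=1e-12)
        assert population_from_kd(KD, ctx) == pytest.approx(0.007, abs=0.001)

    def test_weak_binding_limit(self, ctx):
        assert population_from_kd(1e3, ctx) < 1e-6

    @pytest.mark.parametrize("p", np.logspace(-5, -0.05, 12).tolist())
    def test_round_trip_p_kd(self, ctx, p):
        assert population_from_kd(kd_from_population(p, ctx), ctx) == pytest.approx(
            p, rel=1e-9
        )

    def test_degenerate_populations_rejected(self, ctx):
        with pytest.raises(ValueError):
            kd_from_population(0.0, ctx)
        with pytest.raises(ValueError):
            kd_from_population(1.0, ctx)

    def test_infeasible_bound_exceeds_partner(self):
        ctx = BindingContext(labeled_total=100e-6, partner_total=10e-6)
        with pytest.raises(ValueError):
            kd_from_population(0.5, ctx)

    def test_mass_conservation(self, ctx):
        for kd in (1e-6, 1e-4, 1e-2, 1.0):
            p = population_from_kd(kd, ctx)
            assert 0 < p < 1
            assert p * ctx.labeled_total < ctx.partner_total


class TestDistanceAtRatio:
    def test_strong_pre_distance_bound(self, params):
        r = distance_at_ratio(0.4, 1.0, params)
        assert r <= 19.0
        assert r == pytest.approx(18.54, abs=0.1)
        assert predicted_pre(r, 1.0, params) == pytest.approx(0.4, abs=1e-6)

    def test_sparse_population_boundary(self, params):
        # ratio 0.2 at 0.1% occupancy only within ~5 A of the probe
        r = distance_at_ratio(0.2, 0.001, params)
        assert r >= 5.0
        assert predicted_pre(5.0, 0.001, params) < 0.2

    def test_distance_grows_near_unit_target(self, params):
        assert distance_at_ratio(0.9999, 1.0, params) > distance_at_ratio(
            0.9, 1.0, params
        ) > distance_at_ratio(0.4, 1.0, params)

    def test_zero_population_has_no_solution(self, params):
        with pytest.raises(ValueError):
            distance_at_ratio(0.4, 0.0, params)

    @pytest.mark.parametrize("target", [0.1, 0.4, 0.8, 0.95])
    @pytest.mark.parametrize("p", [1e-4, 1e-2, 1.0])
    def test_root_finding_oracle_agreement(self, params, target, p):
        from scipy.optimize import brentq

        r_closed = distance_at_ratio(target, p, params)
        r_oracle = brentq(
            lambda r: predicted_pre(r, p, params) - target, 1e-2, 1e4, xtol=1e-10
        )
        assert r_closed == pytest.approx(r_oracle, rel=1e-6)


class TestRoundTripGrids:
    def test_ratio_gamma2_round_trip_over_distance_population_grid(self, params):
        rs = np.linspace(4, 40, 10)
        ps = np.logspace(-5, 0, 10)
        for r in rs:
            for p in ps:
                ratio = predicted_pre(r, p, params)
                if ratio < 1e-12:  # beyond detection, inversion meaningless
                    continue
                g = gamma2_from_ratio(ratio, params)
                assert g == pytest.approx(
                    p * gamma2_from_distance(r, params), rel=1e-9
                )


class TestSpinSystemParams:
    def test_derived_quantities(self, params):
        assert params.r2_dia == pytest.approx(math.pi * 25.0)
        assert params.omega_h == pytest.approx(2 * math.pi * 8e8)

    def test_positive_field_validation(self):
        with pytest.raises(ValueError):
            SpinSystemParams(tau_c=-1e-9)
        with pytest.raises(ValueError):
            SpinSystemParams(linewidth_dia=0.0)
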