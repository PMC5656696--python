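import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centiloid.calibration import (
    STANDARD_PIB_MAP,
    CohortStats,
    LinearMap,
    apply_map,
    calibrate_level2,
    cohort_stats,
    compose_maps,
    fit_ols,
    invert_map,
    upper_normal_limit,
    validate_level1,
    variance_ratio,
)
from centiloid.suvr import SuvrRecord

finite_maps = st.builds(
    LinearMap,
    m=st.floats(min_value=0.05, max_value=20.0),
    b=st.floats(min_value=-200.0, max_value=200.0),
)


def _pairs(x, y, tracer="FBB"):
    return [
        (
            SuvrRecord.from_means(f"S{i}", "PiB", xi, 1.0),
            SuvrRecord.from_means(f"S{i}", tracer, yi, 1.0),
        )
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


class TestFitOls:
    def test_collinear_recovers_generating_line(self):
        x = np.linspace(1.0, 2.2, 10)
        fit = fit_ols(x, 0.61 * x + 0.39)
        np.testing.assert_allclose(fit.map.m, 0.61, rtol=1e-12)
        np.testing.assert_allclose(fit.map.b, 0.39, atol=1e-12)
        np.testing.assert_allclose(fit.r_squared, 1.0, atol=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_identity_line(self):
        x = np.array([0.0, 1.0, 2.0])
        fit = fit_ols(x, x)
        assert fit.map.m == pytest.approx(1.0)
        assert fit.map.b == pytest.approx(0.0, abs=1e-15)

    def test_four_point_hand_arithmetic(self):
        # Sxx=5, Sxy=1 -> slope 0.2; ybar - slope*xbar = 0.2; R2 = 1/(5*1) = 0.2
        fit = fit_ols([0, 1, 2, 3], [0, 1, 0, 1])
        np.testing.assert_allclose(fit.map.m, 0.2, rtol=1e-12)
        np.testing.assert_allclose(fit.map.b, 0.2, rtol=1e-12)
        np.testing.assert_allclose(fit.r_squared, 0.2, rtol=1e-12)

    def test_matches_statsmodels_on_noisy_data(self):
        """Independent route: statsmodels OLS on the same data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.uniform(1.0, 2.2, 35)
        y = 0.61 * x + 0.39 + rng.normal(0, 0.05, 35)
        fit = fit_ols(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.map.m, ref.params[1], rtol=1e-10)
        np.testing.assert_allclose(fit.map.b, ref.params[0], rtol=1e-10)
        np.testing.assert_allclose(fit.r_squared, ref.rsquared, rtol=1e-10)
        np.testing.assert_allclose(fit.residual_sd, np.sqrt(ref.mse_resid), rtol=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            fit_ols([1, 2], [1, 2])
        with pytest.raises(ValueError, match="zero variance"):
            fit_ols([1.0, 1.0, 1.0], [1, 2, 3])


class TestLinearMapAlgebra:
    def test_standard_pib_map_values(self):
        # root of the line, and CL at SUVR 1.0
        assert apply_map(STANDARD_PIB_MAP, 94.6 / 93.7) == pytest.approx(0.0, abs=1e-12)
        assert apply_map(STANDARD_PIB_MAP, 1.0) == pytest.approx(-0.9, abs=1e-12)

    def test_direct_fbb_map_hand_value(self):
        direct = LinearMap(153.4, -154.9, "SUVR_FBB", "CL")
        assert apply_map(direct, 2.0) == pytest.approx(151.9)

    def test_invert_printed_relation(self):
        inv = invert_map(LinearMap(0.61, 0.39, "SUVR_PiB", "SUVR_FBB"))
        np.testing.assert_allclose(inv.m, 1 / 0.61, rtol=1e-12)
        np.testing.assert_allclose(inv.b, -0.39 / 0.61, rtol=1e-12)
        assert inv.domain_scale == "SUVR_FBB"
        assert inv.range_scale == "SUVR_PiB"

    def test_zero_slope_not_invertible(self):
        with pytest.raises(ZeroDivisionError):
            invert_map(LinearMap(0.0, 1.0))

    def test_compose_hand_arithmetic(self):
        got = compose_maps(LinearMap(2, 1, "a", "b"), LinearMap(3, -1, "b", "c"))
        assert (got.m, got.b) == (6, 2)
        assert (got.domain_scale, got.range_scale) == ("a", "c")

    def test_compose_scale_mismatch(self):
        with pytest.raises(ValueError, match="scale mismatch"):
            compose_maps(LinearMap(1, 0, "a", "b"), LinearMap(1, 0, "c", "d"))

    def test_identity_is_neutral(self):
        f = LinearMap(0.61, 0.39, "a", "b")
        ident = LinearMap(1.0, 0.0, "b", "b")
        got = compose_maps(f, ident)
        assert (got.m, got.b) == (f.m, f.b)

    @given(finite_maps)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_invert_is_involution(self, f):
        back = invert_map(invert_map(f))
        np.testing.assert_allclose(back.m, f.m, rtol=1e-12)
        np.testing.assert_allclose(back.b, f.b, rtol=1e-9, atol=1e-12)

    @given(finite_maps, st.floats(min_value=-50, max_value=50))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_inverse_composition_is_identity(self, f, x):
        ident = compose_maps(invert_map(f), f)
        np.testing.assert_allclose(apply_map(ident, x), x, rtol=1e-9, atol=1e-6)


class TestLevel1Validation:
    def test_constant_offset_fit_passes(self):
        """A computed = reference - 0.07 pipeline passes every gate."""
        ref = np.linspace(-5.0, 120.0, 20)
        rep = validate_level1(ref - 0.07, ref)
        assert rep.fit.map.m == pytest.approx(1.0)
        assert rep.fit.map.b == pytest.approx(-0.07, abs=1e-9)
        assert rep.fit.r_squared > 0.9999
        assert rep.pass_overall

    def test_identity_passes(self):
        ref = np.array([0.0, 30.0, 60.0, 90.0])
        assert validate_level1(ref, ref).pass_overall

    def test_slope_shrinkage_fails_slope_gate(self):
        ref = np.linspace(0.0, 100.0, 10)
        rep = validate_level1(0.95 * ref, ref)
        assert not rep.pass_slope
        assert not rep.pass_overall
        assert rep.pass_intercept

    def test_intercept_shift_fails_intercept_gate(self):
        ref = np.linspace(0.0, 100.0, 10)
        rep = validate_level1(ref - 3.0, ref)
        assert not rep.pass_intercept
        assert rep.pass_slope

    def test_slope_bounds_are_sharp(self):
        ref = np.linspace(0.0, 100.0, 10)
        assert validate_level1(0.98 * ref, ref).pass_slope
        assert not validate_level1(0.9799 * ref, ref).pass_slope
        assert validate_level1(1.02 * ref, ref).pass_slope
        assert not validate_level1(1.0201 * ref, ref).pass_slope

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            validate_level1([1.0, 2.0], [1.0, 2.0, 3.0])


class TestLevel2Calibration:
    def test_noise_free_printed_line_reproduces_direct_equation(self):
        x = np.linspace(1.0, 2.2, 35)
        rep = calibrate_level2(_pairs(x, 0.61 * x + 0.39))
        # exact arithmetic: 93.7/0.61 and -(93.7*0.39/0.61) - 94.6
        np.testing.assert_allclose(rep.direct_cl.m, 93.7 / 0.61, rtol=1e-10)
        np.testing.assert_allclose(rep.direct_cl.b, -(93.7 * 0.39 / 0.61) - 94.6, rtol=1e-10)
        assert rep.pass_gate
        # within rounding of the printed coefficients
        assert abs(rep.direct_cl.m - 153.4) < 0.25
        assert abs(rep.direct_cl.b - (-154.9)) < 0.5

    def test_identity_relation_yields_standard_map(self):
        x = np.linspace(1.0, 2.2, 10)
        rep = calibrate_level2(_pairs(x, x))
        np.testing.assert_allclose(rep.direct_cl.m, STANDARD_PIB_MAP.m, rtol=1e-10)
        np.testing.assert_allclose(rep.direct_cl.b, STANDARD_PIB_MAP.b, rtol=1e-10)

    def test_uncorrelated_noise_fails_gate_but_reports(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1.0, 2.0, 30)
        y = rng.uniform(1.0, 2.0, 30)
        rep = calibrate_level2(_pairs(x, y))
        assert not rep.pass_gate
        assert rep.fit.r_squared <= 0.70
        assert rep.direct_cl is not None  # QC stays inspectable

    def test_unmatched_subject_ids_rejected(self):
        pairs = _pairs([1.0, 1.5, 2.0], [1.0, 1.3, 1.6])
        bad = (
            SuvrRecord.from_means("SX", "PiB", 1.2, 1.0),
            SuvrRecord.from_means("SY", "FBB", 1.1, 1.0),
        )
        with pytest.raises(ValueError, match="unmatched subject ids"):
            calibrate_level2(pairs + [bad])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="insufficient pairs"):
            calibrate_level2(_pairs([1.0, 2.0], [1.0, 1.6]))

    def test_young_normal_anchor_maps_to_zero_cl(self):
        """The PiB CL=0 anchor, pushed through the fitted relation and the
        direct map, lands back at 0 CL."""
        x = np.linspace(1.0, 2.2, 12)
        rep = calibrate_level2(_pairs(x, 0.61 * x + 0.39))
        anchor_fbb = rep.fit.map(94.6 / 93.7)
        assert apply_map(rep.direct_cl, anchor_fbb) == pytest.approx(0.0, abs=1e-9)


class TestCohortQc:
    def test_constant_list_zero_sd_requires_two(self):
        st_ = cohort_stats([5.0, 5.0, 5.0], "young_control", "PiB")
        assert st_.sd_cl == 0.0
        with pytest.raises(ValueError):
            cohort_stats([5.0], "g", "PiB")

    def test_two_point_hand_arithmetic(self):
        st_ = cohort_stats([-1.0, 1.0], "g", "PiB")
        assert st_.mean_cl == 0.0
        assert st_.sd_cl == pytest.approx(np.sqrt(2.0))

    def test_variance_ratio_published_sds(self):
        fbb = CohortStats("young", "FBB", 10, -1.08, 6.81)
        pib = CohortStats("young", "PiB", 10, -0.32, 3.48)
        assert variance_ratio(fbb, pib) == pytest.approx(6.81 / 3.48)
        assert round(variance_ratio(fbb, pib), 2) == 1.96

    def test_variance_ratio_hand_cases(self):
        a = CohortStats("g", "FBB", 5, 0.0, 7.0)
        b = CohortStats("g", "PiB", 5, 0.0, 3.5)
        assert variance_ratio(a, b) == pytest.approx(2.0)
        assert variance_ratio(b, b) == pytest.approx(1.0)

    def test_upper_normal_limits_round_to_published_integers(self):
        pib = CohortStats("young", "PiB", 10, -0.32, 3.48)
        fbb = CohortStats("young", "FBB", 10, 0.0, 6.81)
        assert upper_normal_limit(pib, include_mean=True) == 7
        assert upper_normal_limit(pib, include_mean=False) == 7
        assert upper_normal_limit(fbb, include_mean=False) == 14
        assert upper_normal_limit(pib, k=0, rounding="none", include_mean=False) == 0.0

    def test_simulated_young_normals_recover_generator_sd(self):
        rng = np.random.default_rng(42)
        draws = rng.normal(-1.08, 6.81, 200)
        st_ = cohort_stats(draws, "young_control", "FBB")
        assert st_.sd_cl == pytest.approx(6.81, rel=0.15)
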