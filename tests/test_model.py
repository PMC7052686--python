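"""Unit and property tests for the normative model and decision rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bvnlscreen import (BVNLScreen, NormativeModel, RuleThresholds, classify,
                        ellipse_radius_sq, fit_normative_model, mahalanobis_sq,
                        normal_probability_plot, standardize)
from bvnlscreen.errors import (DegenerateCohortError, InsufficientDataError,
                               InvalidProbabilityError, InvalidValueError,
                               SingularCorrelationError)

REF_MODEL = NormativeModel(mu_log_idua=4.1453, sd_log_idua=0.472,
                           mu_log_hs=3.7532, sd_log_hs=0.335,
                           rho=0.0934, n=5000)

finite_z = st.floats(min_value=-50, max_value=50, allow_nan=False)


class TestFitNormativeModel:
    def test_matches_hand_computed_moments(self):
        # 4 paired rows whose log moments are computable by hand:
        # logs of idua are {4,4,5,5}, logs of hs are {1,2,1,2}.
        cohort = pd.DataFrame({
            "idua": np.exp([4.0, 4.0, 5.0, 5.0]),
            "hs": np.exp([1.0, 2.0, 1.0, 2.0]),
        })
        m = fit_normative_model(cohort)
        assert m.mu_log_idua == pytest.approx(4.5)
        assert m.mu_log_hs == pytest.approx(1.5)
        assert m.sd_log_idua == pytest.approx(math.sqrt(1 / 3))
        assert m.sd_log_hs == pytest.approx(math.sqrt(1 / 3))
        assert m.rho == pytest.approx(0.0, abs=1e-15)
        assert m.n == 4

    def test_duplicated_rows_change_only_the_sd_denominator(self):
        rng = np.random.default_rng(5)
        base = pd.DataFrame({"idua": np.exp(rng.normal(4, 0.5, 20)),
                             "hs": np.exp(rng.normal(3.7, 0.3, 20))})
        k = 3
        dup = pd.concat([base] * k, ignore_index=True)
        m1, mk = fit_normative_model(base), fit_normative_model(dup)
        assert mk.mu_log_idua == pytest.approx(m1.mu_log_idua)
        assert mk.rho == pytest.approx(m1.rho)
        # sample SD rescales by sqrt((n-1)/(kn-1) * k) when rows repeat k times
        n = len(base)
        scale = math.sqrt((n - 1) * k / (k * n - 1))
        assert mk.sd_log_idua == pytest.approx(m1.sd_log_idua * scale)

    def test_error_conditions(self):
        two = pd.DataFrame({"idua": [1.0, 2.0], "hs": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            fit_normative_model(two)
        const = pd.DataFrame({"idua": [5.0] * 4, "hs": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(DegenerateCohortError):
            fit_normative_model(const)
        neg = pd.DataFrame({"idua": [1.0, -2.0, 3.0], "hs": [1.0, 2.0, 3.0]})
        with pytest.raises(InvalidValueError):
            fit_normative_model(neg)

    def test_values_at_the_floor_are_floored_not_rejected(self):
        cohort = pd.DataFrame({"idua": [0.1, 50.0, 60.0, 70.0],
                               "hs": [40.0, 45.0, 50.0, 55.0]})
        m = fit_normative_model(cohort, detection_limits=(0.5, 1.0))
        # the 0.1 reading is floored to 0.5 before logging
        assert m.mu_log_idua == pytest.approx(
            np.mean(np.log([0.5, 50.0, 60.0, 70.0])))


class TestStandardize:
    def test_identity_at_the_log_mean(self):
        assert standardize(math.exp(3.21), 3.21, 0.7) == pytest.approx(0.0)

    def test_gifu_cut_sits_near_the_pseudo_deficiency_quantile(self):
        # raw 16.68 under the default synthetic calibration
        z = standardize(16.68, 4.1453, 0.472)
        assert z == pytest.approx(-2.820, abs=5e-4)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidValueError):
            standardize(0.0, 1.0, 1.0)
        with pytest.raises(InvalidValueError):
            standardize(-3.0, 1.0, 1.0)
        with pytest.raises(InvalidValueError):
            standardize(1.0, 1.0, 0.0)

    def test_fit_standardize_round_trip(self, fitted_screen, normative):
        z = fitted_screen.transform(normative)
        assert np.mean(z, axis=0) == pytest.approx([0.0, 0.0], abs=1e-10)
        assert np.std(z, axis=0, ddof=1) == pytest.approx([1.0, 1.0], rel=1e-10)


class TestMahalanobisSq:
    @pytest.mark.parametrize("z1,z2,rho,expected", [
        (0.0, 0.0, 0.5, 0.0),
        (3.0, 4.0, 0.0, 25.0),
        (-3.62, 1.90, 0.0934, 18.157609395013967),
        (-3.7, 2.0, 0.0934, 19.240162713843983),
        (-6.0, 4.0, 0.0934, 56.98027081123808),
    ])
    def test_frozen_values(self, z1, z2, rho, expected):
        assert mahalanobis_sq(z1, z2, rho) == pytest.approx(expected)

    @given(z1=finite_z, z2=finite_z,
           rho=st.floats(min_value=-0.99, max_value=0.99))
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_matches_matrix_inverse_oracle(self, z1, z2, rho):
        cov_inv = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))
        z = np.array([z1, z2])
        expected = float(z @ cov_inv @ z)
        got = mahalanobis_sq(z1, z2, rho)
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)
        assert got >= 0.0
        assert mahalanobis_sq(-z1, -z2, rho) == pytest.approx(got, rel=1e-12)

    def test_zero_only_at_the_origin(self):
        assert mahalanobis_sq(0.0, 0.0, 0.3) == 0.0
        assert mahalanobis_sq(1e-8, 0.0, 0.3) > 0.0

    def test_singular_correlation_rejected(self):
        with pytest.raises(SingularCorrelationError):
            mahalanobis_sq(1.0, 1.0, 1.0)


class TestEllipseRadiusSq:
    def test_chi_square_closed_form(self):
        assert ellipse_radius_sq(1.0) == pytest.approx(0.0)
        assert ellipse_radius_sq(1e-7) == pytest.approx(32.23619130191664)
        # dual route: numeric chi-square quantile inversion
        assert ellipse_radius_sq(0.05) == pytest.approx(
            stats.chi2.ppf(0.95, 2), rel=1e-12)
        assert ellipse_radius_sq(0.05) == pytest.approx(5.9915, abs=1e-4)

    def test_f_prediction_exceeds_and_converges_to_chi_square(self):
        p = 1e-7
        chi = ellipse_radius_sq(p)
        gaps = [ellipse_radius_sq(p, n, "f_prediction") - chi
                for n in (10, 100, 5000)]
        assert all(g > 0 for g in gaps)
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.2  # essentially the chi-square radius at n = 5000

    def test_errors(self):
        with pytest.raises(InvalidProbabilityError):
            ellipse_radius_sq(0.0)
        with pytest.raises(InvalidProbabilityError):
            ellipse_radius_sq(1.5)
        with pytest.raises(InsufficientDataError):
            ellipse_radius_sq(0.05, 3, "f_prediction")


class TestClassify:
    def test_population_center_is_negative_everywhere(self):
        v = classify(0.0, 0.0, REF_MODEL)
        assert not any(bool(v[r]) for r in ("bvnl", "idua_only", "hs_only", "joint"))

    def test_inside_ellipse_corner_is_joint_but_not_bvnl(self):
        # beyond both thresholds yet inside the (1-1e-7) ellipse: the regime
        # where BVNL and the joint-threshold rule disagree
        v = classify(-3.7, 2.0, REF_MODEL)
        assert bool(v["idua_only"]) and bool(v["hs_only"]) and bool(v["joint"])
        assert v["mahalanobis_sq"] < 32.237
        assert not bool(v["bvnl"])

    def test_far_corner_is_bvnl_positive(self):
        v = classify(-6.0, 4.0, REF_MODEL)
        assert bool(v["bvnl"])

    def test_boundary_points_are_negative(self):
        for z1, z2 in [(-3.62, 2.5), (-4.0, 1.90)]:
            v = classify(z1, z2, REF_MODEL)
            assert not bool(v["joint"]) and not bool(v["bvnl"])

    @given(z1=finite_z, z2=finite_z)
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_rule_nesting(self, z1, z2):
        v = classify(z1, z2, REF_MODEL)
        assert (not v["bvnl"]) or v["joint"]
        assert (not v["joint"]) or (v["idua_only"] and v["hs_only"])


class TestNormalProbabilityPlot:
    def test_perfectly_straight_for_exact_quantiles(self):
        n = 101
        exact = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        theo, ordered, r = normal_probability_plot(exact)
        assert np.array_equal(ordered, exact)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_normal_sample_is_straighter_than_skewed_sample(self):
        rng = np.random.default_rng(11)
        normal = rng.standard_normal(10_000)
        _, _, r_norm = normal_probability_plot(normal)
        _, _, r_skew = normal_probability_plot(np.exp(normal))
        assert r_norm > 0.99
        assert r_skew < r_norm

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            normal_probability_plot([1.0, 2.0])


class TestBVNLScreenEstimator:
    def test_sklearn_params_round_trip(self):
        screen = BVNLScreen(ellipse_p=1e-6)
        params = screen.get_params()
        assert params["ellipse_p"] == 1e-6
        screen.set_params(z_hs_cut=2.0)
        assert screen.z_hs_cut == 2.0

    def test_predict_flags_the_affected_profile(self, fitted_screen):
        # enzyme at the assay floor, GAG strongly elevated
        assert fitted_screen.predict([[0.5, 300.0]]) == [1]
        # typical healthy profile
        assert fitted_screen.predict([[70.0, 45.0]]) == [0]

    def test_screen_table_schema_and_nesting(self, screen_table):
        for col in ("sample_id", "z_idua", "z_hs", "mahalanobis_sq",
                    "verdict_bvnl", "verdict_idua_only", "verdict_hs_only",
                    "verdict_joint", "verdict_gifu"):
            assert col in screen_table.columns
        bvnl = screen_table["verdict_bvnl"] == "positive"
        joint = screen_table["verdict_joint"] == "positive"
        idua = screen_table["verdict_idua_only"] == "positive"
        hs = screen_table["verdict_hs_only"] == "positive"
        assert (joint[bvnl]).all()
        assert (idua[joint]).all() and (hs[joint]).all()

    def test_from_model_matches_fit(self, fitted_screen, normative):
        clone = BVNLScreen.from_model(fitted_screen.model_)
        a = fitted_screen.screen(normative)
        b = clone.screen(normative)
        pd.testing.assert_frame_equal(a, b)

    def test_unfitted_raises(self):
        with pytest.raises(InvalidValueError):
            BVNLScreen().predict([[1.0, 1.0]])
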