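"""Closed forms, limits and quadrature contracts of the hazard models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad as scipy_quad

from tempattn.errors import InvalidParameterError
from tempattn.hazard import (
    IntervalDistribution,
    MissParams,
    NoiseParams,
    PredictiveParams,
    QuadratureSpec,
    ScalingParams,
    expected_subjective_hazard,
    hazard_rate,
    measurement_likelihood,
    predicted_threshold,
    predictive_hazard,
    quadrature_error,
    subjective_hazard,
    subjective_predictive_hazard,
)


class TestHazardRate:
    @pytest.mark.parametrize(
        "t, k, expected",
        [
            (1.0, 0.5, (1 / 0.6) / (1 - 0.5 * 0.5)),  # = 2.2222...
            (1.0, 0.0, 1 / 0.6),  # no miss discount: h = f
            (0.5, 0.5, 0.0),  # below support
            (1.4, 0.5, 0.0),  # above support
            (0.7, 0.5, 1 / 0.6),  # F(t_min)=0
        ],
    )
    def test_closed_form(self, exp1_dist, t, k, expected):
        assert hazard_rate(t, exp1_dist, MissParams(k)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_classical_limit_is_one_over_remaining_time(self, exp1_dist):
        # as k -> 1 the miss-corrected hazard approaches f/(1-F) = 1/(t_max - t)
        t = np.linspace(0.7, 1.25, 12)
        h = hazard_rate(t, exp1_dist, MissParams(1 - 1e-9))
        np.testing.assert_allclose(h, 1.0 / (1.3 - t), rtol=1e-6)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            MissParams(1.0)
        with pytest.raises(InvalidParameterError):
            MissParams(-0.1)

    @given(
        k=st.floats(0.0, 0.99),
        t_min=st.floats(0.2, 1.0),
        span=st.floats(0.1, 2.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_nondecreasing_on_support_and_at_least_f(self, k, t_min, span):
        dist = IntervalDistribution(t_min, t_min + span)
        t = np.linspace(t_min, t_min + span, 33)
        h = hazard_rate(t, dist, MissParams(k))
        assert np.all(np.diff(h) >= -1e-12)
        assert np.all(h >= dist.pdf(t) - 1e-12)


class TestMeasurementLikelihood:
    def test_peak_value(self):
        assert measurement_likelihood(1.0, 1.0, NoiseParams(0.1)) == pytest.approx(
            1.0 / (np.sqrt(2 * np.pi) * 0.1)
        )

    def test_normalises_over_m(self):
        val, _ = scipy_quad(
            lambda m: measurement_likelihood(m, 1.0, NoiseParams(0.11)), -np.inf, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_asymmetric_in_t_for_fixed_m(self):
        # SD scales with t, so the likelihood of t given m is skewed
        n = NoiseParams(0.2)
        assert measurement_likelihood(1.0, 0.8, n) != pytest.approx(
            measurement_likelihood(1.0, 1.2, n)
        )

    def test_nonpositive_t_rejected(self):
        with pytest.raises(InvalidParameterError):
            measurement_likelihood(1.0, 0.0, NoiseParams(0.1))


class TestPredictiveHazard:
    def test_closed_form_example(self, exp1_dist):
        # (1/0.6)(1 - e^-3) / (1 - 0.5 * 0.5)
        expected = (1 / 0.6) * (1 - np.exp(-3.0)) / 0.75
        got = predictive_hazard(1.0, exp1_dist, MissParams(0.5), PredictiveParams(0.1))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_mu_to_zero_recovers_classical(self, exp1_dist):
        t = np.linspace(0.7, 1.29, 9)
        h0 = hazard_rate(t, exp1_dist)
        hp = predictive_hazard(t, exp1_dist, pred=PredictiveParams(1e-6))
        np.testing.assert_allclose(hp, h0, rtol=1e-3)
        np.testing.assert_allclose(
            predictive_hazard(t, exp1_dist, pred=PredictiveParams(0.0)), h0
        )

    def test_zero_above_support(self, exp1_dist):
        assert predictive_hazard(1.4, exp1_dist, pred=PredictiveParams(0.1)) == 0.0

    def test_anticipation_raises_pre_support_hazard(self, exp1_dist):
        t = np.array([0.5, 0.6, 0.69])
        hp = predictive_hazard(t, exp1_dist, pred=PredictiveParams(0.2))
        assert np.all(hp > hazard_rate(t, exp1_dist))  # classical is 0 there

    def test_negative_mu_rejected(self):
        with pytest.raises(InvalidParameterError):
            PredictiveParams(-0.1)


class TestSubjectiveHazard:
    def test_noiseless_limit(self, exp1_dist):
        got = subjective_hazard(1.0, exp1_dist, noise=NoiseParams(1e-6))
        assert got == pytest.approx(2.2222222, rel=1e-3)

    def test_mc_oracle_agreement(self, exp1_dist, mc_oracle):
        est = subjective_hazard(1.0, exp1_dist, noise=NoiseParams(0.11))
        ref, se = mc_oracle(1.0, exp1_dist, 0.5, 0.11, seed=7)
        assert abs(est - ref) < 3 * se + 1e-4 * ref

    def test_far_above_support_matches_oracle(self, exp1_dist, mc_oracle):
        m = 2 * exp1_dist.t_max
        est = subjective_hazard(m, exp1_dist, noise=NoiseParams(0.11))
        ref, se = mc_oracle(m, exp1_dist, 0.5, 0.11, seed=11)
        assert est > 0
        assert abs(est - ref) < 3 * se + 0.02 * ref

    def test_nonpositive_m_rejected(self, exp1_dist):
        with pytest.raises(InvalidParameterError):
            subjective_hazard(0.0, exp1_dist)

    def test_quadrature_contracts(self, exp1_dist, exp3_dist):
        # over the measurement range that carries weight: the support up to
        # its noise-blurred upper neighbourhood
        for dist in (exp1_dist, exp3_dist):
            m = np.linspace(dist.t_min, dist.t_max * 1.1, 9)
            assert quadrature_error(m, dist, noise=NoiseParams(0.11)) < 1e-4
            assert (
                quadrature_error(
                    m, dist, noise=NoiseParams(0.11), pred=PredictiveParams(0.106)
                )
                < 1e-4
            )

    def test_quadspec_validation(self):
        with pytest.raises(InvalidParameterError):
            QuadratureSpec(32, 8.0)
        with pytest.raises(InvalidParameterError):
            QuadratureSpec(128, 4.0)


class TestSubjectivePredictiveHazard:
    def test_mu_to_zero_is_subjective(self, exp1_dist):
        m = np.linspace(0.75, 1.25, 7)
        a = subjective_predictive_hazard(
            m, exp1_dist, noise=NoiseParams(0.11), pred=PredictiveParams(1e-6)
        )
        b = subjective_hazard(m, exp1_dist, noise=NoiseParams(0.11))
        np.testing.assert_allclose(a, b, rtol=1e-3)

    def test_w_to_zero_is_predictive(self, exp1_dist):
        m = np.linspace(0.75, 1.25, 7)
        a = subjective_predictive_hazard(
            m, exp1_dist, noise=NoiseParams(1e-6), pred=PredictiveParams(0.106)
        )
        b = predictive_hazard(m, exp1_dist, pred=PredictiveParams(0.106))
        np.testing.assert_allclose(a, b, rtol=1e-3)

    def test_mc_oracle_agreement(self, exp1_dist, mc_oracle):
        est = subjective_predictive_hazard(
            1.0, exp1_dist, noise=NoiseParams(0.11), pred=PredictiveParams(0.106)
        )
        ref, se = mc_oracle(1.0, exp1_dist, 0.5, 0.11, mu=0.106, seed=13)
        assert abs(est - ref) < 3 * se + 1e-4 * ref


class TestPredictedThreshold:
    def test_beta1_zero_collapses_to_beta0(self, exp1_dist):
        t = np.linspace(0.7, 1.3, 5)
        y = predicted_threshold(t, exp1_dist, ScalingParams(0.42, 0.0))
        np.testing.assert_allclose(y, 0.42)

    def test_all_blurs_collapse_to_classical_hazard(self, exp1_dist):
        y = predicted_threshold(
            1.0,
            exp1_dist,
            ScalingParams(0.0, 1.0),
            noise=NoiseParams(1e-6),
            pred=PredictiveParams(1e-6),
        )
        assert y == pytest.approx(2.2222222, rel=1e-3)

    def test_grid_refinement(self, exp1_dist):
        s = ScalingParams(0.3, -0.02)
        kw = dict(noise=NoiseParams(0.11), pred=PredictiveParams(0.106))
        t = np.linspace(0.7, 1.3, 7)
        y = predicted_threshold(t, exp1_dist, s, quad=QuadratureSpec(512, 8.0), **kw)
        y2 = predicted_threshold(t, exp1_dist, s, quad=QuadratureSpec(1024, 8.0), **kw)
        assert np.max(np.abs(y - y2) / np.abs(y2)) < 1e-4


class TestUnitInvariance:
    def test_hazards_rescale_with_time_units(self, exp1_dist):
        # seconds -> milliseconds: rates scale by 1/1000, w is unitless,
        # mu scales with the unit
        ms = IntervalDistribution(700.0, 1300.0)
        t = np.array([0.8, 1.0, 1.2])
        np.testing.assert_allclose(
            hazard_rate(t * 1e3, ms) * 1e3, hazard_rate(t, exp1_dist), rtol=1e-12
        )
        np.testing.assert_allclose(
            predictive_hazard(t * 1e3, ms, pred=PredictiveParams(106.0)) * 1e3,
            predictive_hazard(t, exp1_dist, pred=PredictiveParams(0.106)),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            subjective_hazard(t * 1e3, ms, noise=NoiseParams(0.11)) * 1e3,
            subjective_hazard(t, exp1_dist, noise=NoiseParams(0.11)),
            rtol=1e-9,
        )

    def test_threshold_rescales_with_beta1(self, exp1_dist):
        ms = IntervalDistribution(700.0, 1300.0)
        kw = dict(noise=NoiseParams(0.11), pred=PredictiveParams(0.106))
        kw_ms = dict(noise=NoiseParams(0.11), pred=PredictiveParams(106.0))
        y_s = predicted_threshold(1.0, exp1_dist, ScalingParams(0.8, -0.16), **kw)
        y_ms = predicted_threshold(1000.0, ms, ScalingParams(0.8, -160.0), **kw_ms)
        assert y_ms == pytest.approx(y_s, rel=1e-9)

    def test_expected_hazard_positive_in_blurred_neighbourhood(self, exp3_dist):
        g = expected_subjective_hazard(
            np.linspace(0.5, 3.0, 11), exp3_dist, noise=NoiseParams(0.11)
        )
        assert np.all(g > 0)
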