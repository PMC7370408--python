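"""Model parameterisations, priors and likelihood against hand-coded oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from bayesdose import (
    HierEmaxParams,
    SecondNdlmParams,
    SimpleNdlmParams,
    TrialDataset,
    dose_ladder,
    fixture_dataset,
    hier_emax_theta,
    inv_logit,
    log_likelihood,
    log_prior,
    logit,
    ndlm_transition_variance,
    second_ndlm_theta,
)
from bayesdose.models import ControlParam, second_ndlm_path


def norm_lpdf(x, mu, sd):
    return -0.5 * math.log(2 * math.pi * sd**2) - (x - mu) ** 2 / (2 * sd**2)


def invgamma_lpdf(x, a, b):
    return a * math.log(b) - math.lgamma(a) - (a + 1) * math.log(x) - b / x


class TestLinkFunctions:
    def test_mutually_inverse(self):
        p = np.linspace(0.01, 0.99, 23)
        np.testing.assert_allclose(inv_logit(logit(p)), p, atol=1e-12)

    def test_anchor_values(self):
        assert logit(0.5) == pytest.approx(0.0)
        assert inv_logit(0.0) == pytest.approx(0.5)
        # the control prior mean corresponds to a median response of 0.40
        assert inv_logit(-0.41) == pytest.approx(0.3989, abs=5e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            logit(1.0)


class TestHierEmaxTheta:
    def test_no_dose_effect(self):
        params = HierEmaxParams(phi1=-0.3, phi2=0.0, phi3=2.0)
        np.testing.assert_allclose(hier_emax_theta(params), -0.3)

    def test_half_maximal_definition(self):
        # at nu = phi3 the curve sits at phi1 + phi2/2
        ladder = dose_ladder()
        params = HierEmaxParams(phi1=0.1, phi2=1.8, phi3=ladder.strength[4])
        theta = hier_emax_theta(params, ladder)
        assert theta[3] == pytest.approx(0.1 + 0.9)

    def test_hand_arithmetic(self):
        params = HierEmaxParams(phi1=-0.41, phi2=2.0, phi3=3.0)
        theta = hier_emax_theta(params)
        assert theta[-1] == pytest.approx(-0.41 + 2 * 9.52 / 12.52)

    def test_psi_centred_sum_to_zero(self):
        params = HierEmaxParams(phi1=0, phi2=1, phi3=1, psi=np.arange(7.0))
        assert abs(params.psi.sum()) < 1e-10
        theta = hier_emax_theta(params)
        flat = hier_emax_theta(HierEmaxParams(phi1=0, phi2=1, phi3=1))
        assert abs((theta - flat).sum()) < 1e-10

    def test_invalid_phi3(self):
        with pytest.raises(ValueError):
            HierEmaxParams(phi1=0, phi2=1, phi3=-1.0)


class TestNdlmPieces:
    def test_transition_variance_values(self):
        ladder = dose_ladder()
        assert ndlm_transition_variance(1.0, ladder, 3) == pytest.approx(4.17 - 2.60)
        assert ndlm_transition_variance(0.0, ladder, 5) == 0.0
        assert ndlm_transition_variance(0.04, ladder, 8) == pytest.approx(0.04 * (9.52 - 7.76))

    def test_transition_variance_range(self):
        with pytest.raises(ValueError):
            ndlm_transition_variance(1.0, dose_ladder(), 2)

    def test_second_order_flat_and_linear_extrapolation(self):
        ladder = dose_ladder()
        assert second_ndlm_theta(0.7, 0.7, 0.0, ladder, 5) == pytest.approx(0.7)
        # points on a line in nu continue the line when zeta = 0
        slope = 0.3
        nu = ladder.strength
        th = second_ndlm_theta(slope * nu[4], slope * nu[5], 0.0, ladder, 7)
        assert th == pytest.approx(slope * nu[6])

    def test_second_order_hand_evaluation(self):
        ladder = dose_ladder()
        got = second_ndlm_theta(0.0, 1.0, 0.5, ladder, 4)
        expected = (1.0 / (4.17 - 2.60) + 0.5) * (5.40 - 4.17) + 1.0
        assert got == pytest.approx(expected)

    def test_second_order_params_consistency_checked(self):
        zeta = np.array([0.1, -0.2, 0.0, 0.3, -0.1])
        params = SecondNdlmParams.from_innovations(0.0, 0.5, zeta, 0.01)
        np.testing.assert_allclose(
            params.theta, second_ndlm_path(0.0, 0.5, zeta, dose_ladder())
        )
        bad = params.theta.copy()
        bad[4] += 0.5
        with pytest.raises(ValueError, match="inconsistent"):
            SecondNdlmParams(bad, zeta, 0.01)


class TestLogPrior:
    def test_hier_emax_truncation(self):
        params = HierEmaxParams(phi1=0, phi2=1, phi3=1.0)
        object.__setattr__(params, "phi3", -1.0)  # bypass constructor guard
        assert log_prior("hier_emax", params) == -np.inf

    def test_hier_emax_matches_hand_density(self):
        psi = np.array([0.1, -0.05, 0.2, 0.0, -0.1, 0.05, -0.2])
        params = HierEmaxParams(phi1=-0.2, phi2=1.5, phi3=4.0, psi=psi, phi4_sq=0.3)
        expected = (
            norm_lpdf(-0.2, -0.41, 1.0)
            + norm_lpdf(1.5, 0.0, 5.0)
            + norm_lpdf(4.0, 3.0, 10.0)
            - math.log(1 - stats.norm.cdf(0, 3, 10))
            + invgamma_lpdf(0.3, 0.1, 0.001)
            + sum(norm_lpdf(v, 0.0, math.sqrt(0.3)) for v in psi)
        )
        assert log_prior("hier_emax", params) == pytest.approx(expected, rel=1e-10)

    def test_ndlm1_matches_hand_density(self):
        theta = np.array([-0.4, -0.1, 0.2, 0.3, 0.5, 0.8, 1.1])
        params = SimpleNdlmParams(theta=theta, tau_sq=0.05)
        nu = dose_ladder().active_strength
        expected = invgamma_lpdf(0.05, 0.05, 0.002) + norm_lpdf(theta[0], -0.41, 0.75)
        for j in range(1, 7):
            var = 0.05 * (nu[j] - nu[j - 1])
            expected += norm_lpdf(theta[j], theta[j - 1], math.sqrt(var))
        assert log_prior("ndlm1", params) == pytest.approx(expected, rel=1e-10)

    def test_ndlm2_matches_hand_density(self):
        zeta = np.array([0.1, -0.2, 0.0, 0.3, -0.1])
        params = SecondNdlmParams.from_innovations(-0.3, 0.1, zeta, 0.02)
        expected = (
            invgamma_lpdf(0.02, 0.1, 0.001)
            + norm_lpdf(-0.3, -0.41, 0.75)
            + norm_lpdf(0.1, -0.3, math.sqrt(0.02 * (4.17 - 2.60)))
            + sum(norm_lpdf(z, 0.0, math.sqrt(0.02)) for z in zeta)
        )
        assert log_prior("ndlm2", params) == pytest.approx(expected, rel=1e-10)

    def test_independent_is_separable(self):
        theta = np.linspace(-1, 1, 7)
        total = log_prior("independent", theta)
        parts = sum(norm_lpdf(t, -0.41, 1.0) for t in theta)
        assert total == pytest.approx(parts, rel=1e-10)

    def test_control_prior(self):
        assert log_prior("control", ControlParam(0.0)) == pytest.approx(
            norm_lpdf(0.0, -0.41, 0.75), rel=1e-12
        )

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            log_prior("spline", None)

    def test_emax_is_hier_emax_without_off_curve_terms(self):
        params = HierEmaxParams(phi1=-0.2, phi2=1.5, phi3=4.0)
        emax_lp = log_prior("emax", params)
        hier_lp = log_prior("hier_emax", HierEmaxParams(-0.2, 1.5, 4.0, None, 0.3))
        off_curve = invgamma_lpdf(0.3, 0.1, 0.001) + 7 * norm_lpdf(0, 0, math.sqrt(0.3))
        assert hier_lp == pytest.approx(emax_lp + off_curve, rel=1e-10)
        np.testing.assert_allclose(
            hier_emax_theta(params), hier_emax_theta(HierEmaxParams(-0.2, 1.5, 4.0))
        )


class TestLogLikelihood:
    def test_no_data_is_flat(self):
        data = TrialDataset(n=np.zeros(8, int), y=np.zeros(8, int))
        assert log_likelihood(np.linspace(-2, 2, 8), data) == 0.0

    def test_single_bernoulli(self):
        n = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        assert log_likelihood(np.zeros(8), TrialDataset(n, y)) == pytest.approx(
            math.log(0.5)
        )

    def test_matches_hand_pmf_oracle(self):
        data = fixture_dataset("LargeMonotone")
        theta = logit(data.y / data.n)
        expected = 0.0
        for n_d, y_d in zip(data.n, data.y):
            p = y_d / n_d
            expected += (
                math.log(math.comb(n_d, y_d))
                + y_d * math.log(p)
                + (n_d - y_d) * math.log(1 - p)
            )
        assert log_likelihood(theta, data) == pytest.approx(expected, rel=1e-12)


class TestPriorPosteriorProperties:
    @pytest.mark.parametrize("fixture", ["LargeMonotone", "NBHOnly", "OverDose"])
    def test_unnormalised_posterior_finite_on_interior(self, fixture):
        data = fixture_dataset(fixture)
        theta_full = np.full(8, 0.1)
        cases = {
            "hier_emax": HierEmaxParams(0.0, 1.0, 3.0, np.full(7, 0.1), 0.2),
            "ndlm1": SimpleNdlmParams(np.full(7, 0.1), 0.05),
            "ndlm2": SecondNdlmParams.from_innovations(0.1, 0.1, np.zeros(5), 0.01),
            "independent": np.full(7, 0.1),
        }
        for mid, params in cases.items():
            val = log_prior(mid, params) + log_likelihood(theta_full, data)
            assert np.isfinite(val)

    def test_inverse_gamma_convention(self):
        # X ~ IG(a, b)  =>  1/X ~ Gamma(shape a, rate b), so E[1/X] = a/b
        rng = np.random.default_rng(5)
        x = stats.invgamma(0.1, scale=0.001).rvs(200_000, random_state=rng)
        assert np.mean(1.0 / x) == pytest.approx(0.1 / 0.001, rel=0.05)
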