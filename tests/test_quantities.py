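"""Decision quantities: superiority, maximum-dose, predictive power, success rule."""

import numpy as np
import pytest
from scipy import stats

from bayesdose import (
    DecisionRule,
    QuantitySet,
    compute_quantities,
    evaluate_success,
    phase3_power,
    pr_max,
    pr_phase3_success,
    pr_superiority,
)


def exact_power_enumeration(p1, pd, n=500, alpha=0.025):
    """Brute-force power: enumerate both binomial outcomes, apply the z rule."""
    k = np.arange(n + 1)
    w1 = stats.binom.pmf(k, n, p1)
    w2 = stats.binom.pmf(k, n, pd)
    ph1 = k[None, :] / n
    ph2 = k[:, None] / n
    var = ph2 * (1 - ph2) / n + ph1 * (1 - ph1) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ph2 - ph1) / np.sqrt(var)
    reject = np.where(var > 0, z > stats.norm.ppf(1 - alpha), ph2 > ph1)
    return float(w2 @ reject @ w1)


def draws_with(p_by_dose, n_draws=4000, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    p = np.tile(np.asarray(p_by_dose, float), (n_draws, 1))
    if jitter:
        p = np.clip(p + jitter * rng.standard_normal(p.shape), 1e-6, 1 - 1e-6)
    return p


class TestPrSuperiority:
    def test_constant_shift_gives_one(self):
        p = draws_with([0.4] + [0.5] * 7)
        np.testing.assert_allclose(pr_superiority(p), [0] + [1.0] * 7)

    def test_exchangeable_gives_half(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.8, size=(20_000, 8))
        np.testing.assert_allclose(pr_superiority(p)[1:], 0.5, atol=0.02)

    def test_control_entry_zero(self):
        assert pr_superiority(draws_with(np.linspace(0.1, 0.8, 8)))[0] == 0.0


class TestPrMax:
    def test_degenerate_maximum(self):
        p = draws_with([0.4, 0.4, 0.4, 0.4, 0.9, 0.4, 0.4, 0.4])
        out = pr_max(p)
        assert out[4] == 1.0 and out.sum() == pytest.approx(1.0)

    def test_exchangeable_uniform_over_active(self):
        rng = np.random.default_rng(2)
        p = np.empty((40_000, 8))
        p[:, 0] = 0.4
        p[:, 1:] = rng.uniform(0.3, 0.7, size=(40_000, 7))
        np.testing.assert_allclose(pr_max(p)[1:], 1 / 7, atol=0.01)

    def test_normalises_over_active_doses(self):
        rng = np.random.default_rng(3)
        p = rng.beta(2, 2, size=(1000, 8))
        out = pr_max(p)
        assert out[0] == 0.0
        assert out[1:].sum() == pytest.approx(1.0, abs=1e-12)

    def test_ties_break_to_lowest_index(self):
        p = draws_with([0.4, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6])
        assert pr_max(p)[1] == 1.0


class TestPhase3Power:
    def test_size_at_null(self):
        assert phase3_power(0.4, 0.4) == pytest.approx(0.025, abs=1e-12)

    def test_consistency_in_n(self):
        assert phase3_power(0.40, 0.401, n_per_arm=10**8) > 0.99

    def test_monotone_in_effect(self):
        pd = np.linspace(0.4, 0.7, 50)
        power = phase3_power(0.4, pd)
        assert np.all(np.diff(power) > 0)

    @pytest.mark.parametrize("p1, pd", [(0.4, 0.5), (0.4, 0.45), (0.3, 0.42)])
    def test_against_exact_enumeration(self, p1, pd):
        assert phase3_power(p1, pd) == pytest.approx(
            exact_power_enumeration(p1, pd), abs=0.01
        )

    def test_pooled_variant_close_to_unpooled(self):
        # the pooled-null-variance alternative differs only slightly at the
        # design's operating point
        diff = abs(phase3_power(0.4, 0.5) - phase3_power(0.4, 0.5, pooled=True))
        assert diff < 0.02


class TestPrPhase3Success:
    def test_degenerate_at_null_is_alpha(self):
        p = draws_with([0.4] * 8)
        out = pr_phase3_success(p, DecisionRule(beta=0.9))
        np.testing.assert_allclose(out, 0.025, atol=1e-9)

    def test_bounded_below_by_alpha_when_superior(self):
        rng = np.random.default_rng(4)
        p = np.empty((2000, 8))
        p[:, 0] = rng.uniform(0.3, 0.5, 2000)
        p[:, 1:] = p[:, :1] + rng.uniform(0, 0.3, (2000, 7))
        p = np.clip(p, 1e-6, 1 - 1e-6)
        out = pr_phase3_success(p, DecisionRule(beta=0.9))
        assert np.all(out[1:] >= 0.025 - 1e-12)

    def test_monotone_coupling(self):
        # shifting one dose's draws up cannot reduce its pr_sup or pr_ph3
        rng = np.random.default_rng(5)
        theta = rng.normal(0, 1, size=(3000, 8))
        p = 1 / (1 + np.exp(-theta))
        theta_up = theta.copy()
        theta_up[:, 4] += 0.3
        p_up = 1 / (1 + np.exp(-theta_up))
        rule = DecisionRule(beta=0.9)
        assert pr_superiority(p_up)[4] >= pr_superiority(p)[4]
        assert pr_phase3_success(p_up, rule)[4] >= pr_phase3_success(p, rule)[4]


class TestSuccessRule:
    def _qs(self, pr_sup_sel, pr_ph3_sel, sel=5):
        pm = np.zeros(8)
        pm[sel - 1] = 1.0
        ps = np.zeros(8)
        ps[sel - 1] = pr_sup_sel
        pf = np.zeros(8)
        pf[sel - 1] = pr_ph3_sel
        return QuantitySet(pm, ps, pf, selected=sel, success=False)

    def test_success_requires_both_criteria(self):
        rule = DecisionRule(beta=0.922)
        assert evaluate_success(self._qs(0.99, 0.9), rule).success
        assert not evaluate_success(self._qs(0.91, 0.9), rule).success
        assert not evaluate_success(self._qs(0.99, 0.4), rule).success

    def test_selection_is_argmax_pr_max(self):
        rng = np.random.default_rng(6)
        p = np.empty((3000, 8))
        p[:, 0] = 0.4
        p[:, 1:] = rng.uniform(0.3, 0.6, size=(3000, 7))
        p[:, 7] += 0.2
        q = compute_quantities(np.clip(p, 1e-6, 1 - 1e-6), DecisionRule(beta=0.9))
        assert q.selected == 8
        assert q.pr_max[1:].sum() == pytest.approx(1.0)

    def test_quantity_set_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            QuantitySet(
                np.full(8, 0.5), np.zeros(8), np.zeros(8), selected=2, success=False
            )


class TestPowerProperties:
    from hypothesis import given, settings as hyp_settings, strategies as st

    @given(
        st.floats(min_value=0.05, max_value=0.95),
        st.floats(min_value=0.0, max_value=0.4),
        st.integers(min_value=10, max_value=2000),
    )
    @hyp_settings(max_examples=150, derandomize=True, deadline=None)
    def test_power_bounded_and_at_least_alpha_under_superiority(self, p1, lift, n):
        pd = min(p1 + lift, 0.99)
        power = phase3_power(p1, pd, n_per_arm=n)
        assert 0.0 <= power <= 1.0
        assert power >= 0.025 - 1e-12

    @given(st.lists(st.floats(min_value=0.01, max_value=0.99), min_size=8, max_size=8))
    @hyp_settings(max_examples=100, derandomize=True, deadline=None)
    def test_pr_max_is_distribution_for_any_draws(self, row):
        p = np.tile(np.asarray(row), (50, 1))
        out = pr_max(p)
        assert out[0] == 0.0
        assert out[1:].sum() == pytest.approx(1.0)
        assert np.all((out >= 0) & (out <= 1))
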