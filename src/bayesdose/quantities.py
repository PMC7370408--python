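"""Bayesian decision quantities and the trial-level success rule.

Three quantities are computed from a posterior sample of the per-arm response
probabilities (P_1..P_8):

* ``pr_max``      — per active dose, the posterior probability it has the
                    largest response probability among active doses;
* ``pr_sup``      — per active dose, Pr(P_d > P_1), superiority to control;
* ``pr_ph3``      — per dose, the predictive probability that a fixed
                    confirmatory trial (500 per arm, one-sided alpha=0.025
                    two-sample test of proportions) would succeed, i.e. the
                    posterior mean of the power function.

The trial succeeds when, at the dose with the greatest ``pr_max``, both
``pr_sup > beta`` and ``pr_ph3 > 0.5``.  ``beta`` is model-specific and
calibrated by simulation to a 10% type I error (see
:mod:`bayesdose.trial_sim`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import BETA_DEFAULTS

__all__ = [
    "DecisionRule",
    "QuantitySet",
    "pr_superiority",
    "pr_max",
    "phase3_power",
    "pr_phase3_success",
    "evaluate_success",
    "compute_quantities",
]


@dataclass(frozen=True)
class DecisionRule:
    """Final-analysis decision rule.

    ``beta`` is the superiority cutoff at the selected dose; ``ph3_cut`` the
    minimum predictive probability of confirmatory success; the confirmatory
    trial is fixed at ``n_ph3`` per arm with one-sided level ``alpha_ph3``.
    """

    beta: float
    ph3_cut: float = 0.5
    alpha_ph3: float = 0.025
    n_ph3: int = 500
    pooled: bool = False

    def __post_init__(self):
        if not 0 <= self.beta < 1:
            raise ValueError("beta must lie in [0, 1)")

    @classmethod
    def for_model(cls, model_id: str, **kw) -> "DecisionRule":
        """Rule with the model's calibrated beta (0.922 / 0.903 / 0.938)."""
        try:
            return cls(beta=BETA_DEFAULTS[model_id], **kw)
        except KeyError:
            raise ValueError(f"no calibrated beta for model {model_id!r}") from None


@dataclass(frozen=True)
class QuantitySet:
    """Per-dose decision quantities plus the implied trial decision.

    All arrays have length 8 (dose 1 = control); ``pr_max`` and ``pr_sup``
    are 0 at the control by convention, and ``pr_max`` sums to one over the
    active doses.
    """

    pr_max: np.ndarray
    pr_sup: np.ndarray
    pr_ph3: np.ndarray
    selected: int
    success: bool

    def __post_init__(self):
        for name in ("pr_max", "pr_sup", "pr_ph3"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (8,):
                raise ValueError(f"{name} must have length 8")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            object.__setattr__(self, name, arr)
        if abs(self.pr_max[1:].sum() - 1.0) > 1e-9:
            raise ValueError("pr_max must sum to 1 over active doses")
        if not 2 <= self.selected <= 8:
            raise ValueError("selected dose must be an active dose")

    def to_frame(self, model: str | None = None, scenario: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "dose_index": np.arange(1, 9),
                "pr_max": self.pr_max,
                "pr_sup": self.pr_sup,
                "pr_ph3": self.pr_ph3,
            }
        )
        if scenario is not None:
            df.insert(0, "scenario", scenario)
        if model is not None:
            df.insert(0, "model", model)
        return df


def _p_matrix(draws):
    """Pooled (n_draws, 8) probability matrix from draws or an array."""
    if hasattr(draws, "p_flat"):
        return draws.p_flat
    p = np.asarray(draws, float)
    return p.reshape(-1, 8)


def pr_superiority(draws) -> np.ndarray:
    """Per-dose fraction of posterior draws with P_d > P_1 (0 at the control)."""
    p = _p_matrix(draws)
    out = np.zeros(8)
    out[1:] = (p[:, 1:] > p[:, :1]).mean(axis=0)
    return out


def pr_max(draws) -> np.ndarray:
    """Per-dose frequency of being the largest active-dose response probability.

    The control is excluded and reported as 0; ties (measure zero under a
    continuous posterior) go to the lowest dose index.
    """
    p = _p_matrix(draws)
    idx = np.argmax(p[:, 1:], axis=1)
    out = np.zeros(8)
    out[1:] = np.bincount(idx, minlength=7) / p.shape[0]
    return out


def phase3_power(p1, pd, n_per_arm: int = 500, alpha: float = 0.025, pooled: bool = False):
    """Power of a one-sided two-sample test of proportions at true rates (p1, pd).

    The default is the unpooled-variance normal approximation

        power = Phi( (pd - p1) sqrt(n / (pd(1-pd) + p1(1-p1))) - z_{1-alpha} );

    ``pooled=True`` uses the pooled-variance statistic under the null instead.
    Vectorised over ``p1``/``pd``.
    """
    p1 = np.asarray(p1, float)
    pd_ = np.asarray(pd, float)
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be at least 1")
    z = stats.norm.ppf(1.0 - alpha)
    var = pd_ * (1 - pd_) + p1 * (1 - p1)
    sd = np.sqrt(var / n_per_arm)
    if pooled:
        pbar = 0.5 * (p1 + pd_)
        null_sd = np.sqrt(2 * pbar * (1 - pbar) / n_per_arm)
        arg = ((pd_ - p1) - z * null_sd) / sd
    else:
        arg = (pd_ - p1) / sd - z
    return stats.norm.cdf(arg)


def pr_phase3_success(draws, rule: DecisionRule) -> np.ndarray:
    """Posterior-mean power per dose: the predictive probability of phase III success.

    The control entry averages power at (P_1, P_1) and therefore sits at the
    test's one-sided level.
    """
    p = _p_matrix(draws)
    return phase3_power(
        p[:, :1], p, rule.n_ph3, rule.alpha_ph3, pooled=rule.pooled
    ).mean(axis=0)


@dataclass(frozen=True)
class TrialDecision:
    selected: int
    success: bool


def evaluate_success(q, rule: DecisionRule) -> TrialDecision:
    """Apply the final evaluation criteria to a set of quantities.

    The selected dose is the active dose with the greatest ``pr_max`` (ties
    to the lowest index); the trial succeeds iff, at that dose,
    ``pr_sup > beta`` and ``pr_ph3 > ph3_cut``.
    """
    pr_max_arr = np.asarray(q.pr_max, float)
    selected = int(np.argmax(pr_max_arr[1:])) + 2
    success = bool(
        q.pr_sup[selected - 1] > rule.beta and q.pr_ph3[selected - 1] > rule.ph3_cut
    )
    return TrialDecision(selected=selected, success=success)


class _QuantityView:
    """Lightweight carrier used before the decision is attached."""

    def __init__(self, pr_max, pr_sup, pr_ph3):
        self.pr_max, self.pr_sup, self.pr_ph3 = pr_max, pr_sup, pr_ph3


def compute_quantities(draws, rule: DecisionRule) -> QuantitySet:
    """All three quantities plus the trial decision, from one posterior sample."""
    pm = pr_max(draws)
    ps = pr_superiority(draws)
    pf = pr_phase3_success(draws, rule)
    decision = evaluate_success(_QuantityView(pm, ps, pf), rule)
    return QuantitySet(
        pr_max=pm,
        pr_sup=ps,
        pr_ph3=pf,
        selected=decision.selected,
        success=decision.success,
    )
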