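"""Model / Results front end.

Usage mirrors the fitting idiom of mainstream statistical packages: build a
model from data, call ``fit()``, inspect the results object.

>>> from bayesdose import HierarchicalEmax, fixture_dataset
>>> res = HierarchicalEmax(fixture_dataset("LargeMonotone")).fit(seed=1)
>>> print(res.summary())          # doctest: +SKIP
>>> res.quantities().selected
8
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import BETA_DEFAULTS, MODEL_IDS
from .quantities import DecisionRule, QuantitySet, compute_quantities
from .sampler import PosteriorDraws, SamplerSettings, sample_posterior
from .scenarios import DoseLadder, TrialDataset, dose_ladder

__all__ = [
    "DoseResponseModel",
    "DoseResponseResults",
    "HierarchicalEmax",
    "FirstOrderNDLM",
    "SecondOrderNDLM",
    "IndependentDoses",
    "Emax",
    "model_for",
]

_LABELS = {
    "hier_emax": "Hierarchical EMAX",
    "ndlm1": "Simple NDLM (first order)",
    "ndlm2": "Second-order NDLM",
    "independent": "Independent doses",
    "emax": "EMAX",
}


class DoseResponseModel:
    """Base class: one dose-response model bound to one trial dataset.

    Subclasses fix ``model_id``.  ``fit`` runs the MCMC sampler and returns a
    :class:`DoseResponseResults`.
    """

    model_id: str = ""

    def __init__(self, data: TrialDataset, ladder: DoseLadder | None = None):
        if not isinstance(data, TrialDataset):
            data = TrialDataset(*np.asarray(data))
        self.data = data
        self.ladder = ladder or dose_ladder()

    @classmethod
    def from_counts(cls, n, y, ladder: DoseLadder | None = None):
        return cls(TrialDataset(n=np.asarray(n), y=np.asarray(y)), ladder=ladder)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ladder: DoseLadder | None = None):
        """Build from a frame with columns ``dose_index``, ``n``, ``y``."""
        return cls(TrialDataset.from_frame(df), ladder=ladder)

    def fit(
        self,
        n_chains: int = 4,
        n_burn: int = 5000,
        n_keep: int = 10000,
        seed: int = 0,
        settings: SamplerSettings | None = None,
    ) -> "DoseResponseResults":
        settings = settings or SamplerSettings(
            n_burn=n_burn, n_keep=n_keep, n_chains=n_chains, seed=seed
        )
        draws = sample_posterior(self.model_id, self.data, settings, self.ladder)
        return DoseResponseResults(self, draws)

    def __repr__(self):
        return f"{type(self).__name__}(n={self.data.n.tolist()}, y={self.data.y.tolist()})"


class HierarchicalEmax(DoseResponseModel):
    """EMAX curve with hierarchical off-curve effects (sum-to-zero, IG variance)."""

    model_id = "hier_emax"


class FirstOrderNDLM(DoseResponseModel):
    """Random walk in dose strength on the log-odds scale."""

    model_id = "ndlm1"


class SecondOrderNDLM(DoseResponseModel):
    """Local linear trend in dose strength with slope innovations."""

    model_id = "ndlm2"


class IndependentDoses(DoseResponseModel):
    """No smoothing: independent N(-0.41, 1) prior per active dose."""

    model_id = "independent"


class Emax(DoseResponseModel):
    """Plain EMAX curve (off-curve effects pinned to zero)."""

    model_id = "emax"


_MODEL_CLASSES = {
    cls.model_id: cls
    for cls in (HierarchicalEmax, FirstOrderNDLM, SecondOrderNDLM, IndependentDoses, Emax)
}


def model_for(model_id: str, data: TrialDataset, ladder=None) -> DoseResponseModel:
    """Instantiate the model class registered under ``model_id``."""
    try:
        return _MODEL_CLASSES[model_id](data, ladder=ladder)
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}; choose from {MODEL_IDS}") from None


class DoseResponseResults:
    """Posterior fit of one model on one dataset.

    Carries the raw draws, convergence diagnostics, posterior summaries of
    the per-arm response probabilities, and the Bayesian decision quantities.
    """

    def __init__(self, model: DoseResponseModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._quantities: dict = {}

    # -- estimates ---------------------------------------------------------

    @property
    def p_mean(self) -> np.ndarray:
        """Posterior mean response probability per arm."""
        return self.draws.p_flat.mean(axis=0)

    @property
    def p_sd(self) -> np.ndarray:
        return self.draws.p_flat.std(axis=0, ddof=1)

    def p_interval(self, prob: float = 0.95) -> np.ndarray:
        """Equal-tailed posterior interval per arm, shape (2, 8)."""
        lo = (1 - prob) / 2
        return np.quantile(self.draws.p_flat, [lo, 1 - lo], axis=0)

    @property
    def converged(self) -> bool:
        return self.draws.converged

    def quantities(self, rule: DecisionRule | None = None) -> QuantitySet:
        """Decision quantities under ``rule`` (default: the model's calibrated beta)."""
        if rule is None:
            beta = BETA_DEFAULTS.get(self.model.model_id, 0.922)
            rule = DecisionRule(beta=beta)
        key = (rule.beta, rule.ph3_cut, rule.alpha_ph3, rule.n_ph3, rule.pooled)
        if key not in self._quantities:
            self._quantities[key] = compute_quantities(self.draws, rule)
        return self._quantities[key]

    # -- presentation ------------------------------------------------------

    def summary_frame(self, rule: DecisionRule | None = None) -> pd.DataFrame:
        q = self.quantities(rule)
        ci = self.p_interval(0.95)
        return pd.DataFrame(
            {
                "dose_index": np.arange(1, 9),
                "strength": self.model.ladder.strength,
                "n": self.model.data.n,
                "y": self.model.data.y,
                "obs_rate": self.model.data.rate,
                "post_mean": self.p_mean,
                "post_sd": self.p_sd,
                "ci_2.5": ci[0],
                "ci_97.5": ci[1],
                "pr_max": q.pr_max,
                "pr_sup": q.pr_sup,
                "pr_ph3": q.pr_ph3,
            }
        )

    def summary(self, rule: DecisionRule | None = None) -> str:
        q = self.quantities(rule)
        rule_used = rule or DecisionRule(beta=BETA_DEFAULTS.get(self.model.model_id, 0.922))
        df = self.summary_frame(rule)
        lines = [
            f"{_LABELS.get(self.model.model_id, self.model.model_id)} posterior fit",
            f"chains={self.draws.theta.shape[0]}  draws/chain={self.draws.theta.shape[1]}"
            f"  max Rhat={np.nanmax(self.draws.rhat):.3f}"
            f"  converged={self.converged}",
            "",
            df.round(3).to_string(index=False),
            "",
            f"selected dose: {q.selected}  "
            f"(Pr(sup)={q.pr_sup[q.selected - 1]:.3f} vs beta={rule_used.beta}, "
            f"Pr(phIII)={q.pr_ph3[q.selected - 1]:.3f} vs {rule_used.ph3_cut})  "
            f"trial success: {q.success}",
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None, interval: float = 0.95):
        """Observed rates with posterior mean and credible band per arm."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(1, 9)
        ci = self.p_interval(interval)
        ax.fill_between(x, ci[0], ci[1], alpha=0.3, label=f"{int(interval * 100)}% CrI")
        ax.plot(x, self.p_mean, "-o", label="posterior mean")
        ax.plot(x, self.model.data.rate, "ks", label="observed rate")
        ax.set_xlabel("dose index")
        ax.set_ylabel("response probability")
        ax.set_ylim(0, 1)
        ax.set_title(_LABELS.get(self.model.model_id, self.model.model_id))
        ax.legend()
        return ax

    def __repr__(self):
        return (
            f"<DoseResponseResults {self.model.model_id} "
            f"chains={self.draws.theta.shape[0]} draws={self.draws.theta.shape[1]}>"
        )
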