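"""Log-odds dose-response models: likelihood, priors and parameter-to-theta maps.

Every model works on the log-odds scale ``theta_d = logit(P_d)`` with the
per-arm likelihood ``Y_d ~ Binomial(n_d, P_d)``.  The control arm (d=1) is
always modelled separately with the vague prior ``theta_1 ~ N(-0.41, 0.75^2)``
(median response 0.40); the five active-dose models are:

``hier_emax``
    Hierarchical EMAX: ``theta_d = phi1 + phi2 nu_d / (nu_d + phi3) + psi_d``
    with off-curve effects ``psi_d ~ N(0, phi4_sq)`` constrained to sum to
    zero, letting the saturating EMAX curve bend toward non-monotone data.
``ndlm1``
    First-order normal dynamic linear model (random walk in dose strength):
    ``theta_d ~ N(theta_{d-1}, tau_sq (nu_d - nu_{d-1}))``.
``ndlm2``
    Second-order NDLM (local linear trend): theta extrapolates the slope of
    the previous two doses, perturbed by slope innovations
    ``zeta_d ~ N(0, tau2_sq)``.
``independent``
    Separate ``N(-0.41, 1)`` priors per active dose, no smoothing.
``emax``
    Plain EMAX: the hierarchical model with the off-curve effects pinned to
    zero, same (phi1, phi2, phi3) priors.

Variance hyperpriors are inverse-gamma.  ``IG(a, b)`` here means density
proportional to ``x^{-a-1} exp(-b/x)``; the NDLM hyperprior
``IG(tau_n/2, tau_u^2 tau_n/2)`` then has prior central value ``tau_u^2``
with weight ``tau_n``, matching the BUGS precision-gamma convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .scenarios import DoseLadder, TrialDataset, dose_ladder

__all__ = [
    "MODEL_IDS",
    "BETA_DEFAULTS",
    "CONTROL_MEAN",
    "CONTROL_SD",
    "HierEmaxParams",
    "SimpleNdlmParams",
    "SecondNdlmParams",
    "ControlParam",
    "NdlmHyper",
    "logit",
    "inv_logit",
    "hier_emax_theta",
    "ndlm_transition_variance",
    "second_ndlm_theta",
    "log_prior",
    "log_likelihood",
]

#: Active-dose model identifiers understood throughout the package.
MODEL_IDS = ("hier_emax", "ndlm1", "ndlm2", "independent", "emax")

#: Model-specific superiority thresholds calibrated to a 10% type I error.
BETA_DEFAULTS = {"hier_emax": 0.922, "ndlm1": 0.903, "ndlm2": 0.938}

CONTROL_MEAN = -0.41
CONTROL_SD = 0.75

# Hierarchical EMAX prior constants
PHI1_MEAN, PHI1_SD = -0.41, 1.0
PHI2_MEAN, PHI2_SD = 0.0, 5.0
PHI3_MEAN, PHI3_SD = 3.0, 10.0  # positively truncated
PHI4SQ_SHAPE, PHI4SQ_RATE = 0.1, 0.001

INDEP_MEAN, INDEP_SD = -0.41, 1.0


def logit(p):
    """Log-odds of a probability in the open interval (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("logit requires 0 < p < 1")
    return special.logit(p)


def inv_logit(theta):
    """Inverse logit (logistic) function."""
    return special.expit(np.asarray(theta, dtype=float))


@dataclass(frozen=True)
class ControlParam:
    """Control-arm log-odds theta_1."""

    theta1: float


@dataclass(frozen=True)
class NdlmHyper:
    """Inverse-gamma smoothness hyperprior: central value ``tau_u``, weight ``tau_n``.

    The implied prior on the system variance is
    ``IG(tau_n / 2, tau_u^2 tau_n / 2)``.  Defaults are (0.2, 0.1) for the
    first-order NDLM and (0.1, 0.2) for the second-order NDLM.
    """

    tau_u: float
    tau_n: float

    def __post_init__(self):
        if self.tau_u <= 0 or self.tau_n <= 0:
            raise ValueError("tau_u and tau_n must be positive")

    @property
    def shape(self) -> float:
        return self.tau_n / 2.0

    @property
    def rate(self) -> float:
        return self.tau_u**2 * self.tau_n / 2.0


NDLM1_HYPER = NdlmHyper(tau_u=0.2, tau_n=0.1)
NDLM2_HYPER = NdlmHyper(tau_u=0.1, tau_n=0.2)


@dataclass(frozen=True)
class HierEmaxParams:
    """Hierarchical EMAX parameters.

    ``psi`` may be passed unconstrained (seven free effects); it is stored
    raw in ``psi_raw`` while the ``psi`` attribute always returns the
    centred (sum-to-zero) effects that enter the dose-response curve —
    centring inside the theta map is how the sum-to-zero constraint is
    imposed.
    """

    phi1: float
    phi2: float
    phi3: float
    psi_raw: np.ndarray = field(default_factory=lambda: np.zeros(7))
    phi4_sq: float = 1.0

    def __init__(self, phi1, phi2, phi3, psi=None, phi4_sq=1.0):
        object.__setattr__(self, "phi1", float(phi1))
        object.__setattr__(self, "phi2", float(phi2))
        object.__setattr__(self, "phi3", float(phi3))
        psi = np.zeros(7) if psi is None else np.asarray(psi, dtype=float)
        if psi.shape != (7,):
            raise ValueError("psi must have 7 entries (doses 2..8)")
        object.__setattr__(self, "psi_raw", psi)
        object.__setattr__(self, "phi4_sq", float(phi4_sq))
        if self.phi3 <= 0:
            raise ValueError("phi3 must be positive")
        if self.phi4_sq <= 0:
            raise ValueError("phi4_sq must be positive")

    @property
    def psi(self) -> np.ndarray:
        """Centred off-curve effects; sums to zero by construction."""
        return self.psi_raw - self.psi_raw.mean()


@dataclass(frozen=True)
class SimpleNdlmParams:
    """First-order NDLM state (theta_2..theta_8) and system variance tau_sq."""

    theta: np.ndarray
    tau_sq: float

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        if theta.shape != (7,):
            raise ValueError("theta must have 7 entries (doses 2..8)")
        if self.tau_sq <= 0:
            raise ValueError("tau_sq must be positive")
        object.__setattr__(self, "theta", theta)


@dataclass(frozen=True)
class SecondNdlmParams:
    """Second-order NDLM state.

    ``theta`` holds theta_2..theta_8; ``zeta`` the slope innovations for
    doses 4..8.  theta_4..theta_8 are deterministic given (theta_2, theta_3,
    zeta), and the constructor checks that consistency.  theta_3 takes a
    first-order step from theta_2 (the local-linear recursion needs two
    dosed predecessors and the control has no dose strength).
    """

    theta: np.ndarray
    zeta: np.ndarray
    tau2_sq: float
    ladder: DoseLadder = field(default_factory=dose_ladder, repr=False)

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        zeta = np.asarray(self.zeta, dtype=float)
        if theta.shape != (7,) or zeta.shape != (5,):
            raise ValueError("theta must have 7 entries and zeta 5 (doses 4..8)")
        if self.tau2_sq <= 0:
            raise ValueError("tau2_sq must be positive")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "zeta", zeta)
        expected = second_ndlm_path(theta[0], theta[1], zeta, self.ladder)
        if not np.allclose(theta, expected, atol=1e-8):
            raise ValueError("theta inconsistent with (theta_2, theta_3, zeta) recursion")

    @classmethod
    def from_innovations(cls, theta2, theta3, zeta, tau2_sq, ladder=None):
        ladder = ladder or dose_ladder()
        theta = second_ndlm_path(theta2, theta3, np.asarray(zeta, float), ladder)
        return cls(theta, np.asarray(zeta, float), tau2_sq, ladder)


def hier_emax_theta(params: HierEmaxParams, ladder: DoseLadder | None = None) -> np.ndarray:
    """Evaluate theta_2..theta_8 = phi1 + phi2 nu/(nu + phi3) + psi (psi centred)."""
    ladder = ladder or dose_ladder()
    if params.phi3 <= 0:
        raise ValueError("phi3 must be positive")
    nu = ladder.active_strength
    return params.phi1 + params.phi2 * nu / (nu + params.phi3) + params.psi


def ndlm_transition_variance(tau_sq: float, ladder: DoseLadder, d: int) -> float:
    """Variance of the first-order NDLM step into dose ``d``: tau_sq (nu_d - nu_{d-1})."""
    if not 3 <= d <= 8:
        raise ValueError("transition variance is defined for doses 3..8")
    if tau_sq < 0:
        raise ValueError("tau_sq must be nonnegative")
    return tau_sq * (ladder.strength[d - 1] - ladder.strength[d - 2])


def second_ndlm_theta(theta_prev2, theta_prev1, zeta_d, ladder: DoseLadder, d: int):
    """One second-order NDLM step: extrapolate the previous slope, perturbed by zeta_d.

    theta_d = ((theta_{d-1} - theta_{d-2}) / (nu_{d-1} - nu_{d-2}) + zeta_d)
              * (nu_d - nu_{d-1}) + theta_{d-1}
    """
    if not 4 <= d <= 8:
        raise ValueError("the second-order recursion applies to doses 4..8")
    nu = ladder.strength
    back = nu[d - 2] - nu[d - 3]
    ahead = nu[d - 1] - nu[d - 2]
    if back == 0 or ahead == 0:
        raise ValueError("dose strengths must be distinct")
    slope = (np.asarray(theta_prev1) - np.asarray(theta_prev2)) / back
    return (slope + zeta_d) * ahead + theta_prev1


def second_ndlm_path(theta2, theta3, zeta, ladder: DoseLadder) -> np.ndarray:
    """theta_2..theta_8 from (theta_2, theta_3) and slope innovations zeta_4..zeta_8."""
    theta = np.zeros(np.broadcast_shapes(np.shape(theta2), np.shape(zeta)[:-1]) + (7,))
    theta[..., 0] = theta2
    theta[..., 1] = theta3
    for d in range(4, 9):
        theta[..., d - 2] = second_ndlm_theta(
            theta[..., d - 4], theta[..., d - 3], zeta[..., d - 4], ladder, d
        )
    return theta


def _invgamma_logpdf(x, shape, rate):
    # density b^a / Gamma(a) x^{-a-1} exp(-b/x)
    return stats.invgamma.logpdf(x, shape, scale=rate)


def _truncnorm_pos_logpdf(x, mean, sd):
    x = np.asarray(x, dtype=float)
    lp = stats.norm.logpdf(x, mean, sd) - np.log(stats.norm.sf(0.0, mean, sd))
    return np.where(x > 0, lp, -np.inf)


def log_prior(model_id: str, params, ladder: DoseLadder | None = None) -> float:
    """Log joint prior density of a model's parameter set (−inf off support).

    For ``hier_emax`` the seven raw off-curve effects carry independent
    ``N(0, phi4_sq)`` priors; the sum-to-zero constraint is the centring
    applied inside the theta map, not a density restriction.
    """
    ladder = ladder or dose_ladder()
    if model_id == "control":
        return float(stats.norm.logpdf(params.theta1, CONTROL_MEAN, CONTROL_SD))

    if model_id in ("hier_emax", "emax"):
        p = params
        if p.phi3 <= 0:
            return -np.inf
        lp = (
            stats.norm.logpdf(p.phi1, PHI1_MEAN, PHI1_SD)
            + stats.norm.logpdf(p.phi2, PHI2_MEAN, PHI2_SD)
            + _truncnorm_pos_logpdf(p.phi3, PHI3_MEAN, PHI3_SD)
        )
        if model_id == "hier_emax":
            if p.phi4_sq <= 0:
                return -np.inf
            lp += _invgamma_logpdf(p.phi4_sq, PHI4SQ_SHAPE, PHI4SQ_RATE)
            lp += stats.norm.logpdf(p.psi_raw, 0.0, np.sqrt(p.phi4_sq)).sum()
        return float(lp)

    if model_id == "ndlm1":
        p = params
        if p.tau_sq <= 0:
            return -np.inf
        hyper = NDLM1_HYPER
        lp = _invgamma_logpdf(p.tau_sq, hyper.shape, hyper.rate)
        lp += stats.norm.logpdf(p.theta[0], CONTROL_MEAN, CONTROL_SD)
        for d in range(3, 9):
            var = ndlm_transition_variance(p.tau_sq, ladder, d)
            lp += stats.norm.logpdf(p.theta[d - 2], p.theta[d - 3], np.sqrt(var))
        return float(lp)

    if model_id == "ndlm2":
        p = params
        if p.tau2_sq <= 0:
            return -np.inf
        hyper = NDLM2_HYPER
        lp = _invgamma_logpdf(p.tau2_sq, hyper.shape, hyper.rate)
        lp += stats.norm.logpdf(p.theta[0], CONTROL_MEAN, CONTROL_SD)
        var3 = ndlm_transition_variance(p.tau2_sq, ladder, 3)
        lp += stats.norm.logpdf(p.theta[1], p.theta[0], np.sqrt(var3))
        lp += stats.norm.logpdf(p.zeta, 0.0, np.sqrt(p.tau2_sq)).sum()
        return float(lp)

    if model_id == "independent":
        theta = np.asarray(params.theta if hasattr(params, "theta") else params, float)
        return float(stats.norm.logpdf(theta, INDEP_MEAN, INDEP_SD).sum())

    raise ValueError(f"unknown model_id {model_id!r}")


def log_likelihood(theta_full, data: TrialDataset) -> float:
    """Binomial log-likelihood of theta_1..theta_8 (binomial coefficients included)."""
    theta = np.asarray(theta_full, dtype=float)
    if theta.shape[-1] != 8:
        raise ValueError("theta_full must cover all 8 doses")
    n, y = data.n, data.y
    if np.any(y > n):
        raise ValueError("y_d cannot exceed n_d")
    const = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    core = y * theta - n * np.logaddexp(0.0, theta)
    return float((core + const).sum(axis=-1)) if theta.ndim == 1 else (core + const).sum(axis=-1)


def bernoulli_loglik_core(theta, n, y):
    """Likelihood kernel without binomial coefficients, batched over leading axes."""
    return (y * theta - n * np.logaddexp(0.0, theta)).sum(axis=-1)


def prior_constants() -> dict:
    """All prior hyperconstants, for provenance echoes in results files."""
    return {
        "control": {"mean": CONTROL_MEAN, "sd": CONTROL_SD},
        "phi1": {"mean": PHI1_MEAN, "sd": PHI1_SD},
        "phi2": {"mean": PHI2_MEAN, "sd": PHI2_SD},
        "phi3": {"mean": PHI3_MEAN, "sd": PHI3_SD, "truncated_at": 0.0},
        "phi4_sq": {"shape": PHI4SQ_SHAPE, "rate": PHI4SQ_RATE},
        "ndlm1": {"tau_u": NDLM1_HYPER.tau_u, "tau_n": NDLM1_HYPER.tau_n},
        "ndlm2": {"tau_u": NDLM2_HYPER.tau_u, "tau_n": NDLM2_HYPER.tau_n},
        "independent": {"mean": INDEP_MEAN, "sd": INDEP_SD},
    }
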