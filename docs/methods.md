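# Methods

## Design being modelled

The package models a fixed (non-adaptive) eight-arm phase II dose-selection
trial with a binary endpoint. Arm 1 is standard of care; arms 2–8 are oxygen
regimens ordered by a scalar dose strength ν ∈ {2.60, 4.17, 5.40, 5.92, 6.20,
7.76, 9.52} (daily oxygen toxicity units / 100). The control has no defined ν
and is modelled separately everywhere. Allocation puts ≈20% of subjects on
control and splits the remainder equally over the seven active arms; at the
design's n = 200 this is (39, 23, …, 23). The general rule takes the feasible
control size nearest round(0.2 n) such that the remainder divides by 7,
preferring the smaller size on ties — the only allocation the design tables
pin down is n = 200, which this rule reproduces.

## Likelihood and models

Y_d ~ Binomial(n_d, P_d) independently per arm, θ_d = logit(P_d), and
θ_1 ~ N(−0.41, 0.75²) for the control (prior median response 0.40). The
quoted 95% interval for this prior (0.09–0.83 on the probability scale) is
actually consistent with an sd of 1 rather than 0.75; the package follows the
stated 0.75 and exposes the sd as a parameter.

Active-dose models (model ids in parentheses):

* Hierarchical EMAX (`hier_emax`): θ_d = φ₁ + φ₂ν_d/(ν_d+φ₃) + ψ_d with
  φ₁ ~ N(−0.41, 1²), φ₂ ~ N(0, 5²), φ₃ ~ N⁺(3, 10²), ψ_d ~ N(0, φ₄²) and
  φ₄² ~ IG(0.1, 0.001). IG(a, b) throughout means density ∝ x^(−a−1)e^(−b/x)
  (equivalently, the precision is Gamma(a, rate b) — the BUGS convention).
  The sum-to-zero constraint Σψ_d = 0 is imposed by sampling seven free
  effects and centring them inside the θ map; this is symmetric across doses,
  and the uncentred effects keep their iid prior (so the variance update
  stays conjugate with shape increment 7/2).
* First-order NDLM (`ndlm1`): θ₂ ~ N(−0.41, 0.75²), then
  θ_d ~ N(θ_{d−1}, τ²(ν_d − ν_{d−1})) — a random walk whose step variance
  scales with the dose-strength spacing. τ² ~ IG(τ_n/2, τ_u²τ_n/2) with
  central value τ_u = 0.2 and weight τ_n = 0.1.
* Second-order NDLM (`ndlm2`): θ₂ ~ N(−0.41, 0.75²);
  θ_d = ((θ_{d−1}−θ_{d−2})/(ν_{d−1}−ν_{d−2}) + ζ_d)(ν_d−ν_{d−1}) + θ_{d−1}
  for d ≥ 4, with slope innovations ζ_d ~ N(0, τ₂²) and
  τ₂² ~ IG(τ_n/2, τ_u²τ_n/2), τ_u = 0.1, τ_n = 0.2. (The (τ_u, τ_n) values
  really are swapped between the two NDLMs; both are implemented exactly as
  specified.) The recursion needs two dosed predecessors, which dose 3 does
  not have (the control has no ν), so θ₃ takes a first-order step
  θ₃ ~ N(θ₂, τ₂²(ν₃−ν₂)); this keeps τ₂² the only smoothness parameter and
  is the package's own choice — the original specification of that corner
  case is not recoverable.
* Independent (`independent`): θ_d ~ N(−0.41, 1²) per active dose, no
  smoothing. Used as a reference model and as a quadrature-checkable test
  case (its posterior factorises into seven 1-D problems).
* Plain EMAX (`emax`): the hierarchical model with ψ ≡ 0, same curve priors.

## Decision quantities and success rule

From a posterior sample of (P_1, …, P_8):

* Pr(D_max): per active dose, the fraction of draws in which it has the
  largest response probability among active doses (control excluded; exact
  ties, a measure-zero event, go to the lowest index).
* Pr(P_d > P_1): the fraction of draws in which the dose beats control.
* Pr(phase III success): the posterior mean of the power of a fixed
  confirmatory trial — 500 per arm, one-sided α = 0.025 two-sample test of
  proportions. The power function is the unpooled-variance normal
  approximation Φ((p_d−p_1)√(n/(p_d(1−p_d)+p_1(1−p_1))) − z_{1−α}); a
  pooled-null-variance alternative is available via `DecisionRule(pooled=True)`
  and differs by < 0.02 at the design's operating point. The approximation is
  within ~0.003 of exact enumeration of both binomial arms at n = 500. At
  p_d = p_1 the power is exactly α, which is why the control column of the
  predictive-probability output sits at 0.025.

The trial succeeds iff, at the selected dose (argmax Pr(D_max)),
Pr(P_d > P_1) > β and Pr(phase III success) > 0.5. β is model-specific so
that every model has the same 10% type I error: 0.922 (hierarchical EMAX),
0.903 (simple NDLM), 0.938 (second-order NDLM).

## Sampler

Adaptive random-walk Metropolis-within-Gibbs:

* Scalar parameters (φ₁, φ₂, φ₃, θ_d states, ζ_d, θ₁) use Gaussian
  random-walk proposals. Step sizes adapt per coordinate toward 44%
  acceptance with a Robbins–Monro schedule (t^−0.6) during burn-in and are
  frozen afterwards. φ₃ proposals reflect at zero (the kernel stays
  symmetric, and the truncation constant cancels).
* ψ and ζ proposal scales are multiplied by the current hierarchical sd
  (clipped to [0.02, 2]) so the effects keep mixing whether the data shrink
  them hard or let them roam.
* Variance hyperparameters (φ₄², τ², τ₂²) get exact conjugate inverse-gamma
  Gibbs updates in the centred parameterisation, followed by an interweaving
  move: transform to the non-centred parameterisation (effects divided by the
  sd), propose the variance from its prior, rescale the effects back, accept
  on the likelihood ratio alone. The pair of moves crosses the funnel between
  an effect vector and its variance; with empty data the interweave accepts
  always and hence draws the variance exactly from its prior, which is what
  makes prior-recovery tests sharp.
* The control log-odds θ₁ is updated from its own prior times the control
  binomial likelihood only, independent of the active-dose model.

The whole state carries a leading batch axis. A "batch" is chains for a
single fit, or chains × replicate datasets for simulation, so one sweep
advances everything in a handful of vectorised array operations — this is
what makes 500-replicate operating characteristics computable in ~20 s per
(model, scenario) on one CPU.

Defaults: 4 chains × 5000 burn-in × 10000 kept for single fits (Monte-Carlo
error of reported probabilities ≲ 0.005, appropriate for quantities read to
two decimals); 2 chains × 1500 burn-in × 2000 kept per replicate inside
simulation, where only the threshold comparisons at the selected dose
matter. Convergence is monitored with split-R̂ (and bulk ESS for single
fits) via ArviZ; any dose with R̂ > 1.1 flags the result — a warning and a
`flagged` attribute for single fits, a per-replicate flag and count in
simulation (flagged replicates are retained and reported, not dropped). At
the lightweight simulation settings the second-order NDLM flags a
noticeable minority of replicates (its global trend moves mix slowest);
its aggregate operating characteristics are nonetheless stable across seeds.

Reproducibility: a single fit is bit-reproducible from `SamplerSettings.seed`.
In `run_trials`, replicate datasets come from per-trial `SeedSequence`
streams (each dataset reproducible in isolation); the batched MCMC consumes
one sibling stream for the whole batch, so a replicate's posterior is
reproducible given the run's seed and n_trials. The alternative — one
independent MCMC stream per replicate — would forfeit the batch
vectorisation that makes the simulation study tractable.

## Simulation study and operating characteristics

`run_trials` simulates complete trials under a scenario truth with the
n = 200 allocation. The built-in truths cover the design's qualitative
dose-response shapes — Large (monotone rise 0.40 → 0.65), NBH (0.70 only at
the four arms with added normobaric oxygen), OverDose (rise to 0.70 at d = 5
then collapse), and Null (0.40 everywhere, used only for calibration; it is
a conventional no-effect truth, with the control rate taken from the other
scenarios). Defaults are 500 replicates per scenario and 1000 for
calibration: binomial Monte-Carlo error ≈ 0.022 near p = 0.5 at n = 500,
comfortably inside the ±0.07 bands used in the acceptance tests, at a
fraction of the cost of more replicates.

P(correct) and P(incorrect) are unconditional frequencies over all simulated
trials of "succeeds and selects inside/outside the correct set"; they need
not sum to one (the remainder is trials that stop without success). P(best)
restricts to the doses attaining the maximum true rate. Type I error is the
success rate under the Null truth.

`calibrate_beta` exploits the fact that the selected dose does not depend on
β: one batch of null trials is fit once, the per-trial
(Pr(P_d > P_1), Pr(phase III)) at the selected dose are cached, and the
success rule is re-evaluated over a 0.001 grid; the returned β is the
smallest grid value whose null success rate is ≤ the target. The rate is
nonincreasing in β by construction, so the search is exact.

The ideal design percentage treats the selected dose as "practiced" after a
successful trial and the control after a failure, and rescales the expected
true rate of the practiced arm between the worst and best true rates:
ID = (E[rate] − min)/(max − min). The mixture over dose-response shapes is
(1−π)·ID_Large + (π/2)·ID_NBH + (π/2)·ID_OverDose, with π the probability of
a non-monotone pattern.

## What the synthetic data does and does not capture

Simulated trials are independent binomial draws per arm at fixed true rates —
exactly the design's data-generating model. Passing tests therefore
demonstrate the behaviour of the *design machinery* (model fits, decision
rule, calibration) under its own assumptions; they say nothing about
covariate drift, non-exchangeable patients, misspecified endpoints or
interim-analysis behaviour, none of which the fixed design models.

## Numerical choices and degenerate inputs

* Binomial coefficients are included in `log_likelihood` so absolute values
  match a pmf oracle; the sampler's internal kernel drops them (they cancel
  in every ratio).
* Likelihood terms use y·θ − n·log(1+e^θ) via `logaddexp`, stable for |θ| of
  any size (prior proposals for variances can be astronomically large; they
  are simply rejected).
* Inverse-gamma draws are taken as rate/Gamma(shape) with a 1e-300 floor on
  the gamma variate.
* Zero-count or zero-size arms are valid inputs (n_d = 0 makes the arm's
  likelihood flat); `logit` rejects p ∉ (0,1); `allocate` rejects totals
  below 8; ideal design is undefined (raises) for constant truths.
* `pr_max` tie-breaking to the lowest index matters only for degenerate
  (discrete) draw sets, as in tests.

## Known limitations

* The per-dose posterior quantities printed in the original OpenBUGS analysis
  of the three example datasets are only partly reproducible from the models
  as stated; this package's fits agree with an independent JAGS
  implementation of the same priors and likelihood, and its simulated
  operating characteristics agree with the published (FACTS-derived) ones,
  so the package follows the stated models. The acceptance tests record the
  disagreeing cells honestly rather than adjusting the models toward them.
* No response-adaptive randomisation, interim analyses, covariates,
  longitudinal endpoints or alternative link functions.
* The second-order NDLM's dose-3 prior is an explicit modelling choice (see
  above), not a reproduction.
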