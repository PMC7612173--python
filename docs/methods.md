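# Methods

This note documents the statistical model, the numerical choices and the
synthetic study designs implemented by `betel`, and what the shipped tests
do and do not establish.

## Model and estimands

Data records Dᵢ are i.i.d. from an unknown P₀. A parameter θ ∈ Θ ⊂ ℝᵐ is
identified by a just-identified unbiased estimating function g:
E[g(D, θ₀)] = 0 with dim g = dim θ. Over-identified systems are out of
scope. Two settings are implemented.

**Design setting.** Records are (RZ, R, Rπ): a selection indicator R, the
outcome block Z observed only when R = 1, and the known sampling
probability π (also observed only when R = 1). Z and R are conditionally
independent given the design variables that generated π, and π ≥ δ > 0
(positivity). A full-data estimating function u(Z, θ) lifts to the
observed-data moment g = (R/π) u(Z, θ), with R/(Rπ) := 0 when R = 0;
conditional independence makes g unbiased for the full-data moment. For
u = Y − θ the M-estimator is the Hájek ratio estimator
Σ(R/π)Y / Σ(R/π), invariant to rescaling of the weights; a
survey-weighted linear-regression score u = Xᵀ(Y − Xθ) is also provided.

**Observational setting.** Records are (RZ, R, W) with W fully observed
and selection ignorable given W. Parametric working models are the
logistic propensity π(W; α) = expit(α₀ + αᵀW) and the linear outcome
regression m(W; β) = β₀ + βᵀW, both with intercept-first design vectors
(1, W). The target mean γ enters through the augmented IPW moment

    h(D, α, β, γ) = R(Y − γ)/π(W; α) − φ(W, γ; β){R/π(W; α) − 1},

with φ(W, γ; β) = m(W; β) − γ — the unique affine choice whose averaged
root reproduces the standard AIPW estimator exactly. The stacked system
g = (U_α, U_β, h) is just-identified and block triangular, so its root
coincides with the sequential fit (logistic ML, complete-case least
squares, then the AIPW functional); the block of auxiliary parameters
between β and γ is empty in every shipped model, and extending the stack
amounts to inserting extra score columns there. The γ-margin of the root
is consistent when at least one working model is correct (double
robustness), and the posterior inherits this.

## ETEL evaluation

At fixed θ with moment rows gᵢ, the likelihood is L_n = ∏ n pᵢ with p the
maximum-entropy distribution on the data points satisfying Σpᵢgᵢ = 0;
L_n = 0 when the origin is not in the convex hull of the rows. Numerics:

* **Feasibility.** The documented check is an LP: find x ∈ [0,1]ⁿ with
  Σx = 1 and |Gᵀx| ≤ `feas_tol` (default 1e-10) componentwise, solved by
  HiGHS; LP failures other than proven infeasibility raise, never
  silently report infeasible. For m = 1 an exact sign test
  (min < 0 < max, or all rows zero) replaces the LP.
* **Dual solve.** λ̂ minimizes the smooth convex objective
  log Σ exp(λᵀgᵢ) by Newton iteration from λ = 0 (the unconstrained
  entropy maximizer) with step-halving backtracking (≤ 30 halvings), so
  the objective never increases; when backtracking cannot decrease the
  objective in double precision, a step that still shrinks the gradient
  is accepted. Convergence is declared when the weighted-mean residual
  ‖Σ wᵢ(λ) gᵢ‖∞ ≤ `tol` (default 1e-8) — the weighted-mean form makes
  the tolerance scale-free in n. Softmax/log-sum-exp shifts make any
  finite input overflow-safe.
* **Boundary and infeasible points.** Parameter values whose
  maximum-entropy weights vanish (origin on the hull boundary) have
  L_n = 0 because some n·pᵢ = 0: the evaluation returns an explicit
  infeasible flag with a −∞ log-likelihood, never NaN, so samplers
  reject. A converged dual whose smallest weight is below 100·`tol` is
  classified as boundary (at a boundary the smallest weight is of the
  order of the dual residual; interior weights sit far above it — states
  that close to the boundary carry likelihood below e⁻¹⁸ regardless).
  Degenerate n = 1 input is feasible iff the single row is the zero
  vector.
* **Sampler fast path.** Inside samplers the per-evaluation LP is
  replaced by divergence detection of the dual iteration itself
  (`feasibility="dual"`): an empty or boundary feasible set manifests as
  a diverging iterate (guard at ‖λ‖∞ > 1e10), a stalled line search, or
  iteration-budget exhaustion, all mapped to the −∞ sentinel; a singular
  dual Hessian — indistinguishable from degeneracy without the LP
  certificate — is likewise a rejection there, while the LP-checked path
  raises it. Equality of the two modes is tested on random feasible and
  infeasible instances. Successive sampler evaluations warm-start the
  Newton iteration at the previous tilt; the dual optimum is unique
  (strictly convex), so warm starts change the iteration count only, and
  a failed warm start is retried cold before any infeasibility verdict.
* Large simulation studies in this literature often run at tolerance 1e-4; this
  implementation defaults to the tighter 1e-8 in sup-norm.

## M-estimation and the sandwich

Roots of n⁻¹Σg(dᵢ, θ) = 0 are found by damped Newton with the averaged
analytic Jacobian when supplied, otherwise central finite differences
with step h_k = max(1e-6, 1e-6·|θ_k|); iterates are projected onto the
parameter box; a failed start is retried from a data-driven initial value
(e.g. the sequential fit for the stacked system). The sandwich pieces are
Ĝ = n⁻¹Σ∂θg, Ω̂ = n⁻¹Σggᵀ and Σ̂ = (ĜᵀΩ̂⁻¹Ĝ)⁻¹ assembled with linear
solves (no inverse chains), symmetrized; Σ̂ estimates the covariance of
√n(θ̂ − θ₀), so standard errors are √(diag Σ̂ / n). Working-model fits
(logistic, weighted least squares) are solved by the package's own
Newton/lstsq routines — they are exactly the roots of the shipped score
moments and are called ~10⁵ times with fractional weights by the
Bayesian-bootstrap comparator; reference fits from a standard GLM/OLS
library serve as independent oracles in the test suite.

## Priors and posterior sampling

Priors are products of independent scalar components — beta, uniform,
normal, generalized Student-t (location, scale, df) and half-normal
(sign, scale) — covering every prior used in the shipped analyses;
supports are open intervals and the posterior-mean theory additionally
wants a finite prior mean (flagged: t with df ≤ 1 fails it). Samplers:

* **Importance sampling** (default for the scalar design-mean model):
  particles are prior draws, so the log-weights are exactly the ETEL
  log-likelihood; summaries are self-normalized, with Kish ESS reported
  and a hard failure below ESS 10. Appropriate when the prior covers the
  posterior (the low-dimensional settings here); a posterior-centred
  normal proposal would be the alternative for diffuse priors.
* **Random-walk Metropolis–Hastings** (the stacked model): Gaussian
  proposals with covariance (2.38²/m)·Σ̂/n from the sandwich fit,
  initialized at θ̂ (a guaranteed-feasible maximizer of the likelihood);
  −∞ states auto-reject. During burn-in only, the scalar proposal
  multiplier is nudged every 50 iterations toward the 20–40% acceptance
  band and then frozen, so the retained chain targets the exact
  posterior. Defaults mirror the study configuration: 2000 iterations,
  500 burn-in.

Point summaries are posterior means; intervals are equal-tailed
(central) quantile intervals, not HPD. One seeded generator drives each
run; replication r of any Monte-Carlo study uses seed base + r, so every
replication is reproducible in isolation.

## Comparators

* **Normal-approximation posterior**: working likelihood
  θ̂ | θ ~ N(θ, V̂) around a consistent estimator with V̂ from the
  nonparametric bootstrap (default B = 1000 resamples; failed resamples
  are redrawn with a counter, > 10% failures abort), combined with the
  prior by the same importance-sampling machinery.
* **Bayesian-bootstrap doubly robust posterior**: per draw, uniform
  Dirichlet weights ω over the records; ω-weighted logistic ML for α,
  ω-weighted least squares on the selected records for β, and the
  ω-weighted AIPW functional for μ (default S = 2000 draws). The printed
  outcome-model utility in the source literature is a *maximization* of
  a squared error; it is implemented as the weighted least-squares
  minimizer, the only reading consistent with matching the AIPW
  specification, and the propensity utility as the standard weighted
  logistic log-likelihood.

## Synthetic study designs

**Design study.** W ~ Be(1.5, 3.5), Y | W ~ Ber(W) — so the estimand is
E Y = E W = 0.3 — and R | W ~ Ber(expit(W)): outcome and selection
probability are positively correlated, so unweighted estimation is biased
upward. Emitted records are (R, RY, Rπ) only, with Y and π stored as
explicit missing values when R = 0; the generator never leaks the design
variable. These defaults are the study conditions, not tuning knobs.

**Observational study** (the classic misspecification benchmark).
W ~ N(0, I₄); R | W ~ Ber(expit(−W₁ + 0.5W₂ − 0.25W₃ − 0.1W₄))
(selection fraction 1/2 by symmetry); Y | W ~ N(m₀(W), 1) with
m₀(W) = 210 + 27.4W₁ + 13.7(W₂ + W₃ + W₄), so μ₀ = 210. Misspecified
working models use the nonlinear transforms W′₁ = exp(W₁/2),
W′₂ = W₂/{1+exp(W₁)} + 10, W′₃ = (W₁W₃/25 + 0.6)³, W′₄ = (W₂+W₄+20)³ in
place of W. Working-model priors are weakly informative t₃ with unit
scale, centred at (0,…,0) for α and at (210, 30, 10, 10, 10) (correct
outcome model) or (35, 50, 0, −135, 0) (transformed covariates) for β;
the mean prior is t₃(210, 1) (weakly informative) or N(210, 1)
(informative). The source study does not print its sample size for this
design; the harness takes n explicitly with default n = 200, the
customary size for this benchmark, and printed results for it are
treated as qualitative orderings only.

**Replication harness.** Per replication: generate with seed base + r,
run each method, record point estimate (posterior mean for Bayes
methods), central 95% interval and truth. Aggregates: bias, RMSE, MAE
(median absolute error), ESD (empirical sd, (reps−1) denominator;
RMSE² = bias² + ESD²·(reps−1)/reps is asserted as an identity) and
coverage. Method failures are caught, counted and excluded per method; a
method failing on more than 2% of replications is flagged prominently.
At n = 25 roughly 0.7% of design datasets have every observed outcome
identical: there the moment variance is singular (no sandwich interval)
and the ETEL is zero for every parameter value (no posterior), so these
replications fail for all interval-producing methods and are excluded by
that protocol.

## What the tests show — and problem sizes

The validation suite computes, among others: exact closed forms for the
two-point ETEL instance; agreement of the dual solve with a brute-force
primal entropy maximizer (n ≤ 12, m ≤ 3) to 1e-6; zero ETEL
log-likelihood at the M-estimate and no improvement over 50 random
perturbations, in both settings; design-study Hájek RMSE at
n = 25/50/100 over 2000 replications; Bernstein–von Mises calibration at
n = 1000 (posterior sd within 15% of the sandwich SE, posterior mean
within 0.25 sandwich SEs of θ̂, aggregated over 100 replications of 2000
importance particles — at that size the importance-sampling error is
~2% of the posterior sd); and double-robustness coverage at n = 200 over
100 replications per misspecification cell (binomial 3·SE band around
95%), with the both-models-wrong cell checked as an ordering (the
frequentist estimator degrades; the informative-prior posterior mean has
the smallest RMSE) over 60 replications. Replication counts are chosen
so the full suite runs in minutes; every stochastic tolerance is derived
from the replication count actually used.

Passing these tests shows the machinery is correct *for these
generators*: i.i.d. records, correctly recorded sampling probabilities,
low-dimensional smooth working models, moderate n. They do not establish
behaviour under practical positivity violations (propensities near 0),
high-dimensional or machine-learned nuisance models, clustered or
informative-cluster sampling, or model classes outside the two shipped
moment systems.

## Known limitations

* Just-identified systems only; no over-identified GMM weighting or
  continuous-updating variants, and no empirical-likelihood (reverse-KL)
  weights.
* The ETEL evaluation is O(n·m) per Newton step but is called once per
  posterior evaluation; MCMC over large stacks is the dominant cost.
* Importance sampling with the prior as proposal degrades for diffuse
  priors at large n (ESS collapse); the MH sampler is the fallback.
* The boundary-weight classification threshold (100·tol) deliberately
  rejects states within e⁻¹⁸ of the hull boundary; this is invisible at
  the shipped tolerances but couples the feasibility verdict to `tol`.
* Single-entry caches keyed on frame identity assume input frames are
  not mutated in place between evaluations.
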