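# betel — Bayesian exponentially tilted empirical likelihood under unequal probability sampling

`betel` performs Bayesian inference for population parameters when the data
were collected with unequal selection probabilities — the situation faced
by analysts of public-use survey data (selection probabilities known for
the sampled units) and of observational / missing-data problems (selection
unknown but ignorable given fully observed covariates). It is aimed at
biostatisticians and epidemiologists who want the robustness of
inverse-probability-weighted estimating equations together with the
practical benefits of a posterior distribution: priors for regularization
and evidence synthesis, parameter-space constraints, and credible
intervals with asymptotically nominal frequentist coverage.

## The model

A parameter θ ∈ ℝᵐ is defined by a just-identified unbiased moment
condition E[g(D, θ₀)] = 0. The exponentially tilted empirical likelihood
(ETEL) at θ is

    L_n(θ) = ∏ᵢ n pᵢ(θ),

where p(θ) maximizes entropy Σᵢ −pᵢ log pᵢ over the probability simplex
subject to Σᵢ pᵢ g(dᵢ, θ) = 0, and L_n(θ) = 0 whenever the origin lies
outside the convex hull of {g(dᵢ, θ)}. The solution is computed through
the convex dual: pᵢ ∝ exp{λ̂(θ)ᵀ g(dᵢ, θ)} with λ̂ solving
Σᵢ exp(λᵀgᵢ) gᵢ = 0 (Newton iteration; LP hull check). The posterior is

    p(θ | d₁…d_n) ∝ L_n(θ) p(θ).

By a Bernstein–von Mises argument this posterior is asymptotically
N(θ̂_n, Σ̂/n), centred at the M-estimator θ̂_n solving
n⁻¹ Σ g(dᵢ, θ) = 0 with sandwich covariance Σ̂ = (ĜᵀΩ̂⁻¹Ĝ)⁻¹ — so
credible sets inherit the estimator's frequentist calibration, including
double robustness in the observational setting.

Two concrete moment systems ship:

* **design setting** — data (R, RY, Rπ); g = (R/π) u(Z, θ) with, e.g.,
  u = Y − θ (the Hájek ratio estimator) or a weighted linear regression
  score;
* **observational setting** — data (R, RY, W); the stacked doubly robust
  system g = (U_α, U_β, h) combining the logistic propensity score
  π(W; α), the complete-case least-squares outcome score for m(W; β), and
  the augmented IPW moment
  h = R(Y−γ)/π(W;α) − {m(W;β)−γ}{R/π(W;α) − 1},
  whose γ-margin is consistent if either working model is correct.

Comparators from the same literature are included: a normal-approximation
posterior around θ̂ with bootstrap variance, and a Bayesian-bootstrap
doubly robust posterior (uniform Dirichlet record weights).

## Worked example

Estimate a population mean of a binary outcome from a 100-record design
sample with known selection probabilities, combining the ETEL with an
informative Be(1.5, 3.5) prior:

```python
from betel import BETELDesignMean, gen_design_data

df = gen_design_data(100, seed=1)          # columns R, Y, pi (masked when R=0)
fit = BETELDesignMean(prior="beta:1.5,3.5", n_particles=5000,
                      random_state=0).fit(df)
print(fit.theta_hat_, fit.se_)             # Hajek estimate and sandwich SE
print(fit.posterior_mean_, fit.posterior_sd_, fit.credible_interval_)
```

prints

```
Hajek estimate       : 0.2594 (SE 0.0581)
posterior mean (sd)  : 0.2642 (0.0551)
95% credible interval: (0.1631, 0.3764)
importance-sampling ESS: 1921 / 5000
```

The posterior mean is shrunk slightly from the Hájek estimate toward the
prior mean 0.3, the posterior sd tracks the sandwich SE (the
Bernstein–von Mises calibration), and every draw respects the (0, 1)
support enforced by the beta prior.

The same workflow is available from the shell:

```bash
betel fit --data design.csv --model design-mean --prior beta:1.5,3.5 \
      --seed 0 --outdir out/            # writes mestimate.json, draws.csv,
                                        # summary.json, config.yaml, run.log
betel simulate --scenario design --reps 50 --n 25 --methods hajek,betel:uniform \
      --seed 0 --outdir sim/            # Monte-Carlo replication report
```

For the observational setting, `BETELDoublyRobustMean` (or
`betel fit --model dr-mean --ps-cols W1,W2,W3,W4`) fits the stacked system
and samples the posterior over (α, β, μ) by adaptive random-walk
Metropolis–Hastings initialized at the M-estimate.

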