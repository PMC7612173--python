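"""Comparator methods: normal-approximation Bayes and the Bayesian
bootstrap, plus the nonparametric bootstrap variance they rely on.

The normal-approximation posterior treats a consistent, asymptotically
normal estimator theta_hat as a summary statistic with working likelihood
theta_hat | theta ~ N(theta, V_hat), V_hat estimated by the nonparametric
bootstrap, and combines it with a prior:  p(theta | theta_hat) is
proportional to N(theta_hat; theta, V_hat) p(theta).

The Bayesian-bootstrap doubly robust posterior draws uniform Dirichlet
weights omega over the records and recomputes the weighted nuisance fits
and the weighted AIPW functional under each omega; the induced draws of
mu form a posterior-predictive sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import BetelError, SamplingError, ValidationError
from .moments import sequential_dr_fit
from .posterior import PosteriorDraws, importance_sample
from .priors import IndependentPrior, ScalarPrior

__all__ = ["bootstrap_variance", "wang_posterior", "saarela_posterior",
           "BayesianBootstrapDraws"]

_MAX_FAILURE_FRACTION = 0.10


def bootstrap_variance(
    estimator,
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
) -> float:
    """Nonparametric bootstrap variance of ``estimator(data)``.

    Resamples the n records with replacement B times; a resample on which
    the estimator fails (e.g. no selected records) is redrawn and counted,
    and more than 10% failures aborts.  Deterministic given ``seed``.
    """
    if B < 2:
        raise ValidationError("bootstrap needs B >= 2 replicates")
    rng = np.random.default_rng(seed)
    n = len(data)
    reps = np.empty(B)
    failures = 0
    max_failures = int(np.ceil(_MAX_FAILURE_FRACTION * B))
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                reps[b] = float(estimator(data.iloc[idx].reset_index(drop=True)))
                break
            except BetelError:
                failures += 1
                if failures > max_failures:
                    raise SamplingError(
                        f"bootstrap estimator failed on more than "
                        f"{_MAX_FAILURE_FRACTION:.0%} of resamples"
                    )
    return float(np.var(reps, ddof=1))


def wang_posterior(
    theta_hat: float,
    V_hat: float,
    prior: ScalarPrior | IndependentPrior,
    n_particles: int = 5000,
    seed: int = 0,
) -> PosteriorDraws:
    """Normal-approximation posterior, sampled by prior-proposal
    importance sampling (log-weights N(theta_hat; theta, V_hat))."""
    if not V_hat > 0:
        raise ValidationError("V_hat must be positive")
    if isinstance(prior, ScalarPrior):
        prior = IndependentPrior([prior])
    if prior.dim != 1:
        raise ValidationError("normal-approximation comparator is scalar-only")
    sd = float(np.sqrt(V_hat))

    def log_lik(theta):
        return stats.norm.logpdf(theta_hat, loc=float(theta[0]), scale=sd)

    return importance_sample(
        model=None,
        data=None,
        prior=prior,
        n_particles=n_particles,
        seed=seed,
        log_lik=log_lik,
    )


@dataclass
class BayesianBootstrapDraws:
    """Draws of (alpha, beta, mu) under uniform Dirichlet record weights."""

    alpha: np.ndarray  # (S, p)
    beta: np.ndarray  # (S, q)
    mu: np.ndarray  # (S,)
    seed: int
    n_redraws: int = 0

    def mu_posterior(self) -> PosteriorDraws:
        """The mu margin as unweighted posterior draws."""
        return PosteriorDraws(
            draws=self.mu[:, None],
            log_weights=np.zeros(self.mu.size),
            method="bb",
            seed=self.seed,
        )


def saarela_posterior(
    data: pd.DataFrame,
    ps_cols,
    or_cols,
    n_draws: int = 2000,
    seed: int = 0,
) -> BayesianBootstrapDraws:
    """Bayesian-bootstrap doubly robust posterior.

    Per draw: omega ~ Dirichlet(1, ..., 1); alpha(omega) the omega-weighted
    logistic MLE; beta(omega) the omega-weighted least-squares fit on the
    selected records; mu(omega) the omega-weighted AIPW functional.  Draws
    whose weighted fit fails are redrawn (with a counter); more than 10%
    failures aborts.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    alphas, betas, mus = [], [], []
    failures = 0
    max_failures = int(np.ceil(_MAX_FAILURE_FRACTION * n_draws))
    for _ in range(n_draws):
        while True:
            omega = rng.dirichlet(np.ones(n))
            try:
                a, b, mu = sequential_dr_fit(data, ps_cols, or_cols, weights=omega)
                break
            except BetelError:
                failures += 1
                if failures > max_failures:
                    raise SamplingError(
                        "Bayesian bootstrap: weighted fits failed on more "
                        f"than {_MAX_FAILURE_FRACTION:.0%} of draws"
                    )
        alphas.append(a)
        betas.append(b)
        mus.append(mu)
    return BayesianBootstrapDraws(
        alpha=np.array(alphas),
        beta=np.array(betas),
        mu=np.array(mus),
        seed=seed,
        n_redraws=failures,
    )
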