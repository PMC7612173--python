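"""High-level estimators in the scikit-learn idiom.

Each estimator validates its inputs in ``fit``, exposes its configuration
through ``get_params`` / ``set_params`` and stores results in trailing-
underscore attributes, so they compose with scikit-learn model-selection
utilities.  They are thin orchestration layers: the moment functions,
M-estimation, ETEL evaluation and samplers all live in the corresponding
library modules.

``BETELDesignMean`` — population mean under known sampling probabilities
(design setting): Hajek point estimate with sandwich standard error, and a
BETEL posterior for the mean sampled by prior-proposal importance sampling
(suited to this scalar, bounded-support setting) or random-walk MH.

``BETELDoublyRobustMean`` — population mean under ignorable selection
(observational setting): stacked doubly robust system (propensity score,
outcome regression, AIPW moment) solved as one just-identified
M-estimation problem, then a BETEL posterior over the full parameter
stack sampled by MH; the target-mean margin is the last coordinate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .etel import SolverSettings
from .exceptions import ValidationError
from .io import validate_design_frame, validate_obs_frame
from .mestimation import solve_m_estimator
from .moments import design_mean_model, hajek_mean, stacked_dr_model
from .posterior import (
    etel_logpost_fn,
    importance_sample,
    metropolis_hastings,
    summarize,
)
from .priors import IndependentPrior, parse_prior

__all__ = ["BETELDesignMean", "BETELDoublyRobustMean"]

_RW_SCALE = 2.38  # standard random-walk scaling constant


class BETELDesignMean(BaseEstimator):
    """Bayesian ETEL inference for a population mean with known sampling
    probabilities.

    Parameters
    ----------
    prior : str or ScalarPrior, default "uniform"
        Prior for the mean; e.g. ``"uniform"``, ``"jeffreys"``,
        ``"beta:1.5,3.5"``, ``"normal:0.3,0.1"``.
    sampler : {"is", "mh"}
        Importance sampling from the prior (default) or random-walk MH.
    n_particles : int
        Importance-sampling particle count.
    n_iter, burn_in : int
        MH chain length and burn-in (used when ``sampler="mh"``).
    level : float
        Credible level for the central interval.
    tol : float
        ETEL dual convergence tolerance (sup-norm, weighted-mean form).
    random_state : int
        Seed for the sampler.

    Attributes
    ----------
    theta_hat_ : float        Hajek point estimate.
    se_ : float               sandwich standard error of ``theta_hat_``.
    mestimate_ : MEstimate    full M-estimation output.
    posterior_ : PosteriorDraws
    summary_ : dict           posterior mean/sd/interval and diagnostics.
    posterior_mean_, posterior_sd_ : float
    credible_interval_ : tuple[float, float]
    """

    def __init__(
        self,
        prior="uniform",
        sampler="is",
        n_particles=5000,
        n_iter=2000,
        burn_in=500,
        level=0.95,
        tol=1e-8,
        random_state=0,
    ):
        self.prior = prior
        self.sampler = sampler
        self.n_particles = n_particles
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.level = level
        self.tol = tol
        self.random_state = random_state

    def fit(self, data: pd.DataFrame, y=None):
        df = validate_design_frame(data)
        settings = SolverSettings(tol=self.tol)
        model = design_mean_model()
        est = solve_m_estimator(model, df, np.array([hajek_mean(df)]))
        prior = IndependentPrior([parse_prior(self.prior)])

        if self.sampler == "is":
            post = importance_sample(
                model,
                df,
                prior,
                n_particles=self.n_particles,
                seed=self.random_state,
                settings=settings,
            )
        elif self.sampler == "mh":
            logpost = etel_logpost_fn(model, df, prior, settings)
            post = metropolis_hastings(
                lambda t: logpost(t)[0],
                init=est.theta_hat,
                proposal_cov=(_RW_SCALE**2) * est.cov,
                n_iter=self.n_iter,
                burn_in=self.burn_in,
                seed=self.random_state,
            )
        else:
            raise ValidationError("sampler must be 'is' or 'mh'")

        self.mestimate_ = est
        self.theta_hat_ = float(est.theta_hat[0])
        self.se_ = float(est.se[0])
        self.posterior_ = post
        self.summary_ = summarize(post, level=self.level)
        self.posterior_mean_ = float(self.summary_["mean"][0])
        self.posterior_sd_ = float(self.summary_["sd"][0])
        self.credible_interval_ = (
            float(self.summary_["lower"][0]),
            float(self.summary_["upper"][0]),
        )
        self.n_features_in_ = df.shape[1]
        return self


class BETELDoublyRobustMean(BaseEstimator):
    """Bayesian ETEL inference for a population mean under ignorable
    selection, doubly robust through the stacked moment system.

    Parameters
    ----------
    ps_cols, or_cols : sequence of str
        Covariate columns for the propensity (logistic) and outcome
        (linear) working models; ``or_cols`` defaults to ``ps_cols``.
    prior_alpha, prior_beta : str/prior or sequence thereof
        Priors for the working-model coefficient blocks, intercept first.
        A single spec is broadcast across the block.  Defaults are weakly
        informative: ``t:0,2.5,3`` per propensity coefficient and a
        diffuse ``t:0,1000,3`` per outcome coefficient.
    prior_mu : str or prior, default "t:0,1000,3"
        Prior for the target mean.
    n_iter, burn_in : int
        MH chain length and burn-in (defaults 2000 / 500).
    level, tol, random_state : as in :class:`BETELDesignMean`.

    Attributes
    ----------
    theta_hat_ : ndarray      stacked M-estimate (alpha, beta, mu).
    mu_hat_ : float           AIPW point estimate (last coordinate).
    mu_se_ : float            its sandwich standard error.
    posterior_ : PosteriorDraws over the full stack.
    summary_ : dict
    mu_posterior_mean_, mu_posterior_sd_ : float
    mu_credible_interval_ : tuple[float, float]
    """

    def __init__(
        self,
        ps_cols=("W1", "W2", "W3", "W4"),
        or_cols=None,
        prior_alpha="t:0,2.5,3",
        prior_beta="t:0,1000,3",
        prior_mu="t:0,1000,3",
        n_iter=2000,
        burn_in=500,
        level=0.95,
        tol=1e-8,
        random_state=0,
    ):
        self.ps_cols = ps_cols
        self.or_cols = or_cols
        self.prior_alpha = prior_alpha
        self.prior_beta = prior_beta
        self.prior_mu = prior_mu
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.level = level
        self.tol = tol
        self.random_state = random_state

    def _block_prior(self, spec, size, label):
        if isinstance(spec, (list, tuple)):
            comps = [parse_prior(s) for s in spec]
            if len(comps) != size:
                raise ValidationError(
                    f"{label} prior needs {size} components, got {len(comps)}"
                )
            return comps
        return [parse_prior(spec) for _ in range(size)]

    def fit(self, data: pd.DataFrame, y=None):
        ps_cols = list(self.ps_cols)
        or_cols = list(self.or_cols) if self.or_cols is not None else ps_cols
        needed = sorted(set(ps_cols) | set(or_cols))
        df, _ = validate_obs_frame(data, w_cols=needed)
        p, q = len(ps_cols) + 1, len(or_cols) + 1

        settings = SolverSettings(tol=self.tol)
        model = stacked_dr_model(ps_cols, or_cols)
        init = model.default_init(df)
        est = solve_m_estimator(model, df, init)

        prior = IndependentPrior(
            self._block_prior(self.prior_alpha, p, "alpha")
            + self._block_prior(self.prior_beta, q, "beta")
            + [parse_prior(self.prior_mu)]
        )
        logpost = etel_logpost_fn(model, df, prior, settings)
        post = metropolis_hastings(
            lambda t: logpost(t)[0],
            init=est.theta_hat,
            proposal_cov=(_RW_SCALE**2 / model.dim) * est.cov,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            seed=self.random_state,
        )

        self.mestimate_ = est
        self.theta_hat_ = est.theta_hat
        self.alpha_hat_ = est.theta_hat[:p]
        self.beta_hat_ = est.theta_hat[p : p + q]
        self.mu_hat_ = float(est.theta_hat[-1])
        self.mu_se_ = float(est.se[-1])
        self.posterior_ = post
        self.summary_ = summarize(post, level=self.level)
        self.mu_posterior_mean_ = float(self.summary_["mean"][-1])
        self.mu_posterior_sd_ = float(self.summary_["sd"][-1])
        self.mu_credible_interval_ = (
            float(self.summary_["lower"][-1]),
            float(self.summary_["upper"][-1]),
        )
        self.n_features_in_ = df.shape[1]
        return self
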