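"""BETEL posterior sampling and summaries.

The posterior is p(theta | d) proportional to L_n(theta) p(theta), with
L_n the exponentially tilted empirical likelihood of the chosen moment
model.  Two samplers are provided:

* importance sampling with the prior as proposal (log-weights are then
  exactly the ETEL log-likelihood at each particle), suited to low
  dimension with a prior that covers the posterior; and
* Gaussian random-walk Metropolis-Hastings initialized at the M-estimate,
  with proposal covariance (2.38^2 / m) * Sigma_hat / n and a scalar
  adaptation of that scale during burn-in targeting 20-40% acceptance.

Parameter values where the ETEL is zero (origin outside the hull of the
moment evaluations) or outside the prior support have log-posterior -inf
and are rejected by both samplers.

Inside the samplers the hull check is delegated to the dual solve itself
(`feasibility="dual"`): a divergent dual iteration certifies an empty or
boundary feasible set, at a fraction of the cost of an LP per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .etel import SolverSettings, etel_loglik
from .exceptions import SamplingError, ValidationError
from .mestimation import MomentModel
from .priors import IndependentPrior

__all__ = [
    "PosteriorDraws",
    "log_posterior",
    "importance_sample",
    "metropolis_hastings",
    "summarize",
]


@dataclass
class PosteriorDraws:
    """Posterior draws with their sampling metadata.

    ``log_weights`` are all zero for MCMC output; importance-sampling
    output carries the unnormalized log-weights and all summaries are
    self-normalized.
    """

    draws: np.ndarray  # (S, m)
    log_weights: np.ndarray  # (S,)
    method: str  # "is" or "mh"
    seed: int | None = None
    acceptance: float | None = None  # MH only
    n_proposed: int = 0

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def dim(self) -> int:
        return self.draws.shape[1]

    def weights(self) -> np.ndarray:
        """Self-normalized importance weights (uniform for MCMC)."""
        lw = self.log_weights - self.log_weights.max()
        w = np.exp(lw)
        return w / w.sum()

    @property
    def ess(self) -> float:
        """Kish effective sample size (sum w)^2 / sum w^2."""
        w = self.weights()
        return float(1.0 / np.sum(w**2))


def etel_logpost_fn(
    model: MomentModel,
    data,
    prior: IndependentPrior,
    settings: SolverSettings | None = None,
    feasibility: str = "dual",
):
    """Return theta -> (log posterior, log likelihood) for sampler use."""
    settings = settings or SolverSettings()

    warm = {"lam": None}

    def parts(theta):
        lp = prior.logpdf(theta)
        if lp == -np.inf:
            return -np.inf, -np.inf
        G = model.moments(data, theta)
        ev = etel_loglik(G, settings, feasibility=feasibility, lam0=warm["lam"])
        if not ev.feasible:
            return -np.inf, -np.inf
        warm["lam"] = ev.lam  # warm-start the next nearby evaluation
        return ev.loglik + lp, ev.loglik

    return parts


def log_posterior(
    model: MomentModel,
    data,
    prior: IndependentPrior,
    theta,
    settings: SolverSettings | None = None,
) -> float:
    """ETEL log-likelihood plus prior log-density (-inf when either is)."""
    return etel_logpost_fn(model, data, prior, settings, feasibility="lp")(
        np.atleast_1d(np.asarray(theta, float))
    )[0]


def importance_sample(
    model: MomentModel,
    data,
    prior: IndependentPrior,
    n_particles: int = 5000,
    seed: int = 0,
    settings: SolverSettings | None = None,
    log_lik=None,
) -> PosteriorDraws:
    """Prior-proposal importance sampler.

    Particles are prior draws; each log-weight is the ETEL log-likelihood
    (the prior density cancels between target and proposal).  ``log_lik``
    overrides the likelihood (used by the normal-approximation comparator).
    Deterministic given ``seed``.
    """
    if n_particles < 1:
        raise ValidationError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    particles = prior.sample(rng, n_particles)
    if log_lik is None:
        parts = etel_logpost_fn(model, data, prior, settings)
        lw = np.array([parts(t)[1] for t in particles])
    else:
        lw = np.array([float(log_lik(t)) for t in particles])
    if not np.any(np.isfinite(lw)):
        raise SamplingError(
            "all importance particles have zero likelihood; widen the prior "
            "or use Metropolis-Hastings"
        )
    return PosteriorDraws(
        draws=particles,
        log_weights=lw,
        method="is",
        seed=seed,
        n_proposed=n_particles,
    )


def metropolis_hastings(
    log_post,
    init,
    proposal_cov,
    n_iter: int = 2000,
    burn_in: int = 500,
    seed: int = 0,
    adapt: bool = True,
) -> PosteriorDraws:
    """Gaussian random-walk Metropolis-Hastings.

    ``log_post`` maps theta to a log-density (may be -inf; such proposals
    are auto-rejected).  ``init`` must have finite log-posterior.  During
    burn-in the scalar multiplier of the proposal covariance is adapted
    every 50 iterations toward 20-40% acceptance; it is frozen afterwards
    so the retained chain targets the exact posterior.  Deterministic
    given ``seed``.
    """
    init = np.atleast_1d(np.asarray(init, dtype=float))
    m = init.size
    if burn_in >= n_iter:
        raise ValidationError("burn_in must be smaller than n_iter")
    lp = float(log_post(init))
    if not np.isfinite(lp):
        raise SamplingError("MH initial state has zero posterior density")
    cov = np.atleast_2d(np.asarray(proposal_cov, dtype=float))
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("proposal covariance must be positive definite") from exc

    rng = np.random.default_rng(seed)
    scale = 1.0
    theta = init.copy()
    kept = np.empty((n_iter - burn_in, m))
    accepted_post = 0
    window_acc = 0

    for it in range(n_iter):
        prop = theta + scale * (L @ rng.standard_normal(m))
        lp_prop = float(log_post(prop))
        if lp_prop - lp > np.log(rng.uniform()):
            theta, lp = prop, lp_prop
            if it >= burn_in:
                accepted_post += 1
            else:
                window_acc += 1
        if adapt and it < burn_in and (it + 1) % 50 == 0:
            rate = window_acc / 50.0
            # nudge the log-scale toward the 0.2-0.4 acceptance band
            scale *= float(np.exp(rate - 0.3))
            scale = float(np.clip(scale, 1e-3, 1e3))
            window_acc = 0
        if it >= burn_in:
            kept[it - burn_in] = theta

    acc_rate = accepted_post / (n_iter - burn_in)
    return PosteriorDraws(
        draws=kept,
        log_weights=np.zeros(n_iter - burn_in),
        method="mh",
        seed=seed,
        acceptance=acc_rate,
        n_proposed=n_iter,
    )


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    """Quantiles of a weighted sample by inverse-CDF interpolation."""
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws) - 0.5 * ws
    cw /= ws.sum()
    return np.interp(q, cw, xs)


def summarize(post: PosteriorDraws, level: float = 0.95) -> dict:
    """Mean, sd and central (equal-tailed) interval per component.

    Importance-sampled draws are summarized with self-normalized weights;
    MCMC draws with uniform weights.  Raises when the effective sample
    size is below 10 (summaries would be dominated by a handful of
    particles).
    """
    if post.n_draws == 0:
        raise ValidationError("no draws to summarize")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must be in (0, 1)")
    ess = post.ess
    if ess < 10.0:
        raise SamplingError(
            f"effective sample size {ess:.1f} < 10; posterior summaries "
            "would be unreliable"
        )
    w = post.weights()
    qs = ((1.0 - level) / 2.0, (1.0 + level) / 2.0)
    mean = np.einsum("s,sm->m", w, post.draws)
    centered = post.draws - mean
    sd = np.sqrt(np.einsum("s,sm->m", w, centered**2))
    lower = np.empty(post.dim)
    upper = np.empty(post.dim)
    for k in range(post.dim):
        lower[k], upper[k] = _weighted_quantile(post.draws[:, k], w, qs)
    out = {
        "mean": mean,
        "sd": sd,
        "lower": lower,
        "upper": upper,
        "level": level,
        "ess": ess,
        "method": post.method,
    }
    if post.acceptance is not None:
        out["acceptance"] = post.acceptance
        if post.acceptance < 0.01:
            out["warning"] = "acceptance rate below 1%; chain may be stuck"
    return out
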