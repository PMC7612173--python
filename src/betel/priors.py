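"""Prior specifications.

Priors are composed from independent scalar components, each backed by a
frozen scipy distribution.  The supported families cover every prior used
by the shipped analyses: beta, uniform, normal, generalized Student-t
(location/scale/df) and half-normal (restricted to one sign).

A component exposes a log-density, a sampler, its support interval and a
finite-mean flag (the posterior-mean theory needs E||theta|| < inf under
the prior; a t with df <= 1 would violate it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import betaln as sp_betaln, gammaln

from .exceptions import ValidationError

__all__ = ["ScalarPrior", "IndependentPrior", "make_prior", "parse_prior"]


@dataclass
class ScalarPrior:
    """One independent prior component.

    ``logpdf_fn`` is an optional closed-form log-density used in sampler
    hot loops; it must agree with ``dist.logpdf`` on the support interior.
    """

    name: str
    dist: object  # frozen scipy.stats distribution
    support: tuple[float, float]
    finite_mean: bool = True
    logpdf_fn: object = None

    def logpdf(self, x):
        if self.logpdf_fn is not None:
            return self.logpdf_fn(x)
        return self.dist.logpdf(x)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.dist.rvs(size=size, random_state=rng)


class IndependentPrior:
    """Product prior over an m-vector from independent scalar components."""

    def __init__(self, components):
        components = list(components)
        if not components:
            raise ValidationError("prior needs at least one component")
        self.components = components
        self.dim = len(components)
        self.lower = np.array([c.support[0] for c in components])
        self.upper = np.array([c.support[1] for c in components])
        self.finite_mean = all(c.finite_mean for c in components)

    def logpdf(self, theta) -> float:
        """Sum of component log-densities; -inf outside the open support."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.shape != (self.dim,):
            raise ValidationError(f"theta must have length {self.dim}")
        # open-interval support: boundary points count as outside
        if np.any(theta <= self.lower) or np.any(theta >= self.upper):
            return -np.inf
        lp = 0.0
        for c, x in zip(self.components, theta):
            v = float(c.logpdf(x))
            if not np.isfinite(v):
                return -np.inf
            lp += v
        return lp

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draws of shape (size, dim)."""
        cols = [c.sample(rng, size) for c in self.components]
        return np.column_stack(cols)

    def __mul__(self, other: "IndependentPrior") -> "IndependentPrior":
        return IndependentPrior(self.components + other.components)


def make_prior(name: str, *params) -> ScalarPrior:
    """Build a scalar prior component by family name.

    Families: ``beta(a, b)``, ``uniform(lo, hi)``, ``normal(mean, sd)``,
    ``t(loc, scale, df)``, ``halfnormal(sign, scale)`` with sign '+' or '-'.
    ``jeffreys`` is the Be(0.5, 0.5) shorthand for a probability parameter.
    """
    name = name.lower().replace("-", "").replace("_", "")
    if name == "jeffreys":
        return make_prior("beta", 0.5, 0.5)
    if name == "beta":
        a, b = map(float, params)
        lnB = float(sp_betaln(a, b))
        return ScalarPrior(
            "beta",
            stats.beta(a, b),
            (0.0, 1.0),
            logpdf_fn=lambda x: (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - lnB,
        )
    if name == "uniform":
        lo, hi = (0.0, 1.0) if not params else map(float, params)
        if not hi > lo:
            raise ValidationError("uniform prior needs hi > lo")
        c = -np.log(hi - lo)
        return ScalarPrior(
            "uniform", stats.uniform(lo, hi - lo), (lo, hi), logpdf_fn=lambda x: c
        )
    if name in ("normal", "gaussian"):
        mean, sd = map(float, params)
        if sd <= 0:
            raise ValidationError("normal prior needs sd > 0")
        c = -0.5 * np.log(2.0 * np.pi) - np.log(sd)
        return ScalarPrior(
            "normal",
            stats.norm(mean, sd),
            (-np.inf, np.inf),
            logpdf_fn=lambda x: c - 0.5 * ((x - mean) / sd) ** 2,
        )
    if name in ("t", "studentt"):
        loc, scale, df = map(float, params)
        if scale <= 0 or df <= 0:
            raise ValidationError("t prior needs scale > 0 and df > 0")
        c = (
            gammaln((df + 1.0) / 2.0)
            - gammaln(df / 2.0)
            - 0.5 * np.log(df * np.pi)
            - np.log(scale)
        )
        half = (df + 1.0) / 2.0

        def t_logpdf(x, c=c, half=half, loc=loc, scale=scale, df=df):
            z = (x - loc) / scale
            return c - half * np.log1p(z * z / df)

        return ScalarPrior(
            "t", stats.t(df, loc=loc, scale=scale), (-np.inf, np.inf),
            finite_mean=df > 1,
            logpdf_fn=t_logpdf,
        )
    if name == "halfnormal":
        sign, scale = params
        scale = float(scale)
        if scale <= 0:
            raise ValidationError("half-normal prior needs scale > 0")
        if sign in ("+", 1, "pos"):
            return ScalarPrior("halfnormal+", stats.halfnorm(0.0, scale), (0.0, np.inf))
        if sign in ("-", -1, "neg"):
            # mirror of halfnorm on the negative axis
            dist = _NegHalfNorm(scale)
            return ScalarPrior("halfnormal-", dist, (-np.inf, 0.0))
        raise ValidationError("half-normal sign must be '+' or '-'")
    raise ValidationError(f"unknown prior family '{name}'")


class _NegHalfNorm:
    """Half-normal supported on the negative reals (mirror of halfnorm)."""

    def __init__(self, scale):
        self._pos = stats.halfnorm(0.0, scale)

    def logpdf(self, x):
        return self._pos.logpdf(-np.asarray(x, float))

    def rvs(self, size, random_state):
        return -self._pos.rvs(size=size, random_state=random_state)


def parse_prior(spec) -> ScalarPrior:
    """Parse 'family:p1,p2,...' strings, e.g. 'beta:1.5,3.5' or 't:210,1,3'.

    Passes through objects that are already prior components.
    """
    if isinstance(spec, ScalarPrior):
        return spec
    if not isinstance(spec, str):
        raise ValidationError(f"cannot interpret prior spec {spec!r}")
    name, _, rest = spec.partition(":")
    params = []
    if rest:
        for tok in rest.split(","):
            tok = tok.strip()
            if tok in ("+", "-"):
                params.append(tok)
            else:
                try:
                    params.append(float(tok))
                except ValueError as exc:
                    raise ValidationError(
                        f"bad prior parameter {tok!r} in {spec!r}"
                    ) from exc
    try:
        return make_prior(name, *params)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"bad prior spec {spec!r}: {exc}") from exc
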