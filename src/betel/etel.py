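"""Exponentially tilted empirical likelihood (ETEL) evaluation.

For a moment model ``E[g(D, theta)] = 0`` with a just-identified m-vector of
estimating functions, the ETEL at a fixed parameter value is built from the
multinomial distribution on the observed points that maximizes entropy
subject to the moment constraint:

    max sum_i (-p_i log p_i)   s.t.  sum_i p_i = 1,  sum_i p_i g_i = 0,

with ``g_i = g(d_i, theta)``.  The likelihood is ``L_n = prod_i n p_i``; it
is zero whenever the origin is outside the convex hull of the ``g_i``.  The
solution is obtained through the convex dual: minimize
``log sum_i exp(lam' g_i)`` over the tilting vector ``lam``, whose optimum
satisfies the weighted-mean equation ``sum_i w_i(lam) g_i = 0`` with softmax
weights ``w_i``.

This module works on the n x m matrix of moment evaluations only; it knows
nothing about data records or parameters.  All entry points reject
non-finite input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.special import softmax

from .exceptions import (
    FeasibilityError,
    NonConvergenceError,
    SingularJacobianError,
    ValidationError,
)

__all__ = [
    "SolverSettings",
    "ETELEvaluation",
    "check_feasibility",
    "solve_dual",
    "etel_weights",
    "etel_loglik",
]

#: Sentinel log-likelihood for parameter values with zero ETEL.
NEG_INF = -np.inf

# Divergence guard for the dual iteration: a tilting vector this large only
# arises when the origin sits on (or outside) the hull boundary, where the
# entropy problem has no interior solution.
_LAM_DIVERGED = 1e10

# A converged dual whose smallest weight is at the order of the residual
# tolerance is a boundary solution (a weight vanishing in the limit), not
# an interior one; interior weights sit far above the dual residual.
_BOUNDARY_WEIGHT_FACTOR = 100.0


@dataclass
class SolverSettings:
    """Numerical controls for the ETEL evaluation.

    Parameters
    ----------
    tol:
        Convergence tolerance on the sup-norm of the weighted-mean dual
        residual ``|| sum_i w_i g_i ||_inf``.  The residual is tested in
        weighted-mean form so the tolerance is scale-free in ``n``.
    max_iter:
        Newton iteration budget for the dual solve.
    feas_tol:
        Two-sided slack on ``G' x = 0`` in the LP feasibility check.
    max_halvings:
        Backtracking line-search budget per Newton step.
    """

    tol: float = 1e-8
    max_iter: int = 100
    feas_tol: float = 1e-10
    max_halvings: int = 30

    def __post_init__(self):
        if not self.tol > 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


@dataclass
class ETELEvaluation:
    """Result of evaluating the ETEL at one parameter value.

    When ``feasible`` is false, ``loglik`` is ``-inf`` and ``lam``/``p`` are
    ``None``; samplers reject such states instead of crashing.
    """

    feasible: bool
    loglik: float
    lam: np.ndarray | None = None
    p: np.ndarray | None = None
    iterations: int = 0
    converged: bool = False


def _as_moment_matrix(G) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.ndim != 2 or G.shape[0] < 1 or G.shape[1] < 1:
        raise ValidationError("moment matrix must be n x m with n, m >= 1")
    if not np.all(np.isfinite(G)):
        raise ValidationError("moment matrix contains non-finite entries")
    return G


def check_feasibility(G, settings: SolverSettings | None = None) -> bool:
    """Return True iff the origin lies in the convex hull of the rows of G.

    Solved as an LP feasibility problem: find x with 0 <= x_i <= 1,
    sum x_i = 1 and ``|G' x| <= feas_tol`` componentwise.  A solver failure
    that is not a certificate of infeasibility is raised as
    :class:`FeasibilityError`, never silently reported as infeasible.
    """
    settings = settings or SolverSettings()
    G = _as_moment_matrix(G)
    n, m = G.shape
    A_ub = np.vstack([G.T, -G.T])
    b_ub = np.full(2 * m, settings.feas_tol)
    res = linprog(
        c=np.zeros(n),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=np.ones((1, n)),
        b_eq=[1.0],
        bounds=(0.0, 1.0),
        method="highs",
    )
    if res.status == 0:
        return True
    if res.status == 2:  # proven infeasible
        return False
    raise FeasibilityError(f"LP feasibility check failed: {res.message}")


def _softmax_lse(z: np.ndarray):
    """(softmax(z), logsumexp(z)) with a single shift; inlined hot path."""
    zmax = z.max()
    ez = np.exp(z - zmax)
    s = ez.sum()
    return ez / s, zmax + np.log(s)


def solve_dual(G, settings: SolverSettings | None = None, lam0=None):
    """Solve the dual problem for the tilting vector ``lam``.

    Minimizes the convex dual objective ``log sum_i exp(lam' g_i)`` by
    Newton's method with step-halving backtracking, so the objective never
    increases.  The default start ``lam = 0`` is the unconstrained entropy
    maximizer; ``lam0`` warm-starts from a nearby solution (samplers reuse
    the last accepted tilt) without affecting the optimum, which is unique.

    Returns ``(lam, iterations, converged)``.  Raises
    :class:`NonConvergenceError` when the tolerance is not met within the
    iteration budget or the iterate diverges (origin on the hull boundary),
    and :class:`SingularJacobianError` when the weighted moment covariance
    is rank deficient (``sum g_i g_i'`` not positive definite).
    """
    settings = settings or SolverSettings()
    G = _as_moment_matrix(G)
    n, m = G.shape
    if lam0 is None:
        lam = np.zeros(m)
        z = np.zeros(n)  # G @ lam
        f = np.log(n)  # logsumexp(z)
    else:
        lam = np.asarray(lam0, dtype=float).copy()
        z = G @ lam
        _, f = _softmax_lse(z)

    for it in range(settings.max_iter):
        w, _ = _softmax_lse(z)
        grad = w @ G
        resid = np.max(np.abs(grad))
        if resid <= settings.tol:
            return lam, it, True
        H = G.T @ (w[:, None] * G) - np.outer(grad, grad)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SingularJacobianError(
                "dual Hessian is singular: the moment outer-product matrix "
                "sum g_i g_i' is rank deficient",
                residual=resid,
                iterations=it,
            ) from exc
        if not np.all(np.isfinite(step)):
            raise SingularJacobianError(
                "dual Newton step is non-finite (ill-conditioned Hessian)",
                residual=resid,
                iterations=it,
            )
        # Backtracking: accept the first halved step that decreases f, or —
        # when f is flat to double precision near the optimum — a step that
        # still shrinks the gradient residual.
        t = 1.0
        accepted = False
        for _ in range(settings.max_halvings):
            lam_new = lam - t * step
            z_new = G @ lam_new
            _, f_new = _softmax_lse(z_new)
            if f_new < f:
                accepted = True
                break
            if f_new == f:
                w_new, _ = _softmax_lse(z_new)
                if np.max(np.abs(w_new @ G)) < resid:
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            raise NonConvergenceError(
                "dual line search stalled (origin likely on the hull "
                "boundary)",
                residual=resid,
                iterations=it,
            )
        lam, z, f = lam_new, z_new, f_new
        if np.max(np.abs(lam)) > _LAM_DIVERGED:
            raise NonConvergenceError(
                "dual iterate diverged: no interior solution",
                residual=resid,
                iterations=it,
            )

    w, _ = _softmax_lse(z)
    resid = np.max(np.abs(w @ G))
    if resid <= settings.tol:
        return lam, settings.max_iter, True
    raise NonConvergenceError(
        f"dual Newton did not converge in {settings.max_iter} iterations "
        f"(residual {resid:.3e})",
        residual=resid,
        iterations=settings.max_iter,
    )


def etel_weights(G, lam) -> np.ndarray:
    """Tilted probabilities ``p_i = exp(lam' g_i) / sum_j exp(lam' g_j)``.

    Computed through a log-sum-exp shift so any finite input is safe.
    """
    G = _as_moment_matrix(G)
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if not np.all(np.isfinite(lam)):
        raise ValidationError("tilting vector must be finite")
    return softmax(G @ lam)


def _scalar_interior(col: np.ndarray) -> bool:
    """Exact interior-of-hull test for m = 1.

    The origin is interior to the hull of scalars iff min < 0 < max, or all
    values are exactly zero (then the uniform weights already satisfy the
    constraint).
    """
    lo, hi = col.min(), col.max()
    if lo == 0.0 and hi == 0.0:
        return True
    return lo < 0.0 < hi


def etel_loglik(
    G,
    settings: SolverSettings | None = None,
    feasibility: str = "lp",
    lam0=None,
) -> ETELEvaluation:
    """Evaluate ``log L_n = sum_i log(n p_i)`` for a moment matrix.

    Parameters
    ----------
    feasibility:
        ``"lp"`` (default) runs the LP hull check before the dual solve;
        ``"dual"`` skips it and relies on divergence of the dual iteration
        to detect an empty or boundary feasible set, which is much faster
        inside samplers.  For m = 1 an exact sign test replaces the LP in
        both modes.

    Hull-boundary points (some maximizing weight exactly zero) have
    ``L_n = 0`` since ``log(n p_i) = -inf`` there, so both the infeasible
    and the boundary case return the ``-inf`` sentinel with
    ``feasible=False``.
    """
    settings = settings or SolverSettings()
    G = _as_moment_matrix(G)
    n, m = G.shape

    if m == 1:
        if not _scalar_interior(G[:, 0]):
            return ETELEvaluation(feasible=False, loglik=NEG_INF)
    elif feasibility == "lp":
        if not check_feasibility(G, settings):
            return ETELEvaluation(feasible=False, loglik=NEG_INF)
    elif feasibility != "dual":
        raise ValidationError("feasibility must be 'lp' or 'dual'")

    try:
        lam, iterations, converged = solve_dual(G, settings, lam0=lam0)
    except NonConvergenceError:
        if lam0 is not None:
            # a poor warm start is not evidence of infeasibility: retry cold
            return etel_loglik(G, settings, feasibility=feasibility)
        # Origin on the hull boundary (or outside it, in 'dual' mode): the
        # entropy problem has no interior solution and L_n = 0.
        return ETELEvaluation(feasible=False, loglik=NEG_INF)
    except SingularJacobianError:
        if feasibility == "dual" and m > 1:
            # Without the LP certificate a singular dual Hessian cannot be
            # told apart from a degenerate (infeasible) moment cloud, and
            # samplers must reject, not crash.
            return ETELEvaluation(feasible=False, loglik=NEG_INF)
        raise

    z = G @ lam
    p, lse = _softmax_lse(z)
    if p.min() < _BOUNDARY_WEIGHT_FACTOR * max(settings.tol, 1e-14):
        # The dual residual can vanish while some weight collapses to 0:
        # the origin sits on the hull boundary, the entropy problem has no
        # interior solution, and L_n = 0 (some n*p_i = 0).
        return ETELEvaluation(feasible=False, loglik=NEG_INF)
    loglik = n * np.log(n) + z.sum() - n * lse
    # The entropy bound guarantees loglik <= 0; clamp roundoff.
    loglik = min(loglik, 0.0)
    return ETELEvaluation(
        feasible=True,
        loglik=float(loglik),
        lam=lam,
        p=p,
        iterations=iterations,
        converged=converged,
    )
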