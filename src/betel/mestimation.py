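"""Just-identified M-estimation with sandwich covariance.

An M-estimator solves the sample estimating equation
``n^{-1} sum_i g(d_i, theta) = 0`` for a moment function whose dimension
matches the parameter.  Its asymptotic covariance is the sandwich

    Sigma = (G' Omega^{-1} G)^{-1},
    G     = n^{-1} sum_i d g / d theta,
    Omega = n^{-1} sum_i g g',

so the standard error of component k is ``sqrt(Sigma[k, k] / n)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import MEstimationError, ValidationError

__all__ = ["MomentModel", "MEstimate", "solve_m_estimator", "sandwich"]


@dataclass
class MomentModel:
    """A parameter space plus a vectorized estimating function.

    Parameters
    ----------
    dim:
        Parameter (and moment) dimension m.
    g:
        ``g(data, theta) -> (n, m)`` matrix of per-record moment
        evaluations.  ``data`` is whatever container the concrete model
        understands (typically a :class:`pandas.DataFrame`).
    dg:
        Optional analytic Jacobian ``dg(data, theta) -> (m, m)`` of the
        averaged moment ``n^{-1} sum_i g``.  When absent, central finite
        differences with step ``h_k = max(1e-6, 1e-6 |theta_k|)`` are used.
    theta_space:
        Optional box constraints ``(lower, upper)`` (arrays of length m,
        +-inf allowed).  Newton iterates are projected onto the box.
    default_init:
        Optional data-driven starting value ``default_init(data) -> theta``
        used as a second start when the user-supplied one fails.
    """

    dim: int
    g: Callable[..., np.ndarray]
    dg: Callable[..., np.ndarray] | None = None
    theta_space: tuple[np.ndarray, np.ndarray] | None = None
    default_init: Callable[..., np.ndarray] | None = None
    name: str = "moment model"

    def moments(self, data, theta) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.shape != (self.dim,):
            raise ValidationError(
                f"theta must have length {self.dim}, got {theta.shape}"
            )
        G = np.asarray(self.g(data, theta), dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        if G.shape[1] != self.dim:
            raise ValidationError(
                f"moment function returned {G.shape[1]} columns, "
                f"expected {self.dim}"
            )
        return G

    def mean_moment(self, data, theta) -> np.ndarray:
        return self.moments(data, theta).mean(axis=0)

    def jacobian(self, data, theta) -> np.ndarray:
        """Averaged m x m Jacobian of the moment in theta."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if self.dg is not None:
            J = np.asarray(self.dg(data, theta), dtype=float)
            return J.reshape(self.dim, self.dim)
        J = np.empty((self.dim, self.dim))
        for k in range(self.dim):
            h = max(1e-6, 1e-6 * abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            J[:, k] = (self.mean_moment(data, tp) - self.mean_moment(data, tm)) / (
                2.0 * h
            )
        return J

    def project(self, theta: np.ndarray) -> np.ndarray:
        if self.theta_space is None:
            return theta
        lo, hi = self.theta_space
        return np.clip(theta, lo, hi)


@dataclass
class MEstimate:
    """Solved estimating equation with its sandwich covariance.

    ``Sigma_hat`` estimates the asymptotic covariance of
    ``sqrt(n) (theta_hat - theta_0)``; divide by n for the finite-sample
    covariance of ``theta_hat``.
    """

    theta_hat: np.ndarray
    G_hat: np.ndarray
    Omega_hat: np.ndarray
    Sigma_hat: np.ndarray
    converged: bool
    residual: float
    n: int
    iterations: int = 0

    @property
    def se(self) -> np.ndarray:
        """Standard errors sqrt(diag(Sigma_hat) / n)."""
        return np.sqrt(np.diag(self.Sigma_hat) / self.n)

    @property
    def cov(self) -> np.ndarray:
        """Finite-sample covariance estimate Sigma_hat / n."""
        return self.Sigma_hat / self.n


def sandwich(model: MomentModel, data, theta_hat):
    """Sandwich pieces ``(G_hat, Omega_hat, Sigma_hat)`` at a root.

    ``Sigma_hat = (G' Omega^{-1} G)^{-1}`` is assembled with linear solves
    rather than an explicit inverse chain, then symmetrized.
    """
    theta_hat = np.atleast_1d(np.asarray(theta_hat, dtype=float))
    G = model.moments(data, theta_hat)
    n = G.shape[0]
    G_hat = model.jacobian(data, theta_hat)
    Omega_hat = (G.T @ G) / n
    try:
        X = np.linalg.solve(Omega_hat, G_hat)
        A = G_hat.T @ X
        Sigma_hat = np.linalg.solve(A, np.eye(model.dim))
    except np.linalg.LinAlgError as exc:
        raise MEstimationError(
            "singular sandwich component: the moment variance Omega or "
            "Jacobian G is not invertible"
        ) from exc
    Sigma_hat = 0.5 * (Sigma_hat + Sigma_hat.T)
    return G_hat, Omega_hat, Sigma_hat


def solve_m_estimator(
    model: MomentModel,
    data,
    theta_init,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> MEstimate:
    """Solve ``n^{-1} sum_i g(d_i, theta) = 0`` by damped Newton.

    Starts from ``theta_init``; on failure retries from the model's
    data-driven ``default_init`` when one is provided.  Iterates are
    projected onto the parameter box.  Non-convergence raises
    :class:`MEstimationError` carrying the last iterate and residual.
    """
    starts = [np.atleast_1d(np.asarray(theta_init, dtype=float)).copy()]
    if model.default_init is not None:
        starts.append(np.atleast_1d(np.asarray(model.default_init(data), float)))

    last_exc = None
    for start in starts:
        try:
            return _newton_solve(model, data, start, tol, max_iter)
        except MEstimationError as exc:
            last_exc = exc
    raise last_exc


def _newton_solve(model, data, theta, tol, max_iter):
    theta = model.project(theta)
    F = model.mean_moment(data, theta)
    norm = np.max(np.abs(F))
    n = model.moments(data, theta).shape[0]

    for it in range(max_iter):
        if norm <= tol:
            G_hat, Omega_hat, Sigma_hat = sandwich(model, data, theta)
            return MEstimate(
                theta_hat=theta,
                G_hat=G_hat,
                Omega_hat=Omega_hat,
                Sigma_hat=Sigma_hat,
                converged=True,
                residual=float(norm),
                n=n,
                iterations=it,
            )
        J = model.jacobian(data, theta)
        try:
            step = np.linalg.solve(J, F)
        except np.linalg.LinAlgError as exc:
            raise MEstimationError(
                "singular averaged Jacobian in the Newton solve",
                theta_last=theta,
                residual=float(norm),
            ) from exc
        t = 1.0
        for _ in range(40):
            cand = model.project(theta - t * step)
            Fc = model.mean_moment(data, cand)
            nc = np.max(np.abs(Fc))
            if np.isfinite(nc) and nc < norm:
                break
            t *= 0.5
        else:
            raise MEstimationError(
                "Newton damping stalled",
                theta_last=theta,
                residual=float(norm),
            )
        theta, F, norm = cand, Fc, nc

    if norm <= tol:
        G_hat, Omega_hat, Sigma_hat = sandwich(model, data, theta)
        return MEstimate(
            theta_hat=theta,
            G_hat=G_hat,
            Omega_hat=Omega_hat,
            Sigma_hat=Sigma_hat,
            converged=True,
            residual=float(norm),
            n=n,
            iterations=max_iter,
        )
    raise MEstimationError(
        f"estimating equation not solved in {max_iter} iterations "
        f"(residual {norm:.3e})",
        theta_last=theta,
        residual=float(norm),
    )
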