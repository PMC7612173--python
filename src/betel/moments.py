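"""Concrete estimating functions for unequal-probability sampling.

Design setting (known sampling probabilities): for a full-data estimating
function u(Z, theta), the observed-data moment is

    g(D, theta) = (R / pi) u(Z, theta),      R/(R pi) := 0 when R = 0,

which is unbiased for the population moment by conditional independence of
Z and R given the design variables.  With u = Y - theta this yields the
Hajek (ratio IPW) estimator.

Observational setting (unknown selection, ignorable given covariates W):
the target mean gamma is stacked with the nuisance working models into the
just-identified system

    g(D, theta) = ( U_alpha,  U_beta,  h ),      theta = (alpha, beta, gamma),

where U_alpha is the logistic-regression score for the propensity model
pi(W; alpha) = expit(a0 + a' W), U_beta the complete-case least-squares
score for the outcome model m(W; beta) = b0 + b' W, and

    h = R u(Z, gamma) / pi(W; alpha) - phi(W, gamma; beta) {R / pi(W; alpha) - 1}

with phi = m(W; beta) - gamma for mean estimation (the unique choice whose
averaged root reproduces the standard AIPW estimator).  The auxiliary
parameter block rho is empty in every shipped model; extending the stack
amounts to appending extra score columns between U_beta and h.

Intercepts are always the first coefficient: design vectors are (1, W) in
the stated covariate order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import MEstimationError, PositivityError, ValidationError
from .io import masked_outcome
from .mestimation import MomentModel

__all__ = [
    "design_moment",
    "design_mean_model",
    "hajek_mean",
    "weighted_linreg_moment",
    "logistic_score",
    "ols_score",
    "dr_moment",
    "aipw",
    "stacked_dr_model",
    "fit_logistic",
    "fit_wls",
    "sequential_dr_fit",
    "design_matrix",
]


# ----------------------------------------------------------------- design


def _design_arrays(df: pd.DataFrame, _cache={}):
    # single-entry cache: repeated evaluations on the same frame (samplers)
    # skip the pandas->numpy extraction; the frame itself is the key so a
    # recycled object id can never alias
    if _cache.get("df") is df:
        return _cache["val"]
    r, y = masked_outcome(df)
    pi = np.where(r == 1, df["pi"].to_numpy(float), 1.0)
    with np.errstate(divide="ignore"):
        w = np.where(r == 1, r / pi, 0.0)
    _cache["df"], _cache["val"] = df, (r, y, w)
    return r, y, w


def design_moment(u, dim: int, name: str = "design moment") -> MomentModel:
    """Lift a full-data estimating function u(Z-frame, theta) -> (n, m)
    into the observed-data design moment (R/pi) u, exactly zero when R=0."""

    def g(df, theta):
        r, _, w = _design_arrays(df)
        U = np.asarray(u(df, theta), dtype=float)
        if U.ndim == 1:
            U = U[:, None]
        # rows with R=0 are exactly zero even where u is NaN-masked
        return np.where(w[:, None] > 0.0, w[:, None] * U, 0.0)

    return MomentModel(dim=dim, g=g, name=name)


def design_mean_model() -> MomentModel:
    """Moment (R/pi)(Y - theta) whose root is the Hajek mean."""

    def g(df, theta):
        _, y, w = _design_arrays(df)
        return (w * (y - theta[0]))[:, None]

    def dg(df, theta):
        _, _, w = _design_arrays(df)
        return np.array([[-w.mean()]])

    return MomentModel(
        dim=1,
        g=g,
        dg=dg,
        default_init=lambda df: np.array([hajek_mean(df)]),
        name="design mean (Hajek)",
    )


def hajek_mean(df: pd.DataFrame) -> float:
    """Ratio IPW mean sum(R/pi * Y) / sum(R/pi); invariant to rescaling pi."""
    r, y, w = _design_arrays(df)
    total = w.sum()
    if total <= 0.0:
        raise MEstimationError("Hajek estimator undefined: no selected records")
    return float((w * y).sum() / total)


def weighted_linreg_moment(x_cols, y_col="Y", weight_col="weight") -> MomentModel:
    """Survey-weighted linear regression moment R*W*(Y - X'theta)*X.

    ``x_cols`` are the non-intercept covariates; the design vector is
    (1, X1, ..., Xk).  Weights need only be proportional to 1/pi — the root
    is invariant to rescaling them by any positive constant.
    """
    dim = len(x_cols) + 1

    def g(df, theta):
        r, y = masked_outcome(df)
        w = np.where(r == 1, df[weight_col].to_numpy(float), 0.0)
        X = design_matrix(df, x_cols)
        resid = y - X @ theta
        return (r * w * resid)[:, None] * X

    def default_init(df):
        sel = df["R"].to_numpy() == 1
        X = design_matrix(df.loc[sel], x_cols)
        y = df.loc[sel, "Y"].to_numpy(float)
        w = df.loc[sel, weight_col].to_numpy(float)
        return fit_wls(X, y, w)

    return MomentModel(
        dim=dim, g=g, default_init=default_init, name="weighted linear regression"
    )


# ----------------------------------------------------- observational stack


def design_matrix(df: pd.DataFrame, w_cols) -> np.ndarray:
    """Intercept-first design matrix (1, W) in the given column order."""
    n = len(df)
    return np.column_stack([np.ones(n), df[list(w_cols)].to_numpy(float)])


def logistic_score(X: np.ndarray, r: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-record logistic-regression score (R - expit(X alpha)) X."""
    return (r - expit(X @ alpha))[:, None] * X


def ols_score(
    X: np.ndarray, y: np.ndarray, r: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Complete-case least-squares score R (Y - X beta) X (zero when R=0)."""
    return (r * (y - X @ beta))[:, None] * X


def _propensity(X: np.ndarray, alpha: np.ndarray, r: np.ndarray) -> np.ndarray:
    e = expit(X @ alpha)
    if np.any(e[r == 1] <= 0.0):
        raise PositivityError(
            "fitted propensity is numerically zero for a selected record; "
            "positivity is violated"
        )
    return e


def dr_moment(
    r: np.ndarray,
    y: np.ndarray,
    X_ps: np.ndarray,
    X_or: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """Doubly robust moment h for the mean, one value per record:

    h = R (Y - gamma)/pi(W; alpha) - (m(W; beta) - gamma) {R/pi(W; alpha) - 1}
    """
    e = _propensity(X_ps, alpha, r)
    with np.errstate(divide="ignore", over="ignore"):
        inv = np.where(r == 1, 1.0 / e, 0.0)
    m = X_or @ beta
    return r * (y - gamma) * inv - (m - gamma) * (r * inv - 1.0)


def aipw(df: pd.DataFrame, ps_cols, or_cols, alpha, beta) -> float:
    """Standard doubly robust (AIPW) mean at supplied nuisance fits:

    n^{-1} sum_i [ R_i Y_i / pi_i - m_i (R_i / pi_i - 1) ].
    """
    r, y = masked_outcome(df)
    X_ps = design_matrix(df, ps_cols)
    X_or = design_matrix(df, or_cols)
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    e = _propensity(X_ps, alpha, r)
    inv = np.where(r == 1, 1.0 / e, 0.0)
    m = X_or @ beta
    return float(np.mean(r * y * inv - m * (r * inv - 1.0)))


def stacked_dr_model(ps_cols, or_cols) -> MomentModel:
    """Stacked doubly robust system g = (U_alpha, U_beta, h).

    Parameter layout: (alpha_0..alpha_p, beta_0..beta_q, gamma), intercepts
    first within each block; total dimension p + q + 3 for p propensity and
    q outcome covariates.  The system is block triangular, so its root is
    exactly the sequential fit (logistic MLE, complete-case least squares,
    then the AIPW functional).
    """
    ps_cols, or_cols = list(ps_cols), list(or_cols)
    p = len(ps_cols) + 1
    q = len(or_cols) + 1
    dim = p + q + 1

    cache = {}

    def arrays(df):
        if cache.get("df") is not df:
            r, y = masked_outcome(df)
            cache["df"] = df
            cache["val"] = (r, y, design_matrix(df, ps_cols), design_matrix(df, or_cols))
        return cache["val"]

    def g(df, theta):
        alpha, beta, gamma = theta[:p], theta[p : p + q], theta[-1]
        r, y, X_ps, X_or = arrays(df)
        h = dr_moment(r, y, X_ps, X_or, alpha, beta, gamma)
        return np.hstack(
            [
                logistic_score(X_ps, r, alpha),
                ols_score(X_or, y, r, beta),
                h[:, None],
            ]
        )

    def default_init(df):
        alpha, beta, gamma = sequential_dr_fit(df, ps_cols, or_cols)
        return np.concatenate([alpha, beta, [gamma]])

    return MomentModel(
        dim=dim,
        g=g,
        default_init=default_init,
        name="stacked doubly robust mean",
    )


# --------------------------------------------------------- nuisance fits


def fit_logistic(
    X: np.ndarray,
    r: np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-11,
    max_iter: int = 60,
) -> np.ndarray:
    """Weighted logistic regression by Newton iteration on the score.

    Solves sum_i w_i (r_i - expit(x_i' a)) x_i = 0 from a = 0 with
    step-halving on the weighted log-likelihood.
    """
    n, k = X.shape
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    alpha = np.zeros(k)

    def loglik(a):
        z = X @ a
        # log f = r*z - log(1 + e^z), stable via logaddexp
        return float(np.sum(w * (r * z - np.logaddexp(0.0, z))))

    ll = loglik(alpha)
    for _ in range(max_iter):
        e = expit(X @ alpha)
        score = X.T @ (w * (r - e))
        if np.max(np.abs(score)) <= tol:
            return alpha
        H = X.T @ ((w * e * (1.0 - e))[:, None] * X)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise MEstimationError("singular Hessian in logistic fit") from exc
        t = 1.0
        for _ in range(40):
            cand = alpha + t * step
            llc = loglik(cand)
            if llc >= ll:
                break
            t *= 0.5
        alpha, ll = cand, llc
    e = expit(X @ alpha)
    resid = np.max(np.abs(X.T @ (w * (r - e))))
    if resid > 1e-6:
        raise MEstimationError(
            f"logistic fit did not converge (score residual {resid:.2e})"
        )
    return alpha


def fit_wls(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
    """Weighted least squares via a scaled QR solve (lstsq)."""
    if weights is None:
        sw = np.ones(len(y))
    else:
        weights = np.asarray(weights, float)
        if np.any(weights < 0):
            raise ValidationError("weights must be nonnegative")
        sw = np.sqrt(weights)
    beta, _, rank, _ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
    if rank < X.shape[1]:
        raise MEstimationError("rank-deficient weighted design matrix")
    return beta


def sequential_dr_fit(
    df: pd.DataFrame, ps_cols, or_cols, weights: np.ndarray | None = None
):
    """Two-step nuisance fit followed by the AIPW functional.

    With Dirichlet ``weights`` this is one Bayesian-bootstrap draw; with
    uniform weights it is the frequentist doubly robust estimate
    (alpha_hat, beta_hat, mu_hat_DR).
    """
    r, y = masked_outcome(df)
    n = len(df)
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    X_ps = design_matrix(df, ps_cols)
    X_or = design_matrix(df, or_cols)
    alpha = fit_logistic(X_ps, r, w)
    sel = r == 1
    beta = fit_wls(X_or[sel], y[sel], w[sel])
    e = _propensity(X_ps, alpha, r)
    inv = np.where(sel, 1.0 / e, 0.0)
    m = X_or @ beta
    num = np.sum(w * (r * y * inv - m * (r * inv - 1.0)))
    gamma = float(num / w.sum())
    return alpha, beta, gamma
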