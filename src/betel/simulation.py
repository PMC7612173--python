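"""Synthetic-data generators and the Monte-Carlo replication harness.

Two study designs are emulated.

Design setting ("beta-design"): design variables W ~ Be(1.5, 3.5), binary
outcomes Y | W ~ Ber(W) (so the population mean is E(Y) = E(W) = 0.3),
selection R | W ~ Ber(pi) with logit(pi) = W.  Outcome and selection
probability are positively correlated, so unweighted estimates are biased
upward.  The analyst sees only (R, R*Y, R*pi): design variables are
dropped and Y, pi are masked (blank) when R = 0.

Observational setting ("Kang-Schafer"): covariates W ~ N(0, I4), selection
R | W ~ Ber(expit(alpha0' (1, W))) with alpha0 = (0, -1, 0.5, -0.25, -0.1)
(selection fraction 1/2 by symmetry), outcomes Y | W ~ N(m0(W), 1) with
m0(W) = 210 + 27.4 W1 + 13.7 (W2 + W3 + W4), so the target mean is 210.
The frame also carries the four nonlinear transforms

    Wp1 = exp(W1/2),            Wp2 = W2 / (1 + exp(W1)) + 10,
    Wp3 = (W1 W3 / 25 + 0.6)^3, Wp4 = (W2 + W4 + 20)^3,

used as covariates by a *misspecified* working model (fitting a linear or
logistic model in Wp when the truth is linear/logistic in W).

The harness replicates a scenario, runs a set of methods per replication
(seeded ``base_seed + r`` so any single replication is reproducible in
isolation) and aggregates bias, RMSE, MAE (median absolute error), ESD
(empirical sd of the point estimates, (reps-1) denominator) and the
coverage of central 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .comparators import bootstrap_variance, saarela_posterior, wang_posterior
from .estimators import BETELDesignMean, BETELDoublyRobustMean
from .exceptions import BetelError, ValidationError
from .mestimation import solve_m_estimator
from .moments import design_mean_model, hajek_mean, stacked_dr_model
from .posterior import summarize
from .priors import parse_prior

__all__ = [
    "gen_design_data",
    "gen_ks_data",
    "KS_ALPHA0",
    "KS_BETA0",
    "run_replications",
    "ReplicationReport",
    "hajek_method",
    "betel_design_method",
    "wang_method",
    "dr_method",
    "saarela_method",
    "betel_dr_method",
    "ks_columns",
    "ks_beta_prior_center",
    "render_table",
    "DESIGN_TRUTH",
    "KS_TRUTH",
]

DESIGN_TRUTH = 0.3
KS_TRUTH = 210.0
KS_ALPHA0 = np.array([0.0, -1.0, 0.5, -0.25, -0.1])
KS_BETA0 = np.array([210.0, 27.4, 13.7, 13.7, 13.7])

# Prior centers for the outcome-regression coefficient block, matched to
# the covariates the working model actually uses.
_BETA_PRIOR_CENTER_RAW = (210.0, 30.0, 10.0, 10.0, 10.0)
_BETA_PRIOR_CENTER_TRANSFORMED = (35.0, 50.0, 0.0, -135.0, 0.0)


# ------------------------------------------------------------- generators


def gen_design_data(n: int, seed=None, a: float = 1.5, b: float = 3.5) -> pd.DataFrame:
    """One beta-design dataset with masked unselected records."""
    if n < 2:
        raise ValidationError("need n >= 2")
    rng = np.random.default_rng(seed)
    w = rng.beta(a, b, size=n)
    y = (rng.uniform(size=n) < w).astype(float)
    pi = expit(w)
    r = (rng.uniform(size=n) < pi).astype(int)
    sel = r == 1
    return pd.DataFrame(
        {
            "R": r,
            "Y": np.where(sel, y, np.nan),
            "pi": np.where(sel, pi, np.nan),
        }
    )


def gen_ks_data(n: int, seed=None) -> pd.DataFrame:
    """One Kang-Schafer-style dataset, raw and transformed covariates."""
    if n < 2:
        raise ValidationError("need n >= 2")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, 4))
    pi0 = expit(KS_ALPHA0[0] + W @ KS_ALPHA0[1:])
    r = (rng.uniform(size=n) < pi0).astype(int)
    m0 = KS_BETA0[0] + W @ KS_BETA0[1:]
    y = m0 + rng.standard_normal(n)
    df = pd.DataFrame(W, columns=["W1", "W2", "W3", "W4"])
    df["Wp1"] = np.exp(W[:, 0] / 2.0)
    df["Wp2"] = W[:, 1] / (1.0 + np.exp(W[:, 0])) + 10.0
    df["Wp3"] = (W[:, 0] * W[:, 2] / 25.0 + 0.6) ** 3
    df["Wp4"] = (W[:, 1] + W[:, 3] + 20.0) ** 3
    df.insert(0, "R", r)
    df.insert(1, "Y", np.where(r == 1, y, np.nan))
    return df


def ks_columns(correct: bool) -> list[str]:
    """Covariate columns for a correctly / incorrectly specified model."""
    return ["W1", "W2", "W3", "W4"] if correct else ["Wp1", "Wp2", "Wp3", "Wp4"]


def ks_beta_prior_center(or_correct: bool) -> tuple[float, ...]:
    return _BETA_PRIOR_CENTER_RAW if or_correct else _BETA_PRIOR_CENTER_TRANSFORMED


# ---------------------------------------------------------------- methods
#
# A method is a callable (df, seed) -> (estimate, lower, upper).  Factories
# below close over configuration; Bayes methods report the posterior mean
# and the central credible interval.

_Z95 = float(stats.norm.ppf(0.975))


def hajek_method(level: float = 0.95):
    z = float(stats.norm.ppf(0.5 + level / 2.0))

    def run(df, seed):
        est = solve_m_estimator(design_mean_model(), df, np.array([hajek_mean(df)]))
        t, se = float(est.theta_hat[0]), float(est.se[0])
        return t, t - z * se, t + z * se

    return run


def betel_design_method(prior="uniform", n_particles: int = 5000, level: float = 0.95):
    def run(df, seed):
        fit = BETELDesignMean(
            prior=prior, n_particles=n_particles, level=level, random_state=seed
        ).fit(df)
        return (fit.posterior_mean_, *fit.credible_interval_)

    return run


def wang_method(
    prior="uniform",
    B: int = 1000,
    n_particles: int = 5000,
    level: float = 0.95,
):
    """Normal-approximation posterior around the Hajek estimator."""
    prior_obj = parse_prior(prior)

    def run(df, seed):
        theta_hat = hajek_mean(df)
        V_hat = bootstrap_variance(hajek_mean, df, B=B, seed=seed)
        post = wang_posterior(
            theta_hat, V_hat, prior_obj, n_particles=n_particles, seed=seed
        )
        s = summarize(post, level=level)
        return float(s["mean"][0]), float(s["lower"][0]), float(s["upper"][0])

    return run


def dr_method(ps_correct: bool = True, or_correct: bool = True, level: float = 0.95):
    """Frequentist AIPW with stacked-sandwich Wald interval."""
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    ps_cols, or_cols = ks_columns(ps_correct), ks_columns(or_correct)

    def run(df, seed):
        model = stacked_dr_model(ps_cols, or_cols)
        est = solve_m_estimator(model, df, model.default_init(df))
        mu, se = float(est.theta_hat[-1]), float(est.se[-1])
        return mu, mu - z * se, mu + z * se

    return run


def saarela_method(
    ps_correct: bool = True,
    or_correct: bool = True,
    n_draws: int = 2000,
    level: float = 0.95,
):
    ps_cols, or_cols = ks_columns(ps_correct), ks_columns(or_correct)

    def run(df, seed):
        bb = saarela_posterior(df, ps_cols, or_cols, n_draws=n_draws, seed=seed)
        s = summarize(bb.mu_posterior(), level=level)
        return float(s["mean"][0]), float(s["lower"][0]), float(s["upper"][0])

    return run


def betel_dr_method(
    ps_correct: bool = True,
    or_correct: bool = True,
    prior_mu: str = "t:210,1,3",
    n_iter: int = 2000,
    burn_in: int = 500,
    level: float = 0.95,
):
    """BETEL over the stacked system with the study's weakly informative
    t priors on the working models and a user prior on the mean."""
    ps_cols, or_cols = ks_columns(ps_correct), ks_columns(or_correct)
    beta_center = ks_beta_prior_center(or_correct)
    prior_alpha = ["t:0,1,3"] * 5
    prior_beta = [f"t:{c},1,3" for c in beta_center]

    def run(df, seed):
        fit = BETELDoublyRobustMean(
            ps_cols=ps_cols,
            or_cols=or_cols,
            prior_alpha=prior_alpha,
            prior_beta=prior_beta,
            prior_mu=prior_mu,
            n_iter=n_iter,
            burn_in=burn_in,
            level=level,
            random_state=seed,
        ).fit(df)
        return (fit.mu_posterior_mean_, *fit.mu_credible_interval_)

    return run


# ---------------------------------------------------------------- harness


@dataclass
class ReplicationReport:
    """Aggregated Monte-Carlo metrics, one row per method."""

    table: pd.DataFrame
    truth: float
    reps: int
    n: int
    base_seed: int
    estimates: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def scaled(self, factor: float = 100.0) -> pd.DataFrame:
        """Bias/RMSE/MAE/ESD scaled (e.g. x100); coverage left in %."""
        out = self.table.copy()
        for col in ("bias", "rmse", "mae", "esd"):
            out[col] = out[col] * factor
        return out


def run_replications(
    generate,
    methods: dict,
    truth: float,
    reps: int,
    n: int,
    base_seed: int = 0,
    level: float = 0.95,
) -> ReplicationReport:
    """Replicate a scenario and aggregate the error metrics.

    ``generate(n, seed)`` produces one dataset; each method in ``methods``
    maps ``(df, seed)`` to ``(estimate, lower, upper)``.  Replication r
    uses seed ``base_seed + r`` for both data and methods.  Per-method
    failures are caught and counted; a method failing on more than 2% of
    replications is flagged in the report.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    names = list(methods)
    est = {name: np.full(reps, np.nan) for name in names}
    cover = {name: np.full(reps, np.nan) for name in names}
    fails = {name: 0 for name in names}

    for r in range(reps):
        seed = base_seed + r
        df = generate(n, seed)
        for name in names:
            try:
                e, lo, hi = methods[name](df, seed)
            except BetelError:
                fails[name] += 1
                continue
            est[name][r] = e
            cover[name][r] = float(lo <= truth <= hi)

    rows = []
    for name in names:
        ok = np.isfinite(est[name])
        e = est[name][ok]
        if e.size == 0:
            raise BetelError(f"method '{name}' failed on every replication")
        err = e - truth
        esd = float(np.std(e, ddof=1)) if e.size > 1 else np.nan
        fail_frac = fails[name] / reps
        rows.append(
            {
                "method": name,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "mae": float(np.median(np.abs(err))),
                "esd": esd,
                "coverage": float(np.nanmean(cover[name][ok])),
                "reps_ok": int(e.size),
                "fail_frac": fail_frac,
                "flagged": fail_frac > 0.02,
            }
        )
    table = pd.DataFrame(rows).set_index("method")
    return ReplicationReport(
        table=table,
        truth=truth,
        reps=reps,
        n=n,
        base_seed=base_seed,
        estimates=est,
        failures=fails,
    )


def render_table(report: ReplicationReport, scale: float = 1.0) -> str:
    """Plain-text table in the usual simulation-study layout."""
    t = report.scaled(scale) if scale != 1.0 else report.table.copy()
    lines = [
        f"n = {report.n}, reps = {report.reps}, truth = {report.truth}"
        + (f", metrics x{scale:g}" if scale != 1.0 else ""),
        f"{'Method':<18}{'Bias':>10}{'RMSE':>10}{'MAE':>10}{'ESD':>10}{'CR(%)':>8}",
    ]
    for name, row in t.iterrows():
        flag = "  [>2% failures]" if row["flagged"] else ""
        lines.append(
            f"{name:<18}{row['bias']:>10.2f}{row['rmse']:>10.2f}"
            f"{row['mae']:>10.2f}{row['esd']:>10.2f}"
            f"{100 * row['coverage']:>8.1f}{flag}"
        )
    return "\n".join(lines)
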