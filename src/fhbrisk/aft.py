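"""Weibull accelerated failure time regression on f-Hb pseudo-time.

Model: for pseudo-time T (f-Hb + offset), ``log T = b0 + X b + sigma * W``
with W standard Gumbel-minimum, i.e. T is Weibull with shape k = 1/sigma
and scale lambda = exp(b0 + X b).  The exponentiated coefficient of a
disease-status level is its time ratio (TR): the multiplicative shift of
the whole f-Hb distribution versus the normal colon reference.  Disease
groups bleed more, so their TRs exceed 1 — on the hazard scale the same
coefficients enter with opposite sign, which is why f-Hb-as-time models
are sometimes described through negated coefficients.

The likelihood is maximized by damped Newton iterations with analytic
gradient and Hessian in (b, log sigma).  Repeated screens of one subject
are accommodated by a cluster-robust (sandwich) variance grouped by
subject; point estimates are unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import AGE_BANDS, BRANDS, SEXES, STATUSES

#: reference levels come first; remaining levels get one indicator each
FACTOR_LEVELS: dict[str, tuple] = {
    "status": STATUSES,
    "sex": SEXES,
    "age_band": AGE_BANDS,
    "family_history": ("no", "yes"),
    "fit_brand": BRANDS,
}

DEFAULT_COVARIATES = ["sex", "age_band", "family_history", "fit_brand"]

#: modal covariate cell; "adjusted" percentiles are evaluated here by default
DEFAULT_REFERENCE_PROFILE = {
    "sex": "female",
    "age_band": "50-54",
    "family_history": False,
    "fit_brand": "OC-Sensor",
}


def _factor_values(frame: pd.DataFrame, col: str) -> np.ndarray:
    vals = frame[col].to_numpy()
    if col == "family_history":
        vals = np.where(vals.astype(bool), "yes", "no")
    return vals


def _design(frame: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix with fixed level order; first column intercept."""
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    for col in ["status", *covariates]:
        levels = FACTOR_LEVELS[col]
        vals = _factor_values(frame, col)
        present = set(np.unique(vals))
        unknown = present - set(levels)
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} in column {col!r}")
        for level in levels[1:]:
            if level in present:  # absent levels would make the design singular
                cols.append((vals == level).astype(float))
                names.append(f"{col}:{level}")
    return np.column_stack(cols), names


@dataclass
class WeibullAftFit:
    """Fitted Weibull AFT model on the pseudo-time scale.

    ``params`` holds the log-scale coefficients (intercept first, order as
    ``param_names``); the last free parameter, log sigma, is kept separate.
    Both the model-based and the cluster-robust covariance cover the full
    parameter vector (coefficients then log sigma).
    """

    params: np.ndarray
    param_names: list[str]
    sigma: float
    covariance: np.ndarray
    covariance_robust: np.ndarray | None
    loglik: float
    n_rows: int
    n_clusters: int
    cluster_robust: bool
    converged: bool
    grad_norm: float
    offset: float

    @property
    def shape(self) -> float:
        """Weibull shape k = 1 / sigma."""
        return 1.0 / self.sigma

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.params))

    def coef(self, name: str) -> float:
        return self.coefficients[name]

    def se(self, name: str, robust: bool | None = None) -> float:
        robust = self.cluster_robust if robust is None else robust
        cov = self.covariance_robust if robust else self.covariance
        i = self.param_names.index(name)
        return float(np.sqrt(cov[i, i]))

    def linear_predictor(self, profile: dict, status: str = "normal") -> float:
        """log Weibull scale at a covariate profile and disease status."""
        lp = self.coef("intercept")
        if status not in FACTOR_LEVELS["status"]:
            raise ValueError(f"unknown status {status!r}")
        if status != "normal":
            lp += self.coef(f"status:{status}")
        for col, value in profile.items():
            if col == "family_history":
                value = "yes" if value in (True, "yes") else "no"
            levels = FACTOR_LEVELS.get(col)
            if levels is None or value not in levels:
                raise ValueError(f"unknown covariate level {col}={value!r}")
            if value != levels[0]:
                name = f"{col}:{value}"
                if name not in self.param_names:
                    raise ValueError(f"covariate level {name!r} not in fitted model")
                lp += self.coef(name)
        return float(lp)


def _neg_loglik_parts(theta, X, log_t, delta, with_hessian: bool = True):
    """Log-likelihood, gradient and Hessian of the Weibull AFT in (beta, log sigma)."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    z = (log_t - X @ beta) / sigma
    if np.max(z) > 690.0:  # exp overflow: signal the line search to back off
        return -np.inf, None, None
    ez = np.exp(z)
    ll = float(np.sum(delta * (-log_sigma - log_t + z) - ez))
    score_rows = np.empty((X.shape[0], X.shape[1] + 1))
    score_rows[:, :-1] = X * ((ez - delta) / sigma)[:, None]
    score_rows[:, -1] = -delta + z * (ez - delta)
    grad = score_rows.sum(axis=0)
    if not with_hessian:
        return ll, grad, None
    H = np.empty((X.shape[1] + 1, X.shape[1] + 1))
    H[:-1, :-1] = -(X * (ez / sigma**2)[:, None]).T @ X
    cross = -(X * ((z * ez + ez - delta) / sigma)[:, None]).sum(axis=0)
    H[:-1, -1] = cross
    H[-1, :-1] = cross
    H[-1, -1] = float(np.sum(-z * ez * (1.0 + z) + z * delta))
    return ll, grad, (H, score_rows)


def fit_weibull_aft(
    frame: pd.DataFrame,
    covariates=None,
    cluster_robust: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> WeibullAftFit:
    """Maximum-likelihood Weibull AFT fit of pseudo-time on status + covariates.

    Censored rows (unimputed interval cancers) contribute the survival
    probability; events contribute the density.  Deterministic
    initialization: intercept at the log median pseudo-time, all other
    coefficients 0, sigma 1; damped Newton until the gradient max-norm
    falls below ``tol``.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else list(covariates)
    t = frame["pseudo_time"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("all pseudo-times must be strictly positive")
    delta = frame["event"].to_numpy(dtype=float)
    for status in np.unique(frame["status"]):
        sub = delta[frame["status"].to_numpy() == status]
        if sub.sum() < 1:
            raise ValueError(f"status {status!r} has no events; cannot fit")
        grp_t = t[frame["status"].to_numpy() == status]
        if len(grp_t) > 1 and np.ptp(grp_t) == 0:
            warnings.warn(
                f"status {status!r} has all-identical pseudo-times (separation)",
                stacklevel=2,
            )
    X, names = _design(frame, covariates)
    log_t = np.log(t)

    theta = np.zeros(X.shape[1] + 1)
    theta[0] = np.log(np.median(t))

    def _negll_and_grad(th):
        ll, grad, _parts = _neg_loglik_parts(th, X, log_t, delta, with_hessian=False)
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(th)
        return -ll, -grad

    res = optimize.minimize(
        _negll_and_grad,
        theta,
        jac=True,
        method="BFGS",
        options={"gtol": 1e-9, "maxiter": 500},
    )
    theta = res.x
    ll, grad, hess_parts = _neg_loglik_parts(theta, X, log_t, delta)
    # Newton polish: quadratic convergence down to the tight gradient tolerance
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        H = hess_parts[0]
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            break
        if np.dot(step, grad) <= 0:  # not an ascent direction
            break
        alpha, accepted = 1.0, False
        for _ in range(60):
            cand = theta + alpha * step
            ll_new, grad_new, hess_new = _neg_loglik_parts(cand, X, log_t, delta)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                theta, ll, grad, hess_parts = cand, ll_new, grad_new, hess_new
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
    grad_norm = float(np.max(np.abs(grad)))
    if not converged and grad_norm > 1e-4:
        raise RuntimeError(
            f"Weibull AFT did not converge: gradient max-norm {grad_norm:.3e}"
        )

    H, score_rows = hess_parts
    A = -H
    covariance = np.linalg.inv(A)
    covariance = (covariance + covariance.T) / 2.0
    covariance_robust = None
    if cluster_robust:
        cluster = frame["cluster_id"].to_numpy()
        g = pd.DataFrame(score_rows).groupby(cluster).sum().to_numpy()
        B = g.T @ g
        covariance_robust = covariance @ B @ covariance
        covariance_robust = (covariance_robust + covariance_robust.T) / 2.0

    return WeibullAftFit(
        params=theta[:-1],
        param_names=names,
        sigma=float(np.exp(theta[-1])),
        covariance=covariance,
        covariance_robust=covariance_robust,
        loglik=ll,
        n_rows=len(frame),
        n_clusters=int(pd.unique(frame["cluster_id"]).size),
        cluster_robust=cluster_robust,
        converged=converged,
        grad_norm=grad_norm,
        offset=float(frame.attrs.get("offset", 0.5)),
    )


def time_ratios(
    fit: WeibullAftFit, level: float = 0.95, robust: bool | None = None
) -> pd.DataFrame:
    """Time ratios exp(beta) with Wald confidence intervals on the log scale."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    rows = []
    for name in fit.param_names:
        if name == "intercept":
            continue
        beta = fit.coef(name)
        se = fit.se(name, robust=robust)
        rows.append(
            {
                "term": name,
                "tr": np.exp(beta),
                "ci_low": np.exp(beta - z * se),
                "ci_high": np.exp(beta + z * se),
                "se_log": se,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def aft_percentiles(
    fit: WeibullAftFit,
    status: str,
    p_grid,
    reference_profile: dict | None = None,
    subtract_offset: bool = True,
) -> pd.DataFrame:
    """Covariate-adjusted parametric percentile-table rows for one disease group.

    q_p = exp(b0 + x_ref b + b_status) * (-ln(1-p))^sigma, minus the
    pseudo-time offset (floored at 0) so values are on the raw μg/g scale.
    """
    profile = DEFAULT_REFERENCE_PROFILE if reference_profile is None else reference_profile
    p_grid = list(p_grid)
    if any(not 0.0 < p < 1.0 for p in p_grid):
        raise ValueError("all percentile levels must lie strictly in (0, 1)")
    lam = np.exp(fit.linear_predictor(profile, status=status))
    q = lam * (-np.log1p(-np.asarray(p_grid, dtype=float))) ** fit.sigma
    if subtract_offset:
        q = np.maximum(q - fit.offset, 0.0)
    return pd.DataFrame(
        {"method": "parametric", "status": status, "p": p_grid, "fhb_ug_per_g": q}
    )


def calibrate_weibull_from_two_percentiles(
    p1: float, q1: float, p2: float, q2: float
) -> tuple[float, float]:
    """Unique Weibull (shape k, scale lam) whose quantile function passes
    through (p1, q1) and (p2, q2).

    Inverts q_p = lam * (-ln(1-p))^(1/k) given two quantile points; used
    for internal-consistency checks of published percentile tables.
    """
    if not 0.0 < p1 < p2 < 1.0:
        raise ValueError("need 0 < p1 < p2 < 1")
    if not 0.0 < q1 < q2:
        raise ValueError("need 0 < q1 < q2")
    a1 = -np.log1p(-p1)
    a2 = -np.log1p(-p2)
    inv_k = np.log(q2 / q1) / np.log(a2 / a1)
    k = 1.0 / inv_k
    lam = q1 / a1**inv_k
    return float(k), float(lam)


def weibull_quantile(p, shape: float, scale: float):
    """Closed-form Weibull quantile q_p = scale * (-ln(1-p))^(1/shape)."""
    return scale * (-np.log1p(-np.asarray(p, dtype=float))) ** (1.0 / shape)
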