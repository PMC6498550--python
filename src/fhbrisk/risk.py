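"""Bayesian inversion: disease risk by f-Hb percentile or value.

Two ingredients are combined by Bayes' theorem:

* a **prior**: baseline probability of developing each colorectal
  neoplasm over a risk horizon, obtained by integrating Poisson-regression
  incidence rates (fitted on incident cases only, excluding neoplasia
  present at the first screen) — ``pi_d = 1 - exp(-rate_d * horizon)``;
* a **likelihood**: the percentile-conditional f-Hb distribution of each
  disease group, read off the fitted Weibull AFT model at a covariate
  reference profile, optionally zero-inflated for the normal group.

The posterior for disease d at f-Hb value x is, against the normal group,

    P(d | x) = pi_d f_d(x) / (pi_d f_d(x) + pi_normal f_normal(x)),

or normalized over all statuses in multiclass mode.  Percentile-indexed
risk tables resolve each disease group's row percentile to that group's
own f-Hb percentile value before evaluation, so the rows of different
groups refer to different f-Hb values and need not sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .aft import DEFAULT_REFERENCE_PROFILE, WeibullAftFit, aft_percentiles, _design
from .cohort import STATUSES

DISEASE_STATUSES = ("nada", "ada", "crc")


@dataclass
class BaselinePrior:
    """Horizon-integrated baseline probabilities of each colorectal neoplasm.

    ``rates`` are incidence rates per person-year; ``pi`` holds the prior
    probability of developing each neoplasm over ``horizon_years``, with
    the normal group receiving the complement so the prior is a proper
    distribution over all four statuses.
    """

    rates: dict[str, float]
    horizon_years: float
    pi: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        for d in DISEASE_STATUSES:
            if d not in self.rates or self.rates[d] < 0:
                raise ValueError(f"rates[{d!r}] must be a nonnegative incidence rate")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        pi = {
            d: 1.0 - np.exp(-self.rates[d] * self.horizon_years)
            for d in DISEASE_STATUSES
        }
        pi["normal"] = 1.0 - sum(pi.values())
        if pi["normal"] < 0:
            raise ValueError("prior probabilities exceed 1; shorten the horizon")
        assert abs(sum(pi.values()) - 1.0) < 1e-12
        self.pi = pi


def fit_baseline_incidence(
    records: pd.DataFrame,
    horizon_years: float = 30.0,
    covariates=("sex", "age_band"),
    reference_profile: dict | None = None,
) -> BaselinePrior:
    """Poisson incidence rates from incident cases only, integrated to a prior.

    Subjects with colorectal neoplasia at the first screen are excluded.
    Each remaining subject contributes person-years until first disease
    onset (or end of follow-up) and at most one incident event per
    status.  With covariates, a Poisson log-linear model with log
    person-years offset is fitted per status and the rate evaluated at
    the reference profile; with ``covariates=()`` the closed-form
    marginal rate events / person-years is used.
    """
    profile = DEFAULT_REFERENCE_PROFILE if reference_profile is None else reference_profile
    first = records.loc[records["round_index"] == 1]
    baseline_free = set(first.loc[first["status"] == "normal", "subject_id"])
    sub = records.loc[records["subject_id"].isin(baseline_free)].sort_values(
        ["subject_id", "round_index"], kind="mergesort"
    )

    # per subject: exposure until first disease onset; the first diseased
    # round (any detection mode, or none) is the incident event
    sub = sub.assign(
        _cpy=sub.groupby("subject_id")["person_years"].cumsum(),
        _diseased=(sub["status"] != "normal"),
    )
    covs = ["sex", "age_band", "family_history", "fit_brand"]
    first_row = sub.groupby("subject_id", sort=True).first()
    last_cpy = sub.groupby("subject_id", sort=True)["_cpy"].last()
    onset = (
        sub.loc[sub["_diseased"]]
        .groupby("subject_id", sort=True)
        .first()[["status", "_cpy"]]
    )
    per_subject = first_row[covs].copy()
    per_subject["event_status"] = onset["status"].reindex(per_subject.index).fillna("none")
    per_subject["person_years"] = (
        onset["_cpy"].reindex(per_subject.index).fillna(last_cpy)
    )
    per_subject = per_subject.reset_index()
    per_subject = per_subject.loc[per_subject["person_years"] > 0]
    total_py = per_subject["person_years"].sum()
    if total_py <= 0:
        raise ValueError("zero total person-years of exposure")

    rates: dict[str, float] = {}
    for d in DISEASE_STATUSES:
        events = (per_subject["event_status"] == d).to_numpy(dtype=float)
        if not covariates or events.sum() == 0:
            rates[d] = float(events.sum() / total_py)
            continue
        frame = per_subject.assign(status="normal")  # design helper expects a status col
        X, names = _design(frame, list(covariates))
        keep = [i for i, n in enumerate(names) if not n.startswith("status:")]
        X = X[:, keep]
        names = [names[i] for i in keep]
        model = sm.GLM(
            events,
            X,
            family=sm.families.Poisson(),
            offset=np.log(per_subject["person_years"].to_numpy(dtype=float)),
        )
        res = model.fit()
        lp = res.params[names.index("intercept")]
        for col in covariates:
            value = profile.get(col)
            if col == "family_history":
                value = "yes" if value in (True, "yes") else "no"
            name = f"{col}:{value}"
            if name in names:
                lp += res.params[names.index(name)]
        rates[d] = float(np.exp(lp))
    return BaselinePrior(rates=rates, horizon_years=horizon_years)


def likelihood_at(
    fit: WeibullAftFit,
    status: str,
    x,
    reference_profile: dict | None = None,
    zero_mass_normal: float | None = None,
    bin_edges=None,
):
    """f-Hb likelihood f(x | status) from the fitted Weibull AFT.

    The density of pseudo-time ``x + offset`` under the status-specific
    Weibull scale at the reference profile.  When ``zero_mass_normal`` is
    given, the normal group is a mixture: a point mass at x == 0 and the
    continuous density (scaled by the complement) for x > 0; point-mass
    and density values then live on different measures and are only
    meaningfully compared at x > 0 versus x == 0 separately.

    ``bin_edges`` (increasing f-Hb values) switches to a binned
    likelihood: the Weibull probability mass of the bin containing x,
    a sensitivity mode approximating inversion on a percentile grid
    rather than a continuous density.

    Pseudo-time is at least the offset by construction (f-Hb >= 0), so
    both forms are normalized over the observable region: they divide by
    the Weibull survival at the offset and integrate (sum) to 1 over
    x in (0, inf).
    """
    profile = DEFAULT_REFERENCE_PROFILE if reference_profile is None else reference_profile
    xs = np.asarray(x, dtype=float)
    if np.any(xs < 0):
        raise ValueError("f-Hb must be nonnegative")
    lam = np.exp(fit.linear_predictor(profile, status=status))
    norm = stats.weibull_min.sf(fit.offset, c=fit.shape, scale=lam)
    if bin_edges is not None:
        edges = np.asarray(bin_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing with >= 2 values")
        lo_edges = np.concatenate([[0.0], edges])
        hi_edges = np.concatenate([edges, [np.inf]])
        idx = np.searchsorted(edges, xs, side="right")
        cdf = stats.weibull_min.cdf
        mass = (
            cdf(hi_edges[idx] + fit.offset, c=fit.shape, scale=lam)
            - cdf(lo_edges[idx] + fit.offset, c=fit.shape, scale=lam)
        ) / norm
        return float(mass) if np.isscalar(x) else mass
    dens = stats.weibull_min.pdf(xs + fit.offset, c=fit.shape, scale=lam) / norm
    if zero_mass_normal is not None and status == "normal":
        p0 = float(zero_mass_normal)
        dens = np.where(xs == 0.0, p0, (1.0 - p0) * dens)
    out = dens
    return float(out) if np.isscalar(x) else out


@dataclass
class RiskTable:
    """Posterior disease risk indexed by percentile or by f-Hb value.

    ``df`` has columns (status, p or fhb, risk); ``mode`` is
    ``by_percentile`` or ``by_value``; ``comparison`` is
    ``binary_vs_normal`` or ``multiclass``.
    """

    df: pd.DataFrame
    mode: str
    comparison: str

    def __post_init__(self) -> None:
        risks = self.df["risk"].to_numpy(dtype=float)
        if np.any(risks < -1e-12) or np.any(risks > 1 + 1e-12):
            raise ValueError("risks must lie in [0, 1]")

    def risk(self, status: str, at: float) -> float:
        key = "p" if self.mode == "by_percentile" else "fhb"
        sel = self.df.loc[
            (self.df["status"] == status) & np.isclose(self.df[key], at)
        ]
        if len(sel) == 0:
            raise KeyError(f"no entry for status={status!r}, {key}={at!r}")
        return float(sel["risk"].iloc[0])

    def fold_change(self, status: str, at_from: float, at_to: float) -> float:
        """Ratio of the risk at ``at_to`` over the risk at ``at_from``."""
        return fold_change(self.risk(status, at_from), self.risk(status, at_to))


def fold_change(risk_from: float, risk_to: float) -> float:
    """Multiplicative risk increase between two table entries."""
    if risk_from <= 0:
        raise ValueError("risk_from must be positive to form a fold change")
    return risk_to / risk_from


def posterior_risk(
    prior: BaselinePrior,
    fit: WeibullAftFit,
    status: str,
    x: float | None = None,
    p: float | None = None,
    comparison: str = "binary_vs_normal",
    reference_profile: dict | None = None,
    zero_mass_normal: float | None = None,
) -> float:
    """Posterior probability of one disease status at an f-Hb value.

    Give either ``x`` (μg/g) directly or a percentile ``p``, which is
    resolved through the status's own adjusted percentile value.
    """
    if status not in DISEASE_STATUSES:
        raise ValueError(f"status must be one of {DISEASE_STATUSES}")
    if (x is None) == (p is None):
        raise ValueError("give exactly one of x or p")
    if x is None:
        x = float(
            aft_percentiles(fit, status, [p], reference_profile=reference_profile)[
                "fhb_ug_per_g"
            ].iloc[0]
        )
    lik = {
        s: likelihood_at(
            fit, s, x, reference_profile=reference_profile,
            zero_mass_normal=zero_mass_normal,
        )
        for s in STATUSES
    }
    if comparison == "binary_vs_normal":
        num = prior.pi[status] * lik[status]
        den = num + prior.pi["normal"] * lik["normal"]
    elif comparison == "multiclass":
        num = prior.pi[status] * lik[status]
        den = sum(prior.pi[s] * lik[s] for s in STATUSES)
    else:
        raise ValueError("comparison must be 'binary_vs_normal' or 'multiclass'")
    if den == 0:
        raise ValueError(f"all likelihoods vanish at x={x}; posterior undefined")
    return float(num / den)


def risk_table(
    prior: BaselinePrior,
    fit: WeibullAftFit,
    p_grid=None,
    x_grid=None,
    comparison: str = "binary_vs_normal",
    reference_profile: dict | None = None,
    zero_mass_normal: float | None = None,
) -> RiskTable:
    """Posterior risk table over a percentile grid or an f-Hb value grid.

    ``p_grid`` builds the percentile-indexed table (each disease group's
    percentile resolved to its own f-Hb value); ``x_grid`` builds the
    value-indexed table, where in multiclass mode the risks over all
    statuses (normal included) sum to one at each value.
    """
    if (p_grid is None) == (x_grid is None):
        raise ValueError("give exactly one of p_grid or x_grid")
    rows = []
    if p_grid is not None:
        for status in DISEASE_STATUSES:
            for p in p_grid:
                rows.append(
                    {
                        "status": status,
                        "p": float(p),
                        "risk": posterior_risk(
                            prior, fit, status, p=float(p), comparison=comparison,
                            reference_profile=reference_profile,
                            zero_mass_normal=zero_mass_normal,
                        ),
                    }
                )
        return RiskTable(pd.DataFrame(rows), mode="by_percentile", comparison=comparison)
    for x in x_grid:
        for status in DISEASE_STATUSES:
            rows.append(
                {
                    "status": status,
                    "fhb": float(x),
                    "risk": posterior_risk(
                        prior, fit, status, x=float(x), comparison=comparison,
                        reference_profile=reference_profile,
                        zero_mass_normal=zero_mass_normal,
                    ),
                }
            )
        if comparison == "multiclass":
            lik_norm = likelihood_at(
                fit, "normal", float(x), reference_profile=reference_profile,
                zero_mass_normal=zero_mass_normal,
            )
            num = prior.pi["normal"] * lik_norm
            den = num + sum(
                prior.pi[s]
                * likelihood_at(
                    fit, s, float(x), reference_profile=reference_profile,
                    zero_mass_normal=zero_mass_normal,
                )
                for s in DISEASE_STATUSES
            )
            rows.append({"status": "normal", "fhb": float(x), "risk": num / den})
    return RiskTable(pd.DataFrame(rows), mode="by_value", comparison=comparison)
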