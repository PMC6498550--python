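"""f-Hb as survival time: pseudo-time frames and Kaplan-Meier percentile curves.

The ranked f-Hb value plays the role of a survival time.  Because many
subjects have undetectable hemoglobin (f-Hb exactly 0) and a survival time
must be positive, a small offset (default 0.5 μg/g) is added to every
observation; all reported percentiles subtract it back, so outputs stay on
the raw μg/g scale.

Interval cancers carry no f-Hb measurement.  The primary analysis imputes
them beforehand (see :mod:`fhbrisk.imputation`); as a sensitivity option
they can instead enter as right-censored at the subject's last observed
f-Hb (their true value at diagnosis is only known to exceed what was last
measured), or be dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

DEFAULT_OFFSET = 0.5

_COVARIATE_COLS = ["age_band", "sex", "family_history", "fit_brand"]


def make_pseudo_time(
    records: pd.DataFrame,
    offset: float = DEFAULT_OFFSET,
    missing: str = "error",
) -> pd.DataFrame:
    """Build the analysis frame with ``pseudo_time = fhb_std + offset``.

    Parameters
    ----------
    records
        Long-format screening records; every screen round of a subject
        becomes one row, sharing ``cluster_id``.
    offset
        Positive shift applied to every f-Hb value so zeros become valid
        survival times.
    missing
        Handling of rows with absent f-Hb (unimputed interval cancers):
        ``"error"`` (default) refuses them, ``"censor"`` right-censors at
        the subject's last observed f-Hb, ``"drop"`` excludes them.

    Returns
    -------
    DataFrame with columns ``pseudo_time``, ``event``, ``status``, the
    covariates, and ``cluster_id``; the offset is recorded in
    ``frame.attrs["offset"]``.
    """
    if offset <= 0:
        raise ValueError("offset must be positive so all pseudo-times are > 0")
    if missing not in ("error", "censor", "drop"):
        raise ValueError("missing must be one of 'error', 'censor', 'drop'")
    df = records.copy()
    absent = df["fhb_std"].isna()
    if absent.any() and missing == "error":
        raise ValueError(
            f"{int(absent.sum())} rows have absent f-Hb (interval cancers); "
            "impute them first or pass missing='censor' or 'drop'"
        )
    observed = df["fhb_std"].to_numpy(dtype=float)
    if np.any(observed[~absent.to_numpy()] < 0):
        raise ValueError("fhb_std must be nonnegative")

    if missing == "drop":
        df = df.loc[~absent].copy()
        pseudo = df["fhb_std"].to_numpy(dtype=float) + offset
        event = np.ones(len(df), dtype=bool)
    else:
        pseudo = observed + offset
        event = ~absent.to_numpy()
        if absent.any():
            # censor at the subject's last observed f-Hb (0 if none)
            last_obs = (
                df.loc[~absent]
                .sort_values("round_index")
                .groupby("subject_id")["fhb_std"]
                .last()
            )
            cens_ids = df.loc[absent, "subject_id"]
            pseudo[absent.to_numpy()] = (
                cens_ids.map(last_obs).fillna(0.0).to_numpy(dtype=float) + offset
            )

    frame = pd.DataFrame(
        {
            "pseudo_time": pseudo,
            "event": event,
            "status": df["status"].to_numpy(),
            **{c: df[c].to_numpy() for c in _COVARIATE_COLS},
            "cluster_id": df["subject_id"].to_numpy(),
        }
    )
    frame.attrs["offset"] = float(offset)
    return frame


@dataclass
class CumulativeCurve:
    """Cumulative (complementary-survival) step function of f-Hb for one group.

    ``fhb`` holds the distinct event values on the raw μg/g scale and
    ``cum_frac`` the cumulative fraction reached at each; with no censoring
    this is exactly the empirical CDF.
    """

    status: str
    fhb: np.ndarray
    cum_frac: np.ndarray

    def __call__(self, x) -> np.ndarray:
        """Evaluate the right-continuous cumulative fraction at f-Hb value(s) x."""
        idx = np.searchsorted(self.fhb, np.asarray(x, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cum_frac])
        return padded[idx]

    def percentile(self, p: float) -> float:
        """Smallest f-Hb value whose cumulative fraction reaches p (NaN if censored below p)."""
        if not 0.0 < p < 1.0:
            raise ValueError("p must lie strictly between 0 and 1")
        reach = np.flatnonzero(self.cum_frac >= p - 1e-9)
        if reach.size == 0:
            return float("nan")
        return float(self.fhb[reach[0]])


def km_cumulative_curve(frame: pd.DataFrame, status: str) -> CumulativeCurve:
    """Kaplan-Meier cumulative f-Hb curve for one disease group.

    The survival function of pseudo-time is estimated with the standard
    product-limit estimator (ties handled as one step of the pooled mass)
    and returned as the cumulative curve ``1 - S`` on the raw f-Hb scale.
    """
    sub = frame.loc[frame["status"] == status]
    if len(sub) == 0:
        raise ValueError(f"empty group: no rows with status {status!r}")
    offset = frame.attrs.get("offset", DEFAULT_OFFSET)
    kmf = KaplanMeierFitter()
    kmf.fit(sub["pseudo_time"], event_observed=sub["event"])
    surv = kmf.survival_function_
    times = surv.index.to_numpy(dtype=float)
    s = surv.iloc[:, 0].to_numpy(dtype=float)
    # keep only event times (drop the prepended time origin / censor-only rows)
    keep = np.concatenate([[False], np.diff(s) < 0])
    event_times = times[keep]
    cum = 1.0 - s[keep]
    return CumulativeCurve(status=status, fhb=event_times - offset, cum_frac=cum)


def km_percentiles(
    frame: pd.DataFrame, status: str, p_grid
) -> pd.DataFrame:
    """Nonparametric percentile-table rows for one disease group.

    Each percentile is the left-continuous inverse of the cumulative curve:
    the smallest observed f-Hb whose cumulative fraction reaches p.  Heavy
    censoring can leave high percentiles unreached; those come back NaN
    with a warning.
    """
    p_grid = list(p_grid)
    if any(not 0.0 < p < 1.0 for p in p_grid):
        raise ValueError("all percentile levels must lie strictly in (0, 1)")
    curve = km_cumulative_curve(frame, status)
    values = [curve.percentile(p) for p in p_grid]
    if any(np.isnan(v) for v in values):
        warnings.warn(
            f"percentiles unreachable for status {status!r} due to censoring",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "method": "nonparametric",
            "status": status,
            "p": p_grid,
            "fhb_ug_per_g": values,
        }
    )
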