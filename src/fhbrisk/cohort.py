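"""Seeded synthetic screening cohorts for quantile-based f-Hb analysis.

The generator mirrors the structure of a biennial population FIT-screening
registry: each subject carries fixed covariates (sex, age band at entry,
family history of colorectal cancer, FIT brand), attends repeated rounds,
and has a latent disease status in {normal, non-advanced adenoma (nada),
advanced adenoma (ada), colorectal cancer (crc)}.

Positive f-Hb values follow a Weibull law whose scale is multiplied by a
status-specific time ratio (TR) and by covariate effects — the generative
counterpart of a Weibull accelerated failure time regression on log f-Hb.
Normal subjects additionally carry a point mass at exactly 0 μg/g,
emulating undetectable hemoglobin.  Disease present at round 1 comes from
cross-sectional prevalence; disease arising between rounds comes from
exponential waiting times with configured incidence rates, so a Poisson
baseline-incidence model is recoverable from the output.  A configured
fraction of cancers arising between rounds surfaces clinically before the
next screen (interval cancers) with no f-Hb measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .standardize import DEFAULT_CALIBRATIONS

STATUSES = ("normal", "nada", "ada", "crc")
AGE_BANDS = ("50-54", "55-59", "60-64", "65-69")
SEXES = ("female", "male")
BRANDS = ("OC-Sensor", "HM-Jack")
DETECTION_MODES = ("prevalent_screen", "subsequent_screen", "interval", "none")

#: column order of the cohort CSV / DataFrame
RECORD_COLUMNS = [
    "subject_id",
    "round_index",
    "age_band",
    "sex",
    "family_history",
    "fit_brand",
    "fhb_raw",
    "fhb_std",
    "fit_positive",
    "status",
    "detection_mode",
    "person_years",
]


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


def _check_prob_map(name: str, mapping: Mapping, keys) -> None:
    if set(mapping) != set(keys):
        raise ConfigError(f"{name}: expected keys {sorted(map(str, keys))}")
    vals = np.array([mapping[k] for k in keys], dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
    if abs(vals.sum() - 1.0) > 1e-12:
        raise ConfigError(f"{name}: probabilities must sum to 1 (got {vals.sum()!r})")


@dataclass
class CohortConfig:
    """Parameters of the synthetic screening cohort.

    Defaults emulate a Taiwanese-style biennial FIT program: disease mix
    heavily dominated by normal colons, a large point mass at f-Hb = 0
    among normals, multiplicative f-Hb shifts of roughly 9x / 11x / 17x
    for non-advanced adenoma / advanced adenoma / CRC versus normal, and
    about half of incident cancers surfacing as interval cancers.
    """

    n_subjects: int = 50_000
    n_rounds: int = 3
    round_interval_years: float = 2.0
    disease_prevalence: dict = field(
        default_factory=lambda: {"normal": 0.982, "nada": 0.009, "ada": 0.004, "crc": 0.005}
    )
    incidence_rates: dict = field(
        default_factory=lambda: {"nada": 1.5e-3, "ada": 6e-4, "crc": 8e-4}
    )
    tr_by_status: dict = field(
        default_factory=lambda: {"normal": 1.0, "nada": 9.13, "ada": 11.35, "crc": 17.02}
    )
    covariate_effects: dict = field(
        default_factory=lambda: {
            "sex:male": 1.10,
            "family_history:yes": 1.08,
            "fit_brand:HM-Jack": 1.96,
            "age_band:55-59": 1.05,
            "age_band:60-64": 1.12,
            "age_band:65-69": 1.20,
        }
    )
    weibull_shape: float = 0.6
    baseline_scale: float = 15.0
    zero_mass_normal: float = 0.55
    covariate_marginals: dict = field(
        default_factory=lambda: {
            "sex": {"female": 0.627, "male": 0.373},
            "age_band": {"50-54": 0.313, "55-59": 0.285, "60-64": 0.198, "65-69": 0.204},
            "family_history": {"no": 0.996, "yes": 0.004},
            "fit_brand": {"OC-Sensor": 0.767, "HM-Jack": 0.233},
        }
    )
    fit_positivity_cutoff: float = 20.0
    interval_cancer_fraction: float = 0.49
    frailty_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        if self.n_rounds <= 0:
            raise ConfigError("n_rounds must be positive")
        if self.round_interval_years <= 0:
            raise ConfigError("round_interval_years must be positive")
        _check_prob_map("disease_prevalence", self.disease_prevalence, STATUSES)
        for status in ("nada", "ada", "crc"):
            rate = self.incidence_rates.get(status)
            if rate is None or rate < 0:
                raise ConfigError(f"incidence_rates[{status!r}] must be a nonnegative rate")
        for status in STATUSES:
            tr = self.tr_by_status.get(status)
            if tr is None or tr <= 0:
                raise ConfigError(f"tr_by_status[{status!r}] must be strictly positive")
        if self.tr_by_status["normal"] != 1.0:
            raise ConfigError("tr_by_status['normal'] must equal 1 (reference group)")
        for key, eff in self.covariate_effects.items():
            if eff <= 0:
                raise ConfigError(f"covariate_effects[{key!r}] must be strictly positive")
        if self.weibull_shape <= 0:
            raise ConfigError("weibull_shape must be positive")
        if self.baseline_scale <= 0:
            raise ConfigError("baseline_scale must be positive")
        if not 0.0 <= self.zero_mass_normal <= 1.0:
            raise ConfigError("zero_mass_normal must lie in [0, 1]")
        if not 0.0 <= self.interval_cancer_fraction <= 1.0:
            raise ConfigError("interval_cancer_fraction must lie in [0, 1]")
        if self.frailty_sd < 0:
            raise ConfigError("frailty_sd must be nonnegative")
        _check_prob_map("covariate_marginals[sex]", self.covariate_marginals["sex"], SEXES)
        _check_prob_map(
            "covariate_marginals[age_band]", self.covariate_marginals["age_band"], AGE_BANDS
        )
        _check_prob_map(
            "covariate_marginals[family_history]",
            self.covariate_marginals["family_history"],
            ("no", "yes"),
        )
        _check_prob_map(
            "covariate_marginals[fit_brand]", self.covariate_marginals["fit_brand"], BRANDS
        )
        if self.fit_positivity_cutoff <= 0:
            raise ConfigError("fit_positivity_cutoff must be positive")


def _covariate_multiplier(config: CohortConfig, sex, age_band, family_history, brand):
    """Per-subject product of multiplicative covariate effects on the f-Hb scale."""
    eff = config.covariate_effects
    mult = np.ones(len(sex))
    for col, levels in (
        ("sex", sex),
        ("age_band", age_band),
        ("fit_brand", brand),
    ):
        for level in np.unique(levels):
            key = f"{col}:{level}"
            if key in eff:
                mult[levels == level] *= eff[key]
    if "family_history:yes" in eff:
        mult[family_history] *= eff["family_history:yes"]
    return mult


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one seeded cohort in long format (one row per subject-round).

    Subjects exit after a disease detection (screen-detected or interval);
    diseased subjects whose f-Hb falls below the positivity cutoff remain
    undetected and continue to the next round with unchanged status.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    k = config.weibull_shape
    interval = config.round_interval_years
    cutoff = config.fit_positivity_cutoff

    sex = rng.choice(SEXES, size=n, p=[config.covariate_marginals["sex"][s] for s in SEXES])
    age_band = rng.choice(
        AGE_BANDS, size=n, p=[config.covariate_marginals["age_band"][a] for a in AGE_BANDS]
    )
    family_history = (
        rng.random(n) < config.covariate_marginals["family_history"]["yes"]
    )
    brand = rng.choice(
        BRANDS, size=n, p=[config.covariate_marginals["fit_brand"][b] for b in BRANDS]
    )
    cov_mult = _covariate_multiplier(config, sex, age_band, family_history, brand)
    if config.frailty_sd > 0:
        cov_mult = cov_mult * np.exp(rng.normal(0.0, config.frailty_sd, size=n))

    status = rng.choice(
        STATUSES, size=n, p=[config.disease_prevalence[s] for s in STATUSES]
    ).astype(object)
    active = np.ones(n, dtype=bool)
    subject_id = np.arange(n)
    tr = np.vectorize(config.tr_by_status.get)
    brand_factor = np.where(
        brand == "HM-Jack",
        DEFAULT_CALIBRATIONS["HM-Jack"].factor,
        DEFAULT_CALIBRATIONS["OC-Sensor"].factor,
    )

    chunks: list[pd.DataFrame] = []
    incident_statuses = ("nada", "ada", "crc")

    for r in range(1, config.n_rounds + 1):
        idx = np.flatnonzero(active)
        m = idx.size
        if m == 0:
            break
        scale = config.baseline_scale * tr(status[idx]).astype(float) * cov_mult[idx]
        fhb = scale * rng.weibull(k, size=m)
        is_normal = status[idx] == "normal"
        zero = is_normal & (rng.random(m) < config.zero_mass_normal)
        fhb[zero] = 0.0
        positive = fhb >= cutoff
        diseased = ~is_normal
        detected = diseased & positive
        mode = np.where(
            detected, "prevalent_screen" if r == 1 else "subsequent_screen", "none"
        )
        chunks.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id[idx],
                    "round_index": r,
                    "age_band": age_band[idx],
                    "sex": sex[idx],
                    "family_history": family_history[idx],
                    "fit_brand": brand[idx],
                    "fhb_raw": fhb / brand_factor[idx],
                    "fhb_std": fhb,
                    "fit_positive": pd.array(positive, dtype="boolean"),
                    "status": status[idx],
                    "detection_mode": mode,
                    "person_years": 0.0 if r == 1 else interval,
                }
            )
        )
        active[idx[detected]] = False

        if r == config.n_rounds:
            break

        # incident disease among still-active normals: competing exponential
        # waiting times over the inter-screen interval
        norm_idx = np.flatnonzero(active & (status == "normal"))
        if norm_idx.size:
            waits = np.column_stack(
                [
                    rng.exponential(1.0 / config.incidence_rates[s], size=norm_idx.size)
                    if config.incidence_rates[s] > 0
                    else np.full(norm_idx.size, np.inf)
                    for s in incident_statuses
                ]
            )
            first = waits.argmin(axis=1)
            wait = waits[np.arange(norm_idx.size), first]
            onset = wait < interval
            new_status = np.array(incident_statuses, dtype=object)[first]
            # a fraction of incident CRCs surfaces clinically before the
            # next screen: interval cancer, f-Hb never measured
            is_interval = (
                onset
                & (new_status == "crc")
                & (rng.random(norm_idx.size) < config.interval_cancer_fraction)
            )
            iv = norm_idx[is_interval]
            if iv.size:
                chunks.append(
                    pd.DataFrame(
                        {
                            "subject_id": subject_id[iv],
                            "round_index": r + 1,
                            "age_band": age_band[iv],
                            "sex": sex[iv],
                            "family_history": family_history[iv],
                            "fit_brand": brand[iv],
                            "fhb_raw": np.nan,
                            "fhb_std": np.nan,
                            "fit_positive": pd.array(
                                [pd.NA] * iv.size, dtype="boolean"
                            ),
                            "status": "crc",
                            "detection_mode": "interval",
                            "person_years": wait[is_interval],
                        }
                    )
                )
                active[iv] = False
            progressed = norm_idx[onset & ~is_interval]
            status[progressed] = new_status[onset & ~is_interval]

    out = pd.concat(chunks, ignore_index=True)
    out = out.sort_values(["subject_id", "round_index"], kind="mergesort").reset_index(
        drop=True
    )
    return out[RECORD_COLUMNS]


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write cohort records to CSV (UTF-8, header row, empty string for absent)."""
    records.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`, validating invariants.

    Raises ``ValueError`` naming the 1-based file line of the first
    offending row (header is line 1).
    """
    df = pd.read_csv(
        path,
        dtype={
            "subject_id": "int64",
            "round_index": "int64",
            "age_band": "object",
            "sex": "object",
            "family_history": "bool",
            "fit_brand": "object",
            "fhb_raw": "float64",
            "fhb_std": "float64",
            "fit_positive": "boolean",
            "status": "object",
            "detection_mode": "object",
            "person_years": "float64",
        },
    )
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")

    def _line(mask) -> int:
        return int(np.flatnonzero(mask.to_numpy())[0]) + 2

    neg = df["fhb_std"] < 0
    if neg.any():
        raise ValueError(f"negative fhb_std at line {_line(neg)}")
    bad_mode = ~df["detection_mode"].isin(DETECTION_MODES)
    if bad_mode.any():
        raise ValueError(f"unknown detection_mode at line {_line(bad_mode)}")
    bad_status = ~df["status"].isin(STATUSES)
    if bad_status.any():
        raise ValueError(f"unknown status at line {_line(bad_status)}")
    absent = df["fhb_std"].isna()
    is_interval = df["detection_mode"] == "interval"
    mismatch = absent != is_interval
    if mismatch.any():
        raise ValueError(
            "fhb_std must be absent exactly for interval-cancer rows; "
            f"violated at line {_line(mismatch)}"
        )
    return df[RECORD_COLUMNS]
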