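"""End-to-end pipeline: cohort -> percentile tables -> risk tables.

Orchestrates the two-step analysis.  Step 1 ranks f-Hb as pseudo-time
and estimates percentiles per disease group, nonparametrically
(Kaplan-Meier) and parametrically (covariate-adjusted Weibull AFT).
Step 2 inverts the fitted f-Hb distributions with a Poisson baseline
incidence prior into posterior disease risk by percentile and by f-Hb
value.  Outputs are publication-style CSV/JSON tables plus a run
manifest (config hash, seeds, version) for byte-reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aft import DEFAULT_REFERENCE_PROFILE, aft_percentiles, fit_weibull_aft, time_ratios
from .cohort import CohortConfig, read_cohort, simulate_cohort
from .imputation import build_donor_pool, impute_interval_fhb
from .pseudotime import km_cumulative_curve, km_percentiles, make_pseudo_time
from .risk import DISEASE_STATUSES, fit_baseline_incidence, risk_table

logger = logging.getLogger("fhbrisk")

#: every 10th percentile plus the quartiles
DEFAULT_P_GRID = (0.10, 0.20, 0.25, 0.30, 0.40, 0.50, 0.60, 0.70, 0.75, 0.80, 0.90)

DEFAULT_X_GRID = (0.0, 5.0, 10.0, 20.0, 40.0, 60.0, 80.0, 90.0, 100.0, 150.0, 200.0)


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    cohort: CohortConfig | None = None
    cohort_path: str | None = None
    out_dir: str | None = None
    offset: float = 0.5
    percentile_grid: tuple = DEFAULT_P_GRID
    x_grid: tuple = DEFAULT_X_GRID
    reference_profile: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCE_PROFILE))
    imputation: bool = True
    imputation_seed: int = 0
    comparison: str = "binary_vs_normal"
    prior_horizon_years: float = 30.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cohort is None and self.cohort_path is None:
            raise ValueError("give either a cohort simulation block or a cohort_path")
        grid = list(self.percentile_grid)
        if any(not 0.0 < p < 1.0 for p in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("percentile_grid must be strictly increasing within (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        for key in ("percentile_grid", "x_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        # output location is not an analysis parameter; keeping it out of the
        # manifest makes runs byte-identical across directories
        out.pop("out_dir", None)
        return out


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def summarize_descriptives(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive f-Hb table by disease status and demographic strata.

    Per stratum: count, percent within its variable, and median / mean /
    SD / IQR of observed f-Hb on the raw μg/g scale (interval cancers,
    which have no measurement, are excluded from the moments but counted).
    Quantiles use linear interpolation, the common convention for
    descriptive tables; a single-observation stratum reports SD 0 with a
    flag rather than propagating NaN.
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")

    def stratum(var: str, level, mask) -> dict:
        fhb = records.loc[mask, "fhb_std"].dropna().to_numpy(dtype=float)
        n = int(mask.sum())
        single = len(fhb) <= 1
        if len(fhb) == 0:
            med = mean = sd = iqr = float("nan")
        else:
            med = float(np.median(fhb))
            mean = float(np.mean(fhb))
            sd = 0.0 if single else float(np.std(fhb, ddof=1))
            iqr = float(np.quantile(fhb, 0.75) - np.quantile(fhb, 0.25))
        return {
            "variable": var,
            "level": str(level),
            "n": n,
            "percent": 100.0 * n / len(records),
            "median_fhb": med,
            "mean_fhb": mean,
            "sd_fhb": sd,
            "iqr_fhb": iqr,
            "single_obs": single,
        }

    rows = []
    for var in ("status", "sex", "age_band", "family_history", "fit_brand"):
        for level in pd.unique(records[var]):
            rows.append(stratum(var, level, records[var] == level))
    rows.append(stratum("overall", "all", pd.Series(True, index=records.index)))
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full two-step analysis and return (and optionally write) the bundle.

    The bundle maps output names to DataFrames / dicts: descriptives,
    percentile tables (both methods), time-ratio report, risk tables (by
    percentile and by value), cumulative curves, imputation audit and the
    run manifest.  With ``out_dir`` set, every table is written as CSV
    (JSON for the fit summary and manifest).
    """
    logging.basicConfig(level=config.log_level)
    logger.info("stage: cohort")
    try:
        if config.cohort is not None:
            records = simulate_cohort(config.cohort)
        else:
            records = read_cohort(config.cohort_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc

    logger.info("stage: descriptives")
    descriptives = summarize_descriptives(records)

    logger.info("stage: imputation")
    audit = pd.DataFrame()
    analysis_records = records
    has_interval = (records["detection_mode"] == "interval").any()
    if config.imputation and has_interval:
        try:
            pool = build_donor_pool(records)
            analysis_records, audit = impute_interval_fhb(
                records, pool, seed=config.imputation_seed
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'imputation' failed: {exc}") from exc

    logger.info("stage: pseudo-time")
    missing = "error" if config.imputation else "censor"
    frame = make_pseudo_time(analysis_records, offset=config.offset, missing=missing)

    logger.info("stage: percentiles")
    try:
        km_rows = pd.concat(
            [km_percentiles(frame, s, config.percentile_grid) for s in DISEASE_STATUSES],
            ignore_index=True,
        )
        fit = fit_weibull_aft(frame, cluster_robust=True)
        aft_rows = pd.concat(
            [
                aft_percentiles(fit, s, config.percentile_grid, config.reference_profile)
                for s in DISEASE_STATUSES
            ],
            ignore_index=True,
        )
        percentile_table = pd.concat([km_rows, aft_rows], ignore_index=True)
        tr_report = time_ratios(fit)
        curves = pd.concat(
            [
                pd.DataFrame(
                    {
                        "status": s,
                        "fhb": (c := km_cumulative_curve(frame, s)).fhb,
                        "cumulative_fraction": c.cum_frac,
                    }
                )
                for s in ("normal", *DISEASE_STATUSES)
            ],
            ignore_index=True,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'percentiles' failed: {exc}") from exc

    logger.info("stage: risk inversion")
    try:
        prior = fit_baseline_incidence(
            records,
            horizon_years=config.prior_horizon_years,
            reference_profile=config.reference_profile,
        )
        zero_mass = (
            config.cohort.zero_mass_normal if config.cohort is not None else None
        )
        risk_by_p = risk_table(
            prior,
            fit,
            p_grid=config.percentile_grid,
            comparison=config.comparison,
            reference_profile=config.reference_profile,
        )
        risk_by_x = risk_table(
            prior,
            fit,
            x_grid=config.x_grid,
            comparison="multiclass",
            reference_profile=config.reference_profile,
            zero_mass_normal=zero_mass,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'risk' failed: {exc}") from exc

    from . import __version__

    fit_summary = {
        "coefficients": fit.coefficients,
        "sigma": fit.sigma,
        "weibull_shape": fit.shape,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "grad_norm": fit.grad_norm,
        "n_rows": fit.n_rows,
        "n_clusters": fit.n_clusters,
        "time_ratios": tr_report.reset_index().to_dict(orient="records"),
    }
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seeds": {
            "cohort": None if config.cohort is None else config.cohort.seed,
            "imputation": config.imputation_seed,
        },
        "prior": {"rates": prior.rates, "horizon_years": prior.horizon_years, "pi": prior.pi},
    }
    bundle = {
        "records": records,
        "descriptives": descriptives,
        "imputation_audit": audit,
        "percentile_table": percentile_table,
        "time_ratios": tr_report,
        "fit_summary": fit_summary,
        "risk_by_percentile": risk_by_p.df,
        "risk_by_value": risk_by_x.df,
        "curves": curves,
        "manifest": manifest,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        descriptives.to_csv(out / "descriptives.csv", index=False)
        percentile_table.to_csv(out / "percentile_table.csv", index=False)
        tr_report.to_csv(out / "time_ratios.csv")
        risk_by_p.df.to_csv(out / "risk_by_percentile.csv", index=False)
        risk_by_x.df.to_csv(out / "risk_by_value.csv", index=False)
        curves.to_csv(out / "cumulative_curves.csv", index=False)
        if len(audit):
            audit.to_csv(out / "imputation_audit.csv", index=False)
        (out / "fit_summary.json").write_text(json.dumps(fit_summary, indent=2))
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
    return bundle
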