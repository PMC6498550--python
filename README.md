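# fhbrisk

Quantile-based analysis of fecal hemoglobin concentration (f-Hb) for
colorectal cancer screening cohorts.

## The problem

Quantitative fecal immunochemical tests (FIT) report f-Hb in μg of
hemoglobin per g of feces. In a screening population the distribution of
f-Hb is extremely right-skewed and carries a large point mass at exactly
0 (undetectable hemoglobin), so ordinary regression on f-Hb — or even on
log f-Hb — represents it poorly. `fhbrisk` implements a rank-based
alternative: treat the *ordering* of f-Hb like the ordering of survival
times and use survival machinery to describe how the whole f-Hb
distribution shifts across the stages of colorectal carcinogenesis
(normal colon → non-advanced adenoma → advanced adenoma → colorectal
cancer, abbreviated `normal`/`nada`/`ada`/`crc`), then invert the fitted
distributions into disease risk by f-Hb percentile.

## The method

Two steps, applied to long-format screening records (one row per subject
per screen round):

1. **f-Hb as pseudo-survival-time.** Each observation becomes
   `t = f-Hb + 0.5` (the offset makes zero readings valid survival
   times; every reported percentile subtracts it back). Percentile
   curves per disease group come from the Kaplan–Meier estimator
   (nonparametric) and from a Weibull accelerated failure time (AFT)
   regression (parametric, covariate-adjusted):

   `log T = β₀ + X β + σ W`, `W ~` standard Gumbel-minimum,

   so `T` is Weibull with shape `k = 1/σ` and scale `λ = exp(β₀ + Xβ)`.
   `exp(β)` is a **time ratio (TR)** — the multiplicative shift of the
   entire f-Hb distribution for that covariate level versus its
   reference — and the covariate-adjusted p-th percentile of a group is
   `λ·(−ln(1−p))^σ`. Repeated screens of one subject are handled with a
   cluster-robust sandwich variance. Interval cancers (diagnosed between
   screens, f-Hb never measured) are filled by cold-deck imputation from
   screen-detected cancers matched on sex and age band.

2. **Bayesian inversion.** Poisson regression on incident cases only
   (neoplasia at the first screen excluded, person-years offset) gives
   baseline incidence rates, integrated over a risk horizon into prior
   probabilities `π_d = 1 − e^{−rate_d·horizon}`. The fitted Weibull
   densities are the likelihood `f_d(x)`, and the posterior risk of
   disease `d` at f-Hb value `x` against the normal group is

   `P(d | x) = π_d f_d(x) / (π_d f_d(x) + π_normal f_normal(x))`,

   or normalized over all four statuses in multiclass mode. Risk tables
   are indexed by percentile (each group's percentile resolved through
   its own fitted quantile) or by f-Hb value.

A seeded synthetic-cohort generator (`fhbrisk.cohort`) produces
screening data with the structure these estimators assume — biennial
rounds, Weibull f-Hb with multiplicative status/covariate effects, the
zero point mass among normals, incident transitions between rounds, and
interval cancers with missing f-Hb — so the full pipeline is testable
without access to any registry.

## Worked example

```python
from fhbrisk import CohortConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(
    cohort=CohortConfig(n_subjects=50_000, seed=1),
    imputation_seed=1,
    log_level="WARNING",
)
bundle = run_pipeline(cfg)

medians = bundle["percentile_table"].query("p == 0.5")
print(medians.pivot(index="method", columns="status", values="fhb_ug_per_g").round(1))
```

prints the adjusted and unadjusted median f-Hb (μg/g) per disease group
on the simulated cohort:

```
status           ada    crc  nada
method
nonparametric  132.8  214.8  98.0
parametric      84.1  120.0  57.6
```

The stepwise increase across disease groups and the
nonparametric-vs-parametric gap (the adjusted values are evaluated at
the reference covariate profile: female, 50–54, no family history,
OC-Sensor) mirror what this estimator family shows on real screening
data. `bundle["risk_by_percentile"]` holds the corresponding posterior
risks, e.g. CRC risk rising from 1.5% at the 25th percentile to 94.5%
at the 75th on this synthetic cohort's baseline incidence.

A parameter-recovery check — simulate a zero-free cohort whose
generating disease TRs are 9.13 / 11.35 / 17.02 (and 1.10 for male sex),
then refit:

```python
from fhbrisk.experiments import run_recovery
fit, report = run_recovery(seed=1, n_subjects=50_000)
print(report[["tr", "true_tr", "rel_error"]].round(3))
```

```
                 tr  true_tr  rel_error
term
status:nada   8.907     9.13     -0.024
status:ada   11.180    11.35     -0.015
status:crc   16.951    17.02     -0.004
sex:male      1.093     1.10     -0.006
```

Every generating ratio is recovered to within a few percent.

The same stages are available from the shell:

```sh
fhbrisk simulate --seed 1 --out cohort.csv
fhbrisk impute --cohort cohort.csv --seed 1 --out imputed.csv
fhbrisk percentiles --cohort imputed.csv --out percentiles.csv
fhbrisk risk --cohort imputed.csv --out risk.csv
fhbrisk run-all --seed 1 --out-dir results/
```

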