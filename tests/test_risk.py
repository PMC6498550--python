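import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from fhbrisk import (
    BaselinePrior,
    RiskTable,
    fit_baseline_incidence,
    fit_weibull_aft,
    fold_change,
    likelihood_at,
    make_pseudo_time,
    posterior_risk,
    risk_table,
    simulate_cohort,
)
from fhbrisk.aft import WeibullAftFit
from fhbrisk.cohort import CohortConfig
from fhbrisk.experiments import recovery_config


def _fit_with_scales(lam_by_status: dict, sigma: float = 1.5, offset: float = 0.5):
    """Hand-built AFT fit with known per-status Weibull scales."""
    names = ["intercept"] + [f"status:{s}" for s in ("nada", "ada", "crc")]
    b0 = np.log(lam_by_status["normal"])
    params = [b0] + [np.log(lam_by_status[s]) - b0 for s in ("nada", "ada", "crc")]
    p = len(params) + 1
    return WeibullAftFit(
        params=np.array(params),
        param_names=names,
        sigma=sigma,
        covariance=np.eye(p) * 1e-6,
        covariance_robust=None,
        loglik=0.0,
        n_rows=100,
        n_clusters=100,
        cluster_robust=False,
        converged=True,
        grad_norm=0.0,
        offset=offset,
    )


@pytest.fixture(scope="module")
def toy_fit():
    return _fit_with_scales(
        {"normal": 17.0, "nada": 137.0, "ada": 170.0, "crc": 255.0}, sigma=1.6
    )


@pytest.fixture(scope="module")
def toy_prior():
    return BaselinePrior(
        rates={"nada": 1.5e-3, "ada": 6e-4, "crc": 8e-4}, horizon_years=30.0
    )


def _subject_rows(sid, statuses, py=2.0):
    rows = []
    for r, status in enumerate(statuses, start=1):
        rows.append(
            {
                "subject_id": sid,
                "round_index": r,
                "age_band": "50-54",
                "sex": "female",
                "family_history": False,
                "fit_brand": "OC-Sensor",
                "fhb_raw": 0.0,
                "fhb_std": 0.0,
                "fit_positive": False,
                "status": status,
                "detection_mode": "none",
                "person_years": 0.0 if r == 1 else py,
            }
        )
    return rows


class TestBaselinePrior:
    def test_closed_form_marginal_rate(self):
        # 100 baseline-normal subjects, 5 py each after entry, 10 incident CRC
        rows = []
        for i in range(90):
            rows += _subject_rows(i, ["normal", "normal"], py=5.0)
        for i in range(90, 100):
            rows += _subject_rows(i, ["normal", "crc"], py=5.0)
        prior = fit_baseline_incidence(
            pd.DataFrame(rows), covariates=(), horizon_years=10.0
        )
        assert prior.rates["crc"] == pytest.approx(10 / 500.0)

    def test_horizon_integration(self):
        prior = BaselinePrior(
            rates={"nada": 0.0, "ada": 0.0, "crc": 0.01}, horizon_years=10.0
        )
        assert prior.pi["crc"] == pytest.approx(1 - np.exp(-0.1))
        assert prior.pi["crc"] == pytest.approx(0.0952, abs=5e-4)
        assert sum(prior.pi.values()) == pytest.approx(1.0, abs=1e-12)

    def test_baseline_prevalent_cases_excluded(self):
        rows = _subject_rows(0, ["crc"]) + _subject_rows(1, ["normal", "normal"])
        prior = fit_baseline_incidence(pd.DataFrame(rows), covariates=())
        assert prior.rates["crc"] == 0.0

    def test_incidence_rate_recovery_across_seeds(self):
        """Marginal Poisson rates recover generator incidence within 3 SE (20 seeds)."""
        hits = 0
        for seed in range(20):
            cfg = CohortConfig(n_subjects=8000, n_rounds=3, seed=100 + seed)
            rec = simulate_cohort(cfg)
            prior = fit_baseline_incidence(rec, covariates=())
            # nearly all subjects stay at risk for 2 inter-screen intervals
            py_approx = cfg.n_subjects * (cfg.n_rounds - 1) * cfg.round_interval_years
            ok = all(
                abs(prior.rates[d] - true_rate)
                <= 3 * np.sqrt(true_rate / py_approx)  # Poisson SE of a rate
                for d, true_rate in cfg.incidence_rates.items()
            )
            hits += ok
        assert hits >= 17

    def test_profile_specific_rate_close_to_marginal_when_homogeneous(self):
        rec = simulate_cohort(CohortConfig(n_subjects=20_000, n_rounds=3, seed=5))
        marginal = fit_baseline_incidence(rec, covariates=())
        profiled = fit_baseline_incidence(rec, covariates=("sex", "age_band"))
        for d in ("nada", "ada", "crc"):
            if marginal.rates[d] > 0:
                assert profiled.rates[d] == pytest.approx(marginal.rates[d], rel=0.75)

    def test_zero_exposure_rejected(self):
        rows = _subject_rows(0, ["normal"])  # single round: 0 person-years
        with pytest.raises(ValueError, match="person-years"):
            fit_baseline_incidence(pd.DataFrame(rows), covariates=())


class TestLikelihood:
    def test_density_integrates_to_one(self, toy_fit):
        for status in ("normal", "crc"):
            total, _ = integrate.quad(
                lambda x: likelihood_at(toy_fit, status, x),
                0.0,
                np.inf,
                limit=200,
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_monotone_decreasing_density_for_shape_below_one(self, toy_fit):
        xs = np.linspace(0.0, 400.0, 50)
        dens = likelihood_at(toy_fit, "crc", xs)
        assert np.all(np.diff(dens) < 0)  # k = 1/1.6 < 1

    def test_mode_location_for_shape_above_one(self):
        fit = _fit_with_scales(
            {"normal": 50.0, "nada": 60.0, "ada": 70.0, "crc": 80.0}, sigma=0.5
        )
        k, lam = 2.0, 80.0
        mode_t = lam * ((k - 1) / k) ** (1 / k)  # Weibull mode on the pseudo-time scale
        xs = np.linspace(0.0, 200.0, 4001)
        dens = likelihood_at(fit, "crc", xs)
        assert xs[np.argmax(dens)] == pytest.approx(mode_t - fit.offset, abs=0.5)

    def test_density_matches_closed_form_weibull_pdf(self, toy_fit):
        x = 163.1
        k = 1.0 / toy_fit.sigma
        lam = 255.0
        t = x + toy_fit.offset
        expected = stats.weibull_min.pdf(t, c=k, scale=lam) / stats.weibull_min.sf(
            toy_fit.offset, c=k, scale=lam
        )
        assert likelihood_at(toy_fit, "crc", x) == pytest.approx(expected, rel=1e-12)

    def test_zero_inflation_point_mass_at_zero(self, toy_fit):
        assert likelihood_at(toy_fit, "normal", 0.0, zero_mass_normal=0.55) == 0.55
        cont = likelihood_at(toy_fit, "normal", 10.0)
        assert likelihood_at(
            toy_fit, "normal", 10.0, zero_mass_normal=0.55
        ) == pytest.approx(0.45 * cont)

    def test_binned_likelihood_sums_to_one(self, toy_fit):
        edges = np.array([5.0, 20.0, 50.0, 100.0, 250.0])
        reps = np.array([2.0, 10.0, 30.0, 70.0, 150.0, 400.0])  # one x per bin
        masses = likelihood_at(toy_fit, "crc", reps, bin_edges=edges)
        assert masses.sum() == pytest.approx(1.0, abs=1e-12)


class TestPosterior:
    def test_uniform_prior_equal_likelihood_multiclass(self):
        fit = _fit_with_scales(
            {"normal": 100.0, "nada": 100.0, "ada": 100.0, "crc": 100.0}
        )
        rate = -np.log(1 - 0.25) / 30.0  # pi = 0.25 for each disease group
        prior = BaselinePrior(
            rates={"nada": rate, "ada": rate, "crc": rate}, horizon_years=30.0
        )
        for d in ("nada", "ada", "crc"):
            assert posterior_risk(
                prior, fit, d, x=50.0, comparison="multiclass"
            ) == pytest.approx(0.25, abs=1e-12)

    def test_binary_bayes_algebra(self, toy_fit):
        """posterior = pi*r / (pi*r + 1 - pi) with r the likelihood ratio."""
        prior = BaselinePrior(
            rates={"nada": 1e-9, "ada": 1e-9, "crc": -np.log(1 - 0.01) / 30.0},
            horizon_years=30.0,
        )
        x = 200.0
        r = likelihood_at(toy_fit, "crc", x) / likelihood_at(toy_fit, "normal", x)
        pi = prior.pi["crc"]
        pi_n = prior.pi["normal"]
        expected = pi * r / (pi * r + pi_n)
        assert posterior_risk(prior, toy_fit, "crc", x=x) == pytest.approx(
            expected, rel=1e-12
        )

    def test_reported_fold_change_identity(self):
        assert fold_change(0.01, 0.5025) == pytest.approx(50.25)
        table = RiskTable(
            pd.DataFrame(
                {"status": ["crc", "crc"], "p": [0.25, 0.75], "risk": [0.005, 0.443]}
            ),
            mode="by_percentile",
            comparison="binary_vs_normal",
        )
        assert table.fold_change("crc", 0.25, 0.75) == pytest.approx(88.6)

    @given(
        pi=st.floats(1e-6, 0.5),
        x=st.floats(0.5, 2000.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_posterior_odds_equals_prior_odds_times_likelihood_ratio(self, pi, x):
        fit = _fit_with_scales(
            {"normal": 17.0, "nada": 137.0, "ada": 170.0, "crc": 255.0}, sigma=1.6
        )
        prior = BaselinePrior(
            rates={
                "nada": 1e-9,
                "ada": 1e-9,
                "crc": -np.log1p(-pi) / 30.0,
            },
            horizon_years=30.0,
        )
        post = posterior_risk(prior, fit, "crc", x=x)
        lr = likelihood_at(fit, "crc", x) / likelihood_at(fit, "normal", x)
        prior_odds = prior.pi["crc"] / prior.pi["normal"]
        assert post / (1 - post) == pytest.approx(prior_odds * lr, rel=1e-9)

    def test_no_information_limit_returns_prior(self, toy_prior):
        fit = _fit_with_scales(
            {"normal": 100.0, "nada": 100.0, "ada": 100.0, "crc": 100.0}
        )
        for d in ("nada", "ada", "crc"):
            assert posterior_risk(
                toy_prior, fit, d, x=30.0, comparison="multiclass"
            ) == pytest.approx(toy_prior.pi[d], rel=1e-12)


class TestRiskTable:
    def test_multiclass_rows_sum_to_one(self, toy_prior, toy_fit):
        table = risk_table(
            toy_prior, toy_fit, x_grid=[0.0, 10.0, 90.0, 300.0], comparison="multiclass"
        )
        sums = table.df.groupby("fhb")["risk"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_risks_monotone_in_percentile_for_monotone_likelihood_ratio(
        self, toy_prior, toy_fit
    ):
        table = risk_table(
            toy_prior, toy_fit, p_grid=[0.1, 0.25, 0.5, 0.75, 0.9]
        )
        for status in ("nada", "ada", "crc"):
            # Weibull scale ratio > 1 with common shape gives a likelihood
            # ratio increasing in x over this range
            risks = table.df.loc[table.df["status"] == status, "risk"].to_numpy()
            assert np.all(np.diff(risks) > 0)

    def test_zero_value_with_zero_inflated_normals_has_near_zero_risk(
        self, toy_prior, toy_fit
    ):
        table = risk_table(
            toy_prior,
            toy_fit,
            x_grid=[0.0],
            comparison="binary_vs_normal",
            zero_mass_normal=0.55,
        )
        assert (table.df["risk"] < 0.01).all()

    def test_empirical_crc_fraction_matches_posterior_in_bins(self):
        """Binary posterior tracks the observed CRC share in narrow f-Hb bins."""
        cfg = recovery_config(seed=9, n_subjects=120_000)
        cfg.n_rounds = 1
        cfg.covariate_effects = {}  # every subject sits at the reference profile
        rec = simulate_cohort(cfg)
        sub = rec.loc[rec["status"].isin(["normal", "crc"])]
        frame = make_pseudo_time(rec, offset=1e-6, missing="drop")
        fit = fit_weibull_aft(frame, covariates=[], cluster_robust=False)
        # prior matching the cross-sectional mix restricted to normal vs CRC
        p_crc = cfg.disease_prevalence["crc"] / (
            cfg.disease_prevalence["crc"] + cfg.disease_prevalence["normal"]
        )
        prior = BaselinePrior(
            rates={"nada": 1e-12, "ada": 1e-12, "crc": -np.log1p(-p_crc) / 30.0},
            horizon_years=30.0,
        )
        for lo, hi in [(20.0, 30.0), (80.0, 110.0), (300.0, 420.0)]:
            in_bin = sub.loc[(sub["fhb_std"] >= lo) & (sub["fhb_std"] < hi)]
            frac = (in_bin["status"] == "crc").mean()
            post = posterior_risk(prior, fit, "crc", x=(lo + hi) / 2)
            se = np.sqrt(frac * (1 - frac) / len(in_bin))
            assert len(in_bin) > 200
            assert abs(post - frac) <= 4 * se

    def test_requires_exactly_one_grid(self, toy_prior, toy_fit):
        with pytest.raises(ValueError):
            risk_table(toy_prior, toy_fit)
        with pytest.raises(ValueError):
            risk_table(toy_prior, toy_fit, p_grid=[0.5], x_grid=[1.0])
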