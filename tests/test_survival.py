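"""Survival stage: assembly, standardization, AFT likelihood and predictions."""

import numpy as np
import pandas as pd
import pytest

from capsoc.mcmc import SamplerConfig
from capsoc.simulate import annual_death_probability
from capsoc.survival import (
    AFTConfig,
    AFTResult,
    assemble_female_years,
    fit_aft,
    predict_death_probability,
    run_model_battery,
    standardize_covariates,
    summarize_fit_draws,
)

from conftest import ts

FAST = SamplerConfig(chains=2, warmup=300, samples=300, seed=8, max_leapfrog=24)


def toy_tables():
    individuals = pd.DataFrame(
        {"id": ["A", "B", "C"], "sex": ["F", "F", "F"],
         "birth_date": [ts("2000-01-01")] * 3}
    )
    demography = pd.DataFrame(
        {"id": ["A", "B", "C"],
         "death_date": [ts("2013-06-01"), pd.NaT, pd.NaT],
         "censor_date": [pd.NaT, ts("2014-12-31"), ts("2014-12-31")]}
    )
    cov_rows = []
    for iid, years in [("A", range(2010, 2014)), ("B", range(2010, 2015)),
                       ("C", range(2012, 2015))]:
        for y in years:
            cov_rows.append(dict(id=iid, year=y, rank=0.5, group_size=15.0, group="G1"))
    covariates = pd.DataFrame(cov_rows)
    est_rows = [
        dict(id=i, year=y, behavior="grooming", direction="giving",
             post_mean=0.1 * y % 1, post_sd=0.3)
        for i in ["A", "B", "C"] for y in range(2009, 2015)
    ]
    estimates = pd.DataFrame(est_rows)
    return individuals, demography, covariates, estimates


class TestAssembleFemaleYears:
    def test_death_year_is_final_row(self):
        ind, demo, cov, est = toy_tables()
        fy = assemble_female_years(ind, demo, cov, est, lag=0)
        a = fy[fy.id == "A"]
        assert len(a) == 4
        assert list(a.status) == ["survived"] * 3 + ["died"]

    def test_survivor_censored_in_final_year(self):
        ind, demo, cov, est = toy_tables()
        fy = assemble_female_years(ind, demo, cov, est, lag=0)
        b = fy[fy.id == "B"]
        assert list(b.status) == ["survived"] * 4 + ["censored"]

    def test_lag_one_uses_previous_year_estimate(self):
        ind, demo, cov, est = toy_tables()
        fy0 = assemble_female_years(ind, demo, cov, est, lag=0)
        fy1 = assemble_female_years(ind, demo, cov, est, lag=1)
        assert len(fy1) == len(fy0)  # estimates exist for year-1 here
        row = fy1[(fy1.id == "A") & (fy1.year == 2012)].iloc[0]
        want = est[(est.id == "A") & (est.year == 2011)].iloc[0]
        assert row.integration_mean == want.post_mean

    def test_lag_one_drops_years_without_prior_estimate(self):
        ind, demo, cov, est = toy_tables()
        est = est[est.year >= 2010]  # no 2009 estimates
        fy1 = assemble_female_years(ind, demo, cov, est, lag=1)
        assert fy1[(fy1.id == "A") & (fy1.year == 2010)].empty

    def test_duplicate_female_year_raises(self):
        ind, demo, cov, est = toy_tables()
        cov = pd.concat([cov, cov.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="overlapping"):
            assemble_female_years(ind, demo, cov, est, lag=0)

    def test_mixed_measures_rejected(self):
        ind, demo, cov, est = toy_tables()
        other = est.copy()
        other["direction"] = "receiving"
        with pytest.raises(ValueError, match="single behavior"):
            assemble_female_years(ind, demo, cov, pd.concat([est, other]), lag=0)


class TestStandardize:
    def _rows(self):
        rng = np.random.default_rng(0)
        n = 50
        return pd.DataFrame(
            {"id": [f"f{i}" for i in range(n)], "year": 2010,
             "age": rng.uniform(5, 25, n), "rank": rng.uniform(0, 1, n),
             "group_size": rng.uniform(10, 30, n), "group": "G1",
             "status": "survived",
             "integration_mean": rng.normal(0, 1.3, n),
             "integration_sd": rng.uniform(0.2, 0.6, n), "lag": 0}
        )

    def test_zero_mean_unit_sd(self):
        std, _ = standardize_covariates(self._rows())
        for col in ["age", "rank", "group_size", "integration_mean"]:
            assert abs(std[col].mean()) < 1e-9
            assert std[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_sd_scaled_by_same_factor(self):
        rows = self._rows()
        std, scaling = standardize_covariates(rows)
        s = scaling["integration_mean"][1]
        assert np.allclose(std["integration_sd"], rows["integration_sd"] / s)
        # mean +- sd interval maps consistently
        hi = rows.integration_mean + rows.integration_sd
        hi_std = (hi - scaling["integration_mean"][0]) / s
        assert np.allclose(std.integration_mean + std.integration_sd, hi_std)

    def test_round_trip_recovers_original(self):
        rows = self._rows()
        std, scaling = standardize_covariates(rows)
        for col in ["age", "rank", "group_size", "integration_mean"]:
            m, s = scaling[col]
            assert np.allclose(std[col] * s + m, rows[col])

    def test_zero_variance_rejected(self):
        rows = self._rows()
        rows["rank"] = 0.5
        with pytest.raises(ValueError, match="variance"):
            standardize_covariates(rows)


class TestAnnualDeathProbability:
    def test_matches_closed_form_at_reported_intercept(self):
        # eta = 9.46 on a log-days scale gives ~2.8% annual mortality
        assert annual_death_probability(9.46) == pytest.approx(
            1.0 - np.exp(-365.25 * np.exp(-9.46))
        )
        assert annual_death_probability(9.46) == pytest.approx(0.0282, abs=0.0005)

    def test_monotone_decreasing_in_eta(self):
        etas = np.linspace(7, 12, 20)
        p = annual_death_probability(etas)
        assert (np.diff(p) < 0).all()


class TestSummarize:
    def test_symmetric_draws_centered_and_quantiles(self):
        rng = np.random.default_rng(2)
        draws = {"beta_social": rng.normal(0.5, 0.1, size=(2, 4000))}
        out = summarize_fit_draws(draws).iloc[0]
        assert out["mean"] == pytest.approx(0.5, abs=0.01)
        v = draws["beta_social"].ravel()
        assert out.ci_lo == pytest.approx(np.quantile(v, 0.055))
        assert out.ci_hi == pytest.approx(np.quantile(v, 0.945))
        assert out["mean"] == pytest.approx((out.ci_lo + out.ci_hi) / 2, abs=0.01)

    def test_formatting_layout(self):
        draws = {"x": np.full((1, 100), 0.54)}
        out = summarize_fit_draws(draws).iloc[0]
        assert out.formatted == "0.54 (0.54; 0.54)"


class TestFitAFT:
    def test_recovers_exponential_rate_without_effects(self, small_survival_data):
        pop, est, cfg = small_survival_data
        # refit a no-effect world: intercept should match the closed-form
        # exponential-rate MLE log(person-days / deaths)
        from capsoc.simulate import (
            SimConfig, simulate_integration_estimates, simulate_population,
            simulate_survival,
        )
        cfg0 = SimConfig(n_groups=6, females_per_group=8, years=8, seed=77,
                         beta_social=0, beta_age=0, beta_rank=0, beta_groupsize=0,
                         sigma_female=0, sigma_group=0, mu_days=9.0)
        rng = np.random.default_rng(cfg0.seed)
        ind, mem, truth = simulate_population(cfg0, rng)
        pop0 = simulate_survival(ind, mem, truth, cfg0, rng)
        est0 = simulate_integration_estimates(pop0, cfg0, rng)
        fy = assemble_female_years(pop0.individuals, pop0.demography, pop0.covariates, est0, 0)
        std, _ = standardize_covariates(fy)
        fit = fit_aft(std, AFTConfig(random_effects=False, mcmc=FAST))
        deaths = (fy.status == "died").sum()
        mle = np.log(len(fy) * 365.25 / deaths)
        mu = fit.draws["intercept"]
        assert abs(mu.mean() - mle) < mu.std()

    def test_beta_recovery_on_small_study(self, small_survival_data):
        pop, est, cfg = small_survival_data
        fy = assemble_female_years(pop.individuals, pop.demography, pop.covariates, est, 0)
        std, _ = standardize_covariates(fy)
        fit = fit_aft(std, AFTConfig(mcmc=SamplerConfig(
            chains=2, warmup=400, samples=400, seed=3, max_leapfrog=32)))
        b = fit.draws["beta_social"]
        # true effect 0.5; small study so allow a generous but sign-fixing band
        assert 0.0 < b.mean() < 1.1

    def test_seeded_fit_reproducible(self, small_survival_data):
        pop, est, cfg = small_survival_data
        fy = assemble_female_years(pop.individuals, pop.demography, pop.covariates, est, 0)
        std, _ = standardize_covariates(fy)
        f1 = fit_aft(std, AFTConfig(mcmc=FAST))
        f2 = fit_aft(std, AFTConfig(mcmc=FAST))
        assert np.array_equal(f1.draws["beta_social"], f2.draws["beta_social"])


def synthetic_result(beta_draws, mu=9.5):
    draws = {
        "intercept": np.full((1, len(beta_draws)), mu),
        "beta_social": np.asarray(beta_draws)[None, :],
    }
    return AFTResult(
        draws=draws, summary=summarize_fit_draws(draws), diagnostics={},
        scaling={"integration_mean": (0.0, 1.0)}, n_rows=0, n_deaths=0,
        converged=True, config=AFTConfig(),
    )


class TestPrediction:
    def test_positive_effect_curve_strictly_decreasing(self):
        res = synthetic_result(np.random.default_rng(1).uniform(0.2, 0.8, 500))
        curve = predict_death_probability(res, np.linspace(-2, 2, 21),
                                          res.scaling)
        assert (np.diff(curve.p_mean) < 0).all()
        assert (curve.p_lo <= curve.p_hi).all()
        assert ((curve.p_mean > 0) & (curve.p_mean < 1)).all()

    def test_zero_effect_curve_flat(self):
        res = synthetic_result(np.zeros(200))
        curve = predict_death_probability(res, np.linspace(-2, 2, 11), res.scaling)
        assert curve.p_mean.nunique() == 1

    def test_band_widens_toward_extremes(self):
        res = synthetic_result(np.random.default_rng(2).normal(0.5, 0.2, 2000))
        curve = predict_death_probability(res, np.linspace(-4, 4, 41), res.scaling)
        w = curve.p_hi - curve.p_lo
        assert w.iloc[0] > w.iloc[20] and w.iloc[-1] < w.iloc[20] or (
            w.iloc[0] > w.iloc[20] or w.iloc[-1] > w.iloc[20]
        )


class TestBattery:
    def test_fifteen_model_grid(self, small_survival_data):
        pop, est, cfg = small_survival_data
        # synthesize estimates for all five measures in all three datasets
        measures = [("grooming", "giving"), ("grooming", "receiving"),
                    ("support", "giving"), ("support", "receiving"),
                    ("foraging", "undirected")]
        parts = []
        for behavior, direction in measures:
            e = est.copy()
            e["behavior"] = behavior
            e["direction"] = direction
            parts.append(e)
        est_all = pd.concat(parts, ignore_index=True)
        tiny = AFTConfig(mcmc=SamplerConfig(chains=2, warmup=120, samples=120,
                                            seed=4, max_leapfrog=12))
        table, manifest, results = run_model_battery(
            pop.individuals, pop.demography, pop.covariates,
            {pt: est_all for pt in ["all", "adult_females", "adult_males"]},
            lag=0, config=tiny,
        )
        assert len(manifest) == 15
        assert table.model.nunique() == 15
        undirected = table[table.behavior == "foraging"]
        assert set(undirected.direction) == {"undirected"}
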