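import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from whalehealth.data_model import ParameterSet, StandardisationConstants
from whalehealth.inference import MCMCConfig, PosteriorDraws
from whalehealth.posterior_analysis import (
    age_structure,
    aggregate_recovery,
    classification_metrics,
    effect_curves,
    effect_surface,
    missed_calving_count,
    recovery_report,
    summarize,
)

CST = StandardisationConstants(27.7, 1.5, 12.0, 8.0, 1650.0, 300.0, 214.0, 43.0)


def fake_draws(param_values: dict, n_draws=500, n_chains=2, rng=None, **latents):
    """PosteriorDraws with given per-parameter values (scalar or array)."""
    rng = rng or np.random.default_rng(0)
    names = ParameterSet.names()
    P = np.zeros((n_chains, n_draws, len(names)))
    for j, n in enumerate(names):
        v = param_values.get(n, 0.0)
        P[:, :, j] = np.broadcast_to(v, (n_chains, n_draws))
    return PosteriorDraws(param_names=names, params=P,
                          logpost=np.zeros((n_chains, n_draws)),
                          constants=CST, mcmc=MCMCConfig(), **latents)


class TestSummarize:
    def test_constant_draws(self):
        d = fake_draws({"beta_h": 1.0})
        out = summarize(d)
        assert out.loc["beta_h", "median"] == 1.0
        assert out.loc["beta_h", "q2.5"] == 1.0 == out.loc["beta_h", "q97.5"]
        assert out.loc["beta_h", "p_positive"] == 1.0

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(1)
        d = fake_draws({"gamma2": rng.normal(size=(2, 20000))}, n_draws=20000)
        out = summarize(d, names=["gamma2"])
        assert out.loc["gamma2", "median"] == pytest.approx(0.0, abs=0.05)
        assert out.loc["gamma2", "q2.5"] == pytest.approx(-1.96, abs=0.08)
        assert out.loc["gamma2", "q97.5"] == pytest.approx(1.96, abs=0.08)
        assert out.loc["gamma2", "p_positive"] == pytest.approx(0.5, abs=0.02)

    def test_empty_draws_rejected(self):
        d = fake_draws({}, n_draws=0)
        with pytest.raises(ValueError, match="empty"):
            summarize(d)


class TestEffectCurves:
    def test_zero_coefficients_flat_half(self):
        d = fake_draws({})
        out = effect_curves(d, "nutrition")
        np.testing.assert_allclose(out["median"], 0.5, atol=1e-12)
        np.testing.assert_allclose(out["q2.5"], 0.5, atol=1e-12)

    def test_degenerate_posterior_equals_logistic(self):
        d = fake_draws({"gamma1": -2.0, "gamma3": 1.36}, n_draws=10)
        grid = np.array([10.0, 12.0, 13.0])
        out = effect_curves(d, "length", grid=grid)
        expected = expit(-2.0 + 1.36 * (grid**3 - CST.L3_mean) / CST.L3_sd)
        np.testing.assert_allclose(out["median"], expected, atol=1e-12)

    def test_monotone_when_positive_length_effect(self):
        rng = np.random.default_rng(2)
        d = fake_draws({"gamma3": np.abs(rng.normal(1.4, 0.3, (2, 500)))})
        out = effect_curves(d, "length")
        assert (np.diff(out["median"]) > 0).all()
        assert ((out["q2.5"] <= out["median"]) & (out["median"] <= out["q97.5"])).all()

    def test_surface_shape_and_bounds(self):
        d = fake_draws({"gamma1": -1.0, "gamma2": 0.8, "gamma3": 1.36})
        surf = effect_surface(d)
        assert surf.shape == (40, 40)
        assert ((surf.values >= 0) & (surf.values <= 1)).all()


def _latent_draws_for(arrays, phi_fn, c_fn, n_draws=40):
    N, T = arrays.n_ind, arrays.n_years
    phi = np.zeros((2, n_draws, N, T), np.float32)
    c = np.zeros((2, n_draws, N, T + 1), np.int8)
    phi[:] = phi_fn(N, T)
    c[:] = c_fn(N, T)
    return {"phi_avail": phi, "c": c}


class TestClassification:
    def test_perfectly_separated(self, study_arrays):
        arrays, _ = study_arrays
        evid = arrays.k | arrays.elsewhere
        score = np.where(evid, 0.9, 0.05).astype(np.float32)

        def c_fn(N, T):
            c = np.zeros((N, T + 1), np.int8)
            c[:, :T] = evid
            return c
        lat = _latent_draws_for(arrays, lambda N, T: score, c_fn)
        d = fake_draws({}, n_draws=40, **lat)
        out = classification_metrics(d, arrays)
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 1.0
        assert out["auc"] == 1.0

    def test_random_scores_give_chance_auc(self, study_arrays):
        arrays, _ = study_arrays
        rng = np.random.default_rng(3)
        score = rng.uniform(0, 1, arrays.k.shape).astype(np.float32)

        def c_fn(N, T):
            c = np.zeros((N, T + 1), np.int8)
            c[:, :T] = arrays.k | arrays.elsewhere
            return c
        lat = _latent_draws_for(arrays, lambda N, T: score, c_fn)
        d = fake_draws({}, n_draws=40, **lat)
        out = classification_metrics(d, arrays)
        assert 0.3 < out["auc"] < 0.7

    def test_bad_threshold_rejected(self, study_arrays):
        arrays, _ = study_arrays
        d = fake_draws({})
        with pytest.raises(ValueError, match="threshold"):
            classification_metrics(d, arrays, threshold=1.5)


class TestMissedCalvings:
    def test_zero_when_every_calving_observed(self, study_arrays):
        arrays, _ = study_arrays
        evid = arrays.k | arrays.elsewhere

        def c_fn(N, T):
            c = np.zeros((N, T + 1), np.int8)
            c[:, :T] = evid
            return c
        lat = _latent_draws_for(arrays, lambda N, T: np.zeros(arrays.k.shape, np.float32), c_fn)
        d = fake_draws({}, n_draws=40, **lat)
        out = missed_calving_count(d, arrays)
        assert out["median"] == 0.0

    def test_bounds(self, study_arrays):
        arrays, truth = study_arrays

        def c_fn(N, T):
            return np.array(truth["c"], np.int8)
        lat = _latent_draws_for(arrays, lambda N, T: np.zeros(arrays.k.shape, np.float32), c_fn)
        d = fake_draws({}, n_draws=20, **lat)
        out = missed_calving_count(d, arrays)
        assert (out["samples"] >= 0).all()
        assert (out["samples"] <= arrays.n_ind * arrays.n_years).all()
        assert out["median"] == truth["n_missed_calvings"]


class TestAgeStructure:
    def test_small_cohort_bars(self):
        import pandas as pd
        from whalehealth.data_model import Dataset, ModelConfig
        cfg = ModelConfig(years=(2022, 2023, 2024))
        ind = pd.DataFrame({
            "individual_id": ["a", "b", "c"], "sex": ["female"] * 3,
            "known_age": [1, 1, 0], "min_age": [2.0, 2.0, 4.0],
            "age_prior_loc": [1.0, 1.0, 4.0], "age_prior_scale": [0.0, 0.0, 2.0],
            "first_year": [2022] * 3,
        })
        for y in cfg.years:
            ind[f"length_mean_{y}"] = [8.0, 8.0, 10.0]
            ind[f"length_sd_{y}"] = [0.2] * 3
        empty_b = pd.DataFrame(columns=["individual_id", "year",
                                        "days_before_season_end", "bai_mean", "bai_sd"])
        from whalehealth.data_model import FGC_COLUMNS, SIGHTING_COLUMNS
        ds = Dataset(individuals=ind, bai=empty_b,
                     fgc=pd.DataFrame(columns=FGC_COLUMNS),
                     sightings=pd.DataFrame(columns=SIGHTING_COLUMNS), config=cfg)
        out = age_structure(ds, 2023)  # ages {2, 2, 5}
        counts = out["counts"].sum(axis=1)
        assert counts.loc[2] == 2 and counts.loc[5] == 1

    def test_kde_integrates_to_one(self, study_arrays):
        arrays, _ = study_arrays
        grid = np.linspace(-30, 80, 4000)
        out = age_structure(arrays, 2023, grid=grid)
        assert np.trapezoid(out["kde_density"], grid) == pytest.approx(1.0, abs=1e-6)

    def test_matches_generator_age_distribution(self, study_arrays):
        arrays, truth = study_arrays
        out = age_structure(arrays, 2023)
        est = np.asarray(out["ages"], float)
        tru = (np.asarray(truth["age_entry"], float)
               + (2023 - 2016) - arrays.entry_t)
        bins = [0, 5, 10, 15, 20, 30, 60]
        h_est, _ = np.histogram(est, bins)
        h_tru, _ = np.histogram(tru, bins)
        from scipy.stats import chisquare
        exp = np.maximum(h_tru, 1) * h_est.sum() / np.maximum(h_tru, 1).sum()
        p = chisquare(h_est, exp).pvalue
        assert p > 0.01


class TestRecoveryReport:
    def test_centred_draws_zero_bias_full_coverage(self):
        truth = {"params": {"beta_h": 0.4, "gamma3": 1.36}}
        rng = np.random.default_rng(5)
        d = fake_draws({"beta_h": 0.4 + 0.01 * rng.normal(size=(2, 500)),
                        "gamma3": 1.36 + 0.01 * rng.normal(size=(2, 500))})
        rep = recovery_report(d, truth)
        assert rep["covered"].all()
        assert abs(rep.loc["beta_h", "bias"]) < 0.01

    def test_truth_outside_draws_flagged(self):
        d = fake_draws({"beta_h": 0.0})
        rep = recovery_report(d, {"params": {"beta_h": 5.0}})
        assert not rep.loc["beta_h", "covered"]

    def test_name_mismatch_raises(self):
        d = fake_draws({})
        with pytest.raises(KeyError, match="not in the fitted"):
            recovery_report(d, {"params": {"not_a_param": 1.0}})

    def test_aggregation(self):
        truth = {"params": {"beta_h": 0.4}}
        reps = [recovery_report(fake_draws({"beta_h": 0.4}), truth),
                recovery_report(fake_draws({"beta_h": 9.0}), truth)]
        agg = aggregate_recovery(reps)
        assert agg.loc["beta_h", "coverage"] == 0.5
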