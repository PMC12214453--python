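import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest, norm

from whalehealth.data_model import ParameterSet, StandardisationConstants
from whalehealth.inference import (
    MCMCConfig,
    adaptive_rwm,
    brute_force_marginal,
    diagnostics,
    enumerate_reproduction_sequences,
    importance_marginal,
    run_mcmc,
)

from conftest import make_toy


class TestEnumeration:
    def test_two_year_window_hand_enumeration(self):
        # boundary pregnancy fixed to 0; phi = 0.5 everywhere
        seqs, probs = enumerate_reproduction_sequences([0.5, 0.5], boundary_p=0.0)
        assert len(seqs) == 3
        table = {tuple(s): p for s, p in zip(seqs, probs)}
        # no calving; calve year 1; calve year 2 (which frees year 1's draw)
        assert table[(0, 0, 0)] == pytest.approx(0.25)
        assert table[(1, 0, 0)] == pytest.approx(0.25)
        assert table[(0, 1, 0)] == pytest.approx(0.50)

    def test_observed_calf_clamps_neighbourhood(self):
        forced = np.zeros(6, bool)
        forced[2] = True
        seqs, probs = enumerate_reproduction_sequences(
            np.full(5, 0.3), 0.05, forced=forced)
        assert (seqs[:, 2] == 1).all()
        assert (seqs[:, 1] == 0).all() and (seqs[:, 3] == 0).all()

    def test_probabilities_normalised(self):
        seqs, probs = enumerate_reproduction_sequences(np.full(8, 0.2), 0.05)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_window_cap_error_mentions_fallback(self):
        with pytest.raises(ValueError, match="Metropolis fallback"):
            enumerate_reproduction_sequences(np.full(12, 0.2), 0.05)

    @settings(max_examples=40, deadline=None)
    @given(
        phi=st.lists(st.floats(0.01, 0.9), min_size=2, max_size=7),
        forced_at=st.integers(0, 6),
        boundary=st.floats(0.01, 0.2),
    )
    def test_support_properties(self, phi, forced_at, boundary):
        phi = np.asarray(phi)
        T = len(phi)
        forced = np.zeros(T + 1, bool)
        forced[min(forced_at, T - 1)] = True
        seqs, probs = enumerate_reproduction_sequences(phi, boundary, forced=forced)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert not ((seqs[:, :-1] == 1) & (seqs[:, 1:] == 1)).any()
        assert (seqs[:, forced] == 1).all()


class TestSamplerBasics:
    def test_zero_iteration_returns_initial_state(self, study_arrays):
        arrays, _ = study_arrays
        draws = run_mcmc(arrays, MCMCConfig(n_chains=1, n_iterations=0, n_burnin=0))
        assert draws.n_draws == 1
        assert np.isfinite(draws.logpost).all()

    def test_seeded_determinism(self, toy_instance):
        ds, _, _ = toy_instance
        arrays = ds.to_arrays()
        cfg = MCMCConfig(n_chains=2, n_iterations=40, n_burnin=10, seed=5)
        a = run_mcmc(arrays, cfg)
        b = run_mcmc(arrays, cfg)
        np.testing.assert_array_equal(a.params, b.params)
        np.testing.assert_array_equal(a.c, b.c)

    def test_constraints_hold_throughout_sampling(self, toy_instance):
        ds, _, _ = toy_instance
        draws = run_mcmc(ds.to_arrays(),
                         MCMCConfig(n_chains=1, n_iterations=60, n_burnin=10,
                                    seed=2, debug_check_constraints=True))
        assert np.isfinite(draws.logpost).all()

    def test_bad_initial_parameters_name_component(self, toy_instance):
        ds, _, scn = toy_instance
        bad = scn.params.replace(nu_s=1e-300, chi_h=0.5, chi_s=0.3)
        with pytest.raises(RuntimeError, match="fgc"):
            run_mcmc(ds.to_arrays(),
                     MCMCConfig(n_chains=1, n_iterations=5, n_burnin=1),
                     params=bad)


class TestElementaryUpdate:
    def test_conjugate_normal_posterior_recovered(self):
        """The scalar adaptive RWM (the sampler's elementary move) must have
        the analytic posterior of the conjugate Normal case as its
        stationary distribution (KS < 0.05)."""
        mu, sd = 1.2, 0.7
        rng = np.random.default_rng(8)
        x = adaptive_rwm(lambda v: norm.logpdf(v, mu, sd), 0.0, 20_000, rng)
        stat = kstest(x[5000::3], lambda v: norm.cdf(v, mu, sd)).statistic
        assert stat < 0.05


class TestDiagnostics:
    def test_identical_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        d = diagnostics({"p": np.stack([x, x])})
        assert d.loc["p", "rhat"] < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        d = diagnostics({"p": np.stack([rng.normal(0, 1, 800),
                                        rng.normal(5, 1, 800)])})
        assert d.loc["p", "rhat"] > 1.2
        assert not d.loc["p", "passed"]

    def test_ar1_effective_sample_size_closed_form(self):
        rho, n = 0.5, 20_000
        rng = np.random.default_rng(42)
        chains = []
        for _ in range(2):
            e = rng.normal(size=n)
            x = np.empty(n)
            x[0] = e[0]
            for i in range(1, n):
                x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * e[i]
            chains.append(x)
        d = diagnostics({"p": np.stack(chains)})
        expected = 2 * n * (1 - rho) / (1 + rho)
        assert d.loc["p", "ess"] == pytest.approx(expected, rel=0.2)

    def test_single_chain_refused(self):
        with pytest.raises(ValueError, match="2 chains"):
            diagnostics({"p": np.zeros((1, 100))})


class TestBruteForceOracle:
    def test_no_observations_marginal_is_one(self):
        ds, truth, scn = make_toy()
        arrays = ds.to_arrays()
        # strip every observation channel
        arrays.b_i = arrays.b_i[:0]
        arrays.b_t = arrays.b_t[:0]
        arrays.b_d = arrays.b_d[:0]
        arrays.b_mean = arrays.b_mean[:0]
        arrays.b_sd = arrays.b_sd[:0]
        for name in ("f_i", "f_t", "f_day", "f_fgc"):
            setattr(arrays, name, getattr(arrays, name)[:0])
        arrays.f_m = arrays.f_m[:0]
        arrays.f_cens = arrays.f_cens[:0]
        arrays.f_lod = arrays.f_lod[:0]
        arrays.e[...] = False
        arrays.k[...] = False
        arrays.elsewhere[...] = False
        cst = StandardisationConstants.from_dict(truth["constants"])
        lm = brute_force_marginal(arrays, scn.params, cst, 161, 61, 41)
        assert lm == pytest.approx(0.0, abs=1e-8)

    def test_grid_halving_self_check(self, toy_instance):
        ds, truth, scn = toy_instance
        arrays = ds.to_arrays()
        cst = StandardisationConstants.from_dict(truth["constants"])
        lm1 = brute_force_marginal(arrays, scn.params, cst, 121, 121, 81)
        lm2 = brute_force_marginal(arrays, scn.params, cst, 241, 241, 161)
        assert abs(lm1 - lm2) < 1e-6

    def test_preconditions_enforced(self, toy_instance):
        ds, truth, scn = toy_instance
        arrays = ds.to_arrays()
        cst = StandardisationConstants.from_dict(truth["constants"])
        with pytest.raises(ValueError, match="gamma4"):
            brute_force_marginal(arrays, scn.params.replace(gamma4=-0.5), cst)
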