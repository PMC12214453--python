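import numpy as np
import pytest

from whalehealth import model_density as md
from whalehealth.data_model import ParameterSet, StandardisationConstants
from whalehealth.model_density import (
    COMPONENTS,
    PARAM_COMPONENTS,
    calf_detection_logpmf,
    calving_logpmf,
    calving_probability,
    component_logpdfs,
    bai_logpdf,
    fgc_logpdf,
    hard_constraint_violations,
    joint_logposterior,
    nutritional_logpdf,
    residual_stress,
    stress_logpdf,
)

from conftest import context_from_truth, make_toy

MODE = -0.5 * np.log(2 * np.pi)  # standard-normal log-density at the mode


def toy_context():
    ds, truth, _ = make_toy()
    return context_from_truth(ds.to_arrays(), truth)


def _mature_female_cell(ctx, min_t=1):
    """(i, t) with a mature female at t and t-1 inside the window."""
    mat = md.maturity_mask(ctx)
    for i, t in zip(*np.nonzero(mat)):
        if t >= min_t and t >= ctx.data.entry_t[i] + 1:
            return int(i), int(t)
    raise AssertionError("toy instance lost its mature female")


class TestNutritional:
    def test_scalar_oracle_value(self):
        ctx = toy_context()
        ctx.constants = StandardisationConstants(27.0, 1.0, 12.0, 8.0, 1650.0, 300.0, 214.0, 43.0)
        ctx.params = ctx.params.replace(beta_h=0.40, sigma_h=1.0)
        i, t = 0, 1
        ctx.state.h[i, t - 1] = 28.0     # h* lag = 1.0
        ctx.state.H[t] = 27.0
        ctx.state.h[i, t] = 28.0         # mean 27.4, residual 0.6
        assert nutritional_logpdf(ctx, i, t) == pytest.approx(-1.0989, abs=1e-4)

    def test_mode_value_and_degenerate_sd(self):
        ctx = toy_context()
        ctx.params = ctx.params.replace(beta_h=0.0, sigma_h=1.0)
        i, t = 0, 1
        ctx.state.h[i, t] = ctx.state.H[t]
        assert nutritional_logpdf(ctx, i, t) == pytest.approx(MODE, abs=1e-10)
        ctx.params = ctx.params.replace(sigma_h=1e-12)
        ctx.state.h[i, t] = ctx.state.H[t] + 1.0
        assert nutritional_logpdf(ctx, i, t) < -1e20  # -> -inf as sd -> 0

    def test_out_of_range_index(self):
        ctx = toy_context()
        with pytest.raises(IndexError):
            nutritional_logpdf(ctx, 0, ctx.data.n_years + 3)


class TestBAI:
    def test_standard_normal_mode(self):
        ctx = toy_context()
        o = 0
        i, t = ctx.data.b_i[o], ctx.data.b_t[o]
        ctx.data.b_d[o] = 0.0
        ctx.data.b_sd[o] = 0.8
        ctx.params = ctx.params.replace(nu_h=0.6, delta1=0.0, delta2=0.0)
        ctx.state.c[i] = 0  # P = 0
        ctx.data.b_mean[o] = ctx.state.h[i, t]
        assert bai_logpdf(ctx, o) == pytest.approx(MODE, abs=1e-10)  # total SD 1.0

    def test_day_and_pregnancy_shift(self):
        # d=30 with delta1=-0.016 and pregnancy with delta2=0.63: net +0.15
        ctx = toy_context()
        o = 0
        i, t = ctx.data.b_i[o], ctx.data.b_t[o]
        ctx.data.b_d[o] = 30.0
        ctx.params = ctx.params.replace(delta1=-0.016, delta2=0.63, nu_h=0.6)
        ctx.data.b_sd[o] = 0.8
        ctx.state.c[i] = 0
        ctx.state.c[i, t + 1] = 1    # pregnant in year t
        ctx.data.b_mean[o] = ctx.state.h[i, t] + 0.15
        assert bai_logpdf(ctx, o) == pytest.approx(MODE, abs=1e-10)

    def test_wider_sd_lowers_density_at_mode(self):
        ctx = toy_context()
        o = 0
        i, t = ctx.data.b_i[o], ctx.data.b_t[o]
        ctx.state.c[i] = 0
        ctx.data.b_d[o] = 0.0
        ctx.params = ctx.params.replace(delta1=0.0, delta2=0.0)
        ctx.data.b_mean[o] = ctx.state.h[i, t]
        lp1 = bai_logpdf(ctx, o)
        ctx.data.b_sd[o] *= 2
        assert bai_logpdf(ctx, o) < lp1


class TestStressAndFGC:
    def test_sex_effect_shifts_mean(self):
        ctx = toy_context()
        ctx.params = ctx.params.replace(beta_s3=0.26)
        unk = np.nonzero(ctx.data.sex_code == -1)[0]
        i = int(unk[0])
        t = int(ctx.data.entry_t[i]) + 1
        ctx.state.g[i] = 0
        lp_male = stress_logpdf(ctx, i, t)
        ctx.state.g[i] = 1
        lp_female = stress_logpdf(ctx, i, t)
        s, S = ctx.state.s[i, t], ctx.state.S[t]
        # density ratio corresponds to a +0.26 mean shift
        mean_m = s - (lp_male - MODE)  # not invertible directly; compare pdfs
        p = ctx.params
        base = (S + p.beta_s1 * md.h_star_lag(ctx)[i, t]
                + p.beta_s2 * md.a_star(ctx)[i, t])
        assert lp_male == pytest.approx(float(md.norm_logpdf(s, base, p.sigma_s)), abs=1e-10)
        assert lp_female == pytest.approx(float(md.norm_logpdf(s, base + 0.26, p.sigma_s)), abs=1e-10)

    def test_fgc_exp_link_oracle(self):
        ctx = toy_context()
        o = 0
        i, t = ctx.data.f_i[o], ctx.data.f_t[o]
        ctx.params = ctx.params.replace(zeta1=0.30, zeta2=0.0, zeta3=0.0,
                                        zeta4=-0.003, nu_s=5.0)
        ctx.state.s[i, t] = 3.0
        ctx.state.m[o] = [1.0, 0.0, 0.0]
        ctx.data.f_day[o] = 200.0
        expected_mean = np.exp(2.7)  # 14.880
        assert expected_mean == pytest.approx(14.880, abs=1e-3)
        assert fgc_logpdf(ctx, o) == pytest.approx(
            float(md.norm_logpdf(ctx.data.f_fgc[o], expected_mean, 5.0)), abs=1e-10)

    def test_fgc_mean_positive_for_any_finite_g(self):
        ctx = toy_context()
        ctx.state.s[...] = -40.0
        lp = COMPONENTS["fgc"](ctx)
        assert np.isfinite(lp)  # mean exp(G) > 0 keeps the density proper


class TestResidualStress:
    def test_zero_at_expectation_and_linearity(self):
        ctx = toy_context()
        i, t = 0, 1
        p, cst = ctx.params, ctx.constants
        expect = (p.lam_s + p.beta_s1 * md.h_star_lag(ctx)[i, t]
                  + p.beta_s2 * md.a_star(ctx)[i, t]
                  + p.beta_s3 * md.sex_covariate(ctx)[i])
        ctx.state.s[i, t] = expect
        assert residual_stress(ctx, i, t) == pytest.approx(0.0, abs=1e-12)
        ctx.state.s[i, t] = expect + 1.0
        assert residual_stress(ctx, i, t) == pytest.approx(1.0, abs=1e-12)

    def test_population_residual_tracks_year_deviation(self):
        # chi_s -> 0 makes S_t == lam_s, so the mean residual -> process noise
        ctx = toy_context()
        ctx.state.S[:] = ctx.params.lam_s
        r = md.residual_stress_matrix(ctx)
        exp_mean = (ctx.state.s - (r + ctx.state.s - r)).mean()  # structural zero
        assert abs(r[ctx.data.active].mean()) < 1.0  # noise-scale, no systematic offset


class TestCalving:
    def test_inverse_logit_of_half_is_half(self):
        ctx = toy_context()
        ctx.params = ctx.params.replace(gamma1=0.0, gamma2=0.0, gamma3=0.0, gamma4=0.0)
        i, t = _mature_female_cell(ctx)
        assert calving_probability(ctx, i, t) == pytest.approx(0.5)

    def test_intercept_048_gives_0618(self):
        ctx = toy_context()
        ctx.params = ctx.params.replace(gamma1=0.48, gamma2=0.0, gamma3=0.0, gamma4=0.0)
        i, t = _mature_female_cell(ctx)
        assert calving_probability(ctx, i, t) == pytest.approx(0.6178, abs=1e-4)

    def test_monotone_in_cubed_length(self):
        ctx = toy_context()
        ctx.params = ctx.params.replace(gamma1=0.0, gamma2=0.0, gamma3=1.36, gamma4=0.0)
        i, t = _mature_female_cell(ctx)
        probs = []
        for L in np.linspace(10.0, 13.0, 7):
            ctx.state.L[i, t - 1] = L
            probs.append(calving_probability(ctx, i, t))
        assert np.all(np.diff(probs) > 0)

    def test_male_raises(self):
        ctx = toy_context()
        male = int(np.nonzero(ctx.state.g == 0)[0][0])
        t = int(ctx.data.entry_t[male]) + 1
        with pytest.raises(ValueError, match="mature female"):
            calving_probability(ctx, male, t)

    def test_pmf_support_and_scalar_value(self):
        ctx = toy_context()
        i, t = _mature_female_cell(ctx)
        ctx.params = ctx.params.replace(
            gamma1=float(np.log(0.3 / 0.7)), gamma2=0.0, gamma3=0.0, gamma4=0.0)
        ctx.state.c[i] = 0
        ctx.state.c[i, t] = 1
        ctx.state.c[i, t + 1] = 0
        assert calving_logpmf(ctx, i, t) == pytest.approx(np.log(0.3), abs=1e-10)
        ctx.state.c[i, t + 1] = 1    # pregnant: calving impossible
        assert calving_logpmf(ctx, i, t) == -np.inf
        ctx.state.c[i, t] = 0
        assert calving_logpmf(ctx, i, t) == pytest.approx(0.0, abs=1e-12)


class TestDetection:
    def test_no_encounter_is_certain_nonobservation(self):
        ctx = toy_context()
        d = ctx.data
        i, t = next(zip(*np.nonzero(~d.e & d.active)))
        assert calf_detection_logpmf(ctx, int(i), int(t)) == 0.0

    def test_complement_of_mean_detection(self):
        ctx = toy_context()
        i, t = _mature_female_cell(ctx)
        d = ctx.data
        d.e[i, t] = True
        d.k[i, t] = False
        d.first_day[i, t] = ctx.constants.f_mean  # standardised day = 0
        ctx.params = ctx.params.replace(eta1=0.48, eta2=-1.80)
        ctx.state.c[i] = 0
        ctx.state.c[i, t] = 1
        assert calf_detection_logpmf(ctx, i, t) == pytest.approx(np.log(1 - 0.6178), abs=1e-3)
        d.k[i, t] = True
        assert calf_detection_logpmf(ctx, i, t) == pytest.approx(np.log(0.6178), abs=1e-3)


class TestJoint:
    def test_additivity(self, truth_context):
        comps = component_logpdfs(truth_context)
        total = joint_logposterior(truth_context)
        assert np.isfinite(total)
        assert total == pytest.approx(sum(comps.values()), rel=1e-12)

    def test_impossible_configuration_is_minus_inf(self, truth_context):
        ctx = truth_context
        i, t = _mature_female_cell(ctx)
        ctx.state.c[i, t] = 1
        ctx.state.c[i, t + 1] = 1
        assert joint_logposterior(ctx) == -np.inf
        assert hard_constraint_violations(ctx)["consecutive_calving"] >= 1

    def test_truth_state_satisfies_all_constraints(self, truth_context):
        assert all(v == 0 for v in hard_constraint_violations(truth_context).values())

    @pytest.mark.parametrize("name", ParameterSet.names())
    def test_parameter_dependency_map_complete(self, truth_context, name):
        """Central finite differences of the joint match the differences of
        the components registered for the parameter — a missing dependency
        would silently corrupt the sampler's scalar updates."""
        ctx = truth_context
        eps = 1e-4 * max(1.0, abs(getattr(ctx.params, name)))
        comps = tuple(PARAM_COMPONENTS[name]) + ("param_prior",)

        def at(v, fn):
            ctx.params = ctx.params.replace(**{name: v})
            return fn()

        v0 = getattr(ctx.params, name)
        d_joint = (at(v0 + eps, lambda: joint_logposterior(ctx))
                   - at(v0 - eps, lambda: joint_logposterior(ctx)))
        d_comp = (at(v0 + eps, lambda: sum(COMPONENTS[c](ctx) for c in comps))
                  - at(v0 - eps, lambda: sum(COMPONENTS[c](ctx) for c in comps)))
        ctx.params = ctx.params.replace(**{name: v0})
        assert d_joint == pytest.approx(d_comp, rel=1e-6, abs=1e-8)
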