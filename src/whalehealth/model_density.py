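"""Exact log-density kernels for every model component.

The model couples, per individual ``i`` and study year ``t``:

* a latent nutritional state ``h[i,t] = H[t] + beta_h * h*[i,t-1] + eps``
  (no AR term at an animal's first modelled year), observed through BAI
  measurements ``bai ~ N(h + delta1*d + delta2*P, sqrt(nu_h^2 + bai_sd^2))``
  (the intermediate per-measurement mean is convolved out analytically);
* a latent stress state ``s[i,t] = S[t] + beta_s1*h*[i,t-1] + beta_s2*a*[i,t]
  + beta_s3*g[i] + ups`` observed through faecal glucocorticoids
  ``fgc ~ N(exp(G), nu_s)`` with ``G = s + zeta.m + zeta4*y``;
* for mature females, a calving indicator
  ``c[i,t] ~ Bernoulli(phi[i,t] * (1 - P[i,t]))`` with
  ``logit phi = gamma1 + gamma2*h*[t-1] + gamma3*L3*[t-1] + gamma4*r[t-2]``
  and the pregnancy link ``P[i,t-1] = c[i,t]``, which enforces a 2-year
  minimum inter-calf interval; and
* a calf-detection channel ``k ~ Bernoulli(c * p * e)`` with
  ``logit p = eta1 + eta2 * f*``.

``r`` is the residual stress state: the deviation of ``s`` from its
demographic-class expectation (the year-effect *mean* ``lam_s`` is
subtracted, not ``S[t]``, so yearly deviations remain part of the residual).

Every kernel is a pure function of a :class:`DensityContext`; the sampler
and the brute-force oracle both consume these functions, so there is a
single definition of the model.  Hard support violations (calving while
pregnant, calf seen without a calving event, age below the known minimum)
return ``-inf`` rather than raising, so Metropolis proposals into invalid
configurations are simply rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.special import expit, log_ndtr
from scipy.stats import halfnorm, norm

from .data_model import ModelArrays, ParameterSet, StandardisationConstants

__all__ = [
    "NormalPrior",
    "HalfNormalPrior",
    "default_priors",
    "LatentState",
    "DensityContext",
    "COMPONENTS",
    "PARAM_COMPONENTS",
    "joint_logposterior",
    "component_logpdfs",
    "nutritional_logpdf",
    "bai_logpdf",
    "stress_logpdf",
    "fgc_logpdf",
    "residual_stress",
    "calving_probability",
    "calving_logpmf",
    "calf_detection_logpmf",
    "hard_constraint_violations",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def norm_logpdf(x, mu, sd):
    """Vectorised Normal log-density (−inf off-support as sd -> 0)."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = (np.asarray(x, float) - mu) / sd
        return -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI


def bernoulli_logpmf(x, p):
    with np.errstate(divide="ignore"):
        return np.where(np.asarray(x, float) > 0.5, np.log(p), np.log1p(-np.asarray(p, float)))


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalPrior:
    mu: float
    sd: float

    def logpdf(self, x):
        return norm_logpdf(x, self.mu, self.sd)

    def cdf(self, x):
        return norm.cdf(x, self.mu, self.sd)

    def rvs(self, rng, size=None):
        return rng.normal(self.mu, self.sd, size=size)

    @property
    def mean(self):
        return self.mu

    def to_dict(self):
        return {"family": "normal", "mu": self.mu, "sd": self.sd}


@dataclass(frozen=True)
class HalfNormalPrior:
    scale: float

    def logpdf(self, x):
        x = np.asarray(x, float)
        return np.where(x > 0, norm_logpdf(x, 0.0, self.scale) + np.log(2.0), -np.inf)

    def cdf(self, x):
        return halfnorm.cdf(x, scale=self.scale)

    def rvs(self, rng, size=None):
        return np.abs(rng.normal(0.0, self.scale, size=size))

    @property
    def mean(self):
        return self.scale * np.sqrt(2.0 / np.pi)

    def to_dict(self):
        return {"family": "halfnormal", "scale": self.scale}


def prior_from_dict(d: Mapping) -> NormalPrior | HalfNormalPrior:
    fam = d["family"]
    if fam == "normal":
        return NormalPrior(float(d["mu"]), float(d["sd"]))
    if fam == "halfnormal":
        return HalfNormalPrior(float(d["scale"]))
    raise ValueError(f"unknown prior family {fam!r}")


def default_priors() -> dict[str, NormalPrior | HalfNormalPrior]:
    """Weakly-informative defaults on each parameter's natural scale.

    Coefficients get Normal(0, 10); process/observation SDs Half-Normal(5);
    the two intercept-scale means sit on the BAI and log-fGC scales; the fGC
    measurement SD (natural concentration scale, typically tens of units)
    gets a wider Half-Normal(20).
    """
    pri: dict[str, NormalPrior | HalfNormalPrior] = {
        "lam_h": NormalPrior(25.0, 10.0),
        "lam_s": NormalPrior(2.0, 5.0),
        "nu_s": HalfNormalPrior(20.0),
    }
    for name in ("chi_h", "sigma_h", "nu_h", "chi_s", "sigma_s"):
        pri[name] = HalfNormalPrior(5.0)
    # logit-scale slopes: Normal(0, 10) would pile mass on probabilities of
    # exactly 0/1, so these get the usual weakly-informative logit scale
    for name in ("gamma2", "gamma3", "gamma4", "eta2"):
        pri[name] = NormalPrior(0.0, 2.5)
    # the two level parameters of the partially-observed calving/detection
    # block sit on a likelihood ridge (hidden events are nearly free), so
    # they carry the model's biological prior knowledge: calving is rare in
    # this population (observed rates ~0.1/yr among mature females; minimum
    # 2-year inter-calf interval), and a calf accompanying an encountered
    # mother is likely to be seen over a season of repeated surveys
    pri["gamma1"] = NormalPrior(-2.0, 1.5)
    pri["eta1"] = NormalPrior(1.0, 1.0)
    for name in ParameterSet.names():
        pri.setdefault(name, NormalPrior(0.0, 10.0))
    return pri


# --------------------------------------------------------------------------
# latent state and context
# --------------------------------------------------------------------------


@dataclass
class LatentState:
    """One full configuration of all latent / imputed quantities.

    ``c`` has ``T+1`` columns: column ``t < T`` is the calving indicator in
    study year ``t``; the final column is the post-study boundary calving
    event, equal to pregnancy status in the last year (prior Bernoulli with
    the configured boundary probability).  ``P[:, t] = c[:, t+1]``.
    ``m`` carries the log-hormone covariates with imputed values substituted
    in the censored slots.
    """

    H: np.ndarray            # (T,)
    S: np.ndarray            # (T,)
    h: np.ndarray            # (N,T)
    s: np.ndarray            # (N,T)
    L: np.ndarray            # (N,T)
    age_entry: np.ndarray    # (N,) age in entry year
    g: np.ndarray            # (N,) int 0/1, imputed where sex unknown
    c: np.ndarray            # (N,T+1) int8
    m: np.ndarray            # (nobs,3)

    @property
    def P(self) -> np.ndarray:
        return self.c[:, 1:]

    def copy(self) -> "LatentState":
        return LatentState(**{f.name: getattr(self, f.name).copy()
                              for f in dataclasses.fields(self)})


@dataclass
class DensityContext:
    """Bundles data, latent state, parameters, constants and priors."""

    data: ModelArrays
    state: LatentState
    params: ParameterSet
    constants: StandardisationConstants
    priors: Mapping[str, NormalPrior | HalfNormalPrior] = field(default_factory=default_priors)

    def replace(self, **kw) -> "DensityContext":
        return dataclasses.replace(self, **kw)


# -- covariate helpers ------------------------------------------------------


def _lag_valid(data: ModelArrays, lag: int = 1) -> np.ndarray:
    """(N,T) mask: True where t - lag is inside the animal's window."""
    return np.arange(data.n_years)[None, :] - lag >= data.entry_t[:, None]


def h_star_lag(ctx: DensityContext) -> np.ndarray:
    """Standardised lagged nutritional state; 0 (the mean) where the lag
    falls before an animal's first modelled year."""
    st, c = ctx.state, ctx.constants
    out = np.zeros_like(st.h)
    out[:, 1:] = (st.h[:, :-1] - c.h_mean) / c.h_sd
    return np.where(_lag_valid(ctx.data), out, 0.0)


def a_star(ctx: DensityContext) -> np.ndarray:
    ages = ctx.data.ages(ctx.state.age_entry)
    return (ages - ctx.constants.age_mean) / ctx.constants.age_sd


def L3_star_lag(ctx: DensityContext) -> np.ndarray:
    st, c = ctx.state, ctx.constants
    out = np.zeros_like(st.L)
    out[:, 1:] = (st.L[:, :-1] ** 3 - c.L3_mean) / c.L3_sd
    return np.where(_lag_valid(ctx.data), np.nan_to_num(out), 0.0)


def sex_covariate(ctx: DensityContext) -> np.ndarray:
    return (ctx.state.g == 1).astype(float) * ctx.data.config.female_code


def residual_stress_matrix(ctx: DensityContext) -> np.ndarray:
    """r[i,t] = s[i,t] − (lam_s + beta_s1 h*[t−1] + beta_s2 a*[t] + beta_s3 g)."""
    p = ctx.params
    base = ctx.state.S[None, :] if ctx.data.config.residual_uses_year_effect else p.lam_s
    expect = (base + p.beta_s1 * h_star_lag(ctx) + p.beta_s2 * a_star(ctx)
              + p.beta_s3 * sex_covariate(ctx)[:, None])
    return ctx.state.s - expect


def residual_stress_lagged(ctx: DensityContext) -> np.ndarray:
    lag = ctx.data.config.stress_lag
    r = residual_stress_matrix(ctx)
    out = np.zeros_like(r)
    out[:, lag:] = r[:, :-lag]
    return np.where(_lag_valid(ctx.data, lag), out, 0.0)


def maturity_mask(ctx: DensityContext) -> np.ndarray:
    """(N,T) True for active mature-female cells."""
    ages = ctx.data.ages(ctx.state.age_entry)
    return (ctx.state.g == 1)[:, None] & (ages >= ctx.data.config.maturity_age) & ctx.data.active


def calving_probability_matrix(ctx: DensityContext) -> np.ndarray:
    p = ctx.params
    lin = (p.gamma1 + p.gamma2 * h_star_lag(ctx) + p.gamma3 * L3_star_lag(ctx))
    if ctx.data.config.use_stress_in_calving:
        lin = lin + p.gamma4 * residual_stress_lagged(ctx)
    return expit(lin)


def first_day_covariate(ctx: DensityContext) -> np.ndarray:
    fd = ctx.data.first_day
    if ctx.data.config.standardise_first_day:
        return (fd - ctx.constants.f_mean) / ctx.constants.f_sd
    return fd


# --------------------------------------------------------------------------
# components
# --------------------------------------------------------------------------


def _reduce(values: np.ndarray, mask: np.ndarray, ind_index: np.ndarray | None,
            n_ind: int, per_individual: bool):
    """Sum masked values, either globally or grouped by individual."""
    if values.ndim == 2:  # (N,T) grids
        v = np.where(mask, values, 0.0)
        return v.sum(axis=1) if per_individual else float(v.sum())
    v = np.where(mask, values, 0.0)
    if per_individual:
        return np.bincount(ind_index, weights=v, minlength=n_ind)
    return float(v.sum())


def year_effects_logpdf(ctx: DensityContext, per_individual: bool = False):
    p = ctx.params
    lp = (norm_logpdf(ctx.state.H, p.lam_h, p.chi_h).sum()
          + norm_logpdf(ctx.state.S, p.lam_s, p.chi_s).sum())
    if per_individual:
        return np.zeros(ctx.data.n_ind)
    return float(lp)


def nutrition_process_logpdf(ctx: DensityContext, per_individual: bool = False):
    p, st, d = ctx.params, ctx.state, ctx.data
    mean = st.H[None, :] + p.beta_h * h_star_lag(ctx)
    lp = norm_logpdf(st.h, mean, p.sigma_h)
    return _reduce(lp, d.active, None, d.n_ind, per_individual)


def stress_process_logpdf(ctx: DensityContext, per_individual: bool = False):
    p, st, d = ctx.params, ctx.state, ctx.data
    mean = (st.S[None, :] + p.beta_s1 * h_star_lag(ctx) + p.beta_s2 * a_star(ctx)
            + p.beta_s3 * sex_covariate(ctx)[:, None])
    lp = norm_logpdf(st.s, mean, p.sigma_s)
    return _reduce(lp, d.active, None, d.n_ind, per_individual)


def bai_obs_logpdf(ctx: DensityContext, per_individual: bool = False):
    p, st, d = ctx.params, ctx.state, ctx.data
    P = st.P[d.b_i, d.b_t].astype(float)
    mean = st.h[d.b_i, d.b_t] + p.delta1 * d.b_d + p.delta2 * P
    sd = np.sqrt(p.nu_h**2 + d.b_sd**2)
    lp = norm_logpdf(d.b_mean, mean, sd)
    return _reduce(lp, np.ones_like(lp, bool), d.b_i, d.n_ind, per_individual)


def fgc_obs_logpdf(ctx: DensityContext, per_individual: bool = False):
    p, st, d = ctx.params, ctx.state, ctx.data
    y = d.f_day - (np.mean(d.f_day) if d.config.center_sampling_day and len(d.f_day) else 0.0)
    G = (st.s[d.f_i, d.f_t] + p.zeta1 * st.m[:, 0] + p.zeta2 * st.m[:, 1]
         + p.zeta3 * st.m[:, 2] + p.zeta4 * y)
    lp = norm_logpdf(d.f_fgc, np.exp(G), p.nu_s)
    return _reduce(lp, np.ones_like(lp, bool), d.f_i, d.n_ind, per_individual)


def length_logpdf(ctx: DensityContext, per_individual: bool = False):
    d, st = ctx.data, ctx.state
    mask = d.active & np.isfinite(d.L_mean)
    lp = norm_logpdf(st.L, np.nan_to_num(d.L_mean), np.where(mask, d.L_sd, 1.0))
    return _reduce(np.nan_to_num(lp, nan=0.0, neginf=-np.inf), mask, None,
                   d.n_ind, per_individual)


def age_logpdf(ctx: DensityContext, per_individual: bool = False):
    """Truncated-Normal prior on the entry-year age of unknown-age animals."""
    d, st = ctx.data, ctx.state
    unk = ~d.known_age
    z_min = (d.min_age - d.age_loc) / np.where(d.age_scale > 0, d.age_scale, 1.0)
    lp = (norm_logpdf(st.age_entry, d.age_loc, np.where(d.age_scale > 0, d.age_scale, 1.0))
          - np.log1p(-np.exp(log_ndtr(z_min))))
    lp = np.where(st.age_entry >= d.min_age, lp, -np.inf)
    lp = np.where(unk, lp, np.where(st.age_entry >= d.min_age, 0.0, -np.inf))
    return lp if per_individual else float(lp.sum())


def sex_logpmf(ctx: DensityContext, per_individual: bool = False):
    """Bernoulli(0.5) imputation prior (1:1 sex ratio) where sex is unknown;
    −inf if an imputed value contradicts a known sex."""
    d, st = ctx.data, ctx.state
    lp = np.where(d.sex_code == -1, np.log(0.5), 0.0)
    lp = np.where((d.sex_code != -1) & (st.g != d.sex_code), -np.inf, lp)
    return lp if per_individual else float(lp.sum())


def censored_hormone_logpdf(ctx: DensityContext, per_individual: bool = False):
    """Uniform(0, LOD) prior on the concentration of each below-LOD hormone."""
    d, st = ctx.data, ctx.state
    if not d.f_cens.any():
        return np.zeros(d.n_ind) if per_individual else 0.0
    conc = np.exp(st.m)
    with np.errstate(divide="ignore"):
        lp = np.where(conc < d.f_lod, -np.log(d.f_lod), -np.inf)
    lp = np.where(d.f_cens, lp, 0.0).sum(axis=1)
    return _reduce(lp, np.ones_like(lp, bool), d.f_i, d.n_ind, per_individual)


def calving_logpmf_all(ctx: DensityContext, per_individual: bool = False):
    d, st = ctx.data, ctx.state
    T = d.n_years
    mat = maturity_mask(ctx)
    cT = st.c[:, :T].astype(float)
    P = st.P.astype(float)
    phi = calving_probability_matrix(ctx)
    avail = phi * (1.0 - P)
    lp = bernoulli_logpmf(cT, avail)
    # outside the mature-female support c must be 0
    lp = np.where(mat, lp, np.where(cT > 0.5, -np.inf, 0.0))
    # external calf reports clamp c to 1
    lp = np.where(d.elsewhere & (cT < 0.5), -np.inf, lp)
    # boundary (post-study) calving event = pregnancy in the final year
    p0 = d.config.boundary_pregnancy_prob
    bnd = np.where(
        mat[:, T - 1],
        bernoulli_logpmf(st.c[:, T].astype(float), p0),
        np.where(st.c[:, T] > 0, -np.inf, 0.0),
    )
    total = lp.sum(axis=1) + bnd
    return total if per_individual else float(total.sum())


def detection_logpmf_all(ctx: DensityContext, per_individual: bool = False):
    d, st = ctx.data, ctx.state
    T = d.n_years
    cT = st.c[:, :T].astype(float)
    fstar = first_day_covariate(ctx)
    p = expit(ctx.params.eta1 + ctx.params.eta2 * np.nan_to_num(fstar))
    prob = cT * p * d.e.astype(float)
    lp = bernoulli_logpmf(d.k.astype(float), prob)
    mask = d.active & d.e
    return _reduce(lp, mask, None, d.n_ind, per_individual)


def parameter_prior_logpdf(ctx: DensityContext, per_individual: bool = False):
    lp = sum(float(ctx.priors[n].logpdf(getattr(ctx.params, n))) for n in ParameterSet.names())
    if per_individual:
        return np.zeros(ctx.data.n_ind)
    return float(lp)


COMPONENTS: dict[str, Callable] = {
    "year_effects": year_effects_logpdf,
    "nutrition": nutrition_process_logpdf,
    "stress": stress_process_logpdf,
    "bai": bai_obs_logpdf,
    "fgc": fgc_obs_logpdf,
    "length": length_logpdf,
    "age": age_logpdf,
    "sex": sex_logpmf,
    "censored": censored_hormone_logpdf,
    "calving": calving_logpmf_all,
    "detection": detection_logpmf_all,
    "param_prior": parameter_prior_logpdf,
}

#: components whose value depends on each top-level parameter (used by the
#: sampler to avoid recomputing the full joint for scalar updates)
PARAM_COMPONENTS: dict[str, tuple[str, ...]] = {
    "lam_h": ("year_effects",),
    "chi_h": ("year_effects",),
    "beta_h": ("nutrition",),
    "sigma_h": ("nutrition",),
    "delta1": ("bai",),
    "delta2": ("bai",),
    "nu_h": ("bai",),
    "lam_s": ("year_effects", "calving"),
    "chi_s": ("year_effects",),
    "beta_s1": ("stress", "calving"),
    "beta_s2": ("stress", "calving"),
    "beta_s3": ("stress", "calving"),
    "sigma_s": ("stress",),
    "zeta1": ("fgc",),
    "zeta2": ("fgc",),
    "zeta3": ("fgc",),
    "zeta4": ("fgc",),
    "nu_s": ("fgc",),
    "gamma1": ("calving",),
    "gamma2": ("calving",),
    "gamma3": ("calving",),
    "gamma4": ("calving",),
    "eta1": ("detection",),
    "eta2": ("detection",),
}

LIKELIHOOD_COMPONENTS = tuple(n for n in COMPONENTS if n != "param_prior")


def component_logpdfs(ctx: DensityContext) -> dict[str, float]:
    return {name: fn(ctx) for name, fn in COMPONENTS.items()}


def joint_logposterior(ctx: DensityContext) -> float:
    """Sum of all component log-densities (−inf propagates)."""
    total = 0.0
    for fn in COMPONENTS.values():
        v = fn(ctx)
        if v == -np.inf:
            return -np.inf
        total += v
    return float(total)


def per_individual_logpdf(ctx: DensityContext, components) -> np.ndarray:
    out = np.zeros(ctx.data.n_ind)
    for name in components:
        out = out + COMPONENTS[name](ctx, per_individual=True)
    return out


# --------------------------------------------------------------------------
# scalar spec-surface wrappers
# --------------------------------------------------------------------------


def _check_index(ctx: DensityContext, i: int, t: int) -> None:
    d = ctx.data
    if not (0 <= i < d.n_ind and 0 <= t < d.n_years):
        raise IndexError(f"(i={i}, t={t}) out of range")
    if t < d.entry_t[i]:
        raise IndexError(f"year index {t} precedes entry of individual {i}")


def nutritional_logpdf(ctx: DensityContext, i: int, t: int) -> float:
    """log N(h[i,t]; H[t] + beta_h h*[i,t−1], sigma_h); no AR term at entry."""
    _check_index(ctx, i, t)
    mean = ctx.state.H[t] + ctx.params.beta_h * h_star_lag(ctx)[i, t]
    return float(norm_logpdf(ctx.state.h[i, t], mean, ctx.params.sigma_h))


def bai_logpdf(ctx: DensityContext, obs_index: int) -> float:
    """Marginal (convolved) two-layer BAI log-density for one measurement."""
    d, p, st = ctx.data, ctx.params, ctx.state
    i, t = d.b_i[obs_index], d.b_t[obs_index]
    mean = st.h[i, t] + p.delta1 * d.b_d[obs_index] + p.delta2 * float(st.P[i, t])
    sd = np.sqrt(p.nu_h**2 + d.b_sd[obs_index] ** 2)
    return float(norm_logpdf(d.b_mean[obs_index], mean, sd))


def stress_logpdf(ctx: DensityContext, i: int, t: int) -> float:
    _check_index(ctx, i, t)
    p = ctx.params
    mean = (ctx.state.S[t] + p.beta_s1 * h_star_lag(ctx)[i, t]
            + p.beta_s2 * a_star(ctx)[i, t] + p.beta_s3 * sex_covariate(ctx)[i])
    return float(norm_logpdf(ctx.state.s[i, t], mean, p.sigma_s))


def fgc_logpdf(ctx: DensityContext, sample_index: int) -> float:
    if ctx.params.nu_s <= 0:
        raise ValueError("nu_s must be positive")
    return _fgc_scalar(ctx, sample_index)


def _fgc_scalar(ctx: DensityContext, o: int) -> float:
    d, p, st = ctx.data, ctx.params, ctx.state
    y = d.f_day[o] - (np.mean(d.f_day) if d.config.center_sampling_day else 0.0)
    G = (st.s[d.f_i[o], d.f_t[o]] + p.zeta1 * st.m[o, 0] + p.zeta2 * st.m[o, 1]
         + p.zeta3 * st.m[o, 2] + p.zeta4 * y)
    return float(norm_logpdf(d.f_fgc[o], np.exp(G), p.nu_s))


def residual_stress(ctx: DensityContext, i: int, t: int) -> float:
    _check_index(ctx, i, t)
    return float(residual_stress_matrix(ctx)[i, t])


def calving_probability(ctx: DensityContext, i: int, t: int) -> float:
    _check_index(ctx, i, t)
    if not maturity_mask(ctx)[i, t]:
        raise ValueError(f"individual {i} is not a mature female in year {t}")
    return float(calving_probability_matrix(ctx)[i, t])


def calving_logpmf(ctx: DensityContext, i: int, t: int) -> float:
    phi = calving_probability(ctx, i, t)
    c = float(ctx.state.c[i, t])
    P = float(ctx.state.P[i, t])
    return float(bernoulli_logpmf(c, phi * (1.0 - P)))


def calf_detection_logpmf(ctx: DensityContext, i: int, t: int) -> float:
    _check_index(ctx, i, t)
    d = ctx.data
    c = float(ctx.state.c[i, t]) if not d.elsewhere[i, t] else 1.0
    p = expit(ctx.params.eta1 + ctx.params.eta2 * np.nan_to_num(first_day_covariate(ctx)[i, t]))
    prob = c * p * float(d.e[i, t])
    return float(bernoulli_logpmf(float(d.k[i, t]), prob))


# --------------------------------------------------------------------------
# constraint audit
# --------------------------------------------------------------------------


def hard_constraint_violations(ctx: DensityContext) -> dict[str, int]:
    """Count violations of every hard constraint in a latent configuration.

    Used by the sampler's debug mode and the acceptance audit; all counts
    must be zero for any state with finite posterior density.
    """
    d, st = ctx.data, ctx.state
    T = d.n_years
    mat = maturity_mask(ctx)
    c = st.c
    consecutive = int(((c[:, :-1] == 1) & (c[:, 1:] == 1)).sum())
    immature = int((c[:, :T][~mat] == 1).sum())
    male = int((c[(st.g != 1)] == 1).sum())
    age = int((st.age_entry < d.min_age).sum())
    missed_clamp = int((d.elsewhere & (c[:, :T] == 0)).sum()
                       + (d.k & (c[:, :T] == 0)).sum())
    return {
        "consecutive_calving": consecutive,
        "immature_calving": immature,
        "male_calving": male,
        "age_below_minimum": age,
        "unclamped_observed_calf": missed_clamp,
    }
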