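"""Metropolis-within-Gibbs MCMC over parameters and latent variables.

The update sweep covers:

* top-level parameters — adaptive random-walk Metropolis, each scalar
  evaluating only the density components it enters;
* yearly effects ``H_t``, ``S_t`` — exact conjugate Normal (Gibbs) updates;
* latent states ``h``, ``s`` — column-wise single-site Metropolis,
  vectorised across individuals (individuals are conditionally independent
  given the yearly effects);
* lengths, ages and censored hormone values — independence Metropolis
  proposing from their priors (the prior density cancels, leaving the
  likelihood ratio; a plain Gibbs draw where nothing depends on the value);
* sex of unknown-sex animals — exact full-conditional Bernoulli, with the
  calving/pregnancy sequence marginalised by enumeration; and
* per-female calving/pregnancy sequences — joint exact draws from the
  conditional distribution over every constraint-feasible binary sequence
  (the pregnancy link makes single-site flips mix poorly, but an 8-year
  window has at most 89 feasible sequences).

A brute-force oracle (:func:`brute_force_marginal`) computes the exact
marginal likelihood of tiny instances by grid quadrature over ``h``/``s``/
``L`` and enumeration of the discrete latents, for validating the kernels
and the sampler; :func:`importance_marginal` is the matching sampler-based
estimate (importance sampling from the generative prior, weighting by the
observation likelihood evaluated through the same density kernels the MCMC
uses).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import truncnorm

from . import model_density as md
from .data_model import (
    Dataset,
    ModelArrays,
    ParameterSet,
    StandardisationConstants,
    compute_standardisation,
)
from .model_density import (
    COMPONENTS,
    DensityContext,
    LatentState,
    PARAM_COMPONENTS,
    default_priors,
    joint_logposterior,
)

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "run_mcmc",
    "initialize_state",
    "enumerate_reproduction_sequences",
    "brute_force_marginal",
    "importance_marginal",
    "diagnostics",
    "adaptive_rwm",
]


@dataclass
class MCMCConfig:
    """Sampler settings; defaults suit study-sized synthetic fits."""

    n_chains: int = 2
    n_iterations: int = 2000
    n_burnin: int = 500
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.44
    adapt_interval: int = 25
    rhat_limit: float = 1.05
    min_ess: float = 100.0
    prior_only: bool = False
    sequence_cap: int = 10
    debug_check_constraints: bool = False
    store_latents: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations and not self.n_burnin < self.n_iterations:
            raise ValueError("n_burnin must be smaller than n_iterations")

    def replace(self, **kw) -> "MCMCConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PosteriorDraws:
    """MCMC output with chain x draw indexing."""

    param_names: tuple[str, ...]
    params: np.ndarray                 # (C, D, P)
    logpost: np.ndarray                # (C, D)
    constants: StandardisationConstants
    mcmc: MCMCConfig
    c: np.ndarray | None = None        # (C, D, N, T+1)
    phi_avail: np.ndarray | None = None  # (C, D, N, T) phi*(1-P), NaN off-support
    h: np.ndarray | None = None
    s: np.ndarray | None = None
    g: np.ndarray | None = None        # (C, D, N)
    age_entry: np.ndarray | None = None
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    @property
    def n_draws(self) -> int:
        return self.params.shape[1]

    def param(self, name: str) -> np.ndarray:
        """(C, D) draws of a named parameter."""
        return self.params[:, :, self.param_names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.param(name).reshape(-1)


# --------------------------------------------------------------------------
# feasible calving/pregnancy sequences
# --------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _no_consecutive_sequences(length: int) -> np.ndarray:
    """All binary sequences of ``length`` without adjacent ones, (M, length)."""
    seqs = [[0], [1]]
    for _ in range(length - 1):
        seqs = [s + [0] for s in seqs] + [s + [1] for s in seqs if s[-1] == 0]
    return np.array(sorted(seqs), dtype=np.int8)


def _sequence_scores(phi, boundary_p, allowed, forced, c_logw, P_logw):
    """Unnormalised log-probability of every feasible (c, P) sequence.

    ``phi`` (T,) calving probabilities; ``allowed`` (T+1,) marks years where
    a calving (or the boundary pregnancy) is structurally possible;
    ``forced`` (T+1,) clamps observed calving events to 1; ``c_logw`` (T, 2)
    and ``P_logw`` (T, 2) carry external log-weights for the value of c_t
    and of P_t = c_{t+1} (calf-detection and BAI-shift terms).
    Returns (sequences (M, T+1), log-scores (M,)).
    """
    T = len(phi)
    seqs = _no_consecutive_sequences(T + 1)
    ok = np.ones(len(seqs), bool)
    if not allowed.all():
        ok &= (seqs[:, ~allowed] == 0).all(axis=1)
    if forced.any():
        ok &= (seqs[:, forced] == 1).all(axis=1)
    seqs = seqs[ok]
    cT = seqs[:, :T].astype(float)
    cT1 = seqs[:, 1:].astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        bern = np.where(cT > 0.5, np.log(phi)[None, :], np.log1p(-phi * (1 - cT1)))
    bern = np.where(allowed[:T], bern, 0.0).sum(axis=1)
    with np.errstate(divide="ignore"):
        bound_val = np.where(seqs[:, T] == 1, np.log(boundary_p),
                             np.log1p(-boundary_p))
    bound = np.where(allowed[T], bound_val, np.where(seqs[:, T] == 1, -np.inf, 0.0))
    ext = (np.where(cT > 0.5, c_logw[:, 1], c_logw[:, 0]).sum(axis=1)
           + np.where(cT1 > 0.5, P_logw[:, 1], P_logw[:, 0]).sum(axis=1))
    return seqs, bern + bound + ext


def enumerate_reproduction_sequences(
    phi: np.ndarray,
    boundary_p: float,
    allowed: np.ndarray | None = None,
    forced: np.ndarray | None = None,
    c_logw: np.ndarray | None = None,
    P_logw: np.ndarray | None = None,
    cap: int = 10,
):
    """Every feasible calving/pregnancy sequence for one female's window.

    A sequence is the binary calving vector over the ``T`` study years plus
    the post-study boundary event (pregnancy in the final year); feasible
    means no calving in consecutive years (the pregnancy link), nothing
    outside the mature-female support (``allowed``), and all observed
    events clamped to 1 (``forced``).  Probabilities are proportional to
    the joint model density restricted to the female, including optional
    external observation weights.

    Returns ``(sequences, probabilities)`` with probabilities normalised to
    sum to one (zero-probability sequences are dropped).  Raises when the
    window exceeds ``cap`` years: enumeration grows exponentially, and a
    Metropolis fallback should be used instead.
    """
    phi = np.asarray(phi, float)
    T = len(phi)
    if T > cap:
        raise ValueError(
            f"window of {T} years exceeds the enumeration cap ({cap}); "
            "use a Metropolis fallback for long windows"
        )
    allowed = np.ones(T + 1, bool) if allowed is None else np.asarray(allowed, bool)
    forced = np.zeros(T + 1, bool) if forced is None else np.asarray(forced, bool)
    c_logw = np.zeros((T, 2)) if c_logw is None else np.asarray(c_logw, float)
    P_logw = np.zeros((T, 2)) if P_logw is None else np.asarray(P_logw, float)
    seqs, scores = _sequence_scores(phi, boundary_p, allowed, forced, c_logw, P_logw)
    finite = scores > -np.inf
    seqs, scores = seqs[finite], scores[finite]
    if len(scores) == 0:
        raise ValueError("no feasible calving sequence under the given constraints")
    probs = np.exp(scores - logsumexp(scores))
    keep = probs > 0
    probs = probs[keep] / probs[keep].sum()
    return seqs[keep], probs


# --------------------------------------------------------------------------
# initialisation
# --------------------------------------------------------------------------


def initialize_state(
    data: ModelArrays,
    constants: StandardisationConstants,
    rng: np.random.Generator,
    params: ParameterSet | None = None,
) -> tuple[ParameterSet, LatentState]:
    """Data-driven initial configuration with finite posterior density.

    h starts at per-individual-year observed BAI means (yearly/population
    means where unobserved), s at the log of observed fGC, lengths and ages
    at their prior means, calving sequences at the observed events.
    """
    N, T = data.n_ind, data.n_years

    key = data.b_i * T + data.b_t
    sums = np.bincount(key, weights=data.b_mean, minlength=N * T).reshape(N, T)
    cnts = np.bincount(key, minlength=N * T).reshape(N, T)
    year_mean = np.where(cnts.sum(0) > 0, sums.sum(0) / np.maximum(cnts.sum(0), 1),
                         data.b_mean.mean() if data.n_bai else 27.0)
    h = np.where(cnts > 0, sums / np.maximum(cnts, 1), year_mean[None, :])

    if data.n_fgc:
        lf = np.log(np.maximum(data.f_fgc, 1.0))
        key_f = data.f_i * T + data.f_t
        sums_f = np.bincount(key_f, weights=lf, minlength=N * T).reshape(N, T)
        cnts_f = np.bincount(key_f, minlength=N * T).reshape(N, T)
        glob = lf.mean()
        ymean = np.where(cnts_f.sum(0) > 0, sums_f.sum(0) / np.maximum(cnts_f.sum(0), 1), glob)
        s = np.where(cnts_f > 0, sums_f / np.maximum(cnts_f, 1), ymean[None, :])
    else:
        s = np.full((N, T), 2.0)

    if params is None:
        pri = default_priors()
        base = {n: float(pri[n].mean) for n in ParameterSet.names()}
        base.update(
            lam_h=float(h.mean()), chi_h=0.5, sigma_h=1.0, nu_h=1.0,
            lam_s=float(s.mean()), chi_s=0.3, sigma_s=0.5,
            nu_s=float(max(1.0, np.std(data.f_fgc) / 2)) if data.n_fgc else 5.0,
        )
        for name in ("beta_h", "beta_s1", "beta_s2", "beta_s3", "delta1", "delta2",
                     "zeta1", "zeta2", "zeta3", "zeta4",
                     "gamma1", "gamma2", "gamma3", "gamma4", "eta1", "eta2"):
            base[name] = 0.0
        params = ParameterSet(**base)

    age_entry = np.where(data.known_age, data.age_loc,
                         np.maximum(data.min_age, data.age_loc))
    g = np.where(data.sex_code == -1,
                 (rng.random(N) < 0.5).astype(int), np.maximum(data.sex_code, 0))
    evid = data.k | data.elsewhere
    g = np.where(evid.any(axis=1), 1, g)
    # a clamped calving year requires the mother to be mature there; lift the
    # initial age of unknown-age mothers accordingly (the truncated prior is
    # unbounded above, so the density stays finite)
    any_evid = evid.any(axis=1)
    if any_evid.any():
        first_evid = np.where(any_evid, evid.argmax(axis=1), T)
        need = data.config.maturity_age - (first_evid - data.entry_t)
        age_entry = np.where(any_evid & ~data.known_age,
                             np.maximum(age_entry, need), age_entry)

    c = np.zeros((N, T + 1), np.int8)
    c[:, :T] = evid.astype(np.int8)

    L = np.where(np.isfinite(data.L_mean), data.L_mean, 11.0)
    m = data.f_m.copy()
    if data.f_cens.any():
        m[data.f_cens] = np.log(data.f_lod[data.f_cens] / 2.0)

    state = LatentState(
        H=h.mean(axis=0), S=s.mean(axis=0), h=h, s=s, L=L,
        age_entry=age_entry.astype(float), g=g.astype(int), c=c, m=m,
    )
    return params, state


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------


class _Adapter:
    """Per-block Robbins-Monro scale adaptation toward a target rate."""

    def __init__(self, target: float, interval: int):
        self.target = target
        self.interval = interval
        self.scales: dict[str, float] = {}
        self.acc: dict[str, float] = {}
        self.tries: dict[str, float] = {}
        self.windows: dict[str, int] = {}

    def scale(self, key: str, default: float = 0.1) -> float:
        return self.scales.setdefault(key, default)

    def record(self, key: str, accepted: float, tried: float = 1.0) -> None:
        self.acc[key] = self.acc.get(key, 0.0) + accepted
        self.tries[key] = self.tries.get(key, 0.0) + tried

    def adapt(self, key: str) -> None:
        tries = self.tries.get(key, 0.0)
        if tries < self.interval:
            return
        rate = self.acc[key] / tries
        w = self.windows[key] = self.windows.get(key, 0) + 1
        gamma = 2.0 / (w + 1) ** 0.6
        self.scales[key] = float(self.scales[key] * np.exp(gamma * (rate - self.target)))
        self.acc[key] = self.tries[key] = 0.0

    def rates(self) -> dict[str, float]:
        return {k: self.acc[k] / t for k, t in self.tries.items() if t > 0}


class GibbsSampler:
    def __init__(self, data: ModelArrays, constants: StandardisationConstants,
                 priors, config: MCMCConfig, params: ParameterSet | None = None):
        self.data = data
        self.constants = constants
        self.priors = priors
        self.cfg = config
        self.init_params = params
        self.T = data.n_years
        self.pos_params = set(ParameterSet.POSITIVE)

    # -- component helpers ------------------------------------------------

    def _comp_sum(self, ctx, names) -> float:
        total = 0.0
        for n in names:
            v = COMPONENTS[n](ctx)
            if v == -np.inf:
                return -np.inf
            total += v
        return total

    def _per_ind(self, ctx, names) -> np.ndarray:
        return md.per_individual_logpdf(ctx, names)

    # -- parameter updates ------------------------------------------------

    #: parameters updated with the calving sequences marginalised out
    COLLAPSED = ("gamma1", "gamma2", "gamma3", "gamma4", "eta1", "eta2")

    def _update_params(self, ctx, rng, adapter, adapting):
        for name in ParameterSet.names():
            if name in self.COLLAPSED and not self.cfg.prior_only:
                continue  # handled by the sequence-marginalised update
            comps = () if self.cfg.prior_only else PARAM_COMPONENTS[name]
            cur = getattr(ctx.params, name)
            sc = adapter.scale(f"p:{name}", default=self._initial_scale(name))
            prop = cur + sc * rng.normal()
            if name in self.pos_params and prop <= 0:
                adapter.record(f"p:{name}", 0.0)
                if adapting:
                    adapter.adapt(f"p:{name}")
                continue
            lp0 = float(self.priors[name].logpdf(cur)) + self._comp_sum(ctx, comps)
            ctx.params = ctx.params.replace(**{name: prop})
            lp1 = float(self.priors[name].logpdf(prop)) + self._comp_sum(ctx, comps)
            if np.log(rng.random()) < lp1 - lp0:
                adapter.record(f"p:{name}", 1.0)
            else:
                ctx.params = ctx.params.replace(**{name: cur})
                adapter.record(f"p:{name}", 0.0)
            if adapting:
                adapter.adapt(f"p:{name}")

    @staticmethod
    def _initial_scale(name: str) -> float:
        return {"lam_h": 0.3, "lam_s": 0.2, "nu_s": 1.0, "gamma1": 0.5,
                "gamma2": 0.3, "gamma3": 0.3, "gamma4": 0.3,
                "eta1": 0.5, "eta2": 0.5}.get(name, 0.05)

    def _update_fgc_ridges(self, ctx, rng, adapter, adapting):
        """Joint shear moves along the flat directions of the fGC model.

        The fGC mean couples the overall stress level to the hormone and
        day-of-year slopes: shifting ``zeta_j`` by d while shifting
        (lam_s, S, s) by ``-d * mean(covariate_j)`` leaves the stress
        density, residual stress and year-effect prior exactly invariant,
        so only the fGC likelihood and the (zeta_j, lam_s) priors change.
        A pure level move (lam_s, S, s all shifted together) completes the
        set.  Scalar updates alone crawl along these ridges.
        """
        d, st = self.data, ctx.state
        if d.n_fgc == 0:
            return
        covs = {"zeta1": float(st.m[:, 0].mean()), "zeta2": float(st.m[:, 1].mean()),
                "zeta3": float(st.m[:, 2].mean()), "zeta4": float(d.f_day.mean()),
                None: 0.0}
        for name, mbar in covs.items():
            key = f"ridge:{name or 'level'}"
            sc = adapter.scale(key, default=0.02 if name else 0.05)
            delta = sc * rng.normal()
            shift = -delta * mbar if name else delta
            p_old = ctx.params
            lp0 = COMPONENTS["fgc"](ctx) + float(self.priors["lam_s"].logpdf(p_old.lam_s))
            new_kw = {"lam_s": p_old.lam_s + shift}
            if name:
                lp0 += float(self.priors[name].logpdf(getattr(p_old, name)))
                new_kw[name] = getattr(p_old, name) + delta
            ctx.params = p_old.replace(**new_kw)
            st.S += shift
            st.s += shift
            lp1 = COMPONENTS["fgc"](ctx) + float(self.priors["lam_s"].logpdf(ctx.params.lam_s))
            if name:
                lp1 += float(self.priors[name].logpdf(getattr(ctx.params, name)))
            if np.log(rng.random()) < lp1 - lp0:
                adapter.record(key, 1.0)
            else:
                ctx.params = p_old
                st.S -= shift
                st.s -= shift
                adapter.record(key, 0.0)
            if adapting:
                adapter.adapt(key)

    def _update_stress_shears(self, ctx, rng, adapter, adapting):
        """Non-centred moves for the stress regression coefficients.

        Most stress states are latent, so the centred conditionals of
        (beta_s1, beta_s2, beta_s3) are pinned by the instantiated field
        and mix glacially.  Shifting a coefficient by d while translating
        the whole s field by d times its covariate leaves every stress
        residual — and therefore the stress density and the residual
        stress covariate r — exactly invariant; the acceptance ratio is
        just the fGC likelihood change at the sampled cells plus the prior.
        """
        d, st, cst = self.data, ctx.state, ctx.constants
        if d.n_fgc == 0:
            return
        covs = {
            "beta_s1": md.h_star_lag(ctx),
            "beta_s2": md.a_star(ctx),
            "beta_s3": np.broadcast_to(md.sex_covariate(ctx)[:, None], st.s.shape),
        }
        for name, cov in covs.items():
            key = f"shear:{name}"
            sc = adapter.scale(key, default=0.05)
            delta = sc * rng.normal()
            p_old = ctx.params
            lp0 = COMPONENTS["fgc"](ctx) + float(self.priors[name].logpdf(getattr(p_old, name)))
            st.s[...] = st.s + delta * cov
            ctx.params = p_old.replace(**{name: getattr(p_old, name) + delta})
            lp1 = COMPONENTS["fgc"](ctx) + float(self.priors[name].logpdf(getattr(ctx.params, name)))
            if np.log(rng.random()) < lp1 - lp0:
                adapter.record(key, 1.0)
            else:
                st.s[...] = st.s - delta * cov
                ctx.params = p_old
                adapter.record(key, 0.0)
            if adapting:
                adapter.adapt(key)

    def _update_sigma_s_scale(self, ctx, rng, adapter, adapting):
        """Joint rescaling of sigma_s and the stress residual field.

        Most stress states are unobserved, so the plain (s, sigma_s) Gibbs
        pair self-reinforces at small sigma_s.  Proposing
        ``sigma_s' = sigma_s * exp(eps)`` while mapping every residual
        ``s - E[s]`` by the same factor leaves the stress density times the
        transformation Jacobian exactly invariant; the acceptance ratio
        reduces to the fGC likelihood, the calving terms (the residual
        stress covariate scales), the sigma_s prior and the log-scale
        proposal Jacobian.
        """
        d, st, p = self.data, ctx.state, ctx.params
        key = "scale:sigma_s"
        sc = adapter.scale(key, default=0.1)
        ratio = float(np.exp(sc * rng.normal()))
        mean = (st.S[None, :] + p.beta_s1 * md.h_star_lag(ctx)
                + p.beta_s2 * md.a_star(ctx)
                + p.beta_s3 * md.sex_covariate(ctx)[:, None])
        comps = ("fgc", "calving")
        lp0 = self._comp_sum(ctx, comps) + float(self.priors["sigma_s"].logpdf(p.sigma_s))
        s_old = st.s.copy()
        st.s[...] = mean + (st.s - mean) * ratio
        ctx.params = p.replace(sigma_s=p.sigma_s * ratio)
        lp1 = (self._comp_sum(ctx, comps)
               + float(self.priors["sigma_s"].logpdf(ctx.params.sigma_s)))
        if np.log(rng.random()) < lp1 - lp0 + np.log(ratio):
            adapter.record(key, 1.0)
        else:
            st.s[...] = s_old
            ctx.params = p
            adapter.record(key, 0.0)
        if adapting:
            adapter.adapt(key)

    # -- conjugate yearly effects -----------------------------------------

    def _update_year_effects(self, ctx, rng):
        p, st, d = ctx.params, ctx.state, self.data
        if self.cfg.prior_only:
            st.H[:] = rng.normal(p.lam_h, p.chi_h, self.T)
            st.S[:] = rng.normal(p.lam_s, p.chi_s, self.T)
            return
        act = d.active
        resid_h = np.where(act, st.h - p.beta_h * md.h_star_lag(ctx), 0.0)
        n_t = act.sum(axis=0)
        prec = 1.0 / p.chi_h**2 + n_t / p.sigma_h**2
        mean = (p.lam_h / p.chi_h**2 + resid_h.sum(axis=0) / p.sigma_h**2) / prec
        st.H[:] = rng.normal(mean, 1.0 / np.sqrt(prec))

        expect = (p.beta_s1 * md.h_star_lag(ctx) + p.beta_s2 * md.a_star(ctx)
                  + p.beta_s3 * md.sex_covariate(ctx)[:, None])
        resid_s = np.where(act, st.s - expect, 0.0)
        prec = 1.0 / p.chi_s**2 + n_t / p.sigma_s**2
        mean = (p.lam_s / p.chi_s**2 + resid_s.sum(axis=0) / p.sigma_s**2) / prec
        st.S[:] = rng.normal(mean, 1.0 / np.sqrt(prec))

    # -- latent state columns ---------------------------------------------

    _H_COMPS = ("nutrition", "stress", "bai", "calving")
    _S_COMPS = ("stress", "fgc", "calving")

    def _s_attached(self, ctx) -> np.ndarray:
        """(N,T) cells where the stress state enters any likelihood term.

        A stress state is informed by fGC samples at its own cell, or (for
        mature females, through the lagged residual) by the calving model.
        Everywhere else its full conditional is the stress process itself,
        so it can be refreshed by an exact Gibbs draw — leaving such cells
        to random-walk Metropolis couples them spuriously to the stress
        coefficients and chokes mixing.
        """
        d, st = self.data, ctx.state
        T = self.T
        att = np.zeros((d.n_ind, T), bool)
        if d.n_fgc:
            att[d.f_i, d.f_t] = True
        if d.config.use_stress_in_calving:
            lag = d.config.stress_lag
            mat = md.maturity_mask(ctx)
            att[:, :T - lag] |= mat[:, lag:]
        return att

    def _update_state_columns(self, ctx, rng, adapter, adapting, which: str):
        st, d = ctx.state, self.data
        arr = st.h if which == "h" else st.s
        comps = self._H_COMPS if which == "h" else self._S_COMPS
        attached = None
        if which == "s":
            attached = self._s_attached(ctx)
            p = ctx.params
            mean = (st.S[None, :] + p.beta_s1 * md.h_star_lag(ctx)
                    + p.beta_s2 * md.a_star(ctx)
                    + p.beta_s3 * md.sex_covariate(ctx)[:, None])
            # partially-collapsed sigma_s update: the unattached cells are
            # leaf nodes, so updating sigma_s from the attached residuals
            # alone and then redrawing the unattached cells from the new
            # process is exact; with the leaves instantiated, sigma_s's
            # conditional is pinned to wherever the leaf field already is
            att = attached & d.active
            n_att = int(att.sum())
            if n_att and not self.cfg.prior_only:
                ss = float(((st.s - mean)[att] ** 2).sum())
                key = "pcg:sigma_s"
                sc = adapter.scale(key, default=0.1)
                prop = p.sigma_s * float(np.exp(sc * rng.normal()))

                def _lp(sig):
                    return (-n_att * np.log(sig) - ss / (2 * sig**2)
                            + float(self.priors["sigma_s"].logpdf(sig)) + np.log(sig))

                if np.log(rng.random()) < _lp(prop) - _lp(p.sigma_s):
                    ctx.params = p = p.replace(sigma_s=prop)
                    adapter.record(key, 1.0)
                else:
                    adapter.record(key, 0.0)
                if adapting:
                    adapter.adapt(key)
            free = d.active & ~attached
            st.s[...] = np.where(free, mean + p.sigma_s * rng.normal(size=st.s.shape), st.s)
        for t in range(self.T):
            key = f"{which}:{t}"
            sc = adapter.scale(key, default=0.5 if which == "h" else 0.3)
            mask = d.active[:, t]
            if attached is not None:
                mask = mask & attached[:, t]
            if not mask.any():
                continue
            lp0 = self._per_ind(ctx, comps)
            cur = arr[:, t].copy()
            arr[:, t] = np.where(mask, cur + sc * rng.normal(size=d.n_ind), cur)
            lp1 = self._per_ind(ctx, comps)
            accept = (np.log(rng.random(d.n_ind)) < lp1 - lp0) & mask
            arr[:, t] = np.where(accept, arr[:, t], cur)
            adapter.record(key, float(accept.sum()), float(mask.sum()))
            if adapting:
                adapter.adapt(key)

    # -- lengths, ages, hormones (independence proposals from the prior) --

    def _update_lengths(self, ctx, rng):
        """Independence proposals from the length prior; the acceptance
        ratio reduces to the next year's calving-term likelihood ratio
        (a pure Gibbs draw where length enters nothing)."""
        st, d, p = ctx.state, self.data, ctx.params
        T = self.T
        cst = ctx.constants
        mat = md.maturity_mask(ctx)
        hl = md.h_star_lag(ctx)
        rl = md.residual_stress_lagged(ctx) if d.config.use_stress_in_calving else None
        cT = st.c[:, :T].astype(float)
        P = st.P.astype(float)
        lag_ok = np.arange(T)[None, :] - 1 >= d.entry_t[:, None]

        def year_term(tt, Lcol, rows):
            L3s = (Lcol**3 - cst.L3_mean) / cst.L3_sd
            lin = p.gamma1 + p.gamma2 * hl[:, tt] + p.gamma3 * L3s
            if rl is not None:
                lin = lin + p.gamma4 * rl[:, tt]
            avail = expit(lin) * (1.0 - P[:, tt])
            with np.errstate(divide="ignore"):
                term = np.where(cT[:, tt] > 0.5, np.log(avail), np.log1p(-avail))
            return np.where(rows, term, 0.0)

        for t in range(T):
            mask = d.active[:, t] & np.isfinite(d.L_mean[:, t])
            if not mask.any():
                continue
            cur = st.L[:, t].copy()
            prop = rng.normal(np.nan_to_num(d.L_mean[:, t], nan=11.0),
                              np.nan_to_num(d.L_sd[:, t], nan=1.0))
            tt = t + 1
            if tt >= T:
                st.L[:, t] = np.where(mask, prop, cur)
                continue
            rows = mat[:, tt] & lag_ok[:, tt] & mask
            delta = year_term(tt, prop, rows) - year_term(tt, cur, rows)
            accept = (np.log(rng.random(d.n_ind)) < delta) & mask
            st.L[:, t] = np.where(accept, prop, cur)

    def _update_ages(self, ctx, rng):
        d = self.data
        unk = ~d.known_age
        if not unk.any():
            return
        st = ctx.state
        a = (d.min_age - d.age_loc) / np.where(d.age_scale > 0, d.age_scale, 1.0)
        prop = truncnorm.rvs(a, np.inf, loc=d.age_loc, scale=np.where(d.age_scale > 0, d.age_scale, 1.0),
                             size=d.n_ind, random_state=rng)
        lp0 = self._per_ind(ctx, ("stress", "calving")) if not self.cfg.prior_only else 0.0
        cur = st.age_entry.copy()
        st.age_entry = np.where(unk, prop, cur)
        lp1 = self._per_ind(ctx, ("stress", "calving")) if not self.cfg.prior_only else 0.0
        accept = (np.log(rng.random(d.n_ind)) < lp1 - lp0) & unk
        st.age_entry = np.where(accept, st.age_entry, cur)

    def _update_hormones(self, ctx, rng):
        d, st = self.data, ctx.state
        if not d.f_cens.any():
            return
        for j in range(3):
            rows = np.nonzero(d.f_cens[:, j])[0]
            if len(rows) == 0:
                continue
            lp0 = self._obs_fgc_logpdf(ctx, rows)
            cur = st.m[rows, j].copy()
            st.m[rows, j] = np.log(rng.uniform(0.0, d.f_lod[rows, j]))
            lp1 = self._obs_fgc_logpdf(ctx, rows)
            accept = np.log(rng.random(len(rows))) < lp1 - lp0
            st.m[rows, j] = np.where(accept, st.m[rows, j], cur)

    def _obs_fgc_logpdf(self, ctx, rows) -> np.ndarray:
        p, st, d = ctx.params, ctx.state, self.data
        y = d.f_day[rows]
        G = (st.s[d.f_i[rows], d.f_t[rows]] + p.zeta1 * st.m[rows, 0]
             + p.zeta2 * st.m[rows, 1] + p.zeta3 * st.m[rows, 2] + p.zeta4 * y)
        return md.norm_logpdf(d.f_fgc[rows], np.exp(G), p.nu_s)

    # -- calving sequences and sex -----------------------------------------

    def _seq_cache(self, ctx) -> dict:
        """Per-sweep vectorised inputs for sequence and sex updates.

        All female-branch quantities (phi, maturity, residual stress) are
        computed *as if female* for every individual, so the same cache
        serves known females, currently-imputed females, and the female
        branch of the sex full-conditional.  Nothing here depends on c.
        """
        d, st, p, cst = self.data, ctx.state, ctx.params, ctx.constants
        T, N = self.T, self.data.n_ind
        hl = md.h_star_lag(ctx)
        L3 = md.L3_star_lag(ctx)
        ages = d.ages(st.age_entry)
        astar = (ages - cst.age_mean) / cst.age_sd
        base = st.S[None, :] if d.config.residual_uses_year_effect else p.lam_s
        expect_f = base + p.beta_s1 * hl + p.beta_s2 * astar + p.beta_s3 * d.config.female_code
        r_f = st.s - expect_f
        lag = d.config.stress_lag
        rlag = np.zeros_like(r_f)
        rlag[:, lag:] = r_f[:, :-lag]
        rlag = np.where(np.arange(T)[None, :] - lag >= d.entry_t[:, None], rlag, 0.0)
        lin = p.gamma1 + p.gamma2 * hl + p.gamma3 * L3
        if d.config.use_stress_in_calving:
            lin = lin + p.gamma4 * rlag
        phi = expit(lin)
        mature_f = (ages >= d.config.maturity_age) & d.active

        # stress-density rows under both sex values (for the sex update)
        lp_s = {}
        for g in (0, 1):
            mean = (st.S[None, :] + p.beta_s1 * hl + p.beta_s2 * astar
                    + p.beta_s3 * g * d.config.female_code)
            lp_s[g] = np.where(d.active, md.norm_logpdf(st.s, mean, p.sigma_s), 0.0).sum(axis=1)

        # BAI log-factors per individual-year for P = 0 / 1
        P_logw = np.zeros((N, T, 2))
        if d.n_bai:
            mean0 = st.h[d.b_i, d.b_t] + p.delta1 * d.b_d
            sd = np.sqrt(p.nu_h**2 + d.b_sd**2)
            lp0 = md.norm_logpdf(d.b_mean, mean0, sd)
            lp1 = md.norm_logpdf(d.b_mean, mean0 + p.delta2, sd)
            key = d.b_i * T + d.b_t
            P_logw[:, :, 0] = np.bincount(key, weights=lp0, minlength=N * T).reshape(N, T)
            P_logw[:, :, 1] = np.bincount(key, weights=lp1, minlength=N * T).reshape(N, T)

        # detection log-factors per individual-year for c = 0 / 1
        c_logw = np.zeros((N, T, 2))
        fstar = md.first_day_covariate(ctx)
        pdet = expit(p.eta1 + p.eta2 * np.nan_to_num(fstar))
        k = d.k.astype(float)
        with np.errstate(divide="ignore"):
            c_logw[:, :, 1] = np.where(d.e, k * np.log(pdet) + (1 - k) * np.log1p(-pdet), 0.0)
            c_logw[:, :, 0] = np.where(d.e & d.k, -np.inf, 0.0)

        evid = d.k | d.elsewhere
        seqs = _no_consecutive_sequences(T + 1)
        return {
            "phi": phi, "mature": mature_f, "P_logw": P_logw, "c_logw": c_logw,
            "lp_s": lp_s, "evid": evid, "hl": hl, "L3": L3, "rlag": rlag,
            "seqs": seqs, "cT": seqs[:, :T].astype(float), "cT1": seqs[:, 1:].astype(float),
        }

    def _refresh_cache_params(self, ctx, cache) -> None:
        """Recompute the parameter-dependent cache pieces (phi, detection)."""
        d, p = self.data, ctx.params
        lin = p.gamma1 + p.gamma2 * cache["hl"] + p.gamma3 * cache["L3"]
        if d.config.use_stress_in_calving:
            lin = lin + p.gamma4 * cache["rlag"]
        cache["phi"] = expit(lin)
        fstar = md.first_day_covariate(ctx)
        pdet = expit(p.eta1 + p.eta2 * np.nan_to_num(fstar))
        k = d.k.astype(float)
        with np.errstate(divide="ignore"):
            cache["c_logw"][:, :, 1] = np.where(
                d.e, k * np.log(pdet) + (1 - k) * np.log1p(-pdet), 0.0)

    def _collapsed_update(self, ctx, cache, rng, adapter, adapting):
        """RWM on the calving/detection parameters with (c, P) collapsed.

        The acceptance ratio uses the likelihood with every female's
        calving/pregnancy sequence summed out by enumeration (a partially
        collapsed Gibbs step); sequences are then redrawn from their exact
        conditional under the new parameters.  This lets the chain cross
        the ridge between "frequent calving, poor detection" and "rare
        calving, good detection" explanations that single-site updates
        cannot traverse.
        """
        d, st = self.data, ctx.state
        T = self.T
        females = np.nonzero(st.g == 1)[0]
        if len(females) == 0:
            return
        seqs, cT, cT1 = cache["seqs"], cache["cT"], cache["cT1"]
        M = len(seqs)
        mature = cache["mature"][females]                       # (F,T)
        allowed_T = mature[:, T - 1]                            # (F,)
        forced = cache["evid"][females]                         # (F,T)
        feas = np.ones((len(females), M), bool)
        feas &= ~((seqs[None, :, :T] == 1) & ~mature[:, None, :]).any(axis=2)
        feas &= ~((seqs[None, :, :T] == 0) & forced[:, None, :]).any(axis=2)
        feas &= ~((seqs[None, :, T] == 1) & ~allowed_T[:, None])

        p0 = d.config.boundary_pregnancy_prob
        bnd = np.where(allowed_T[:, None],
                       np.where(seqs[None, :, T] == 1, np.log(p0), np.log1p(-p0)), 0.0)
        pw = cache["P_logw"][females]                           # (F,T,2)
        Pext = np.where(cT1[None] > 0.5, pw[:, None, :, 1], pw[:, None, :, 0]).sum(axis=2)
        hl, L3 = cache["hl"][females], cache["L3"][females]
        rlag = cache["rlag"][females]
        e_rows = d.e[females]
        k_rows = d.k[females].astype(float)
        fstar = np.nan_to_num(md.first_day_covariate(ctx)[females])

        def loglik(p: ParameterSet) -> float:
            lin = p.gamma1 + p.gamma2 * hl + p.gamma3 * L3
            if d.config.use_stress_in_calving:
                lin = lin + p.gamma4 * rlag
            phi = expit(lin)
            pdet = expit(p.eta1 + p.eta2 * fstar)
            with np.errstate(divide="ignore", invalid="ignore"):
                cw1 = np.where(e_rows, k_rows * np.log(pdet)
                               + (1 - k_rows) * np.log1p(-pdet), 0.0)
                bern = np.where(cT[None] > 0.5, np.log(phi)[:, None, :],
                                np.log1p(-phi[:, None, :] * (1 - cT1[None])))
            bern = np.where(mature[:, None, :], bern, 0.0).sum(axis=2)
            ext = (cT[None] * cw1[:, None, :]).sum(axis=2)
            tot = np.where(feas, bern + ext + bnd + Pext, -np.inf)
            mx = tot.max(axis=1)
            if not np.isfinite(mx).all():
                return -np.inf
            return float((mx + np.log(np.exp(tot - mx[:, None]).sum(axis=1))).sum())

        lcur = loglik(ctx.params)
        for name in self.COLLAPSED:
            key = f"p:{name}"
            sc = adapter.scale(key, default=self._initial_scale(name))
            cur = getattr(ctx.params, name)
            prop = cur + sc * rng.normal()
            cand = ctx.params.replace(**{name: prop})
            lnew = loglik(cand)
            dprior = float(self.priors[name].logpdf(prop) - self.priors[name].logpdf(cur))
            if np.log(rng.random()) < lnew - lcur + dprior:
                ctx.params = cand
                lcur = lnew
                adapter.record(key, 1.0)
            else:
                adapter.record(key, 0.0)
            if adapting:
                adapter.adapt(key)
        self._refresh_cache_params(ctx, cache)

    def _female_scores(self, cache: dict, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(feasible sequences, log-scores) for individual i as a female."""
        T = self.T
        d = self.data
        mature = cache["mature"][i]
        allowed = np.append(mature, mature[T - 1])
        forced = np.append(cache["evid"][i], False)
        seqs, cT, cT1 = cache["seqs"], cache["cT"], cache["cT1"]
        ok = np.ones(len(seqs), bool)
        if not allowed.all():
            ok &= (seqs[:, ~allowed] == 0).all(axis=1)
        if forced.any():
            ok &= (seqs[:, forced] == 1).all(axis=1)
        seqs, cT, cT1 = seqs[ok], cT[ok], cT1[ok]

        phi = cache["phi"][i]
        with np.errstate(divide="ignore", invalid="ignore"):
            bern = np.where(cT > 0.5, np.log(phi)[None, :],
                            np.log1p(-phi[None, :] * (1 - cT1)))
        bern = np.where(mature[None, :], bern, 0.0).sum(axis=1)
        p0 = d.config.boundary_pregnancy_prob
        if allowed[T]:
            bern = bern + np.where(seqs[:, T] == 1, np.log(p0), np.log1p(-p0))
        cw, pw = cache["c_logw"][i], cache["P_logw"][i]
        ext = (np.where(cT > 0.5, cw[None, :, 1], cw[None, :, 0]).sum(axis=1)
               + np.where(cT1 > 0.5, pw[None, :, 1], pw[None, :, 0]).sum(axis=1))
        return seqs, bern + ext

    def _sample_sequence(self, cache: dict, i: int, rng) -> np.ndarray:
        seqs, scores = self._female_scores(cache, i)
        mx = scores.max()
        w = np.exp(scores - mx)
        cum = np.cumsum(w)
        j = int(np.searchsorted(cum, rng.random() * cum[-1]))
        return seqs[min(j, len(seqs) - 1)]

    def _update_sequences(self, ctx, cache, rng):
        st = ctx.state
        for i in np.nonzero(st.g == 1)[0]:
            st.c[i] = self._sample_sequence(cache, i, rng)

    def _update_sex(self, ctx, cache, rng):
        """Exact joint Gibbs draw of (g_i, c_i) for unknown-sex animals.

        Both branch marginals carry all g-dependent terms: the stress
        density, and the calving / detection / BAI-pregnancy-shift terms
        (marginalised over feasible sequences on the female branch; c = 0
        and P = 0 on the male branch).  The Bernoulli(0.5) sex prior
        cancels.
        """
        d, st = self.data, ctx.state
        T = self.T
        for i in np.nonzero(d.sex_code == -1)[0]:
            _, scores = self._female_scores(cache, i)
            mx = scores.max()
            lf = cache["lp_s"][1][i] + (mx + np.log(np.exp(scores - mx).sum())
                                        if np.isfinite(mx) else -np.inf)
            if cache["evid"][i].any():
                lm = -np.inf
            else:
                lm = (cache["lp_s"][0][i] + cache["P_logw"][i, :, 0].sum()
                      + cache["c_logw"][i, :, 0].sum())
            if rng.random() < expit(lf - lm):
                st.g[i] = 1
                st.c[i] = self._sample_sequence(cache, i, rng)
            else:
                st.g[i] = 0
                st.c[i] = 0

    # -- main loop ---------------------------------------------------------

    def run_chain(self, seed: int | np.random.SeedSequence):
        rng = np.random.default_rng(seed)
        cfg = self.cfg
        params, state = initialize_state(self.data, self.constants, rng, self.init_params)
        ctx = DensityContext(self.data, state, params, self.constants, self.priors)

        lp = joint_logposterior(ctx)
        if not np.isfinite(lp) and not cfg.prior_only:
            comps = md.component_logpdfs(ctx)
            bad = [n for n, v in comps.items() if not np.isfinite(v)]
            raise RuntimeError(f"non-finite initial log-posterior; offending component(s): {bad}")

        adapter = _Adapter(cfg.target_accept, cfg.adapt_interval)
        store = {"params": [], "logpost": [], "c": [], "phi": [], "h": [], "s": [],
                 "g": [], "age": []}

        def _store():
            store["params"].append(ctx.params.to_array())
            store["logpost"].append(md.parameter_prior_logpdf(ctx) if cfg.prior_only
                                    else joint_logposterior(ctx))
            if cfg.store_latents:
                mat = md.maturity_mask(ctx)
                phi = md.calving_probability_matrix(ctx) * (1.0 - ctx.state.P)
                store["c"].append(ctx.state.c.copy())
                store["phi"].append(np.where(mat, phi, np.nan).astype(np.float32))
                store["h"].append(ctx.state.h.astype(np.float32))
                store["s"].append(ctx.state.s.astype(np.float32))
                store["g"].append(ctx.state.g.astype(np.int8))
                store["age"].append(ctx.state.age_entry.astype(np.float32))
            if cfg.debug_check_constraints:
                viol = md.hard_constraint_violations(ctx)
                if any(viol.values()):
                    raise AssertionError(f"hard-constraint violation in stored state: {viol}")

        if cfg.n_iterations == 0:
            _store()
            return store, adapter

        for it in range(cfg.n_iterations):
            adapting = it < cfg.n_burnin
            self._update_params(ctx, rng, adapter, adapting)
            self._update_year_effects(ctx, rng)
            if not cfg.prior_only:
                for _ in range(2):
                    self._update_fgc_ridges(ctx, rng, adapter, adapting)
                    self._update_stress_shears(ctx, rng, adapter, adapting)
                self._update_sigma_s_scale(ctx, rng, adapter, adapting)
                self._update_state_columns(ctx, rng, adapter, adapting, "h")
                self._update_state_columns(ctx, rng, adapter, adapting, "s")
                self._update_lengths(ctx, rng)
                self._update_ages(ctx, rng)
                self._update_hormones(ctx, rng)
                cache = self._seq_cache(ctx)
                self._collapsed_update(ctx, cache, rng, adapter, adapting)
                self._update_sequences(ctx, cache, rng)
                self._update_sex(ctx, cache, rng)
            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                _store()
        return store, adapter


def run_mcmc(
    dataset: Dataset | ModelArrays,
    config: MCMCConfig | None = None,
    priors=None,
    constants: StandardisationConstants | None = None,
    params: ParameterSet | None = None,
) -> PosteriorDraws:
    """Run all chains of the Metropolis-within-Gibbs sampler.

    ``constants`` default to :func:`compute_standardisation` of the dataset
    (pass stored constants to reproduce a previous fit exactly).
    """
    data = dataset.to_arrays() if isinstance(dataset, Dataset) else dataset
    cfg = config if config is not None else MCMCConfig()
    priors = priors if priors is not None else default_priors()
    constants = constants if constants is not None else compute_standardisation(data)

    sampler = GibbsSampler(data, constants, priors, cfg, params)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains, acceptance = [], {}
    for ci, ss in enumerate(seeds):
        store, adapter = sampler.run_chain(ss)
        chains.append(store)
        acceptance[f"chain{ci}"] = adapter.rates()

    def _stack(key, dtype=None):
        if not chains[0][key]:
            return None
        arr = np.stack([np.stack(ch[key]) for ch in chains])
        return arr.astype(dtype) if dtype else arr

    return PosteriorDraws(
        param_names=ParameterSet.names(),
        params=_stack("params"),
        logpost=_stack("logpost"),
        constants=constants,
        mcmc=cfg,
        c=_stack("c"),
        phi_avail=_stack("phi"),
        h=_stack("h"),
        s=_stack("s"),
        g=_stack("g"),
        age_entry=_stack("age"),
        acceptance=acceptance,
    )


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


def diagnostics(draws: PosteriorDraws | dict, rhat_limit: float = 1.05,
                min_ess: float = 100.0) -> pd.DataFrame:
    """Split-R-hat and effective sample size per parameter.

    Accepts a :class:`PosteriorDraws` or a mapping name -> (chains, draws)
    array.  Raises when fewer than two chains are available.
    """
    import arviz as az

    if isinstance(draws, PosteriorDraws):
        arrays = {n: draws.param(n) for n in draws.param_names}
    else:
        arrays = {k: np.asarray(v) for k, v in draws.items()}
    n_chains = next(iter(arrays.values())).shape[0]
    if n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    dset = az.convert_to_dataset(arrays)
    rhat = az.rhat(dset)
    ess = az.ess(dset)
    rows = []
    for name in arrays:
        r = float(rhat[name].values)
        n = float(ess[name].values)
        rows.append({"parameter": name, "rhat": r, "ess": n,
                     "passed": bool(r < rhat_limit and n >= min_ess)})
    return pd.DataFrame(rows).set_index("parameter")


def adaptive_rwm(logpdf, x0: float, n_iter: int, rng: np.random.Generator,
                 target: float = 0.44, n_adapt: int | None = None) -> np.ndarray:
    """Scalar adaptive random-walk Metropolis (the sampler's core move).

    Exposed so the stationary distribution of the elementary update can be
    validated against analytic posteriors.
    """
    n_adapt = n_iter // 2 if n_adapt is None else n_adapt
    adapter = _Adapter(target, 25)
    out = np.empty(n_iter)
    x, lp = float(x0), float(logpdf(x0))
    for i in range(n_iter):
        sc = adapter.scale("x", default=1.0)
        prop = x + sc * rng.normal()
        lpp = float(logpdf(prop))
        if np.log(rng.random()) < lpp - lp:
            x, lp = prop, lpp
            adapter.record("x", 1.0)
        else:
            adapter.record("x", 0.0)
        if i < n_adapt:
            adapter.adapt("x")
        out[i] = x
    return out


# --------------------------------------------------------------------------
# brute-force oracle and importance-sampling estimate
# --------------------------------------------------------------------------


def _check_oracle_preconditions(data: ModelArrays, params: ParameterSet) -> None:
    if data.n_ind > 4 or data.n_years > 4:
        raise ValueError("oracle restricted to <= 4 individuals x <= 4 years")
    if data.config.use_stress_in_calving and params.gamma4 != 0.0:
        raise ValueError(
            "oracle requires gamma4 = 0 (the lagged residual-stress effect "
            "would need a joint multi-lag grid)")
    if params.chi_h != 0.0 or params.chi_s != 0.0:
        raise ValueError("oracle conditions on fixed yearly effects (chi_h = chi_s = 0)")
    if data.f_cens.any():
        raise ValueError("oracle does not handle censored hormone values")
    if (~data.known_age).any():
        raise ValueError("oracle requires known ages")


def brute_force_marginal(
    data: ModelArrays,
    params: ParameterSet,
    constants: StandardisationConstants,
    n_grid_h: int = 161,
    n_grid_s: int = 161,
    n_grid_L: int = 101,
    span: float = 8.0,
) -> float:
    """Exact (to quadrature tolerance) log marginal likelihood of a tiny
    instance: trapezoid quadrature over the latent ``h`` chain (forward
    filtering), nested quadrature over ``s`` and ``L``, and enumeration of
    every feasible calving/pregnancy sequence.  Yearly effects are fixed at
    their means (``chi = 0``), which the preconditions enforce.
    """
    _check_oracle_preconditions(data, params)
    p, cst, cfg = params, constants, data.config
    T, N = data.n_years, data.n_ind
    p0 = cfg.boundary_pregnancy_prob

    xs = np.linspace(p.lam_h - span * max(p.sigma_h, 0.5) - abs(p.beta_h) * 3,
                     p.lam_h + span * max(p.sigma_h, 0.5) + abs(p.beta_h) * 3, n_grid_h)
    wx = np.full(n_grid_h, xs[1] - xs[0])
    wx[0] = wx[-1] = 0.5 * (xs[1] - xs[0])
    xstar = (xs - cst.h_mean) / cst.h_sd

    total = 0.0
    for i in range(N):
        branches = []
        if data.sex_code[i] == -1:
            branches = [(0, 0.5), (1, 0.5)]
        else:
            branches = [(int(data.sex_code[i]), 1.0)]
        vals = []
        for g, wgt in branches:
            vals.append(wgt * np.exp(_oracle_individual(
                data, p, cst, i, g, xs, wx, xstar, n_grid_s, n_grid_L, span, p0)))
        total += np.log(sum(vals))
    return float(total)


def _oracle_individual(data, p, cst, i, g, xs, wx, xstar, n_grid_s, n_grid_L, span, p0):
    """log marginal for one individual with known sex g."""
    cfg = data.config
    T = data.n_years
    entry = data.entry_t[i]
    ages = data.age_loc[i] + (np.arange(T) - entry)
    mature = (g == 1) & (ages >= cfg.maturity_age) & data.active[i]
    forced = np.append(data.k[i] | data.elsewhere[i], False)
    allowed = np.append(mature, bool(mature[T - 1]))
    if forced.any() and g == 0:
        return -np.inf

    # precompute BAI emission log-factors per year for P=0/1: (T, 2, G)
    G = len(xs)
    bai_log = np.zeros((T, 2, G))
    rows = np.nonzero(data.b_i == i)[0]
    for o in rows:
        t = data.b_t[o]
        sd = np.sqrt(p.nu_h**2 + data.b_sd[o] ** 2)
        for v in (0, 1):
            mean = xs + p.delta1 * data.b_d[o] + p.delta2 * v
            bai_log[t, v] += md.norm_logpdf(data.b_mean[o], mean, sd)

    # stress integral per year as a function of x_{t-1}: (T, G)
    s_log = np.zeros((T, G))
    for t in range(entry, T):
        rows_f = np.nonzero((data.f_i == i) & (data.f_t == t))[0]
        astar = (ages[t] - cst.age_mean) / cst.age_sd
        mean_base = (p.lam_s + p.beta_s2 * astar + p.beta_s3 * g * cfg.female_code)
        lag_ok = t - 1 >= entry
        means = mean_base + (p.beta_s1 * xstar if lag_ok else 0.0)
        means = np.broadcast_to(np.atleast_1d(means), (G,)).astype(float)
        if len(rows_f) == 0:
            continue  # integral of the state prior is 1
        sg = np.linspace(means.min() - span * p.sigma_s,
                         means.max() + span * p.sigma_s, n_grid_s)
        ws = np.full(n_grid_s, sg[1] - sg[0])
        ws[0] = ws[-1] = 0.5 * (sg[1] - sg[0])
        dens = np.exp(md.norm_logpdf(sg[None, :], means[:, None], p.sigma_s))
        lik = np.zeros(n_grid_s)
        for o in rows_f:
            Gv = (sg + p.zeta1 * data.f_m[o, 0] + p.zeta2 * data.f_m[o, 1]
                  + p.zeta3 * data.f_m[o, 2] + p.zeta4 * data.f_day[o])
            lik += md.norm_logpdf(data.f_fgc[o], np.exp(Gv), p.nu_s)
        integ = (dens * np.exp(lik)[None, :] * ws[None, :]).sum(axis=1)
        with np.errstate(divide="ignore"):
            s_log[t] = np.log(integ)

    # calving factor per year/sequence value as function of x_{t-1}: needs L
    def calving_log(t, c_t, P_t):
        """(G,) log factor for Bern(c_t; phi(x_{t-1}, L_{t-1}) (1-P_t))."""
        if not mature[t]:
            return np.zeros(G) if c_t == 0 else np.full(G, -np.inf)
        lag_ok = t - 1 >= entry
        hterm = p.gamma2 * xstar if lag_ok else np.zeros(G)
        if lag_ok and np.isfinite(data.L_mean[i, t - 1]):
            Lm, Ls = data.L_mean[i, t - 1], data.L_sd[i, t - 1]
            Lg = np.linspace(Lm - span * Ls, Lm + span * Ls, n_grid_L)
            wl = np.full(n_grid_L, Lg[1] - Lg[0])
            wl[0] = wl[-1] = 0.5 * (Lg[1] - Lg[0])
            dens = np.exp(md.norm_logpdf(Lg, Lm, Ls)) * wl
            L3s = (Lg**3 - cst.L3_mean) / cst.L3_sd
            lin = p.gamma1 + hterm[:, None] + p.gamma3 * L3s[None, :]
            phi = expit(lin)
            avail = phi * (1 - P_t)
            pm = avail if c_t == 1 else 1.0 - avail
            val = (pm * dens[None, :]).sum(axis=1)
        else:
            phi = expit(p.gamma1 + hterm)
            avail = phi * (1 - P_t)
            val = avail if c_t == 1 else 1.0 - avail
            val = np.broadcast_to(np.atleast_1d(val), (G,)).astype(float)
        with np.errstate(divide="ignore"):
            return np.log(val)

    # detection factors (scalar per year given c_t)
    def detection_log(t, c_t):
        if not data.e[i, t]:
            return 0.0 if not data.k[i, t] else -np.inf
        fstar = data.first_day[i, t]
        if cfg.standardise_first_day:
            fstar = (fstar - cst.f_mean) / cst.f_sd
        pdet = expit(p.eta1 + p.eta2 * fstar)
        prob = c_t * pdet
        return float(np.log(prob) if data.k[i, t] else np.log1p(-prob))

    seqs = _no_consecutive_sequences(T + 1)
    ok = (seqs[:, ~allowed] == 0).all(axis=1) if not allowed.all() else np.ones(len(seqs), bool)
    if forced.any():
        ok &= (seqs[:, forced] == 1).all(axis=1)
    seqs = seqs[ok]

    trans_mean = p.lam_h + p.beta_h * xstar  # mean of h_t given h_{t-1}=x
    trans = np.exp(md.norm_logpdf(xs[None, :], trans_mean[:, None], p.sigma_h))

    results = []
    for seq in seqs:
        c = seq[:T]
        P = seq[1:]
        log_scalar = 0.0
        if allowed[T]:
            log_scalar += float(np.log(p0) if seq[T] else np.log1p(-p0))
        feasible = True
        for t in range(T):
            dl = detection_log(t, int(c[t])) if data.active[i, t] else 0.0
            if dl == -np.inf:
                feasible = False
                break
            log_scalar += dl
        if not feasible:
            continue

        # forward filter over the h chain
        log_norm = 0.0
        alpha = None
        for t in range(entry, T):
            emit = bai_log[t, int(P[t])].copy()
            if t == entry:
                prior = md.norm_logpdf(xs, p.lam_h, p.sigma_h)
                # entry-year stress/calving factors are constant in x_{t-1};
                # fold their value (evaluated at the lag-free convention) in
                emit += s_log[t]  # constant row when no lag
                emit += calving_log(t, int(c[t]), int(P[t]))
                alpha = np.exp(prior + emit) * wx
            else:
                carry = s_log[t] + calving_log(t, int(c[t]), int(P[t]))
                vec = alpha * np.exp(carry)
                alpha = (vec @ trans) * wx * np.exp(emit)
            scale = alpha.sum()
            if scale <= 0:
                feasible = False
                break
            alpha /= scale
            log_norm += np.log(scale)
        if not feasible:
            continue
        results.append(log_scalar + log_norm)
    if not results:
        return -np.inf
    return logsumexp(results)


def _draw_prior_state(data: ModelArrays, params: ParameterSet,
                      constants: StandardisationConstants,
                      rng: np.random.Generator) -> LatentState:
    """One draw of all latents from the fitted model's generative prior
    (yearly effects fixed at their means, matching the oracle)."""
    p, cst, cfg = params, constants, data.config
    N, T = data.n_ind, data.n_years
    H = np.full(T, p.lam_h)
    S = np.full(T, p.lam_s)
    g = np.where(data.sex_code == -1, (rng.random(N) < 0.5).astype(int),
                 np.maximum(data.sex_code, 0))
    age_entry = data.age_loc.copy()
    L = np.where(np.isfinite(data.L_mean),
                 rng.normal(np.nan_to_num(data.L_mean), np.nan_to_num(data.L_sd, nan=1.0)),
                 11.0)
    h = np.zeros((N, T))
    s = np.zeros((N, T))
    ages = data.ages(age_entry)
    gf = g.astype(float) * cfg.female_code
    for t in range(T):
        lag_ok = (np.arange(T)[t] - 1 >= data.entry_t)
        hstar = np.where(lag_ok, (h[:, t - 1] - cst.h_mean) / cst.h_sd, 0.0)
        h[:, t] = rng.normal(H[t] + p.beta_h * hstar, p.sigma_h)
        astar = (ages[:, t] - cst.age_mean) / cst.age_sd
        s[:, t] = rng.normal(S[t] + p.beta_s1 * hstar + p.beta_s2 * astar
                             + p.beta_s3 * gf, p.sigma_s)
    state = LatentState(H=H, S=S, h=h, s=s, L=L, age_entry=age_entry,
                        g=g, c=np.zeros((N, T + 1), np.int8), m=data.f_m.copy())
    ctx = DensityContext(data, state, params, constants)
    phi = md.calving_probability_matrix(ctx)
    mature = md.maturity_mask(ctx)
    from .synthetic_data import simulate_calving_sequences

    state.c = simulate_calving_sequences(phi, cfg.boundary_pregnancy_prob, rng,
                                         allowed=mature)
    state.c[g != 1] = 0
    return state


def importance_marginal(
    data: ModelArrays,
    params: ParameterSet,
    constants: StandardisationConstants,
    n_draws: int = 20000,
    seed: int = 0,
) -> tuple[float, float]:
    """Importance-sampling estimate of the log marginal likelihood.

    Draws latent configurations from the model prior and weights them by
    the observation likelihood evaluated through the same density kernels
    the sampler uses.  Returns ``(log_marginal, mc_standard_error)`` where
    the SE is on the log scale (delta method).
    """
    _check_oracle_preconditions(data, params)
    rng = np.random.default_rng(seed)
    logw = np.empty(n_draws)
    obs_comps = ("bai", "fgc", "detection")
    ctx = DensityContext(data, _draw_prior_state(data, params, constants, rng),
                         params, constants)
    for n in range(n_draws):
        ctx.state = _draw_prior_state(data, params, constants, rng)
        lw = 0.0
        for name in obs_comps:
            lw += COMPONENTS[name](ctx)
        if data.elsewhere.any():
            if (ctx.state.c[:, : data.n_years][data.elsewhere] != 1).any():
                lw = -np.inf
        logw[n] = lw
    mx = logw.max()
    w = np.exp(logw - mx)
    est = mx + np.log(w.mean())
    se = w.std(ddof=1) / np.sqrt(n_draws) / w.mean()
    return float(est), float(se)
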