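"""Forward simulator generating study-like longitudinal whale datasets.

The generator implements the state, reproduction and observation processes
as generative rules, with two pre-study burn-in years so lagged covariates
exist at the first study year, and reproduces the study's sampling
structure: 8 years, ~139 individuals retained (at least one BAI
measurement), ~665 BAI and ~337 fGC records concentrated in a subset of
animals with heavy-tailed per-individual effort, ~27% unknown sex, ~29%
known ages, sparse calving, seasonal calf-detection decay, and below-LOD
hormone censoring (with the first study year's thyroid values imputable
only up to the maximum observed concentration, mimicking an unmeasured
assay year).

Note the pregnancy link ``P[t-1] = c[t]`` makes the calving chain a
*reverse-time* directed model (this year's availability depends on next
year's birth); :func:`simulate_calving_sequences` therefore samples the
sequence backwards from the post-study boundary event, which reproduces
the model's exact joint distribution, including the 2-year minimum
inter-calf interval.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import (
    Dataset,
    HORMONES,
    ModelConfig,
    ParameterSet,
    StandardisationConstants,
)

__all__ = [
    "SimulationScenario",
    "Population",
    "StateBundle",
    "default_scenario",
    "simulate_population",
    "simulate_states",
    "simulate_calving_sequences",
    "simulate_reproduction",
    "simulate_observations",
    "make_study_like_dataset",
]


@dataclass
class SimulationScenario:
    """All knobs of the generator; defaults are the study conditions."""

    config: ModelConfig = field(default_factory=ModelConfig)
    params: ParameterSet = field(default_factory=lambda: ParameterSet(
        lam_h=27.7, chi_h=0.7, beta_h=0.40, sigma_h=1.0,
        delta1=-0.016, delta2=0.63, nu_h=0.8,
        lam_s=1.9, chi_s=0.25, beta_s1=-0.09, beta_s2=0.10, beta_s3=0.26,
        sigma_s=0.4,
        zeta1=0.30, zeta2=0.18, zeta3=0.23, zeta4=-0.003, nu_s=8.0,
        gamma1=-2.8, gamma2=0.80, gamma3=1.36, gamma4=-0.97,
        eta1=0.48, eta2=-1.80,
    ))
    constants: StandardisationConstants = field(default_factory=lambda: StandardisationConstants(
        h_mean=27.7, h_sd=1.5, age_mean=12.0, age_sd=8.0,
        L3_mean=1650.0, L3_sd=300.0, f_mean=214.0, f_sd=43.0,
    ))
    n_individuals: int = 150          # base cohort; in-study calves add, retention subtracts
    n_burnin_years: int = 2
    encounter_prob: float = 0.62
    bai_rate: float = 0.80            # mean BAI measurements per encountered year
    fgc_individual_frac: float = 0.60
    fgc_rate: float = 0.85            # per encountered year of sampled animals
    effort_sigma: float = 1.0         # log-SD of per-individual effort effect
    sex_known_prob: float = 0.70
    age_known_prob: float = 0.20
    elsewhere_report_prob: float = 0.30
    lod_quantile: float = 0.05
    bai_sd_range: tuple[float, float] = (0.3, 1.0)
    season: tuple[int, int] = (140, 288)      # survey day-of-year window
    hormone_log_mean: tuple[float, float, float] = (3.2, 2.6, 2.4)
    hormone_log_sd: float = 0.8
    hormone_season_slope: tuple[float, float, float] = (0.2, 0.0, -0.3)
    age_gamma_shape: float = 2.0
    age_gamma_scale: float = 6.0
    growth_Linf_mean: float = 12.3
    growth_Linf_sd: float = 0.35
    growth_k: float = 0.30
    length_at_birth: float = 4.6
    length_prior_noise: float = 0.08
    length_prior_sd_range: tuple[float, float] = (0.10, 0.25)
    censor_hormones: bool = True
    retain_only_measured: bool = True

    def __post_init__(self) -> None:
        for name in ("encounter_prob", "fgc_individual_frac", "sex_known_prob",
                     "age_known_prob", "elsewhere_report_prob", "lod_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.config.n_years < 3:
            raise ValueError("need at least 3 study years for the 2-year stress lag")

    def replace(self, **kw) -> "SimulationScenario":
        return dataclasses.replace(self, **kw)


def default_scenario() -> SimulationScenario:
    return SimulationScenario()


@dataclass
class Population:
    """True (generator-side) metadata for every simulated animal."""

    ids: list[str]
    entry_t: np.ndarray            # (N,) in-study entry index
    true_sex: np.ndarray           # (N,) 0/1
    true_age_entry: np.ndarray     # (N,) age in entry year
    sex_known: np.ndarray          # (N,) bool
    known_age: np.ndarray          # (N,) bool
    min_age: np.ndarray            # (N,)
    age_prior_loc: np.ndarray
    age_prior_scale: np.ndarray
    L_true: np.ndarray             # (N, burnin+T) true lengths (NaN before entry)
    L_prior_mean: np.ndarray       # (N, T)
    L_prior_sd: np.ndarray         # (N, T)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class StateBundle:
    """Population + latent trajectories (columns include burn-in years)."""

    scenario: SimulationScenario
    population: Population
    H: np.ndarray                  # (burnin+T,)
    S: np.ndarray
    h: np.ndarray                  # (N, burnin+T), NaN before entry
    s: np.ndarray
    c: np.ndarray | None = None    # (N, T+1) set by simulate_reproduction

    @property
    def burnin(self) -> int:
        return self.scenario.n_burnin_years

    def in_study(self, arr: np.ndarray) -> np.ndarray:
        return arr[..., self.burnin:]


def _vb_length(age, Linf, k, L0):
    return Linf - (Linf - L0) * np.exp(-k * np.maximum(age, 0.0))


def simulate_population(scn: SimulationScenario, rng: np.random.Generator) -> Population:
    """Draw the base cohort (everyone present from the first study year)."""
    N, T = scn.n_individuals, scn.config.n_years
    B = scn.n_burnin_years
    true_sex = (rng.random(N) < 0.5).astype(int)
    age_entry = np.clip(np.floor(rng.gamma(scn.age_gamma_shape, scn.age_gamma_scale, N)), 1, 45)
    sex_known = rng.random(N) < scn.sex_known_prob
    known_age = rng.random(N) < scn.age_known_prob
    gap = rng.integers(0, 13, N)
    min_age = np.where(known_age, age_entry, np.clip(age_entry - gap, 1, None))
    loc = np.where(known_age, age_entry,
                   np.maximum(min_age, age_entry + rng.normal(0, 1.5, N)))
    scale = np.where(known_age, 0.0, 3.0)

    Linf = rng.normal(scn.growth_Linf_mean, scn.growth_Linf_sd, N)
    ages_full = age_entry[:, None] + (np.arange(B + T)[None, :] - B)
    L_true = _vb_length(ages_full, Linf[:, None], scn.growth_k, scn.length_at_birth)
    L_prior_mean = L_true[:, B:] + rng.normal(0, scn.length_prior_noise, (N, T))
    L_prior_sd = rng.uniform(*scn.length_prior_sd_range, (N, T))

    return Population(
        ids=[f"GW{j:04d}" for j in range(N)],
        entry_t=np.zeros(N, int),
        true_sex=true_sex,
        true_age_entry=age_entry,
        sex_known=sex_known,
        known_age=known_age,
        min_age=min_age.astype(float),
        age_prior_loc=loc,
        age_prior_scale=scale,
        L_true=L_true,
        L_prior_mean=L_prior_mean,
        L_prior_sd=L_prior_sd,
    )


def simulate_states(scn: SimulationScenario, rng: np.random.Generator,
                    population: Population | None = None) -> StateBundle:
    """Simulate yearly population effects and individual state trajectories.

    ``h[i,t] = H[t] + beta_h h*[i,t-1] + eps`` (no AR at the entry step) and
    ``s[i,t] = S[t] + beta_s1 h*[i,t-1] + beta_s2 a*[i,t] + beta_s3 g + ups``,
    over burn-in plus study years.
    """
    pop = population if population is not None else simulate_population(scn, rng)
    p, cst = scn.params, scn.constants
    N = pop.n
    B = scn.n_burnin_years
    TB = B + scn.config.n_years
    # base cohort is present from full-column 0 (the burn-in years);
    # mid-study entrants appear at B + entry_t.  Ages are anchored to the
    # *study* entry year, so base animals are younger during burn-in.
    entry_cols = np.where(pop.entry_t == 0, 0, B + pop.entry_t)
    age_ref_cols = B + pop.entry_t

    H = rng.normal(p.lam_h, p.chi_h, TB)
    S = rng.normal(p.lam_s, p.chi_s, TB)
    h = np.full((N, TB), np.nan)
    s = np.full((N, TB), np.nan)
    ages_full = pop.true_age_entry[:, None] + (np.arange(TB)[None, :] - age_ref_cols[:, None])
    g = pop.true_sex.astype(float) * scn.config.female_code

    for t in range(TB):
        present = entry_cols <= t
        lagged = present & (entry_cols < t)
        hstar = np.zeros(N)
        hstar[lagged] = (h[lagged, t - 1] - cst.h_mean) / cst.h_sd
        mean_h = H[t] + p.beta_h * hstar
        h[present, t] = mean_h[present] + rng.normal(0.0, p.sigma_h, int(present.sum()))
        astar = (ages_full[:, t] - cst.age_mean) / cst.age_sd
        mean_s = S[t] + p.beta_s1 * hstar + p.beta_s2 * astar + p.beta_s3 * g
        s[present, t] = mean_s[present] + rng.normal(0.0, p.sigma_s, int(present.sum()))
    return StateBundle(scenario=scn, population=pop, H=H, S=S, h=h, s=s)


def simulate_calving_sequences(phi: np.ndarray, boundary_p: float,
                               rng: np.random.Generator,
                               allowed: np.ndarray | None = None) -> np.ndarray:
    """Exact reverse-time sampling of calving sequences.

    ``phi`` is (M, T); returns c of shape (M, T+1) whose last column is the
    post-study boundary event (~Bernoulli(boundary_p)).  ``allowed`` masks
    years where calving is impossible (immature, pre-entry).  Sequences
    never contain calving in consecutive years.
    """
    M, T = phi.shape
    allowed = np.ones((M, T), bool) if allowed is None else allowed
    c = np.zeros((M, T + 1), np.int8)
    c[:, T] = (rng.random(M) < boundary_p * allowed[:, T - 1]).astype(np.int8)
    for t in range(T - 1, -1, -1):
        prob = phi[:, t] * (1 - c[:, t + 1]) * allowed[:, t]
        c[:, t] = (rng.random(M) < prob).astype(np.int8)
    return c


def _phi_in_study(states: StateBundle) -> tuple[np.ndarray, np.ndarray]:
    """(phi, allowed) for in-study years, using burn-in values for lags."""
    scn, pop = states.scenario, states.population
    p, cst, cfg = scn.params, scn.constants, scn.config
    B, T = states.burnin, scn.config.n_years
    N = pop.n
    entry_cols = np.where(pop.entry_t == 0, 0, B + pop.entry_t)
    age_ref_cols = B + pop.entry_t
    ages_full = pop.true_age_entry[:, None] + (np.arange(B + T)[None, :] - age_ref_cols[:, None])

    hstar = (states.h - cst.h_mean) / cst.h_sd
    astar = (ages_full - cst.age_mean) / cst.age_sd
    L3star = (pop.L_true ** 3 - cst.L3_mean) / cst.L3_sd
    g = pop.true_sex.astype(float) * cfg.female_code
    expect_s = (p.lam_s + p.beta_s1 * _lagged(hstar, entry_cols)
                + p.beta_s2 * astar + p.beta_s3 * g[:, None])
    r = states.s - expect_s

    lin = (p.gamma1
           + p.gamma2 * _lagged(hstar, entry_cols)
           + p.gamma3 * _lagged(L3star, entry_cols))
    if cfg.use_stress_in_calving:
        lin = lin + p.gamma4 * _lagged(r, entry_cols, lag=cfg.stress_lag)
    phi = expit(lin)[:, B:]

    mature = ((pop.true_sex == 1)[:, None]
              & (ages_full[:, B:] >= cfg.maturity_age)
              & (np.arange(T)[None, :] >= pop.entry_t[:, None]))
    return phi, mature


def _lagged(x: np.ndarray, entry_cols: np.ndarray, lag: int = 1) -> np.ndarray:
    out = np.zeros_like(x)
    out[:, lag:] = x[:, :-lag]
    valid = np.arange(x.shape[1])[None, :] - lag >= entry_cols[:, None]
    return np.where(valid, np.nan_to_num(out), 0.0)


def simulate_reproduction(states: StateBundle, rng: np.random.Generator,
                          individuals: np.ndarray | None = None) -> np.ndarray:
    """Sample calving/pregnancy sequences for the bundle's females.

    Requesting specific ``individuals`` that include a male raises a
    ``ValueError``.  Stores and returns c with the boundary column; males
    and immature years are all-zero.
    """
    pop = states.population
    if individuals is not None:
        if (pop.true_sex[np.asarray(individuals)] != 1).any():
            raise ValueError("reproduction requested for a male individual")
    phi, allowed = _phi_in_study(states)
    c = simulate_calving_sequences(phi, states.scenario.config.boundary_pregnancy_prob,
                                   rng, allowed=allowed)
    states.c = c
    return c


def simulate_observations(states: StateBundle, rng: np.random.Generator) -> tuple[Dataset, dict]:
    """Generate the four observation tables plus the truth bundle."""
    scn, pop = states.scenario, states.population
    p, cfg, cst = scn.params, scn.config, scn.constants
    N, T, B = pop.n, cfg.n_years, states.burnin
    if states.c is None:
        simulate_reproduction(states, rng)
    c = states.c
    h_is = states.in_study(states.h)
    s_is = states.in_study(states.s)
    P = c[:, 1:].astype(float)
    active = np.arange(T)[None, :] >= pop.entry_t[:, None]

    effort_b = rng.lognormal(-scn.effort_sigma**2 / 2, scn.effort_sigma, N)
    effort_f = rng.lognormal(-scn.effort_sigma**2 / 2, scn.effort_sigma, N)
    fgc_sampled = rng.random(N) < scn.fgc_individual_frac

    e = (rng.random((N, T)) < scn.encounter_prob) & active
    first_day = np.full((N, T), np.nan)
    first_day[e] = rng.uniform(*scn.season, int(e.sum()))

    # calf detection in the study area, decaying over the season
    fstar = (first_day - cst.f_mean) / cst.f_sd if cfg.standardise_first_day else first_day
    pdet = expit(p.eta1 + p.eta2 * np.nan_to_num(fstar))
    k = (rng.random((N, T)) < c[:, :T] * pdet * e).astype(bool)
    elsewhere = (~k & (c[:, :T] == 1)
                 & (rng.random((N, T)) < scn.elsewhere_report_prob))

    rows_b, rows_f = [], []
    n_bai_iy = rng.poisson(scn.bai_rate * effort_b[:, None] * e)
    n_fgc_iy = rng.poisson(scn.fgc_rate * effort_f[:, None] * (e & fgc_sampled[:, None]))
    for i in range(N):
        for t in range(T):
            year = cfg.years[t]
            for _ in range(int(n_bai_iy[i, t])):
                doy = rng.uniform(*scn.season)
                d = cfg.season_end_doy - doy
                bsd = rng.uniform(*scn.bai_sd_range)
                latent = h_is[i, t] + p.delta1 * d + p.delta2 * P[i, t] \
                    + rng.normal(0, p.nu_h)
                val = np.clip(latent + rng.normal(0, bsd), 10.1, 49.9)
                rows_b.append((pop.ids[i], year, d, val, bsd))
            for _ in range(int(n_fgc_iy[i, t])):
                doy = rng.uniform(*scn.season)
                m = np.array(scn.hormone_log_mean) \
                    + np.array(scn.hormone_season_slope) * (doy - cst.f_mean) / 74.0 \
                    + rng.normal(0, scn.hormone_log_sd, 3)
                G = (s_is[i, t] + p.zeta1 * m[0] + p.zeta2 * m[1] + p.zeta3 * m[2]
                     + p.zeta4 * doy)
                fgc = rng.normal(np.exp(G), p.nu_s)
                while fgc < 0:
                    fgc = rng.normal(np.exp(G), p.nu_s)
                rows_f.append((pop.ids[i], year, doy, fgc, *m))
    bai = pd.DataFrame(rows_b, columns=["individual_id", "year",
                                        "days_before_season_end", "bai_mean", "bai_sd"])
    fgc = pd.DataFrame(rows_f, columns=["individual_id", "year", "day_of_year", "fgc",
                                        "log_progestin", "log_androgen", "log_thyroid"])

    # below-LOD censoring; thyroid unmeasured in the first study year
    for j, hname in enumerate(HORMONES):
        col = f"log_{hname}"
        vals = fgc[col].to_numpy()
        conc = np.exp(vals)
        cens = np.zeros(len(fgc), bool)
        lod = np.full(len(fgc), np.nan)
        if scn.censor_hormones and len(fgc):
            q = np.quantile(conc, scn.lod_quantile)
            cens = conc < q
            lod[cens] = q
            if hname == "thyroid":
                y2016 = fgc["year"].to_numpy() == cfg.years[0]
                mx = conc[~y2016].max() if (~y2016).any() else conc.max()
                cens |= y2016
                lod[y2016] = mx
        fgc[col] = np.where(cens, np.nan, vals)
        fgc[f"{hname}_below_lod"] = cens
        fgc[f"{hname}_lod"] = lod

    # sightings table: one row per active individual-year
    ii, tt = np.nonzero(active)
    sight = pd.DataFrame({
        "individual_id": [pop.ids[i] for i in ii],
        "year": [cfg.years[t] for t in tt],
        "encountered": e[ii, tt].astype(int),
        "first_day": first_day[ii, tt],
        "calf_observed": k[ii, tt].astype(int),
        "calf_reported_elsewhere": elsewhere[ii, tt].astype(int),
    })

    # individuals table; mothers with calf evidence have known (female) sex
    mother_evident = (k | elsewhere).any(axis=1)
    sex_known = pop.sex_known | mother_evident
    sex = np.where(sex_known,
                   np.where(pop.true_sex == 1, "female", "male"), "unknown")
    ind = pd.DataFrame({
        "individual_id": pop.ids,
        "sex": sex,
        "known_age": pop.known_age.astype(int),
        "min_age": pop.min_age,
        "age_prior_loc": pop.age_prior_loc,
        "age_prior_scale": pop.age_prior_scale,
        "first_year": [cfg.years[t] for t in pop.entry_t],
    })
    for t, year in enumerate(cfg.years):
        lm = pop.L_prior_mean[:, t].copy()
        ls = pop.L_prior_sd[:, t].copy()
        lm[~active[:, t]] = np.nan
        ls[~active[:, t]] = np.nan
        ind[f"length_mean_{year}"] = lm
        ind[f"length_sd_{year}"] = ls

    ds = Dataset(individuals=ind, bai=bai, fgc=fgc, sightings=sight, config=cfg)
    truth = {
        "params": p.to_dict(),
        "constants": cst.to_dict(),
        "H": states.in_study(states.H).tolist(),
        "S": states.in_study(states.S).tolist(),
        "h": h_is.tolist(),
        "s": s_is.tolist(),
        "c": c.tolist(),
        "sex": pop.true_sex.tolist(),
        "age_entry": pop.true_age_entry.tolist(),
        "ids": list(pop.ids),
        "n_missed_calvings": int(((c[:, :T] == 1) & ~k & ~elsewhere).sum()),
    }
    return ds, truth


def _retain(ds: Dataset, truth: dict) -> tuple[Dataset, dict]:
    """Keep only individuals with at least one BAI measurement."""
    keep = sorted(set(ds.bai["individual_id"]), key=list(ds.individuals["individual_id"]).index)
    keep_set = set(keep)
    mask = ds.individuals["individual_id"].isin(keep_set).to_numpy()
    ds2 = Dataset(
        individuals=ds.individuals[mask].reset_index(drop=True),
        bai=ds.bai[ds.bai["individual_id"].isin(keep_set)].reset_index(drop=True),
        fgc=ds.fgc[ds.fgc["individual_id"].isin(keep_set)].reset_index(drop=True),
        sightings=ds.sightings[ds.sightings["individual_id"].isin(keep_set)].reset_index(drop=True),
        config=ds.config,
    )
    idx = np.nonzero(mask)[0]
    truth2 = dict(truth)
    for key in ("h", "s", "sex", "age_entry", "c", "ids"):
        truth2[key] = [truth[key][i] for i in idx]
    T = ds.config.n_years
    c = np.asarray(truth2["c"])
    karr = ds2.sightings.pivot_table(index="individual_id", columns="year",
                                     values="calf_observed", aggfunc="max")
    ew = ds2.sightings.pivot_table(index="individual_id", columns="year",
                                   values="calf_reported_elsewhere", aggfunc="max")
    order = truth2["ids"]
    kmat = karr.reindex(order).fillna(0).to_numpy(bool)
    emat = ew.reindex(order).fillna(0).to_numpy(bool)
    truth2["n_missed_calvings"] = int(((c[:, :T] == 1) & ~kmat & ~emat).sum())
    return ds2, truth2


def _add_calves(states: StateBundle, rng: np.random.Generator,
                inclusion_prob: float = 0.6) -> StateBundle:
    """Recruit calves born during the study as new known-age individuals.

    Each simulated birth event produces a calf that enters the catalogue in
    its birth year with the given probability; calves have known age (0 at
    entry) and a higher chance of unknown sex than adults.
    """
    scn, pop = states.scenario, states.population
    cfg = scn.config
    B, T = states.burnin, cfg.n_years
    births_i, births_t = np.nonzero(states.c[:, :T] == 1)
    sel = (births_t >= 1) & (rng.random(len(births_i)) < inclusion_prob)
    births_i, births_t = births_i[sel], births_t[sel]
    M = len(births_i)
    if M == 0:
        return states

    Linf = rng.normal(scn.growth_Linf_mean, scn.growth_Linf_sd, M)
    entry_cols = B + births_t
    ages_full = np.arange(B + T)[None, :] - entry_cols[:, None]
    L_true = np.where(ages_full >= 0,
                      _vb_length(ages_full.astype(float), Linf[:, None],
                                 scn.growth_k, scn.length_at_birth), np.nan)
    L_prior_mean = L_true[:, B:] + rng.normal(0, scn.length_prior_noise, (M, T))
    new_pop = Population(
        ids=pop.ids + [f"GWC{j:03d}" for j in range(M)],
        entry_t=np.concatenate([pop.entry_t, births_t]),
        true_sex=np.concatenate([pop.true_sex, (rng.random(M) < 0.5).astype(int)]),
        true_age_entry=np.concatenate([pop.true_age_entry, np.zeros(M)]),
        sex_known=np.concatenate([pop.sex_known, rng.random(M) < 0.4]),
        known_age=np.concatenate([pop.known_age, np.ones(M, bool)]),
        min_age=np.concatenate([pop.min_age, np.zeros(M)]),
        age_prior_loc=np.concatenate([pop.age_prior_loc, np.zeros(M)]),
        age_prior_scale=np.concatenate([pop.age_prior_scale, np.zeros(M)]),
        L_true=np.vstack([pop.L_true, L_true]),
        L_prior_mean=np.vstack([pop.L_prior_mean, L_prior_mean]),
        L_prior_sd=np.vstack([pop.L_prior_sd,
                              rng.uniform(*scn.length_prior_sd_range, (M, T))]),
    )

    # simulate the calves' state trajectories under the already-drawn H, S
    p, cst = scn.params, scn.constants
    h_new = np.full((M, B + T), np.nan)
    s_new = np.full((M, B + T), np.nan)
    g = new_pop.true_sex[pop.n:].astype(float) * cfg.female_code
    for t in range(B + T):
        present = entry_cols <= t
        if not present.any():
            continue
        lagged = present & (entry_cols < t)
        hstar = np.zeros(M)
        hstar[lagged] = (h_new[lagged, t - 1] - cst.h_mean) / cst.h_sd
        mean_h = states.H[t] + p.beta_h * hstar
        h_new[present, t] = mean_h[present] + rng.normal(0, p.sigma_h, int(present.sum()))
        astar = (ages_full[:, t] - cst.age_mean) / cst.age_sd
        mean_s = (states.S[t] + p.beta_s1 * hstar + p.beta_s2 * astar + p.beta_s3 * g)
        s_new[present, t] = mean_s[present] + rng.normal(0, p.sigma_s, int(present.sum()))

    return StateBundle(
        scenario=scn,
        population=new_pop,
        H=states.H, S=states.S,
        h=np.vstack([states.h, h_new]),
        s=np.vstack([states.s, s_new]),
        c=np.vstack([states.c, np.zeros((M, T + 1), np.int8)]),
    )


def make_study_like_dataset(seed: int, scenario: SimulationScenario | None = None
                            ) -> tuple[Dataset, dict]:
    """One fully reproducible study-like dataset plus its generating truth."""
    scn = scenario if scenario is not None else default_scenario()
    rng = np.random.default_rng(seed)
    pop = simulate_population(scn, rng)
    states = simulate_states(scn, rng, pop)
    simulate_reproduction(states, rng)
    states = _add_calves(states, rng)
    ds, truth = simulate_observations(states, rng)
    if scn.retain_only_measured:
        ds, truth = _retain(ds, truth)
    ds.validate()
    return ds, truth
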