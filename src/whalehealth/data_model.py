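"""Domain types, dataset container, CSV readers/writers and validation.

The package models individual gray whales followed over a yearly study
window.  Three longitudinal observation tables inform two latent yearly
health states per animal (a nutritional state on the body-area-index scale
and a stress state on the log faecal-glucocorticoid scale) and, for mature
females, a calving process:

* ``individuals.csv`` -- static metadata: sex (possibly unknown), age
  information (known age, or a prior with a minimum-age constraint), the
  year of entry into the study, and per-year body-length priors from an
  external photogrammetric growth model.
* ``bai.csv``        -- drone-derived body area index (BAI) measurements,
  each with a posterior mean, SD and the number of days before the end of
  the field season (15 October).
* ``fgc.csv``        -- faecal hormone samples: glucocorticoid (fGC)
  concentration plus log-transformed progestin / androgen / thyroid (T3)
  covariates, with below-limit-of-detection flags and bounds.
* ``sightings.csv``  -- yearly encounter flag, day of first sighting, calf
  observations in the study area, and calves reported by other groups.

Covariates entering the model linearly (lagged nutritional state, age,
cubed length, day of first sighting) are standardised with constants that
are computed once from the observed data and frozen for the whole fit
(:func:`compute_standardisation`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ConsistencyError",
    "DegenerateDataError",
    "ModelConfig",
    "IndividualRecord",
    "ParameterSet",
    "StandardisationConstants",
    "Dataset",
    "ModelArrays",
    "load_dataset",
    "write_dataset",
    "compute_standardisation",
]

HORMONES = ("progestin", "androgen", "thyroid")


class SchemaError(ValueError):
    """A CSV file does not conform to the documented schema."""


class ConsistencyError(ValueError):
    """Rows contradict the support of the observation model."""


class DegenerateDataError(ValueError):
    """A quantity to be standardised has zero variance."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Study-level settings shared by the simulator, densities and sampler.

    Attributes
    ----------
    years:
        Calendar years of the study window, mapped internally to
        ``t = 0 .. T-1``.
    maturity_age:
        Age (years) at which females become sexually mature and enter the
        calving model.
    season_end_doy:
        Day of year of the end of the field season (15 October = 288);
        BAI measurement timing is expressed as days before this date.
    boundary_pregnancy_prob:
        Bernoulli probability that a female is pregnant in the final study
        year (i.e. calves just after the window closes).
    female_code:
        Numeric coding of sex entering the stress model (female = 1 so a
        positive coefficient reads "females higher").
    standardise_first_day:
        Whether the day of first sighting is standardised before entering
        the calf-detection model (default True; the raw day-of-year scale
        would force the slope toward zero).
    center_sampling_day:
        Whether the faecal sampling day of year is centred before entering
        the fGC observation model (default False: raw day of year).
    residual_uses_year_effect:
        If True, the residual stress covariate subtracts the yearly effect
        S_t instead of its mean; default False (yearly deviations remain
        part of the residual).
    stress_lag:
        Lag (years) at which the residual stress state enters the calving
        model (default 2).
    use_stress_in_calving:
        Switch for the model variant without the stress effect on calving.
    """

    years: tuple[int, ...] = tuple(range(2016, 2024))
    maturity_age: int = 8
    season_end_doy: int = 288
    boundary_pregnancy_prob: float = 0.05
    female_code: float = 1.0
    standardise_first_day: bool = True
    center_sampling_day: bool = False
    residual_uses_year_effect: bool = False
    stress_lag: int = 2
    use_stress_in_calving: bool = True

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: np.ndarray | int) -> np.ndarray | int:
        return np.asarray(year) - self.years[0] if np.ndim(year) else int(year) - self.years[0]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise SchemaError(
                f"unknown config keys {sorted(unknown)}; valid keys are {sorted(valid)}"
            )
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(int(y) for y in d["years"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class IndividualRecord:
    """Static metadata and priors for one whale.

    ``age_prior_loc``/``age_prior_scale`` give the prior (in years) for the
    animal's age in its entry year; ages then increase deterministically by
    one per time step.  ``min_age`` is the hard lower bound on the entry-year
    age derived from the sighting history.  ``length_mean``/``length_sd``
    (metres) are per-year priors from the external growth model, indexed by
    calendar year.
    """

    individual_id: str
    sex: str  # "female" | "male" | "unknown"
    known_age: bool
    min_age: float
    age_prior_loc: float
    age_prior_scale: float
    first_year: int
    length_mean: dict[int, float] = field(default_factory=dict)
    length_sd: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "unknown"):
            raise SchemaError(f"invalid sex {self.sex!r} for {self.individual_id}")
        if self.min_age < 0:
            raise ConsistencyError(f"min_age < 0 for {self.individual_id}")
        for y, sd in self.length_sd.items():
            if not sd > 0:
                raise ConsistencyError(
                    f"non-positive length prior SD for {self.individual_id} in {y}"
                )


@dataclass
class ParameterSet:
    """All top-level model parameters.

    Naming follows the roles in the state and observation processes:
    ``lam_h``/``chi_h`` are mean and SD of the yearly nutritional random
    effect, ``beta_h`` the AR coefficient on the standardised lagged state,
    ``sigma_h`` the nutritional process SD; ``delta1``/``delta2``/``nu_h``
    belong to the BAI observation model (per-day drift, pregnancy offset,
    residual SD); ``lam_s``/``chi_s``/``beta_s1..3``/``sigma_s`` mirror the
    stress process (lagged nutrition, standardised age, sex effects);
    ``zeta1..4``/``nu_s`` the fGC observation model; ``gamma1..4`` the
    calving logit (intercept, nutrition, cubed length, residual stress);
    ``eta1``/``eta2`` the calf-detection logit (intercept, first-day slope).
    """

    lam_h: float = 27.0
    chi_h: float = 0.7
    beta_h: float = 0.0
    sigma_h: float = 1.0
    delta1: float = 0.0
    delta2: float = 0.0
    nu_h: float = 1.0
    lam_s: float = 2.0
    chi_s: float = 0.3
    beta_s1: float = 0.0
    beta_s2: float = 0.0
    beta_s3: float = 0.0
    sigma_s: float = 0.5
    zeta1: float = 0.0
    zeta2: float = 0.0
    zeta3: float = 0.0
    zeta4: float = 0.0
    nu_s: float = 8.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    gamma3: float = 0.0
    gamma4: float = 0.0
    eta1: float = 0.0
    eta2: float = 0.0

    POSITIVE = ("chi_h", "sigma_h", "nu_h", "chi_s", "sigma_s", "nu_s")

    def __post_init__(self) -> None:
        # zero is tolerated so degenerate-variance generative checks can run;
        # the priors used in inference keep these strictly positive
        for name in self.POSITIVE:
            if not getattr(self, name) >= 0:
                raise ValueError(f"parameter {name} must be non-negative")

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names()], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ParameterSet":
        return cls(**dict(zip(cls.names(), map(float, arr))))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in self.names()}

    def replace(self, **kw) -> "ParameterSet":
        return dataclasses.replace(self, **kw)


@dataclass
class StandardisationConstants:
    """Frozen centring/scaling constants for the model covariates.

    Computed once from the observed data (:func:`compute_standardisation`)
    and stored with every fit so results are reproducible; they are *not*
    recomputed per MCMC iteration.
    """

    h_mean: float
    h_sd: float
    age_mean: float
    age_sd: float
    L3_mean: float
    L3_sd: float
    f_mean: float
    f_sd: float

    def __post_init__(self) -> None:
        for name in ("h_sd", "age_sd", "L3_sd", "f_sd"):
            if not getattr(self, name) > 0:
                raise DegenerateDataError(f"standardisation SD {name} is not positive")

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "StandardisationConstants":
        return cls(**{k: float(v) for k, v in d.items()})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "StandardisationConstants":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# dataset container
# --------------------------------------------------------------------------

INDIVIDUAL_COLUMNS = [
    "individual_id", "sex", "known_age", "min_age",
    "age_prior_loc", "age_prior_scale", "first_year",
]
BAI_COLUMNS = ["individual_id", "year", "days_before_season_end", "bai_mean", "bai_sd"]
FGC_COLUMNS = (
    ["individual_id", "year", "day_of_year", "fgc"]
    + [f"log_{h}" for h in HORMONES]
    + [f"{h}_below_lod" for h in HORMONES]
    + [f"{h}_lod" for h in HORMONES]
)
SIGHTING_COLUMNS = [
    "individual_id", "year", "encountered", "first_day",
    "calf_observed", "calf_reported_elsewhere",
]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


@dataclass
class Dataset:
    """The three observation tables plus individual metadata.

    ``individuals`` carries one row per animal (wide per-year length-prior
    columns ``length_mean_<year>``/``length_sd_<year>``); ``bai``, ``fgc``
    and ``sightings`` are long tables keyed by ``individual_id`` x ``year``.
    """

    individuals: pd.DataFrame
    bai: pd.DataFrame
    fgc: pd.DataFrame
    sightings: pd.DataFrame
    config: ModelConfig = field(default_factory=ModelConfig)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.individuals["individual_id"])

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise ``SchemaError``/``ConsistencyError`` on any violation."""
        cfg = self.config
        _require_columns(self.individuals, INDIVIDUAL_COLUMNS, "individuals.csv")
        _require_columns(self.bai, BAI_COLUMNS, "bai.csv")
        _require_columns(self.fgc, FGC_COLUMNS, "fgc.csv")
        _require_columns(self.sightings, SIGHTING_COLUMNS, "sightings.csv")

        ids = self.individuals["individual_id"]
        if ids.duplicated().any():
            raise ConsistencyError("duplicate individual_id in individuals.csv")
        known = set(ids)
        for name, tab in (("bai", self.bai), ("fgc", self.fgc), ("sightings", self.sightings)):
            bad = set(tab["individual_id"]) - known
            if bad:
                raise ConsistencyError(f"{name}.csv references unknown individuals {sorted(bad)[:5]}")
            years = tab["year"].to_numpy()
            if len(years) and (years.min() < cfg.years[0] or years.max() > cfg.years[-1]):
                raise ConsistencyError(f"{name}.csv has years outside {cfg.years[0]}-{cfg.years[-1]}")

        ind = self.individuals
        for _, row in ind.iterrows():
            IndividualRecord(
                individual_id=str(row["individual_id"]),
                sex=str(row["sex"]),
                known_age=bool(row["known_age"]),
                min_age=float(row["min_age"]),
                age_prior_loc=float(row["age_prior_loc"]),
                age_prior_scale=float(row["age_prior_scale"]),
                first_year=int(row["first_year"]),
                length_mean={
                    y: float(row[f"length_mean_{y}"]) for y in cfg.years
                    if f"length_mean_{y}" in row and np.isfinite(row[f"length_mean_{y}"])
                },
                length_sd={
                    y: float(row[f"length_sd_{y}"]) for y in cfg.years
                    if f"length_sd_{y}" in row and np.isfinite(row[f"length_sd_{y}"])
                },
            )

        b = self.bai
        if (b["bai_sd"].to_numpy() <= 0).any():
            raise ConsistencyError("bai.csv: bai_sd must be > 0")
        if ((b["bai_mean"] <= 10) | (b["bai_mean"] >= 50)).any():
            raise ConsistencyError("bai.csv: bai_mean outside sanity bounds (10, 50)")
        if (b["days_before_season_end"].to_numpy() < 0).any():
            raise ConsistencyError("bai.csv: measurements must precede the season end (d >= 0)")

        f = self.fgc
        doy = f["day_of_year"].to_numpy()
        if len(doy) and (doy.min() < 1 or doy.max() > 366):
            raise ConsistencyError("fgc.csv: day_of_year outside [1, 366]")
        if (f["fgc"].to_numpy() < 0).any():
            raise ConsistencyError("fgc.csv: negative fGC concentration")
        for h in HORMONES:
            cens = f[f"{h}_below_lod"].astype(bool).to_numpy()
            lod = f[f"{h}_lod"].to_numpy(dtype=float)
            if cens.any() and not (np.isfinite(lod[cens]) & (lod[cens] > 0)).all():
                raise ConsistencyError(
                    f"fgc.csv: below-LOD {h} rows need a finite positive LOD bound"
                )
            vals = f[f"log_{h}"].to_numpy(dtype=float)
            if (~cens & ~np.isfinite(vals)).any():
                raise ConsistencyError(f"fgc.csv: missing log_{h} on an uncensored row")

        s = self.sightings
        enc = s["encountered"].astype(bool).to_numpy()
        k = s["calf_observed"].astype(bool).to_numpy()
        if (k & ~enc).any():
            raise ConsistencyError(
                "sightings.csv: calf_observed=1 requires encountered=1 (observation-model support)"
            )
        fd = s["first_day"].to_numpy(dtype=float)
        if (enc & ~np.isfinite(fd)).any():
            raise ConsistencyError("sightings.csv: first_day required when encountered=1")

        # calving support: no calf evidence for known males or known-immature
        # females, no consecutive years
        sex_by_id = dict(zip(ind["individual_id"], ind["sex"]))
        known_age_by_id = {
            r["individual_id"]: (r["age_prior_loc"], r["first_year"])
            for _, r in ind.iterrows() if r["known_age"]
        }
        evid = s[k | s["calf_reported_elsewhere"].astype(bool).to_numpy()]
        for iid, grp in evid.groupby("individual_id"):
            if sex_by_id.get(iid) == "male":
                raise ConsistencyError(f"calf evidence for known male {iid}")
            yrs = np.sort(grp["year"].to_numpy())
            if iid in known_age_by_id:
                age0, y0 = known_age_by_id[iid]
                if age0 + (yrs.min() - y0) < cfg.maturity_age:
                    raise ConsistencyError(
                        f"calf evidence for {iid} before sexual maturity "
                        f"(age {cfg.maturity_age})"
                    )
            if len(yrs) > 1 and (np.diff(yrs) == 1).any():
                raise ConsistencyError(
                    f"calf evidence in consecutive years for {iid}; the minimum "
                    "inter-calf interval is 2 years"
                )

    # -- conversion ---------------------------------------------------------

    def to_arrays(self) -> "ModelArrays":
        return ModelArrays.from_dataset(self)


@dataclass
class ModelArrays:
    """Dense array view of a :class:`Dataset` used by densities and MCMC.

    Individuals are rows ``0..N-1`` (order of ``individuals.csv``), years are
    columns ``0..T-1``.  Inactive cells (before an animal's entry year) are
    masked by ``active``.
    """

    config: ModelConfig
    ids: list[str]
    entry_t: np.ndarray          # (N,) int
    active: np.ndarray           # (N,T) bool
    sex_code: np.ndarray         # (N,) int: 1 female, 0 male, -1 unknown
    known_age: np.ndarray        # (N,) bool
    min_age: np.ndarray          # (N,) float, at entry year
    age_loc: np.ndarray          # (N,) float
    age_scale: np.ndarray        # (N,) float (0 allowed when known_age)
    L_mean: np.ndarray           # (N,T) float, NaN when absent
    L_sd: np.ndarray             # (N,T)
    b_i: np.ndarray              # BAI obs -> individual index
    b_t: np.ndarray
    b_d: np.ndarray
    b_mean: np.ndarray
    b_sd: np.ndarray
    f_i: np.ndarray              # fGC obs
    f_t: np.ndarray
    f_day: np.ndarray
    f_fgc: np.ndarray
    f_m: np.ndarray              # (nobs,3) log hormone covariates, NaN if censored
    f_cens: np.ndarray           # (nobs,3) bool
    f_lod: np.ndarray            # (nobs,3) concentration-scale upper bounds
    e: np.ndarray                # (N,T) bool encountered
    first_day: np.ndarray        # (N,T) float NaN
    k: np.ndarray                # (N,T) bool calf observed in study area
    elsewhere: np.ndarray        # (N,T) bool calf reported elsewhere

    @property
    def n_ind(self) -> int:
        return len(self.ids)

    @property
    def n_years(self) -> int:
        return self.config.n_years

    @property
    def n_bai(self) -> int:
        return len(self.b_mean)

    @property
    def n_fgc(self) -> int:
        return len(self.f_fgc)

    @classmethod
    def from_dataset(cls, ds: Dataset) -> "ModelArrays":
        cfg = ds.config
        ids = ds.individual_ids
        idx = {iid: j for j, iid in enumerate(ids)}
        N, T = len(ids), cfg.n_years

        ind = ds.individuals
        entry_t = np.clip(ind["first_year"].to_numpy(int) - cfg.years[0], 0, T - 1)
        active = np.arange(T)[None, :] >= entry_t[:, None]
        sex_code = ind["sex"].map({"female": 1, "male": 0, "unknown": -1}).to_numpy(int)

        L_mean = np.full((N, T), np.nan)
        L_sd = np.full((N, T), np.nan)
        for t, y in enumerate(cfg.years):
            cm, cs = f"length_mean_{y}", f"length_sd_{y}"
            if cm in ind.columns:
                L_mean[:, t] = ind[cm].to_numpy(float)
                L_sd[:, t] = ind[cs].to_numpy(float)

        def _ind_idx(tab):
            return tab["individual_id"].map(idx).to_numpy(int)

        b = ds.bai
        f = ds.fgc
        s = ds.sightings

        e = np.zeros((N, T), bool)
        first_day = np.full((N, T), np.nan)
        k = np.zeros((N, T), bool)
        elsewhere = np.zeros((N, T), bool)
        si, st = _ind_idx(s), s["year"].to_numpy(int) - cfg.years[0]
        e[si, st] = s["encountered"].astype(bool).to_numpy()
        first_day[si, st] = s["first_day"].to_numpy(float)
        k[si, st] = s["calf_observed"].astype(bool).to_numpy()
        elsewhere[si, st] = s["calf_reported_elsewhere"].astype(bool).to_numpy()

        return cls(
            config=cfg,
            ids=ids,
            entry_t=entry_t,
            active=active,
            sex_code=sex_code,
            known_age=ind["known_age"].astype(bool).to_numpy(),
            min_age=ind["min_age"].to_numpy(float),
            age_loc=ind["age_prior_loc"].to_numpy(float),
            age_scale=ind["age_prior_scale"].to_numpy(float),
            L_mean=L_mean,
            L_sd=L_sd,
            b_i=_ind_idx(b),
            b_t=b["year"].to_numpy(int) - cfg.years[0],
            b_d=b["days_before_season_end"].to_numpy(float),
            b_mean=b["bai_mean"].to_numpy(float),
            b_sd=b["bai_sd"].to_numpy(float),
            f_i=_ind_idx(f),
            f_t=f["year"].to_numpy(int) - cfg.years[0],
            f_day=f["day_of_year"].to_numpy(float),
            f_fgc=f["fgc"].to_numpy(float),
            f_m=np.column_stack([f[f"log_{h}"].to_numpy(float) for h in HORMONES])
            if len(f) else np.zeros((0, 3)),
            f_cens=np.column_stack([f[f"{h}_below_lod"].astype(bool).to_numpy() for h in HORMONES])
            if len(f) else np.zeros((0, 3), bool),
            f_lod=np.column_stack([f[f"{h}_lod"].to_numpy(float) for h in HORMONES])
            if len(f) else np.zeros((0, 3)),
            e=e,
            first_day=first_day,
            k=k,
            elsewhere=elsewhere,
        )

    def ages(self, age_at_entry: np.ndarray) -> np.ndarray:
        """(N,T) age matrix given each animal's age in its entry year."""
        return age_at_entry[:, None] + (np.arange(self.n_years)[None, :] - self.entry_t[:, None])


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

_FILES = {"individuals": "individuals.csv", "bai": "bai.csv",
          "fgc": "fgc.csv", "sightings": "sightings.csv"}


def write_dataset(ds: Dataset, directory: str | Path) -> None:
    """Write the four CSVs (and the config as YAML) into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _FILES.items():
        getattr(ds, attr).to_csv(directory / fname, index=False)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(ds.config.to_dict(), fh)


def load_dataset(directory: str | Path, config: ModelConfig | None = None) -> Dataset:
    """Read and validate the four CSVs from ``directory``.

    If ``config`` is None and a ``config.yaml`` sits next to the CSVs it is
    used; otherwise defaults apply.
    """
    directory = Path(directory)
    if config is None:
        cfg_path = directory / "config.yaml"
        config = ModelConfig.from_yaml(cfg_path) if cfg_path.exists() else ModelConfig()
    tables = {}
    for attr, fname in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise SchemaError(f"missing required file {fname} in {directory}")
        tables[attr] = pd.read_csv(path)
    ds = Dataset(config=config, **tables)
    ds.validate()
    return ds


# --------------------------------------------------------------------------
# standardisation
# --------------------------------------------------------------------------


def compute_standardisation(ds: Dataset | ModelArrays) -> StandardisationConstants:
    """Means/SDs (population convention, ddof=0) for the model covariates.

    * nutritional state: per individual-year mean of observed BAI means;
    * age: prior-mean ages expanded over each animal's active years;
    * cubed length: prior length means cubed over active years;
    * first sighting day: all observed first days.

    Raises :class:`DegenerateDataError` when any quantity has zero variance.
    """
    arr = ds.to_arrays() if isinstance(ds, Dataset) else ds
    if arr.n_bai == 0:
        raise DegenerateDataError("no BAI observations to standardise against")

    key = arr.b_i * arr.n_years + arr.b_t
    sums = np.bincount(key, weights=arr.b_mean, minlength=arr.n_ind * arr.n_years)
    cnts = np.bincount(key, minlength=arr.n_ind * arr.n_years)
    h_vals = sums[cnts > 0] / cnts[cnts > 0]

    age_mat = arr.ages(arr.age_loc)
    age_vals = age_mat[arr.active]
    L3_vals = arr.L_mean[arr.active & np.isfinite(arr.L_mean)] ** 3
    f_vals = arr.first_day[np.isfinite(arr.first_day)]

    def _ms(x, label):
        m, s = float(np.mean(x)), float(np.std(x))
        if not s > 0:
            raise DegenerateDataError(f"zero variance in {label}; cannot standardise")
        return m, s

    h_mean, h_sd = _ms(h_vals, "individual-year BAI means")
    age_mean, age_sd = _ms(age_vals, "ages")
    L3_mean, L3_sd = _ms(L3_vals, "cubed lengths")
    if len(f_vals):
        f_mean, f_sd = _ms(f_vals, "first sighting days")
    else:
        f_mean, f_sd = 0.0, 1.0
    return StandardisationConstants(h_mean, h_sd, age_mean, age_sd,
                                    L3_mean, L3_sd, f_mean, f_sd)
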