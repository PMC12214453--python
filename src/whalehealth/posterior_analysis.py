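"""Posterior summaries and derived results.

Covers the quantities a fitted model reports: parameter summary tables
(posterior medians, 95% credible intervals, sign probabilities, R-hat and
effective sample size), calving-probability effect curves and the combined
length x nutrition surface, classification metrics of the calving model,
the posterior distribution of missed calving events, the population age
structure, and parameter-recovery tables for simulation experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gaussian_kde

from .data_model import Dataset, ModelArrays, ParameterSet
from .inference import PosteriorDraws

__all__ = [
    "summarize",
    "effect_curves",
    "effect_surface",
    "classification_metrics",
    "missed_calving_count",
    "age_structure",
    "recovery_report",
    "aggregate_recovery",
]


def summarize(draws: PosteriorDraws, names=None) -> pd.DataFrame:
    """Posterior medians, central 95% intervals and sign probabilities.

    ``p_positive`` is the fraction of the posterior at or above zero, the
    form used to report effect-direction statements.  R-hat/ESS columns are
    included when at least two chains are available.
    """
    if draws.n_draws == 0:
        raise ValueError("empty posterior draws")
    names = list(names) if names is not None else list(draws.param_names)
    rows = {}
    for n in names:
        x = draws.flat(n)
        rows[n] = {
            "median": np.median(x),
            "q2.5": np.quantile(x, 0.025),
            "q97.5": np.quantile(x, 0.975),
            "mean": x.mean(),
            "sd": x.std(),
            "p_positive": float((x >= 0).mean()),
        }
    out = pd.DataFrame(rows).T
    if draws.n_chains >= 2 and draws.n_draws >= 4:
        from .inference import diagnostics

        diag = diagnostics({n: draws.param(n) for n in names})
        out["rhat"] = diag["rhat"]
        out["ess"] = diag["ess"]
    return out


_CURVE_COEF = {"length": "gamma3", "nutrition": "gamma2", "stress_residual": "gamma4"}


def _standardised_grid(draws: PosteriorDraws, covariate: str, grid: np.ndarray):
    c = draws.constants
    if covariate == "length":
        return (np.asarray(grid, float) ** 3 - c.L3_mean) / c.L3_sd
    if covariate == "nutrition":
        return (np.asarray(grid, float) - c.h_mean) / c.h_sd
    if covariate == "stress_residual":
        return np.asarray(grid, float)  # already a residual on the log-fGC scale
    raise ValueError(f"unknown covariate {covariate!r}")


def effect_curves(draws: PosteriorDraws, covariate: str,
                  grid: np.ndarray | None = None) -> pd.DataFrame:
    """Median and 95% CI of calving probability along one covariate.

    The other two covariates sit at their (standardised) mean of zero.
    ``covariate`` is one of ``length`` (metres), ``nutrition`` (BAI scale)
    or ``stress_residual`` (log-fGC scale).
    """
    if grid is None:
        grid = {"length": np.linspace(9.0, 13.5, 60),
                "nutrition": np.linspace(23.0, 33.0, 60),
                "stress_residual": np.linspace(-1.5, 1.5, 60)}[covariate]
    xs = _standardised_grid(draws, covariate, grid)
    coef = draws.flat(_CURVE_COEF[covariate])
    g1 = draws.flat("gamma1")
    phi = expit(g1[:, None] + coef[:, None] * xs[None, :])
    return pd.DataFrame({
        "value": grid,
        "median": np.median(phi, axis=0),
        "q2.5": np.quantile(phi, 0.025, axis=0),
        "q97.5": np.quantile(phi, 0.975, axis=0),
    })


def effect_surface(draws: PosteriorDraws,
                   length_grid: np.ndarray | None = None,
                   nutrition_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Posterior-median calving probability over length x nutritional state."""
    length_grid = np.linspace(9.0, 13.5, 40) if length_grid is None else length_grid
    nutrition_grid = np.linspace(23.0, 33.0, 40) if nutrition_grid is None else nutrition_grid
    Ls = _standardised_grid(draws, "length", length_grid)
    hs = _standardised_grid(draws, "nutrition", nutrition_grid)
    g1, g2, g3 = (draws.flat(n) for n in ("gamma1", "gamma2", "gamma3"))
    med = np.empty((len(length_grid), len(nutrition_grid)))
    for a, Lz in enumerate(Ls):
        phi = expit(g1[:, None] + g2[:, None] * hs[None, :] + g3[:, None] * Lz)
        med[a] = np.median(phi, axis=0)
    out = pd.DataFrame(med, index=pd.Index(length_grid, name="length_m"),
                       columns=pd.Index(nutrition_grid, name="nutritional_state"))
    return out


def _arrays(dataset) -> ModelArrays:
    return dataset.to_arrays() if isinstance(dataset, Dataset) else dataset


def classification_metrics(draws: PosteriorDraws, dataset, threshold: float = 0.5) -> dict:
    """Sensitivity/specificity/AUC of posterior calving scores.

    Labels follow the documented operational choice: positives are
    female-years with an observed calf (in the study area or reported
    elsewhere); negatives are encounter-confirmed calf-free years of
    animals that are mature females under the posterior (probability of
    being a mature female > 0.5).  The score is the posterior mean of
    ``phi * (1 - P)``, the probability of an available female calving.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    from sklearn.metrics import roc_auc_score

    data = _arrays(dataset)
    T = data.n_years
    if draws.phi_avail is None:
        raise ValueError("draws were stored without latent states")
    score = np.nanmean(draws.phi_avail.reshape(-1, data.n_ind, T), axis=0)
    mature_p = np.isfinite(draws.phi_avail.reshape(-1, data.n_ind, T)).mean(axis=0)

    pos = data.k | data.elsewhere
    neg = data.e & ~pos & (mature_p > 0.5)
    mask = pos | neg
    if not pos.any() or not (neg & np.isfinite(score)).any():
        raise ValueError("no mature female-years with both labels available")
    y = pos[mask].astype(int)
    x = np.nan_to_num(score[mask], nan=0.0)
    pred = x >= threshold
    sens = float((pred & (y == 1))[y == 1].mean()) if (y == 1).any() else np.nan
    spec = float((~pred)[y == 0].mean()) if (y == 0).any() else np.nan
    auc = float(roc_auc_score(y, x)) if len(np.unique(y)) == 2 else np.nan
    return {"sensitivity": sens, "specificity": spec, "auc": auc,
            "n_positive": int(y.sum()), "n_negative": int((y == 0).sum())}


def missed_calving_count(draws: PosteriorDraws, dataset) -> dict:
    """Posterior of the number of calving events with no observation.

    An event is missed when the model infers ``c = 1`` in a year with no
    calf seen in the study area and none reported elsewhere.
    """
    data = _arrays(dataset)
    T = data.n_years
    if draws.c is None:
        raise ValueError("draws were stored without calving sequences")
    c = draws.c.reshape(-1, data.n_ind, T + 1)[:, :, :T]
    unseen = ~(data.k | data.elsewhere)
    counts = ((c == 1) & unseen[None, :, :]).sum(axis=(1, 2))
    return {
        "median": float(np.median(counts)),
        "q2.5": float(np.quantile(counts, 0.025)),
        "q97.5": float(np.quantile(counts, 0.975)),
        "samples": counts,
    }


def age_structure(dataset, reference_year: int,
                  draws: PosteriorDraws | None = None,
                  bandwidth: float | str = "silverman",
                  grid: np.ndarray | None = None) -> dict:
    """Per-age counts at a reference year, split known/estimated, plus a
    kernel density estimate (Silverman bandwidth by default)."""
    data = _arrays(dataset)
    t_ref = reference_year - data.config.years[0]
    if data.n_ind == 0:
        raise ValueError("empty cohort")
    if draws is not None and draws.age_entry is not None:
        age_entry = np.median(draws.age_entry.reshape(-1, data.n_ind), axis=0)
    else:
        age_entry = np.where(data.known_age, data.age_loc,
                             np.maximum(data.min_age, data.age_loc))
    ages = np.round(age_entry + (t_ref - data.entry_t)).astype(int)
    keep = ages >= 0
    ages, known = ages[keep], data.known_age[keep]
    table = (pd.DataFrame({"age": ages, "known": known})
             .groupby(["age", "known"]).size().unstack(fill_value=0))
    kde = gaussian_kde(ages.astype(float), bw_method=bandwidth)
    if grid is None:
        grid = np.linspace(0, ages.max() + 5, 200)
    return {"counts": table, "kde_grid": grid, "kde_density": kde(grid),
            "ages": ages}


def plot_effect_curves(draws: PosteriorDraws, path) -> None:
    """Three-panel figure: calving probability against length, nutritional
    state and residual stress (posterior median and 95% band)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = {"length": "body length (m)",
              "nutrition": "nutritional state (BAI scale)",
              "stress_residual": "residual stress (log-fGC)"}
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharey=True)
    for ax, cov in zip(axes, labels):
        cur = effect_curves(draws, cov)
        ax.fill_between(cur["value"], cur["q2.5"], cur["q97.5"], alpha=0.3)
        ax.plot(cur["value"], cur["median"], color="k")
        ax.set_xlabel(labels[cov])
    axes[0].set_ylabel("calving probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_age_structure(structure: dict, path) -> None:
    """Bar chart of per-age counts (known vs estimated) with the KDE."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = structure["counts"]
    ages = counts.index.to_numpy()
    known = counts[True] if True in counts.columns else np.zeros(len(counts))
    est = counts[False] if False in counts.columns else np.zeros(len(counts))
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(ages, est, label="estimated age", color="#88a")
    ax.bar(ages, known, bottom=est, label="known age", color="#c66")
    scale = max((np.asarray(est) + np.asarray(known)).max(), 1)
    dens = structure["kde_density"]
    ax.plot(structure["kde_grid"], dens / max(dens.max(), 1e-12) * scale,
            color="darkred", label="kernel density")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("number of individuals")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def recovery_report(draws: PosteriorDraws, truth: dict) -> pd.DataFrame:
    """Per-parameter bias, CI coverage and interval width against truth.

    ``truth`` is the simulator's bundle (or any mapping with a ``params``
    entry); parameter names must match the fitted parameter set.
    """
    tp = truth["params"] if "params" in truth else truth
    unknown = set(tp) - set(draws.param_names)
    if unknown:
        raise KeyError(f"truth names not in the fitted parameter set: {sorted(unknown)}")
    rows = {}
    for n, tv in tp.items():
        x = draws.flat(n)
        lo, hi = np.quantile(x, [0.025, 0.975])
        med = float(np.median(x))
        rows[n] = {
            "truth": tv,
            "median": med,
            "bias": med - tv,
            "q2.5": lo,
            "q97.5": hi,
            "covered": bool(lo <= tv <= hi),
            "width": hi - lo,
            "sign_match": bool(np.sign(med) == np.sign(tv)) if tv != 0 else True,
        }
    return pd.DataFrame(rows).T


def aggregate_recovery(reports: list[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-replicate recovery tables: mean bias, coverage rate,
    sign-match rate and mean interval width per parameter."""
    if not reports:
        raise ValueError("no recovery reports to aggregate")
    cat = pd.concat(reports, keys=range(len(reports)), names=["replicate"])
    return cat.groupby(level=1).agg(
        truth=("truth", "first"),
        mean_bias=("bias", "mean"),
        coverage=("covered", "mean"),
        sign_match=("sign_match", "mean"),
        mean_width=("width", "mean"),
    )
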