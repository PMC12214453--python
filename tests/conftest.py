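import numpy as np
import pytest

from whalehealth.data_model import ModelConfig, ParameterSet, StandardisationConstants
from whalehealth.model_density import DensityContext, LatentState, default_priors
from whalehealth.synthetic_data import default_scenario, make_study_like_dataset


@pytest.fixture(scope="session")
def study_dataset():
    """One study-like synthetic dataset (~139 whales, 8 years) plus truth."""
    return make_study_like_dataset(1)


@pytest.fixture(scope="session")
def study_arrays(study_dataset):
    ds, truth = study_dataset
    return ds.to_arrays(), truth


def make_toy(seed: int = 9):
    """Tiny 4-year instance satisfying the brute-force oracle preconditions
    (fixed yearly effects, no residual-stress lag, known ages, no censoring)
    while exercising females, unknown sex and a calf detection."""
    cfg = ModelConfig(years=tuple(range(2016, 2020)))
    base = default_scenario()
    scn = base.replace(
        config=cfg, n_individuals=3, retain_only_measured=False,
        elsewhere_report_prob=0.0, age_known_prob=1.0, sex_known_prob=1.0,
        censor_hormones=False, bai_rate=0.5, fgc_rate=0.4,
        params=base.params.replace(chi_h=0.0, chi_s=0.0, gamma4=0.0, gamma1=-1.0),
    )
    ds, truth = make_study_like_dataset(seed, scn)
    return ds, truth, scn


@pytest.fixture(scope="session")
def toy_instance():
    return make_toy()


def context_from_truth(arrays, truth, seed: int = 0) -> DensityContext:
    """DensityContext at the generating truth (finite joint by construction)."""
    rng = np.random.default_rng(seed)
    T = arrays.n_years
    h = np.nan_to_num(np.array(truth["h"], float), nan=truth["params"]["lam_h"])
    s = np.nan_to_num(np.array(truth["s"], float), nan=truth["params"]["lam_s"])
    m = arrays.f_m.copy()
    if arrays.f_cens.any():
        m[arrays.f_cens] = np.log(arrays.f_lod[arrays.f_cens] / 2.0)
    state = LatentState(
        H=np.array(truth["H"], float),
        S=np.array(truth["S"], float),
        h=h, s=s,
        L=np.where(np.isfinite(arrays.L_mean), arrays.L_mean, 11.0),
        age_entry=np.array(truth["age_entry"], float),
        g=np.array(truth["sex"], int),
        c=np.array(truth["c"], np.int8),
        m=m,
    )
    return DensityContext(
        data=arrays,
        state=state,
        params=ParameterSet(**truth["params"]),
        constants=StandardisationConstants.from_dict(truth["constants"]),
        priors=default_priors(),
    )


@pytest.fixture()
def truth_context(study_arrays):
    arrays, truth = study_arrays
    return context_from_truth(arrays, truth)
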