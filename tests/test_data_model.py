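import numpy as np
import pandas as pd
import pytest

from whalehealth.data_model import (
    ConsistencyError,
    Dataset,
    DegenerateDataError,
    ModelConfig,
    ParameterSet,
    SchemaError,
    StandardisationConstants,
    compute_standardisation,
    load_dataset,
    write_dataset,
)


def _tiny_dataset(lengths=(10.0, 12.0), bai_means=(20.0, 24.0)):
    cfg = ModelConfig(years=(2016, 2017, 2018))
    ind = pd.DataFrame({
        "individual_id": ["a", "b"],
        "sex": ["female", "male"],
        "known_age": [1, 1],
        "min_age": [5.0, 7.0],
        "age_prior_loc": [5.0, 7.0],
        "age_prior_scale": [0.0, 0.0],
        "first_year": [2016, 2016],
    })
    for y in cfg.years:
        ind[f"length_mean_{y}"] = list(lengths)
        ind[f"length_sd_{y}"] = [0.2, 0.2]
    bai = pd.DataFrame({
        "individual_id": ["a", "b"],
        "year": [2016, 2016],
        "days_before_season_end": [10.0, 50.0],
        "bai_mean": list(bai_means),
        "bai_sd": [0.5, 0.5],
    })
    fgc = pd.DataFrame({
        "individual_id": ["a"], "year": [2016], "day_of_year": [200.0],
        "fgc": [30.0], "log_progestin": [3.0], "log_androgen": [2.5],
        "log_thyroid": [2.0], "progestin_below_lod": [False],
        "androgen_below_lod": [False], "thyroid_below_lod": [False],
        "progestin_lod": [np.nan], "androgen_lod": [np.nan], "thyroid_lod": [np.nan],
    })
    sight = pd.DataFrame({
        "individual_id": ["a", "b", "a"], "year": [2016, 2016, 2017],
        "encountered": [1, 0, 1], "first_day": [180.0, np.nan, 220.0],
        "calf_observed": [0, 0, 0], "calf_reported_elsewhere": [0, 0, 0],
    })
    return Dataset(individuals=ind, bai=bai, fgc=fgc, sightings=sight, config=cfg)


class TestValidation:
    def test_valid_dataset_passes(self):
        _tiny_dataset().validate()

    def test_calf_without_encounter_rejected(self):
        ds = _tiny_dataset()
        ds.sightings.loc[1, "calf_observed"] = 1
        with pytest.raises(ConsistencyError, match="encountered"):
            ds.validate()

    def test_calf_for_known_male_rejected(self):
        ds = _tiny_dataset()
        ds.sightings.loc[1, "encountered"] = 1
        ds.sightings.loc[1, "first_day"] = 150.0
        ds.sightings.loc[1, "calf_observed"] = 1
        with pytest.raises(ConsistencyError, match="male"):
            ds.validate()

    def test_missing_column_names_column(self):
        ds = _tiny_dataset()
        ds.bai = ds.bai.drop(columns=["bai_sd"])
        with pytest.raises(SchemaError, match="bai_sd"):
            ds.validate()

    def test_unknown_individual_rejected(self):
        ds = _tiny_dataset()
        ds.bai.loc[0, "individual_id"] = "ghost"
        with pytest.raises(ConsistencyError, match="ghost"):
            ds.validate()

    def test_below_lod_needs_bound(self):
        ds = _tiny_dataset()
        ds.fgc.loc[0, "progestin_below_lod"] = True
        with pytest.raises(ConsistencyError, match="LOD"):
            ds.validate()

    def test_consecutive_calving_evidence_rejected(self):
        ds = _tiny_dataset()
        extra = ds.sightings.iloc[[0, 0]].copy()
        extra["year"] = [2017, 2018]
        extra["calf_reported_elsewhere"] = [1, 1]
        ds.individuals.loc[0, ["min_age", "age_prior_loc"]] = 12.0
        ds.sightings = pd.concat([ds.sightings, extra], ignore_index=True)
        with pytest.raises(ConsistencyError, match="inter-calf"):
            ds.validate()


class TestRoundTrip:
    def test_writer_reader_round_trip(self, tmp_path, study_dataset):
        ds, _ = study_dataset
        write_dataset(ds, tmp_path)
        back = load_dataset(tmp_path)
        assert back.individual_ids == ds.individual_ids
        a, b = back.to_arrays(), ds.to_arrays()
        for name in ("b_mean", "b_sd", "b_d", "f_fgc", "f_day", "min_age", "L_mean"):
            np.testing.assert_allclose(getattr(a, name), getattr(b, name))
        np.testing.assert_array_equal(a.f_cens, b.f_cens)
        np.testing.assert_array_equal(a.k, b.k)
        np.testing.assert_array_equal(a.elsewhere, b.elsewhere)
        np.testing.assert_array_equal(a.sex_code, b.sex_code)

    def test_study_dataset_validates_cleanly(self, study_dataset):
        ds, _ = study_dataset
        ds.validate()


class TestStandardisation:
    def test_cubed_length_hand_calculation(self):
        # lengths 10 m and 12 m: cubes 1000 and 1728, population convention
        cst = compute_standardisation(_tiny_dataset())
        assert cst.L3_mean == pytest.approx(1364.0)
        assert cst.L3_sd == pytest.approx(364.0)
        assert cst.h_mean == pytest.approx(22.0)
        assert cst.h_sd == pytest.approx(2.0)

    def test_degenerate_lengths_raise(self):
        with pytest.raises(DegenerateDataError, match="cubed lengths"):
            compute_standardisation(_tiny_dataset(lengths=(11.0, 11.0)))

    def test_constants_round_trip(self, tmp_path):
        cst = compute_standardisation(_tiny_dataset())
        cst.save(tmp_path / "c.json")
        back = StandardisationConstants.load(tmp_path / "c.json")
        assert back == cst


class TestConfig:
    def test_unknown_config_key_rejected(self):
        with pytest.raises(SchemaError, match="valid keys"):
            ModelConfig.from_dict({"maturity_age": 8, "banana": 1})

    def test_parameter_set_rejects_negative_sd(self):
        with pytest.raises(ValueError, match="non-negative"):
            ParameterSet(sigma_h=-1.0)

    def test_parameter_array_round_trip(self):
        p = ParameterSet(beta_h=0.4, gamma3=1.36)
        assert ParameterSet.from_array(p.to_array()) == p
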