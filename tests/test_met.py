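"""The boosted-tree meteorology emulator and the 2020-vs-climatology contrast."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from aqattrib.calendar_windows import TOTAL_LOCKDOWN, CnyCalendar
from aqattrib.ingest import InsufficientDataError
from aqattrib.met import (
    build_features,
    climatological_met,
    met_effect,
    met_feature_rows,
    panel_met_effect,
    predict_bau,
    rolling_cv,
    train_final,
)
from aqattrib.synthetic import SyntheticConfig, generate_city

FAST = {"n_estimators": 150}


@pytest.fixture(scope="module")
def city_features(calendar):
    config = SyntheticConfig(n_cities=1, seed=13)
    panel, _ = generate_city(config, 0)
    return panel, build_features(panel, "NO2", calendar)


def test_feature_encodings(city_features, calendar):
    panel, features = city_features
    assert features.loc[features["cny_flag"] == 1].index.min() is not pd.NaT
    cny_day = pd.Timestamp(calendar.cny_date(2019))
    assert features.loc[cny_day, "cny_flag"] == 1.0
    assert (features["hour_of_day"] == 0.0).all()
    # date_index increments by one across gap-free spans
    diffs = np.diff(features["date_index"].to_numpy())
    assert (diffs == 1).all()
    # wind direction on the unit circle
    norms = features["wd_sin"] ** 2 + features["wd_cos"] ** 2
    assert np.allclose(norms, 1.0)


def test_wd_encoding_cardinal_directions(calendar):
    idx = pd.DatetimeIndex(["2019-06-01", "2019-06-02"])
    met = pd.DataFrame(
        {"T": 20.0, "RH": 60.0, "WS": 2.0, "WD": [0.0, 90.0], "Pre": 0.0, "P": 1010.0},
        index=idx,
    )
    rows = met_feature_rows(met, idx, calendar, idx[0])
    assert rows["wd_sin"].to_numpy() == pytest.approx([0.0, 1.0], abs=1e-12)
    assert rows["wd_cos"].to_numpy() == pytest.approx([1.0, 0.0], abs=1e-12)


def test_rolling_cv_structure(city_features):
    _, features = city_features
    report = rolling_cv(features, params=FAST, seed=0)
    assert len(report.splits) == 5
    first = report.splits[0]
    assert first.train_start.year == 2015 and first.train_end.year == 2015
    assert first.test_start == pd.Timestamp("2016-01-01")
    assert first.test_end == pd.Timestamp("2016-03-31")
    for k, split in enumerate(report.splits):
        assert split.train_end < split.test_start  # train strictly precedes test
        assert split.train_start.year == 2015
        assert split.test_start.year == 2016 + k


def test_rolling_cv_requires_six_years(calendar):
    config = SyntheticConfig(n_cities=1, seed=13, years=(2018, 2019, 2020))
    panel, _ = generate_city(config, 0)
    features = build_features(panel, "NO2", calendar)
    with pytest.raises(InsufficientDataError, match="2018"):
        rolling_cv(features, params=FAST)


def test_cv_learnable_limit(city_features):
    """A noiseless deterministic function of the features is learned almost perfectly."""
    _, features = city_features
    learnable = features.copy()
    learnable["target"] = 30.0 + 4.0 * learnable["WS"] - 0.5 * (learnable["P"] - 1013.0)
    report = rolling_cv(learnable, params=FAST, seed=0)
    assert report.mean_pcc > 0.98
    assert report.mean_rmse < 0.1 * learnable["target"].mean()


def test_cv_unlearnable_target(city_features):
    _, features = city_features
    rng = np.random.default_rng(5)
    shuffled = features.copy()
    shuffled["target"] = rng.permutation(shuffled["target"].to_numpy())
    report = rolling_cv(shuffled, params=FAST, seed=0)
    assert abs(report.mean_pcc) < 0.3


def test_train_final_determinism(city_features):
    _, features = city_features
    train = features[features.index.year < 2020]
    test = features[features.index.year == 2020]
    a = train_final(train, params=FAST, seed=1).predict(test)
    b = train_final(train, params=FAST, seed=1).predict(test)
    assert np.array_equal(a, b)


def test_train_final_constant_target(city_features):
    _, features = city_features
    constant = features.copy()
    constant["target"] = 7.0
    with pytest.warns(UserWarning, match="constant"):
        emulator = train_final(constant)
    assert np.all(emulator.predict(constant) == 7.0)


def test_met_features_rank_highest_for_met_driven_target(city_features):
    _, features = city_features
    driven = features.copy()
    driven["target"] = 100.0 - 12.0 * driven["WS"]
    emulator = train_final(driven, params=FAST, seed=0)
    assert max(emulator.importances, key=emulator.importances.get) == "WS"


def test_predict_bau_clamps_negative(city_features):
    _, features = city_features
    negative = features.copy()
    negative["target"] = -5.0 + 0.01 * negative["WS"]
    emulator = train_final(negative, params=FAST, seed=0)
    preds = predict_bau(emulator, negative)
    assert (preds >= 0).all()
    assert emulator.n_clipped > 0


def test_predict_schema_mismatch(city_features):
    _, features = city_features
    emulator = train_final(features[features.index.year < 2020], params=FAST, seed=0)
    with pytest.raises(ValueError, match="missing columns"):
        emulator.predict(features.drop(columns=["WS"]))


def test_climatology_of_identical_years(calendar):
    """If all climatology years share the same met values, the average is that value."""
    config = SyntheticConfig(n_cities=1, seed=13)
    panel, _ = generate_city(config, 0)
    met = panel.met.copy()
    for col, value in (("T", 10.0), ("RH", 60.0), ("WS", 3.0), ("WD", 45.0),
                       ("Pre", 0.0), ("P", 1015.0)):
        met[col] = value
    panel.met = met
    clim = climatological_met(panel, calendar)
    assert np.allclose(clim["WS"], 3.0)
    assert np.allclose(clim["T"], 10.0)
    assert len(clim) == TOTAL_LOCKDOWN.n_days


def test_climatology_wind_direction_is_circular(calendar):
    """350 deg and 10 deg average to north (0 deg), not to south (180 deg)."""
    config = SyntheticConfig(n_cities=1, seed=13, years=(2018, 2019, 2020))
    panel, _ = generate_city(config, 0)
    met = panel.met.copy()
    met["WD"] = np.where(met.index.year == 2018, 350.0, 10.0)
    panel.met = met
    clim = climatological_met(panel, calendar, clim_years=(2018, 2019))
    assert np.allclose(clim["wd_sin"], 0.0, atol=1e-12)
    assert (clim["wd_cos"] > 0.9).all()


def test_met_effect_identity_contrast(city_features, calendar):
    """Identical feature tables give exactly zero, whatever the emulator."""
    panel, features = city_features
    emulator = train_final(features[features.index.year < 2020], params=FAST, seed=0)
    clim = climatological_met(panel, calendar)
    assert met_effect(emulator, clim, clim) == 0.0


def test_met_effect_single_city_recovery(calendar):
    """Low-noise single city: the contrast lands near the generator's truth."""
    config = SyntheticConfig(n_cities=1, seed=23, noise_sd=0.02)
    panel, truth = generate_city(config, 0)
    est = panel_met_effect([panel], "NO2", calendar, seed=0)
    assert est.per_city["city000"] == pytest.approx(
        truth.met_effect_no2_pct, abs=3.0
    )
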