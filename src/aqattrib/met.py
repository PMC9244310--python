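"""Gradient-boosted emulation of daily concentrations from meteorology.

The meteorology driver is estimated with one emulator per city and
pollutant: a gradient-boosted decision-tree model (LightGBM) is trained on
2015-2019 daily meteorology plus calendar features, validated with
expanding-window time-series cross-validation (train spans 2015, 2015-16,
..., 2015-19; test spans the first three months of the following year), and
then queried twice over the Total COVID-lockdown window of 2020: once with
the actual 2020 weather and once with the 2015-2019 climatological weather
aligned at equal CNY-relative day offsets.  The percentage contrast of the
two mean predictions is the meteorology effect.

Wind direction is circular and enters as sine/cosine components, which are
also what the climatology averages (vector averaging); all other features
are averaged arithmetically.  Hour-of-day is retained as a constant column
for schema compatibility with hourly-resolution variants and is inert in the
daily models.
"""
from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .calendar_windows import CNY_WINDOW, TOTAL_LOCKDOWN, CnyCalendar, WindowSpec
from .ingest import InsufficientDataError
from .synthetic import CityPanel

__all__ = [
    "FEATURE_COLUMNS",
    "CvReport",
    "GbmEmulator",
    "MetEffectEstimate",
    "build_features",
    "met_feature_rows",
    "rolling_cv",
    "train_final",
    "predict_bau",
    "climatological_met",
    "met_effect",
    "panel_met_effect",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = (
    "T",
    "RH",
    "WS",
    "wd_sin",
    "wd_cos",
    "Pre",
    "P",
    "julian_day",
    "day_of_week",
    "hour_of_day",
    "cny_flag",
    "date_index",
)

DEFAULT_MODEL_PARAMS = {
    "n_estimators": 400,
    "learning_rate": 0.05,
    "num_leaves": 31,
    "min_child_samples": 20,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
}


def _in_cny_window(date: dt.date, calendar: CnyCalendar) -> int:
    year = date.year
    if year not in calendar:
        return 0
    off = (date - calendar.cny_date(year)).days
    return int(CNY_WINDOW.start_offset <= off <= CNY_WINDOW.end_offset)


def met_feature_rows(
    met: pd.DataFrame,
    dates: pd.DatetimeIndex,
    calendar: CnyCalendar,
    origin: pd.Timestamp,
) -> pd.DataFrame:
    """Feature rows (no target) for the given dates from a meteorology table."""
    sub = met.reindex(dates)
    wd = np.deg2rad(sub["WD"].to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "T": sub["T"].to_numpy(dtype=float),
            "RH": sub["RH"].to_numpy(dtype=float),
            "WS": sub["WS"].to_numpy(dtype=float),
            "wd_sin": np.sin(wd),
            "wd_cos": np.cos(wd),
            "Pre": sub["Pre"].to_numpy(dtype=float),
            "P": sub["P"].to_numpy(dtype=float),
            "julian_day": dates.dayofyear.to_numpy(dtype=float),
            "day_of_week": dates.dayofweek.to_numpy(dtype=float),
            "hour_of_day": 0.0,
            "cny_flag": [
                float(_in_cny_window(d.date(), calendar)) for d in dates
            ],
            "date_index": (dates - origin).days.to_numpy(dtype=float),
        },
        index=dates,
    )
    return out


def build_features(
    panel: CityPanel,
    pollutant: str,
    calendar: CnyCalendar | None = None,
) -> pd.DataFrame:
    """One row per city-date with meteorological + calendar features and target.

    Rows with any missing predictor or target are dropped; the count of
    dropped rows is stored in ``frame.attrs["n_dropped"]``.
    """
    calendar = calendar or CnyCalendar()
    if panel.met.empty or panel.observed.empty:
        raise InsufficientDataError(f"{panel.city_id}: empty panel")
    dates = panel.met.index
    frame = met_feature_rows(panel.met, dates, calendar, dates[0])
    frame["target"] = panel.observed[pollutant].reindex(dates)
    n_before = len(frame)
    frame = frame.dropna()
    frame.attrs["n_dropped"] = n_before - len(frame)
    frame.attrs["origin"] = dates[0]
    if frame.attrs["n_dropped"]:
        logger.info(
            "%s/%s: dropped %d rows with missing values",
            panel.city_id,
            pollutant,
            frame.attrs["n_dropped"],
        )
    return frame


@dataclass
class GbmEmulator:
    """A trained boosted-tree (or constant fallback) emulator."""

    model: object
    feature_names: Tuple[str, ...]
    importances: Dict[str, float]
    constant: Optional[float] = None
    n_clipped: int = 0

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        x = features[list(self.feature_names)].astype(float)
        if self.constant is not None:
            return np.full(len(x), self.constant)
        raw = self.model.predict(x)
        clipped = raw < 0
        if clipped.any():
            self.n_clipped += int(clipped.sum())
            logger.info("clipped %d negative predictions to zero", clipped.sum())
        return np.maximum(raw, 0.0)


def _make_model(params: Optional[dict], seed: int):
    from lightgbm import LGBMRegressor

    merged = dict(DEFAULT_MODEL_PARAMS)
    if params:
        merged.update(params)
    return LGBMRegressor(
        **merged, random_state=seed, n_jobs=1, deterministic=True, verbose=-1
    )


def train_final(
    features: pd.DataFrame, params: Optional[dict] = None, seed: int = 0
) -> GbmEmulator:
    """Fit the emulator on all supplied rows (normally everything before 2020)."""
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    x = features[cols].astype(float)
    y = features["target"].to_numpy(dtype=float)
    if len(y) == 0:
        raise InsufficientDataError("no training rows")
    if np.ptp(y) == 0:
        warnings.warn("constant training target; returning a constant emulator")
        return GbmEmulator(
            model=None,
            feature_names=tuple(cols),
            importances={c: 0.0 for c in cols},
            constant=float(y[0]),
        )
    model = _make_model(params, seed)
    model.fit(x, y)
    importances = dict(zip(cols, model.feature_importances_.astype(float)))
    return GbmEmulator(model=model, feature_names=tuple(cols), importances=importances)


def predict_bau(emulator: GbmEmulator, features: pd.DataFrame) -> pd.Series:
    """Business-as-usual daily predictions (clamped at zero)."""
    return pd.Series(emulator.predict(features), index=features.index, name="predicted")


@dataclass(frozen=True)
class SplitScore:
    train_start: pd.Timestamp
    train_end: pd.Timestamp
    test_start: pd.Timestamp
    test_end: pd.Timestamp
    rmse: float
    pcc: float


@dataclass
class CvReport:
    splits: List[SplitScore]
    mean_rmse: float
    mean_pcc: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "train_start": s.train_start,
                    "train_end": s.train_end,
                    "test_start": s.test_start,
                    "test_end": s.test_end,
                    "rmse": s.rmse,
                    "pcc": s.pcc,
                }
                for s in self.splits
            ]
        )


def rolling_cv(
    features: pd.DataFrame,
    params: Optional[dict] = None,
    seed: int = 0,
    n_splits: int = 5,
    test_months: int = 3,
) -> CvReport:
    """Expanding-window time-series cross-validation.

    Split *k* (k = 1..n_splits) trains on calendar years ``y0 .. y0+k-1`` and
    tests on the first ``test_months`` months of year ``y0+k``; training data
    always strictly precede the test span.
    """
    years = sorted(features.index.year.unique())
    if len(years) < n_splits + 1:
        raise InsufficientDataError(
            f"rolling CV needs >= {n_splits + 1} calendar years, have {years}"
        )
    scores: List[SplitScore] = []
    for k in range(1, n_splits + 1):
        train_years = years[:k]
        test_year = years[k]
        train = features[features.index.year.isin(train_years)]
        test_end = pd.Timestamp(dt.date(test_year, test_months, 1)) + pd.offsets.MonthEnd(0)
        test = features[
            (features.index >= pd.Timestamp(dt.date(test_year, 1, 1)))
            & (features.index <= test_end)
        ]
        if train.empty or test.empty:
            raise InsufficientDataError(
                f"split {k}: empty train ({train_years}) or test ({test_year}) span"
            )
        assert train.index.max() < test.index.min(), "temporal hygiene violated"
        emulator = train_final(train, params=params, seed=seed)
        pred = emulator.predict(test)
        truth = test["target"].to_numpy(dtype=float)
        rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
        if np.ptp(pred) == 0 or np.ptp(truth) == 0:
            pcc = 0.0
        else:
            pcc = float(stats.pearsonr(pred, truth).statistic)
        scores.append(
            SplitScore(
                train_start=train.index.min(),
                train_end=train.index.max(),
                test_start=test.index.min(),
                test_end=test.index.max(),
                rmse=rmse,
                pcc=pcc,
            )
        )
    return CvReport(
        splits=scores,
        mean_rmse=float(np.mean([s.rmse for s in scores])),
        mean_pcc=float(np.mean([s.pcc for s in scores])),
    )


def climatological_met(
    panel: CityPanel,
    calendar: CnyCalendar | None = None,
    window: WindowSpec = TOTAL_LOCKDOWN,
    clim_years: Sequence[int] = (2015, 2016, 2017, 2018, 2019),
    target_year: int = 2020,
    origin: Optional[pd.Timestamp] = None,
) -> pd.DataFrame:
    """Climatological feature table for the target-year window.

    For each CNY-relative offset of ``window``, every meteorological feature
    is averaged across ``clim_years`` at that offset (wind direction through
    its sine/cosine components); calendar features are taken from the
    target-year date at the same offset, so the table is directly comparable
    with the actual target-year feature rows.
    """
    calendar = calendar or CnyCalendar()
    missing = [y for y in clim_years if y not in calendar]
    if missing:
        raise InsufficientDataError(f"climatology years missing from calendar: {missing}")
    origin = origin if origin is not None else panel.met.index[0]
    met_cols = ["T", "RH", "WS", "wd_sin", "wd_cos", "Pre", "P"]

    per_year = {}
    for year in clim_years:
        dates = pd.DatetimeIndex(
            [calendar.cny_date(year) + dt.timedelta(days=o) for o in window.offsets]
        )
        rows = met_feature_rows(panel.met, dates, calendar, origin)
        if rows[met_cols].isna().any().any():
            bad = rows[met_cols].isna().any(axis=1)
            raise InsufficientDataError(
                f"{panel.city_id}: missing meteorology in climatology year {year} "
                f"({int(bad.sum())} days)"
            )
        per_year[year] = rows[met_cols].to_numpy()

    clim = np.mean(np.stack(list(per_year.values())), axis=0)
    target_dates = pd.DatetimeIndex(
        [calendar.cny_date(target_year) + dt.timedelta(days=o) for o in window.offsets]
    )
    out = met_feature_rows(panel.met, target_dates, calendar, origin)
    out[met_cols] = clim
    return out


def met_effect(
    emulator: GbmEmulator, met_2020: pd.DataFrame, met_clim: pd.DataFrame
) -> float:
    """Percent contrast of mean predictions under actual vs climatological weather."""
    pred_2020 = emulator.predict(met_2020)
    pred_clim = emulator.predict(met_clim)
    denom = float(np.mean(pred_clim))
    if denom <= 0:
        raise UndefinedMetBaselineError(
            "mean prediction under climatological meteorology is not positive"
        )
    return 100.0 * (float(np.mean(pred_2020)) - denom) / denom


class UndefinedMetBaselineError(ValueError):
    """Climatological mean prediction is non-positive."""


@dataclass
class MetEffectEstimate:
    pollutant: str
    window: str
    per_city: Dict[str, float]
    national_mean: float
    national_sd: float
    n_cities: int


def panel_met_effect(
    panels: Sequence[CityPanel],
    pollutant: str,
    calendar: CnyCalendar | None = None,
    kept_ids: Optional[Sequence[str]] = None,
    params: Optional[dict] = None,
    seed: int = 0,
    window: WindowSpec = TOTAL_LOCKDOWN,
    train_years: Sequence[int] = (2015, 2016, 2017, 2018, 2019),
) -> MetEffectEstimate:
    """Meteorology driver across a panel: one emulator per kept city."""
    calendar = calendar or CnyCalendar()
    kept = None if kept_ids is None else set(kept_ids)
    per_city: Dict[str, float] = {}
    for panel in panels:
        if kept is not None and panel.city_id not in kept:
            continue
        features = build_features(panel, pollutant, calendar)
        train = features[features.index.year.isin(set(train_years))]
        emulator = train_final(train, params=params, seed=seed)
        dates_2020 = pd.DatetimeIndex(
            [calendar.cny_date(2020) + dt.timedelta(days=o) for o in window.offsets]
        )
        feat_2020 = met_feature_rows(
            panel.met, dates_2020, calendar, features.attrs["origin"]
        )
        feat_clim = climatological_met(
            panel,
            calendar,
            window=window,
            clim_years=train_years,
            origin=features.attrs["origin"],
        )
        per_city[panel.city_id] = met_effect(emulator, feat_2020, feat_clim)
    if not per_city:
        raise InsufficientDataError("no cities with an estimable meteorology effect")
    values = np.array(list(per_city.values()))
    return MetEffectEstimate(
        pollutant=pollutant,
        window=window.name,
        per_city=per_city,
        national_mean=float(values.mean()),
        national_sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        n_cities=len(values),
    )
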