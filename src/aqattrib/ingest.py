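"""Panel readers, grid-to-station interpolation and the slope/PCC quality filter.

A city is usable for attribution only when its counterfactual series tracks
the observations with near-unit gain: the per-city OLS slope S of observed
regressed on counterfactual must satisfy 0.5 < S < 1.5 and the Pearson
correlation PCC > 0.2 (strict inequalities), fitted on the pre-2020 record.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .synthetic import MET_VARS, POLLUTANTS, CityPanel

__all__ = [
    "PanelFormatError",
    "InsufficientDataError",
    "UndefinedSlopeError",
    "OutOfDomainError",
    "FilterWindow",
    "FitDiagnostics",
    "read_panel",
    "interpolate_grid_to_station",
    "fit_city_diagnostics",
    "panel_diagnostics",
    "apply_filter",
]


class PanelFormatError(ValueError):
    """A fixture file is malformed (bad date, missing column...)."""


class InsufficientDataError(ValueError):
    """Too few paired observations for a requested computation."""


class UndefinedSlopeError(ValueError):
    """The regressor series has zero variance; the slope is undefined."""


class OutOfDomainError(ValueError):
    """Station coordinates fall outside the gridded field."""


def _read_dated_csv(path: Path, date_col: str, date_format: str) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if date_col not in frame.columns:
        raise PanelFormatError(f"{path}: missing required column {date_col!r}")
    parsed = pd.to_datetime(frame[date_col], format=date_format, errors="coerce")
    if parsed.isna().any():
        row = int(parsed.isna().idxmax())
        raise PanelFormatError(
            f"{path}: line {row + 2}: invalid ISO-8601 date "
            f"{frame[date_col].iloc[row]!r}"
        )
    frame = frame.drop(columns=[date_col])
    frame.index = pd.DatetimeIndex(parsed.values)
    return frame


def read_panel(directory: str | Path) -> List[CityPanel]:
    """Read a fixture directory written by :func:`aqattrib.synthetic.write_fixture`.

    Missing dates stay missing (gaps are preserved, never filled with zeros).
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise PanelFormatError(f"{manifest_path}: manifest not found")
    manifest = pd.read_csv(manifest_path)
    panels: List[CityPanel] = []
    for row in manifest.itertuples(index=False):
        city_id = str(row.city_id)
        observed = _read_dated_csv(
            directory / f"{city_id}_observed.csv", "date", "%Y-%m-%d"
        )
        counterfactual = _read_dated_csv(
            directory / f"{city_id}_counterfactual.csv", "date", "%Y-%m-%d"
        )
        met = _read_dated_csv(
            directory / f"{city_id}_meteorology.csv", "date", "%Y-%m-%d"
        )
        hourly_path = directory / f"{city_id}_hourly_o3.csv"
        if getattr(row, "hourly_o3", False) and hourly_path.exists():
            hourly = _read_dated_csv(hourly_path, "time", "%Y-%m-%dT%H:%M:%S")
            hourly_o3 = hourly["O3"]
        else:
            hourly_o3 = pd.Series(dtype=float, name="O3")
        panels.append(
            CityPanel(
                city_id=city_id,
                lon=float(row.lon),
                lat=float(row.lat),
                population=float(row.population),
                region=str(row.region),
                observed=observed[list(POLLUTANTS)],
                counterfactual=counterfactual[list(POLLUTANTS)],
                met=met[list(MET_VARS)],
                hourly_o3=hourly_o3,
            )
        )
    return panels


def interpolate_grid_to_station(
    grid: "object", lon: float, lat: float
) -> float:
    """Bilinearly interpolate a 2-D (lat, lon) field to station coordinates.

    ``grid`` is either an ``xarray.DataArray`` with ``lon``/``lat``
    coordinates or a ``(lons, lats, values)`` triple where ``values`` has
    shape ``(len(lats), len(lons))``.  Exact at grid nodes; raises
    :class:`OutOfDomainError` outside the bounding box.
    """
    if hasattr(grid, "coords"):  # xarray.DataArray without importing xarray
        lons = np.asarray(grid["lon"].values, dtype=float)
        lats = np.asarray(grid["lat"].values, dtype=float)
        values = np.asarray(grid.transpose("lat", "lon").values, dtype=float)
    else:
        lons, lats, values = grid
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        values = np.asarray(values, dtype=float)
    interp = RegularGridInterpolator(
        (lats, lons), values, method="linear", bounds_error=True
    )
    try:
        return float(interp([[lat, lon]])[0])
    except ValueError as exc:
        raise OutOfDomainError(
            f"station (lon={lon}, lat={lat}) outside grid domain "
            f"lon[{lons.min()}, {lons.max()}] lat[{lats.min()}, {lats.max()}]"
        ) from exc


@dataclass(frozen=True)
class FilterWindow:
    """The outlier filter window: kept iff slope_lo < S < slope_hi and PCC > pcc_min."""

    slope_lo: float = 0.5
    slope_hi: float = 1.5
    pcc_min: float = 0.2

    def keeps(self, slope: float, pcc: float) -> bool:
        # strict inequalities: boundary values are excluded
        return (self.slope_lo < slope < self.slope_hi) and (pcc > self.pcc_min)


@dataclass(frozen=True)
class FitDiagnostics:
    city_id: str
    pollutant: str
    slope: float  # S: OLS slope of observed on counterfactual
    pcc: float    # Pearson correlation of the same pairs
    n: int
    kept: bool


def fit_city_diagnostics(
    obs: pd.Series,
    cf: pd.Series,
    city_id: str = "",
    pollutant: str = "",
    window: FilterWindow | None = None,
    min_pairs: int = 30,
    orientation: str = "obs~model",
) -> FitDiagnostics:
    """OLS slope and Pearson correlation of paired observed/counterfactual days.

    ``orientation`` selects the regression direction: the default
    ``"obs~model"`` regresses observations on the counterfactual (the filter
    asks whether the counterfactual tracks reality with near-unit gain);
    ``"model~obs"`` is available for sensitivity checks.
    """
    window = window or FilterWindow()
    pairs = pd.concat({"obs": obs, "cf": cf}, axis=1).dropna()
    if len(pairs) < min_pairs:
        raise InsufficientDataError(
            f"{city_id or 'series'}/{pollutant or '?'}: only {len(pairs)} paired "
            f"days, need >= {min_pairs}"
        )
    if orientation == "obs~model":
        x, y = pairs["cf"].to_numpy(), pairs["obs"].to_numpy()
    elif orientation == "model~obs":
        x, y = pairs["obs"].to_numpy(), pairs["cf"].to_numpy()
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if np.ptp(x) == 0:
        raise UndefinedSlopeError(
            f"{city_id or 'series'}/{pollutant or '?'}: predictor has zero variance"
        )
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    pcc = float(fit.rvalue)
    return FitDiagnostics(
        city_id=city_id,
        pollutant=pollutant,
        slope=slope,
        pcc=pcc,
        n=len(pairs),
        kept=window.keeps(slope, pcc),
    )


def panel_diagnostics(
    panels: Sequence[CityPanel],
    pollutants: Sequence[str] = ("NO2", "O3"),
    fit_years: Iterable[int] = range(2015, 2020),
    window: FilterWindow | None = None,
    min_pairs: int = 30,
) -> List[FitDiagnostics]:
    """Fit the quality filter for every city and pollutant on pre-2020 data."""
    fit_years = set(fit_years)
    out: List[FitDiagnostics] = []
    for panel in panels:
        mask = panel.observed.index.year.isin(fit_years)
        for pol in pollutants:
            out.append(
                fit_city_diagnostics(
                    panel.observed.loc[mask, pol],
                    panel.counterfactual.loc[mask, pol],
                    city_id=panel.city_id,
                    pollutant=pol,
                    window=window,
                    min_pairs=min_pairs,
                )
            )
    return out


def apply_filter(
    diags: Sequence[FitDiagnostics], mode: str = "union"
) -> Tuple[List[str], List[str]]:
    """Split cities into (kept, outliers).

    ``mode="union"`` (default, mirroring the single combined outlier set):
    a city is an outlier if it fails the window for *any* pollutant present
    in ``diags``; ``mode="per_pollutant"`` requires callers to pass a single
    pollutant's diagnostics.  The two lists are disjoint and jointly
    exhaustive over the cities appearing in ``diags``.
    """
    if mode not in ("union", "per_pollutant"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if mode == "per_pollutant" and len({d.pollutant for d in diags}) > 1:
        raise ValueError("per_pollutant mode requires diagnostics of one pollutant")
    failed: Dict[str, bool] = {}
    for d in diags:
        failed[d.city_id] = failed.get(d.city_id, False) or not d.kept
    kept = sorted(c for c, bad in failed.items() if not bad)
    outliers = sorted(c for c, bad in failed.items() if bad)
    return kept, outliers


def diagnostics_frame(diags: Sequence[FitDiagnostics]) -> pd.DataFrame:
    """Tabulate diagnostics for CSV output."""
    return pd.DataFrame(
        [
            {
                "city_id": d.city_id,
                "pollutant": d.pollutant,
                "S": d.slope,
                "PCC": d.pcc,
                "n": d.n,
                "kept": d.kept,
            }
            for d in diags
        ]
    )
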