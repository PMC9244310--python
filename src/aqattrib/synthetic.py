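"""Synthetic multi-city panels with injected, known driver effects.

The generator emulates the data-generating structure the attribution
pipeline assumes:

* a *counterfactual* (business-as-usual) concentration series, playing the
  role of a reanalysis whose emission inventory knows nothing about holiday,
  policy or lockdown reductions;
* an *anthropogenic multiplier* on the observed series carrying the Chinese
  New Year (CNY) holiday dip, the 2018+ Clean-Air-Plan (CAP) step, and the
  2020 COVID-lockdown dips;
* a *meteorological modulation* entering observed and counterfactual series
  identically (the reanalysis knows the actual weather of every year, it only
  misses the emission changes);
* multiplicative, mean-one log-normal measurement noise on the observations.

The injected effects are additive inside one multiplier,

    observed = counterfactual * (1 + cny + cap + lockdown) * exp(noise),

with each term switched on only inside its window, so that the synthetic
truth is, by construction, exactly the estimand of the corresponding
window-contrast driver estimate: noise-free recovery is exact, not merely
asymptotic.  Two consequences of that definition are deliberate and
documented in the methods note: the CAP step is suppressed inside the CNY
holiday windows of pre-2020 policy years (a full holiday shutdown subsumes
the policy reduction), and the 2020 lockdown dip covers the whole CNY window
while a separate, stronger extended dip covers days +11..+42.

Meteorology drives concentrations through a simple *ventilation index*
(increasing in wind speed, decreasing in positive surface-pressure
anomalies); 2020 receives a calm/stagnant anomaly over the Total
COVID-lockdown window so that a meteorology driver of known size exists to
be recovered.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .calendar_windows import (
    CNY_WINDOW,
    EXTENDED_LOCKDOWN,
    TOTAL_LOCKDOWN,
    CnyCalendar,
)

__all__ = [
    "POLLUTANTS",
    "REGIONS",
    "MET_VARS",
    "SyntheticConfig",
    "SyntheticTruth",
    "CityPanel",
    "generate_city",
    "generate_panel",
    "write_fixture",
    "read_truth",
]

POLLUTANTS = ("PM2.5", "PM10", "SO2", "NO2", "O3", "CO")
#: The ten study regions of mainland China.
REGIONS = ("NCP", "YRD", "PRD", "CC", "SCB", "FWP", "NEC", "NWC", "QTP", "YGP")
MET_VARS = ("T", "RH", "WS", "WD", "Pre", "P")

# Ventilation-index geometry: one index unit ~ 1 m/s of wind or 8 hPa of
# pressure anomaly relative to the fixed 1013-hPa reference; the 2020 calm
# anomaly is split 80/20 between the two.  The fixed reference makes the
# index a direct function of the raw station variables an emulator sees.
_WS_REF = 2.5
_P_REF = 1013.0
_P_SCALE = 8.0
_ANOM_WS_SHARE = 0.8


def _default_baselines() -> Dict[str, float]:
    # Typical urban annual means (ug/m3; CO mg/m3); PM levels chosen so that
    # winter days cross the CAAQS grade-II daily limits, as they do in
    # northern Chinese cities.
    return {"PM2.5": 58.0, "PM10": 100.0, "SO2": 14.0, "NO2": 38.0, "O3": 55.0, "CO": 0.9}


def _default_primary_scale() -> Dict[str, float]:
    # Fraction of the NO2 anthropogenic change shared by co-emitted primaries.
    return {"NO2": 1.0, "PM2.5": 0.5, "PM10": 0.5, "SO2": 0.5, "CO": 0.5}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic world.

    Effect fractions are relative changes (e.g. ``-0.267`` is a 26.7 %
    reduction); the defaults are the national mean effect sizes the
    attribution pipeline is designed to estimate.
    """

    n_cities: int = 50
    years: Tuple[int, ...] = (2015, 2016, 2017, 2018, 2019, 2020)
    seed: int = 0
    baseline_level: Dict[str, float] = field(default_factory=_default_baselines)
    seasonal_amplitude: float = 0.35
    weekly_amplitude: float = 0.05
    cny_dip: float = -0.267
    cap_step: float = -0.157
    lockdown_dip_2020: float = -0.116
    extended_dip_2020: float = -0.347
    met_sensitivity: float = 0.06      # fractional change per ventilation-index unit
    met_anomaly_2020: float = 1.17     # calm anomaly (index units), calibrated so the
                                       # realised national met effect on NO2 is ~+7.8%
    noise_sd: float = 0.05             # log-scale observation noise
    o3_coupling: float = 0.9           # fraction of NO2 change mirrored (opposite sign) in O3
    o3_met_factor: float = -0.12       # O3 ventilation sensitivity relative to NO2
    effect_scatter: float = 0.15       # relative across-city spread of injected effects
    cap_start_year: int = 2018
    primary_scale: Dict[str, float] = field(default_factory=_default_primary_scale)

    def __post_init__(self) -> None:
        if self.n_cities < 1:
            raise ValueError("n_cities must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in (
            "cny_dip",
            "cap_step",
            "lockdown_dip_2020",
            "extended_dip_2020",
            "met_sensitivity",
            "o3_coupling",
            "seasonal_amplitude",
            "weekly_amplitude",
        ):
            value = getattr(self, name)
            if not -1.0 < value < 1.0:
                raise ValueError(f"{name}={value} outside the open interval (-1, 1)")


@dataclass
class SyntheticTruth:
    """Injected per-city effect sizes, in percent, as the pipeline estimates them."""

    city_id: str
    cny_pct: float
    cap_pct: float
    lockdown_pct: float
    extended_pct: float
    cny2020_mix_pct: float       # cny + cap + lockdown
    cny2020_isolated_pct: float  # cny + lockdown
    met_sensitivity_pct: float
    met_effect_no2_pct: float    # realised 2020-vs-climatology contrast, Total window
    met_effect_o3_pct: float

    def as_dict(self) -> Dict[str, float]:
        return {k: v for k, v in dataclasses.asdict(self).items() if k != "city_id"}


@dataclass
class CityPanel:
    """One city's observed / counterfactual / meteorological record."""

    city_id: str
    lon: float
    lat: float
    population: float
    region: str
    observed: pd.DataFrame        # daily, columns POLLUTANTS
    counterfactual: pd.DataFrame  # daily, columns POLLUTANTS
    met: pd.DataFrame             # daily, columns MET_VARS
    hourly_o3: pd.Series          # hourly O3 for the 8-h peak computation

    @property
    def years(self) -> Tuple[int, ...]:
        return tuple(sorted(self.observed.index.year.unique()))


def _date_index(years: Sequence[int]) -> pd.DatetimeIndex:
    """Daily axis: full calendar years, except 2020 which ends 30 April."""
    parts = []
    for year in sorted(years):
        end = dt.date(year, 4, 30) if year == 2020 else dt.date(year, 12, 31)
        parts.append(pd.date_range(dt.date(year, 1, 1), end, freq="D"))
    return parts[0].append(parts[1:]) if len(parts) > 1 else parts[0]


def _seasonal(doy: np.ndarray, amplitude: float, summer_peak: bool) -> np.ndarray:
    phase = np.cos(2.0 * np.pi * doy / 365.25)
    return 1.0 - amplitude * phase if summer_peak else 1.0 + amplitude * phase


def _weekly(dow: np.ndarray, amplitude: float) -> np.ndarray:
    return 1.0 + amplitude * np.cos(2.0 * np.pi * dow / 7.0)


def _pressure_clim(doy: np.ndarray) -> np.ndarray:
    return 1013.0 + 8.0 * np.cos(2.0 * np.pi * doy / 365.25)


def _draw_effect(rng: np.random.Generator, mean: float, scatter: float) -> float:
    value = mean * (1.0 + scatter * rng.standard_normal())
    return float(np.clip(value, -0.95, 0.95))


def generate_city(
    config: SyntheticConfig, city_index: int, calendar: CnyCalendar | None = None
) -> Tuple[CityPanel, SyntheticTruth]:
    """Generate one city's panel plus the ground truth of its injected effects.

    Deterministic given ``(config.seed, city_index)`` and independent of
    ``config.n_cities``.
    """
    calendar = calendar or CnyCalendar()
    rng = np.random.default_rng([config.seed, city_index])
    city_id = f"city{city_index:03d}"

    # --- metadata -----------------------------------------------------------
    lon = 80.0 + 50.0 * rng.random()
    lat = 20.0 + 30.0 * rng.random()
    if city_index % 7 == 0:
        population = 5.5e6 + 5.0e6 * rng.random()  # megacity stratum (>5 million)
    else:
        population = float(np.exp(rng.normal(13.4, 0.7)))
    region = REGIONS[city_index % len(REGIONS)]

    # --- per-city injected effects -----------------------------------------
    sc = config.effect_scatter
    cny_c = _draw_effect(rng, config.cny_dip, sc)
    cap_c = _draw_effect(rng, config.cap_step, sc)
    lock_c = _draw_effect(rng, config.lockdown_dip_2020, sc)
    ext_c = _draw_effect(rng, config.extended_dip_2020, sc)
    sens_c = _draw_effect(rng, config.met_sensitivity, sc)

    index = _date_index(config.years)
    n = len(index)
    doy = index.dayofyear.to_numpy(dtype=float)
    dow = index.dayofweek.to_numpy(dtype=float)
    year_arr = index.year.to_numpy()

    # --- meteorology --------------------------------------------------------
    t0 = 28.0 - 0.45 * lat
    temp = t0 - 10.0 * np.cos(2.0 * np.pi * doy / 365.25) + rng.normal(0.0, 2.0, n)
    rh = np.clip(70.0 - 0.15 * (temp - 15.0) + rng.normal(0.0, 8.0, n), 20.0, 100.0)
    ws = _WS_REF + 0.5 * np.sin(2.0 * np.pi * doy / 365.25 + rng.random() * 2 * np.pi)
    ws = ws + rng.normal(0.0, 0.8, n)
    wd_mean = 360.0 * rng.random()
    wd = np.mod(wd_mean + rng.normal(0.0, 60.0, n), 360.0)
    pre = np.where(rng.random(n) < 0.25, rng.exponential(4.0, n), 0.0)
    p_clim = _pressure_clim(doy)
    pressure = p_clim + rng.normal(0.0, 4.0, n)

    # CNY-relative offsets (only defined for years in the calendar)
    offsets = np.array(
        [
            (d.date() - calendar.cny_date(y)).days if y in calendar else 10_000
            for d, y in zip(index, year_arr)
        ]
    )

    # 2020 stagnation anomaly over the Total COVID-lockdown window
    in_total_2020 = (year_arr == 2020) & (offsets >= TOTAL_LOCKDOWN.start_offset) & (
        offsets <= TOTAL_LOCKDOWN.end_offset
    )
    anomaly = config.met_anomaly_2020
    ws = np.where(in_total_2020, ws - _ANOM_WS_SHARE * anomaly, ws)
    pressure = np.where(
        in_total_2020,
        pressure + (1.0 - _ANOM_WS_SHARE) * anomaly * _P_SCALE,
        pressure,
    )
    ws = np.maximum(ws, 0.1)

    vent = np.clip((ws - _WS_REF) - (pressure - _P_REF) / _P_SCALE, -4.0, 4.0)

    met = pd.DataFrame(
        {"T": temp, "RH": rh, "WS": ws, "WD": wd, "Pre": pre, "P": pressure},
        index=index,
    )

    # --- anthropogenic multiplier (NO2 reference) ---------------------------
    in_cny = (offsets >= CNY_WINDOW.start_offset) & (offsets <= CNY_WINDOW.end_offset)
    in_ext = (offsets >= EXTENDED_LOCKDOWN.start_offset) & (
        offsets <= EXTENDED_LOCKDOWN.end_offset
    )
    is_2020 = year_arr == 2020
    cap_years = year_arr >= config.cap_start_year

    effect = np.zeros(n)
    pre2020 = ~is_2020
    effect[pre2020 & in_cny] = cny_c
    effect[pre2020 & cap_years & ~in_cny] = cap_c
    effect[is_2020] = cap_c
    effect[is_2020 & in_cny] += cny_c + lock_c
    effect[is_2020 & in_ext] += ext_c

    # --- series per pollutant ----------------------------------------------
    observed = {}
    counterfactual = {}
    sigma = config.noise_sd
    for pol in POLLUTANTS:
        summer_peak = pol == "O3"
        base = (
            config.baseline_level[pol]
            * _seasonal(doy, config.seasonal_amplitude, summer_peak)
            * _weekly(dow, config.weekly_amplitude)
        )
        s_pol = sens_c * (config.o3_met_factor if pol == "O3" else 1.0)
        modulation = np.maximum(1.0 - s_pol * vent, 0.05)
        cf = base * modulation
        if pol == "O3":
            anthro = 1.0 - config.o3_coupling * effect
        else:
            anthro = 1.0 + config.primary_scale[pol] * effect
        noise = (
            np.exp(rng.normal(-0.5 * sigma**2, sigma, n)) if sigma > 0 else np.ones(n)
        )
        counterfactual[pol] = cf
        observed[pol] = cf * anthro * noise

    observed_df = pd.DataFrame(observed, index=index)
    counterfactual_df = pd.DataFrame(counterfactual, index=index)

    # --- hourly O3 (diurnal profile scaled to the daily mean) ---------------
    hours = np.arange(24)
    profile = 1.0 + 0.45 * np.cos(2.0 * np.pi * (hours - 15) / 24.0)
    profile /= profile.mean()
    hourly_index = pd.date_range(index[0], index[-1] + pd.Timedelta(hours=23), freq="h")
    hourly_o3 = pd.Series(
        np.outer(observed_df["O3"].to_numpy(), profile).ravel(),
        index=hourly_index,
        name="O3",
    )

    # --- realised meteorology-driver truth ----------------------------------
    met_no2, met_o3 = _met_effect_truth(
        config, calendar, index, year_arr, offsets, vent, doy, dow, sens_c
    )

    truth = SyntheticTruth(
        city_id=city_id,
        cny_pct=100.0 * cny_c,
        cap_pct=100.0 * cap_c,
        lockdown_pct=100.0 * lock_c,
        extended_pct=100.0 * ext_c,
        cny2020_mix_pct=100.0 * (cny_c + cap_c + lock_c),
        cny2020_isolated_pct=100.0 * (cny_c + lock_c),
        met_sensitivity_pct=100.0 * sens_c,
        met_effect_no2_pct=met_no2,
        met_effect_o3_pct=met_o3,
    )
    panel = CityPanel(
        city_id=city_id,
        lon=lon,
        lat=lat,
        population=population,
        region=region,
        observed=observed_df,
        counterfactual=counterfactual_df,
        met=met,
        hourly_o3=hourly_o3,
    )
    return panel, truth


def _met_effect_truth(
    config: SyntheticConfig,
    calendar: CnyCalendar,
    index: pd.DatetimeIndex,
    year_arr: np.ndarray,
    offsets: np.ndarray,
    vent: np.ndarray,
    doy: np.ndarray,
    dow: np.ndarray,
    sens_c: float,
) -> Tuple[float, float]:
    """Realised 2020-vs-climatology meteorology contrast over the Total window.

    Computed directly from the generated ventilation series (not via any
    emulator): the contrast of baseline-weighted mean modulation under 2020
    ventilation versus the 2015-2019 offset-aligned climatological ventilation.
    Returns NaN when 2020 or any climatology year is absent.
    """
    clim_years = [y for y in range(2015, 2020) if y in config.years]
    if 2020 not in config.years or len(clim_years) < 5:
        return float("nan"), float("nan")

    date_pos = {d.date(): i for i, d in enumerate(index)}
    window = TOTAL_LOCKDOWN
    v2020, vclim, w_no2, w_o3 = [], [], [], []
    for off in window.offsets:
        d20 = calendar.cny_date(2020) + dt.timedelta(days=off)
        i20 = date_pos[d20]
        v2020.append(vent[i20])
        vclim.append(
            np.mean(
                [
                    vent[date_pos[calendar.cny_date(y) + dt.timedelta(days=off)]]
                    for y in clim_years
                ]
            )
        )
        base_no2 = config.baseline_level["NO2"] * _seasonal(
            np.array([doy[i20]]), config.seasonal_amplitude, False
        ) * _weekly(np.array([dow[i20]]), config.weekly_amplitude)
        base_o3 = config.baseline_level["O3"] * _seasonal(
            np.array([doy[i20]]), config.seasonal_amplitude, True
        ) * _weekly(np.array([dow[i20]]), config.weekly_amplitude)
        w_no2.append(base_no2[0])
        w_o3.append(base_o3[0])

    v2020_a, vclim_a = np.array(v2020), np.array(vclim)
    out = []
    for s_pol, weights in (
        (sens_c, np.array(w_no2)),
        (sens_c * config.o3_met_factor, np.array(w_o3)),
    ):
        m2020 = np.maximum(1.0 - s_pol * v2020_a, 0.05)
        mclim = np.maximum(1.0 - s_pol * vclim_a, 0.05)
        out.append(
            100.0
            * (np.sum(weights * m2020) / np.sum(weights * mclim) - 1.0)
        )
    return out[0], out[1]


def generate_panel(
    config: SyntheticConfig, calendar: CnyCalendar | None = None
) -> Tuple[List[CityPanel], List[SyntheticTruth]]:
    """Generate ``config.n_cities`` city panels with their truths."""
    panels, truths = [], []
    for i in range(config.n_cities):
        panel, truth = generate_city(config, i, calendar)
        panels.append(panel)
        truths.append(truth)
    return panels, truths


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(
    panels: Sequence[CityPanel],
    truths: Sequence[SyntheticTruth],
    directory: str | Path,
    write_hourly: bool = True,
) -> List[Path]:
    """Write per-city CSV tables plus a flat key-value truth file.

    Layout: ``manifest.csv`` (one row per city with metadata), and per city
    ``<id>_observed.csv``, ``<id>_counterfactual.csv``, ``<id>_meteorology.csv``
    and optionally ``<id>_hourly_o3.csv``; the truth file is ``truth.txt`` with
    ``city_id.key = value`` lines.  Files round-trip losslessly through
    :func:`aqattrib.ingest.read_panel`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    manifest = pd.DataFrame(
        [
            {
                "city_id": p.city_id,
                "lon": p.lon,
                "lat": p.lat,
                "population": p.population,
                "region": p.region,
                "hourly_o3": bool(write_hourly),
            }
            for p in panels
        ],
        columns=["city_id", "lon", "lat", "population", "region", "hourly_o3"],
    )
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    written.append(manifest_path)

    for panel in panels:
        for name, frame in (
            ("observed", panel.observed),
            ("counterfactual", panel.counterfactual),
            ("meteorology", panel.met),
        ):
            path = directory / f"{panel.city_id}_{name}.csv"
            out = frame.copy()
            out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
            out.to_csv(path, index=False)
            written.append(path)
        if write_hourly:
            path = directory / f"{panel.city_id}_hourly_o3.csv"
            hour = panel.hourly_o3
            pd.DataFrame(
                {"time": hour.index.strftime("%Y-%m-%dT%H:%M:%S"), "O3": hour.values}
            ).to_csv(path, index=False)
            written.append(path)

    truth_path = directory / "truth.txt"
    with open(truth_path, "w") as fh:
        for truth in truths:
            for key, value in truth.as_dict().items():
                fh.write(f"{truth.city_id}.{key} = {value!r}\n")
    written.append(truth_path)
    return written


def read_truth(path: str | Path) -> Dict[str, Dict[str, float]]:
    """Read the flat key-value truth file back into {city_id: {key: value}}."""
    out: Dict[str, Dict[str, float]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        lhs, rhs = line.split("=", 1)
        city_id, key = lhs.strip().split(".", 1)
        value = float(rhs.strip())
        out.setdefault(city_id, {})[key] = value
    return out
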