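"""Window-contrast attribution of concentration changes to named drivers.

Each anthropogenic driver is a percentage contrast between observed and
counterfactual concentrations restricted to a CNY-relative window:

* ``CNY_2020-mix``      : CNY window (-7..+10), year 2020 — holiday, policy and
                          lockdown effects mixed together;
* ``CNY_2015-2019``     : CNY window pooled over 2015-2019 — the ordinary
                          holiday dip;
* ``CAP_2018-2020``     : Before-CNY window (-21..-8) pooled over 2018-2020 —
                          the Clean-Air-Plan step, measured where no holiday
                          or lockdown reaches;
* ``CNY_2020``          : mix minus CAP — 2020 holiday + lockdown, policy removed;
* ``COVID-lockdown``    : mix minus historical CNY minus CAP — the isolated
                          lockdown effect;
* ``Extended lockdown`` : window +11..+42 of 2020, minus CAP.

Percentages compose by plain subtraction, so the isolated drivers satisfy an
exact additivity identity by construction.  The window aggregate is the
ratio of pooled means (mean observed vs mean counterfactual over all window
days of all years), which is robust to low-concentration days; a
mean-of-daily-ratios alternative is available for sensitivity checks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calendar_windows import (
    BEFORE_CNY,
    CNY_WINDOW,
    EXTENDED_LOCKDOWN,
    CnyCalendar,
    WindowSpec,
    window_dates,
)
from .ingest import InsufficientDataError
from .synthetic import CityPanel

__all__ = [
    "UndefinedBaselineError",
    "DriverEstimate",
    "percent_change",
    "window_percent_change",
    "driver_cny_mix_2020",
    "driver_cny_hist",
    "driver_cap",
    "compose_isolated_drivers",
    "driver_extended_lockdown",
    "summarize_national",
    "decompose_city",
    "decompose_panel",
]

#: Canonical driver labels, in the order they are reported.
DRIVERS = (
    "CNY_2020_mix",
    "CNY_2015_2019",
    "CAP_2018_2020",
    "CNY_2020_isolated",
    "COVID_lockdown",
    "Extended_COVID_lockdown",
)


class UndefinedBaselineError(ValueError):
    """The counterfactual window mean is non-positive; a percent change is undefined."""


def percent_change(obs_mean: float, cf_mean: float) -> float:
    """100 x (observed - counterfactual) / counterfactual."""
    if cf_mean <= 0:
        raise UndefinedBaselineError(
            f"counterfactual window mean {cf_mean} is not positive"
        )
    return 100.0 * (obs_mean - cf_mean) / cf_mean


def window_percent_change(
    panel: CityPanel,
    pollutant: str,
    years: Iterable[int],
    spec: WindowSpec,
    calendar: CnyCalendar | None = None,
    method: str = "ratio_of_means",
    min_coverage: float = 0.5,
) -> float:
    """Percent change of pooled window means across the given years.

    Observed and counterfactual series are each averaged over all window
    dates pooled across ``years`` (days missing from the panel are skipped);
    if fewer than ``min_coverage`` of the expected days are available the
    city-window is not estimable.
    """
    calendar = calendar or CnyCalendar()
    dates: List = []
    for year in years:
        dates.extend(window_dates(year, spec, calendar))
    idx = pd.DatetimeIndex(dates)
    obs = panel.observed[pollutant].reindex(idx)
    cf = panel.counterfactual[pollutant].reindex(idx)
    valid = obs.notna() & cf.notna()
    n_expected = len(idx)
    n_valid = int(valid.sum())
    if n_expected == 0 or n_valid / n_expected < min_coverage or n_valid == 0:
        raise InsufficientDataError(
            f"{panel.city_id}/{pollutant}: window {spec.name} has {n_valid}/"
            f"{n_expected} usable days (min coverage {min_coverage:.0%})"
        )
    if method == "ratio_of_means":
        return percent_change(float(obs[valid].mean()), float(cf[valid].mean()))
    if method == "mean_of_ratios":
        cf_pos = valid & (cf > 0)
        if not cf_pos.any():
            raise UndefinedBaselineError(
                f"{panel.city_id}/{pollutant}: no positive counterfactual days"
            )
        return float((100.0 * (obs[cf_pos] / cf[cf_pos] - 1.0)).mean())
    raise ValueError(f"unknown method {method!r}")


def driver_cny_mix_2020(
    panel: CityPanel,
    pollutant: str,
    calendar: CnyCalendar | None = None,
    **kwargs,
) -> float:
    """The mixed 2020 contrast: CNY window of 2020, all anthropogenic effects mixed."""
    return window_percent_change(panel, pollutant, [2020], CNY_WINDOW, calendar, **kwargs)


def driver_cny_hist(
    panel: CityPanel,
    pollutant: str,
    calendar: CnyCalendar | None = None,
    years: Sequence[int] = (2015, 2016, 2017, 2018, 2019),
    **kwargs,
) -> float:
    """The ordinary holiday dip: CNY window pooled over 2015-2019."""
    missing = [y for y in years if y not in panel.years]
    if missing:
        raise InsufficientDataError(
            f"{panel.city_id}: historical CNY years missing from panel: {missing}"
        )
    return window_percent_change(panel, pollutant, years, CNY_WINDOW, calendar, **kwargs)


def driver_cap(
    panel: CityPanel,
    pollutant: str,
    calendar: CnyCalendar | None = None,
    years: Sequence[int] = (2018, 2019, 2020),
    **kwargs,
) -> float:
    """Clean-Air-Plan step from Before-CNY windows of 2018-2020.

    All three years are required; the driver is otherwise not estimable.
    """
    missing = [y for y in years if y not in panel.years]
    if missing:
        raise InsufficientDataError(
            f"{panel.city_id}: CAP estimation needs Before-CNY windows for "
            f"{list(years)}; missing {missing}"
        )
    return window_percent_change(panel, pollutant, years, BEFORE_CNY, calendar, **kwargs)


def compose_isolated_drivers(
    mix2020: float, hist: float, cap: float
) -> Tuple[float, float]:
    """Isolated holiday and lockdown drivers by plain subtraction of percentages.

    Returns ``(cny2020_isolated, covid_lockdown)`` where
    ``cny2020_isolated = mix2020 - cap`` and
    ``covid_lockdown = mix2020 - hist - cap``.
    """
    return mix2020 - cap, mix2020 - hist - cap


def driver_extended_lockdown(
    panel: CityPanel,
    pollutant: str,
    cap: float,
    calendar: CnyCalendar | None = None,
    **kwargs,
) -> float:
    """Extended-lockdown contrast: the +11..+42 window of 2020, with the CAP step removed."""
    combined = window_percent_change(
        panel, pollutant, [2020], EXTENDED_LOCKDOWN, calendar, **kwargs
    )
    return combined - cap


@dataclass
class DriverEstimate:
    """Per-city and national summary of one driver for one pollutant."""

    driver: str
    pollutant: str
    per_city: Dict[str, float]
    national_mean: float
    national_sd: float
    n_cities: int
    n_decreased: int
    n_increased: int
    n_zero: int
    stratum_means: Dict[str, float] = field(default_factory=dict)


def summarize_national(
    per_city: Mapping[str, float],
    metadata: Optional[Mapping[str, Mapping[str, object]]] = None,
    driver: str = "",
    pollutant: str = "",
    population_threshold: float = 5e6,
) -> DriverEstimate:
    """Unweighted national mean/SD plus sign counts and the megacity stratum.

    ``metadata`` maps city_id to a mapping with at least ``population``;
    population enters only through the > ``population_threshold`` stratum
    mean, never as a weight.
    """
    if not per_city:
        raise InsufficientDataError("no per-city estimates to summarize")
    values = np.array(list(per_city.values()), dtype=float)
    stratum: Dict[str, float] = {}
    if metadata:
        big = [
            v
            for c, v in per_city.items()
            if c in metadata
            and float(metadata[c]["population"]) > population_threshold
        ]
        if big:
            stratum[f"population>{population_threshold:g}"] = float(np.mean(big))
    return DriverEstimate(
        driver=driver,
        pollutant=pollutant,
        per_city=dict(per_city),
        national_mean=float(values.mean()),
        national_sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        n_cities=len(values),
        n_decreased=int((values < 0).sum()),
        n_increased=int((values > 0).sum()),
        n_zero=int((values == 0).sum()),
        stratum_means=stratum,
    )


def decompose_city(
    panel: CityPanel,
    pollutant: str,
    calendar: CnyCalendar | None = None,
    **kwargs,
) -> Dict[str, float]:
    """All six window-contrast drivers for one city (meteorology excluded)."""
    mix = driver_cny_mix_2020(panel, pollutant, calendar, **kwargs)
    hist = driver_cny_hist(panel, pollutant, calendar, **kwargs)
    cap = driver_cap(panel, pollutant, calendar, **kwargs)
    isolated, covid = compose_isolated_drivers(mix, hist, cap)
    extended = driver_extended_lockdown(panel, pollutant, cap, calendar, **kwargs)
    return {
        "CNY_2020_mix": mix,
        "CNY_2015_2019": hist,
        "CAP_2018_2020": cap,
        "CNY_2020_isolated": isolated,
        "COVID_lockdown": covid,
        "Extended_COVID_lockdown": extended,
    }


def decompose_panel(
    panels: Sequence[CityPanel],
    pollutant: str,
    calendar: CnyCalendar | None = None,
    kept_ids: Optional[Iterable[str]] = None,
    **kwargs,
) -> Dict[str, DriverEstimate]:
    """Per-driver national estimates over the kept cities of a panel.

    Cities where a driver is not estimable (insufficient coverage, undefined
    baseline) are skipped for that driver.
    """
    kept = None if kept_ids is None else set(kept_ids)
    metadata = {
        p.city_id: {"population": p.population, "region": p.region} for p in panels
    }
    per_driver: Dict[str, Dict[str, float]] = {d: {} for d in DRIVERS}
    for panel in panels:
        if kept is not None and panel.city_id not in kept:
            continue
        try:
            city = decompose_city(panel, pollutant, calendar, **kwargs)
        except (InsufficientDataError, UndefinedBaselineError):
            continue
        for drv, value in city.items():
            per_driver[drv][panel.city_id] = value
    return {
        drv: summarize_national(vals, metadata, driver=drv, pollutant=pollutant)
        for drv, vals in per_driver.items()
        if vals
    }
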