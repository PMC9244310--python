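"""Excess risk and the multi-pollutant Health-based Air Quality Index (HAQI).

Short-term mortality risk of pollutant *i* above its threshold C0_i follows
the exponential exposure-response model

    RR_i = exp(beta_i * (C_i - C0_i))   for C_i > C0_i,   ER_i = RR_i - 1,

with no excess risk at or below the threshold.  Per-pollutant excess risks
add to ER_total; the combined relative risk RR* = 1 + ER_total is mapped
back, per pollutant, to the *equivalent concentration*

    C*_i = ln(RR*) / beta_i + C0_i

that alone would carry the whole multi-pollutant risk.  Standard AQI
piecewise-linear breakpoint interpolation of each C*_i gives per-pollutant
sub-indices, and the HAQI is their maximum.  Because NO2's response
coefficient is the largest among the gases, NO2 decreases and O3 increases
push the HAQI in opposite directions, which is exactly what the index is
designed to weigh.

Exposure-response coefficients (fraction per ug/m3; CO per mg/m3) follow the
published short-term mortality overview for China.  Threshold sets ship for
the WHO-2021 24-h guidelines and the Chinese CAAQS grade-II daily limits,
and the breakpoint table defaults to the HJ 633-2012 daily AQI breakpoints;
all three are reconstructed configuration defaults and user-overridable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "BETA",
    "THRESHOLDS",
    "BREAKPOINTS",
    "RiskConfig",
    "HaqiResult",
    "RegionalSummary",
    "peak_o3_8h",
    "excess_risk",
    "total_excess_risk",
    "equivalent_concentration",
    "iaqi",
    "haqi_day",
    "haqi_series",
    "haqi_change",
    "regional_summary",
    "category",
]

#: Exposure-response coefficients, as fractions per unit concentration
#: (printed percentages / 100); ug/m3 for all pollutants except CO (mg/m3).
BETA: Dict[str, float] = {
    "PM2.5": 0.00038,
    "PM10": 0.00032,
    "SO2": 0.00081,
    "NO2": 0.0013,
    "O3": 0.00048,
    "CO": 0.037,
}

#: Daily threshold concentrations per standard (reconstructed defaults).
THRESHOLDS: Dict[str, Dict[str, float]] = {
    "WHO2021": {"PM2.5": 15.0, "PM10": 45.0, "SO2": 40.0, "NO2": 25.0, "O3": 100.0, "CO": 4.0},
    "CAAQS_II": {"PM2.5": 75.0, "PM10": 150.0, "SO2": 150.0, "NO2": 80.0, "O3": 160.0, "CO": 4.0},
}

# HJ 633-2012 daily breakpoints: (conc_lo, conc_hi, index_lo, index_hi).
_IAQI_LEVELS = (0, 50, 100, 150, 200, 300, 400, 500)


def _rows(concs: Sequence[float]) -> List[Tuple[float, float, float, float]]:
    return [
        (concs[i], concs[i + 1], float(_IAQI_LEVELS[i]), float(_IAQI_LEVELS[i + 1]))
        for i in range(len(concs) - 1)
    ]


BREAKPOINTS: Dict[str, List[Tuple[float, float, float, float]]] = {
    "PM2.5": _rows((0, 35, 75, 115, 150, 250, 350, 500)),
    "PM10": _rows((0, 50, 150, 250, 350, 420, 500, 600)),
    "SO2": _rows((0, 50, 150, 475, 800, 1600, 2100, 2620)),
    "NO2": _rows((0, 40, 80, 180, 280, 565, 750, 940)),
    "CO": _rows((0, 2, 4, 14, 24, 36, 48, 60)),
    # 8-h O3 breakpoints are defined only up to index 300
    "O3": _rows((0, 100, 160, 215, 265, 800))[:5],
}

_CATEGORY_BANDS = (
    (50.0, "excellent"),
    (100.0, "good"),
    (200.0, "unhealthy"),
    (300.0, "very unhealthy"),
    (math.inf, "hazardous"),
)


def category(index_value: float) -> str:
    """Qualitative air-quality band for an (H)AQI value."""
    for upper, label in _CATEGORY_BANDS:
        if index_value <= upper:
            return label
    raise AssertionError("unreachable")


@dataclass
class RiskConfig:
    """Exposure-response coefficients, thresholds and AQI breakpoints."""

    betas: Dict[str, float] = field(default_factory=lambda: dict(BETA))
    thresholds: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in THRESHOLDS.items()}
    )
    breakpoints: Dict[str, List[Tuple[float, float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in BREAKPOINTS.items()}
    )

    def __post_init__(self) -> None:
        for pol, beta in self.betas.items():
            if beta <= 0:
                raise ValueError(f"beta for {pol} must be positive, got {beta}")
        for std, table in self.thresholds.items():
            for pol, c0 in table.items():
                if c0 <= 0:
                    raise ValueError(f"{std}/{pol}: threshold must be positive")
        for pol, rows in self.breakpoints.items():
            for (c_lo, c_hi, i_lo, i_hi), nxt in zip(rows, rows[1:] + [None]):
                if not (c_lo < c_hi and i_lo < i_hi):
                    raise ValueError(f"{pol}: breakpoint row not increasing")
                if nxt is not None and nxt[0] != c_hi:
                    raise ValueError(f"{pol}: breakpoint rows not contiguous")


def peak_o3_8h(
    hourly: Sequence[float], min_valid_hours: int = 18, min_window_hours: int = 6
) -> float:
    """Daily 8-h peak ozone: max over within-day 8-hour moving-window means.

    ``hourly`` holds the day's 24 hourly values (NaN = missing).  The day
    needs at least ``min_valid_hours`` valid hours and each 8-h window at
    least ``min_window_hours``; otherwise NaN is returned.
    """
    values = np.asarray(hourly, dtype=float)
    if values.shape != (24,):
        raise ValueError(f"expected 24 hourly values, got shape {values.shape}")
    valid = np.isfinite(values)
    if valid.sum() < min_valid_hours:
        return float("nan")
    best = -np.inf
    for start in range(17):  # windows 0-7 .. 16-23
        window = values[start : start + 8]
        n_ok = int(np.isfinite(window).sum())
        if n_ok < min_window_hours:
            continue
        best = max(best, float(np.nanmean(window)))
    return best if best > -np.inf else float("nan")


def excess_risk(concentration: float, beta: float, threshold: float) -> float:
    """ER = exp(beta * (C - C0)) - 1 above threshold, 0 at or below it."""
    if concentration < 0:
        raise ValueError(f"negative concentration {concentration}")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if concentration <= threshold:
        return 0.0
    return math.exp(beta * (concentration - threshold)) - 1.0


def total_excess_risk(ers: Sequence[Optional[float]]) -> float:
    """Sum of per-pollutant excess risks (missing pollutants contribute 0)."""
    return float(sum(e for e in ers if e is not None))


def equivalent_concentration(er_total: float, beta: float, threshold: float) -> float:
    """C* = ln(1 + ER_total)/beta + C0: the single-pollutant dose of the total risk."""
    if er_total < 0:
        raise ValueError(f"negative total excess risk {er_total}")
    return math.log1p(er_total) / beta + threshold


def iaqi(
    concentration: float,
    breakpoints: Sequence[Tuple[float, float, float, float]],
) -> float:
    """Piecewise-linear sub-index; above the top row the index is capped."""
    if concentration < 0:
        raise ValueError(f"negative concentration {concentration}")
    for c_lo, c_hi, i_lo, i_hi in breakpoints:
        if c_lo <= concentration <= c_hi:
            return i_lo + (i_hi - i_lo) * (concentration - c_lo) / (c_hi - c_lo)
    # above the table: capped at the maximal defined index
    return float(breakpoints[-1][3])


@dataclass
class HaqiResult:
    standard: str
    concentrations: Dict[str, float]
    er: Dict[str, float]
    er_total: float
    rr_star: float
    c_star: Dict[str, float]
    iaqi: Dict[str, float]
    haqi: float
    category: str
    city_id: str = ""
    date: Optional[pd.Timestamp] = None


def haqi_day(
    concentrations: Mapping[str, float],
    config: Optional[RiskConfig] = None,
    standard: str = "WHO2021",
    city_id: str = "",
    date: Optional[pd.Timestamp] = None,
) -> Optional[HaqiResult]:
    """Full ER -> ER_total -> RR* -> C* -> IAQI -> HAQI chain for one day.

    ``concentrations`` maps pollutant to daily mean (O3 as the 8-h peak);
    NaN/absent pollutants contribute zero excess risk and no sub-index.
    Returns None if no pollutant is observed.
    """
    config = config or RiskConfig()
    thresholds = config.thresholds[standard]
    observed = {
        pol: float(c)
        for pol, c in concentrations.items()
        if c is not None and np.isfinite(c)
    }
    if not observed:
        return None
    er = {
        pol: excess_risk(c, config.betas[pol], thresholds[pol])
        for pol, c in observed.items()
    }
    er_total = total_excess_risk(list(er.values()))
    rr_star = er_total + 1.0
    c_star = {
        pol: equivalent_concentration(er_total, config.betas[pol], thresholds[pol])
        for pol in observed
    }
    sub = {pol: iaqi(c_star[pol], config.breakpoints[pol]) for pol in observed}
    haqi = max(sub.values())
    return HaqiResult(
        standard=standard,
        concentrations=observed,
        er=er,
        er_total=er_total,
        rr_star=rr_star,
        c_star=c_star,
        iaqi=sub,
        haqi=haqi,
        category=category(haqi),
        city_id=city_id,
        date=date,
    )


def haqi_series(
    daily: pd.DataFrame,
    config: Optional[RiskConfig] = None,
    standard: str = "WHO2021",
    city_id: str = "",
) -> pd.DataFrame:
    """Daily HAQI table from a (date x pollutant) concentration frame.

    The O3 column must already be the daily 8-h peak (see :func:`peak_o3_8h`).
    """
    rows = []
    for date, conc in daily.iterrows():
        result = haqi_day(
            conc.to_dict(), config, standard, city_id=city_id, date=date
        )
        rows.append(
            {
                "date": date,
                "er_total": result.er_total if result else float("nan"),
                "haqi": result.haqi if result else float("nan"),
                "category": result.category if result else "",
            }
        )
    return pd.DataFrame(rows).set_index("date")


def haqi_change(
    observed: pd.Series,
    bau: pd.Series,
    window_dates: Optional[pd.DatetimeIndex] = None,
    denominator: str = "observed",
) -> float:
    """Percent difference of window-mean observed vs business-as-usual HAQI.

    Negative = improvement.  The default denominator is the observed-period
    mean; ``denominator="bau"`` selects the counterfactual mean instead.
    """
    if window_dates is not None:
        observed = observed.reindex(window_dates)
        bau = bau.reindex(window_dates)
    pairs = pd.concat({"obs": observed, "bau": bau}, axis=1).dropna()
    if pairs.empty:
        raise ValueError("no overlapping days between observed and BAU HAQI series")
    obs_mean = float(pairs["obs"].mean())
    bau_mean = float(pairs["bau"].mean())
    denom = obs_mean if denominator == "observed" else bau_mean
    if denom == 0:
        raise ValueError("zero denominator in HAQI change")
    return 100.0 * (obs_mean - bau_mean) / denom


@dataclass
class RegionalSummary:
    region_means: Dict[str, float]
    n_increased: int
    n_decreased: int


def regional_summary(
    changes: Mapping[str, float],
    regions: Mapping[str, str],
    valid_regions: Optional[Sequence[str]] = None,
) -> RegionalSummary:
    """Unweighted per-region mean HAQI change plus national sign counts."""
    from .synthetic import REGIONS

    valid = set(valid_regions if valid_regions is not None else REGIONS)
    grouped: Dict[str, List[float]] = {}
    for city, value in changes.items():
        if city not in regions:
            raise KeyError(f"city {city!r} has no region label")
        region = regions[city]
        if region not in valid:
            raise KeyError(f"unknown region label {region!r} for city {city!r}")
        grouped.setdefault(region, []).append(value)
    values = np.array(list(changes.values()))
    return RegionalSummary(
        region_means={r: float(np.mean(v)) for r, v in sorted(grouped.items())},
        n_increased=int((values > 0).sum()),
        n_decreased=int((values < 0).sum()),
    )


def daily_with_o3_peak(panel_observed: pd.DataFrame, hourly_o3: pd.Series) -> pd.DataFrame:
    """Replace the O3 column by the daily 8-h peak computed from hourly data."""
    daily = panel_observed.copy()
    if hourly_o3.empty:
        return daily
    peaks = {}
    for date, group in hourly_o3.groupby(hourly_o3.index.floor("D")):
        values = np.full(24, np.nan)
        values[group.index.hour] = group.to_numpy(dtype=float)
        peaks[date] = peak_o3_8h(values)
    peak_series = pd.Series(peaks)
    daily["O3"] = peak_series.reindex(daily.index)
    return daily
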