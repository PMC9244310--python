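"""Excess risk, equivalent concentrations, IAQI interpolation and the HAQI."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aqattrib.health import (
    BETA,
    BREAKPOINTS,
    THRESHOLDS,
    RiskConfig,
    category,
    equivalent_concentration,
    excess_risk,
    haqi_change,
    haqi_day,
    haqi_series,
    iaqi,
    peak_o3_8h,
    regional_summary,
    total_excess_risk,
)


# ---------------------------------------------------------------------------
# 8-h peak ozone
# ---------------------------------------------------------------------------

def _brute_force_peak(values, min_window_hours=6):
    best = -np.inf
    for start in range(17):
        window = values[start : start + 8]
        ok = np.isfinite(window)
        if ok.sum() < min_window_hours:
            continue
        best = max(best, np.mean(window[ok]))
    return best if best > -np.inf else float("nan")


def test_peak_constant_day():
    assert peak_o3_8h(np.full(24, 100.0)) == pytest.approx(100.0)


def test_peak_block_amid_zeros():
    values = np.zeros(24)
    values[8:16] = 160.0
    assert peak_o3_8h(values) == pytest.approx(160.0)
    assert peak_o3_8h(values) == pytest.approx(_brute_force_peak(values))


def test_peak_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    for _ in range(25):
        values = rng.uniform(0, 200, 24)
        missing = rng.choice(24, size=rng.integers(0, 6), replace=False)
        values[missing] = np.nan
        expected = _brute_force_peak(values)
        got = peak_o3_8h(values)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def test_peak_coverage_rules():
    assert math.isnan(peak_o3_8h(np.full(24, np.nan)))
    sparse = np.full(24, np.nan)
    sparse[:17] = 100.0  # 17 valid < 18 required
    assert math.isnan(peak_o3_8h(sparse))
    with pytest.raises(ValueError):
        peak_o3_8h(np.zeros(23))


# ---------------------------------------------------------------------------
# excess risk chain
# ---------------------------------------------------------------------------

def test_excess_risk_closed_form():
    assert excess_risk(25.0, BETA["NO2"], 25.0) == 0.0
    assert excess_risk(125.0, BETA["NO2"], 25.0) == pytest.approx(
        math.exp(0.13) - 1.0, abs=1e-12
    )
    assert excess_risk(5.0, BETA["CO"], 4.0) == pytest.approx(
        math.exp(0.037) - 1.0, abs=1e-12
    )
    with pytest.raises(ValueError):
        excess_risk(-1.0, 0.001, 10.0)


def test_total_excess_risk_sums():
    assert total_excess_risk([]) == 0.0
    assert total_excess_risk([0.02, 0.03, 0.05]) == pytest.approx(0.10)
    assert total_excess_risk([0.07, None]) == pytest.approx(0.07)


def test_equivalent_concentration_inverts_er():
    assert equivalent_concentration(0.0, BETA["NO2"], 25.0) == 25.0
    er = math.exp(0.13) - 1.0
    assert equivalent_concentration(er, BETA["NO2"], 25.0) == pytest.approx(
        125.0, abs=1e-9
    )


@settings(deadline=None, derandomize=True)
@given(
    pollutant=st.sampled_from(sorted(BETA)),
    excess=st.floats(0.1, 300.0, allow_nan=False),
)
def test_inversion_identity_single_pollutant(pollutant, excess):
    """Mapping a single pollutant's ER back through C* returns its concentration."""
    c0 = THRESHOLDS["WHO2021"][pollutant]
    concentration = c0 + excess
    er = excess_risk(concentration, BETA[pollutant], c0)
    back = equivalent_concentration(total_excess_risk([er]), BETA[pollutant], c0)
    assert back == pytest.approx(concentration, abs=1e-9)


# ---------------------------------------------------------------------------
# IAQI and HAQI
# ---------------------------------------------------------------------------

def test_iaqi_nodes_and_midpoints():
    bp = BREAKPOINTS["PM2.5"]
    for c_lo, c_hi, i_lo, i_hi in bp:
        assert iaqi(c_lo, bp) == pytest.approx(i_lo)
    # midpoint of the 75..115 row (index 100..150) -> 125
    assert iaqi(95.0, bp) == pytest.approx(125.0)
    assert iaqi(10_000.0, bp) == bp[-1][3]  # capped above the table
    with pytest.raises(ValueError):
        iaqi(-1.0, bp)


@settings(deadline=None, derandomize=True)
@given(
    pollutant=st.sampled_from(sorted(BREAKPOINTS)),
    c1=st.floats(0, 900, allow_nan=False),
    c2=st.floats(0, 900, allow_nan=False),
)
def test_iaqi_monotone(pollutant, c1, c2):
    bp = BREAKPOINTS[pollutant]
    lo, hi = sorted((c1, c2))
    assert iaqi(lo, bp) <= iaqi(hi, bp) + 1e-12


def test_haqi_day_threshold_panel():
    """All concentrations at their thresholds: zero ER, C* == C0, HAQI from C0s."""
    conc = dict(THRESHOLDS["WHO2021"])
    result = haqi_day(conc, standard="WHO2021")
    assert result.er_total == 0.0
    assert result.rr_star == 1.0
    for pol, c0 in THRESHOLDS["WHO2021"].items():
        assert result.c_star[pol] == pytest.approx(c0)
    expected = max(iaqi(c0, BREAKPOINTS[p]) for p, c0 in conc.items())
    assert result.haqi == pytest.approx(expected)


def test_haqi_single_pollutant_reduces_to_plain_aqi():
    """With only NO2 observed, HAQI is the ordinary NO2 sub-index of its value."""
    result = haqi_day({"NO2": 125.0}, standard="WHO2021")
    assert result.haqi == pytest.approx(iaqi(125.0, BREAKPOINTS["NO2"]), abs=1e-9)


def test_haqi_monotone_in_concentration():
    base = haqi_day({"NO2": 100.0, "PM2.5": 40.0}, standard="WHO2021")
    worse = haqi_day({"NO2": 160.0, "PM2.5": 40.0}, standard="WHO2021")
    assert worse.haqi > base.haqi
    assert worse.er_total > base.er_total


def test_caaqs_gases_below_standard_contribute_no_er():
    """SO2/NO2/O3/CO below their CAAQS-II daily limits carry zero excess risk."""
    conc = {"SO2": 20.0, "NO2": 40.0, "O3": 120.0, "CO": 1.0, "PM2.5": 110.0}
    result = haqi_day(conc, standard="CAAQS_II")
    for pol in ("SO2", "NO2", "O3", "CO"):
        assert result.er[pol] == 0.0
    assert result.er["PM2.5"] > 0.0


def test_haqi_missing_all_pollutants():
    assert haqi_day({"NO2": float("nan")}) is None


def test_category_bands():
    assert category(75.0) == "good"
    assert category(179.0) == "unhealthy"
    assert category(450.0) == "hazardous"


# ---------------------------------------------------------------------------
# observed-vs-BAU change and regional summaries
# ---------------------------------------------------------------------------

def _series(values):
    return pd.Series(values, index=pd.date_range("2020-01-24", periods=len(values)))


def test_haqi_change_conventions():
    obs = _series([179.0] * 10)
    bau = _series([287.0] * 10)
    assert haqi_change(obs, obs) == 0.0
    # observed-mean denominator: (179-287)/179 ~ -60.3%
    assert haqi_change(obs, bau) == pytest.approx(-60.335, abs=0.01)
    # counterfactual-mean denominator: (179-287)/287 ~ -37.6%
    assert haqi_change(obs, bau, denominator="bau") == pytest.approx(-37.63, abs=0.01)
    # deterioration is positive
    assert haqi_change(bau, obs) > 0


def test_haqi_change_requires_overlap():
    obs = _series([100.0] * 5)
    bau = pd.Series([90.0], index=pd.DatetimeIndex(["2021-06-01"]))
    with pytest.raises(ValueError):
        haqi_change(obs, bau)


def test_regional_summary_means_and_counts():
    changes = {"a": -40.0, "b": -60.0, "c": 10.0}
    regions = {"a": "NCP", "b": "NCP", "c": "YRD"}
    summary = regional_summary(changes, regions)
    assert summary.region_means["NCP"] == pytest.approx(-50.0)
    assert summary.region_means["YRD"] == pytest.approx(10.0)
    assert summary.n_decreased == 2 and summary.n_increased == 1
    with pytest.raises(KeyError):
        regional_summary({"a": 1.0}, {"a": "ATLANTIS"})


def test_haqi_series_over_frame():
    frame = pd.DataFrame(
        {"NO2": [125.0, 20.0], "PM2.5": [40.0, 10.0]},
        index=pd.date_range("2020-02-01", periods=2),
    )
    table = haqi_series(frame, standard="WHO2021")
    assert len(table) == 2
    assert table["haqi"].iloc[0] > table["haqi"].iloc[1]
    assert set(table.columns) == {"er_total", "haqi", "category"}
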