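"""Readers, bilinear grid interpolation and the slope/PCC outlier filter."""
import numpy as np
import pandas as pd
import pytest

from aqattrib.ingest import (
    FilterWindow,
    FitDiagnostics,
    InsufficientDataError,
    OutOfDomainError,
    PanelFormatError,
    UndefinedSlopeError,
    apply_filter,
    fit_city_diagnostics,
    interpolate_grid_to_station,
    read_panel,
)
from aqattrib.synthetic import SyntheticConfig, generate_panel, write_fixture


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def test_non_iso_date_error_names_line(tmp_path):
    config = SyntheticConfig(n_cities=1, seed=1, years=(2019, 2020))
    panels, truths = generate_panel(config)
    write_fixture(panels, truths, tmp_path)
    target = tmp_path / "city000_observed.csv"
    lines = target.read_text().splitlines()
    lines[3] = "01/05/2019" + lines[3][lines[3].index(","):]
    target.write_text("\n".join(lines) + "\n")
    with pytest.raises(PanelFormatError, match="line 4"):
        read_panel(tmp_path)


def test_gaps_preserved_not_zero_filled(tmp_path, calendar):
    from aqattrib.calendar_windows import CNY_WINDOW, window_dates
    from aqattrib.decomposition import window_percent_change

    config = SyntheticConfig(
        n_cities=1, seed=1, noise_sd=0.0, effect_scatter=0.0
    )
    panels, truths = generate_panel(config)
    # knock three CNY-window days out of the observed table
    drop = pd.DatetimeIndex(window_dates(2020, CNY_WINDOW, calendar)[:3])
    panels[0].observed = panels[0].observed.drop(index=drop)
    write_fixture(panels, truths, tmp_path, write_hourly=False)
    back = read_panel(tmp_path)[0]
    assert len(back.observed) == len(panels[0].observed)
    # window mean computed over the remaining days only: still the exact dip,
    # because the injected multiplier is constant inside the window
    change = window_percent_change(back, "NO2", [2020], CNY_WINDOW, calendar)
    assert change == pytest.approx(truths[0].cny2020_mix_pct, abs=1e-9)


# ---------------------------------------------------------------------------
# bilinear interpolation
# ---------------------------------------------------------------------------

def test_bilinear_node_identity():
    lons, lats = np.array([100.0, 101.0]), np.array([30.0, 31.0])
    values = np.array([[1.0, 2.0], [3.0, 4.0]])  # (lat, lon)
    assert interpolate_grid_to_station((lons, lats, values), 100.0, 30.0) == 1.0
    assert interpolate_grid_to_station((lons, lats, values), 101.0, 31.0) == 4.0


def test_bilinear_cell_midpoint():
    lons, lats = np.array([0.0, 1.0]), np.array([0.0, 1.0])
    values = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert interpolate_grid_to_station((lons, lats, values), 0.5, 0.5) == pytest.approx(2.5)


def test_bilinear_reproduces_planes():
    rng = np.random.default_rng(0)
    lons = np.linspace(70.0, 130.0, 9)
    lats = np.linspace(15.0, 55.0, 7)
    a, b, c = 0.7, -1.3, 5.0
    values = a * lons[None, :] + b * lats[:, None] + c
    for _ in range(20):
        lon = rng.uniform(lons[0], lons[-1])
        lat = rng.uniform(lats[0], lats[-1])
        got = interpolate_grid_to_station((lons, lats, values), lon, lat)
        assert got == pytest.approx(a * lon + b * lat + c, abs=1e-10)


def test_bilinear_out_of_domain():
    lons, lats = np.array([100.0, 101.0]), np.array([30.0, 31.0])
    values = np.ones((2, 2))
    with pytest.raises(OutOfDomainError):
        interpolate_grid_to_station((lons, lats, values), 99.0, 30.5)


def test_bilinear_accepts_xarray():
    xr = pytest.importorskip("xarray")
    da = xr.DataArray(
        np.array([[1.0, 2.0], [3.0, 4.0]]),
        coords={"lat": [0.0, 1.0], "lon": [0.0, 1.0]},
        dims=("lat", "lon"),
    )
    assert interpolate_grid_to_station(da, 0.5, 0.5) == pytest.approx(2.5)


# ---------------------------------------------------------------------------
# slope / PCC diagnostics
# ---------------------------------------------------------------------------

def _series(values):
    return pd.Series(values, index=pd.date_range("2018-01-01", periods=len(values)))


def test_identity_series_kept():
    cf = _series(np.linspace(10, 60, 100))
    diag = fit_city_diagnostics(cf, cf)
    assert diag.slope == pytest.approx(1.0)
    assert diag.pcc == pytest.approx(1.0)
    assert diag.kept


def test_double_slope_rejected():
    cf = _series(np.linspace(10, 60, 100))
    diag = fit_city_diagnostics(2.0 * cf, cf)
    assert diag.slope == pytest.approx(2.0)
    assert not diag.kept


def test_independent_noise_rejected():
    rng = np.random.default_rng(1)
    obs = _series(rng.normal(50, 10, 1000))
    cf = _series(rng.normal(50, 10, 1000))
    diag = fit_city_diagnostics(obs, cf)
    assert abs(diag.pcc) < 0.2
    assert not diag.kept


def test_diagnostics_match_closed_form_oracle():
    """Slope and PCC agree with the textbook covariance formulas to 1e-10."""
    rng = np.random.default_rng(2)
    for _ in range(10):
        n = rng.integers(30, 80)
        x = rng.normal(40, 8, n)
        y = 0.9 * x + rng.normal(0, 5, n)
        diag = fit_city_diagnostics(_series(y), _series(x))
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        assert diag.slope == pytest.approx(sxy / sxx, abs=1e-10)
        assert diag.pcc == pytest.approx(sxy / np.sqrt(sxx * syy), abs=1e-10)


def test_insufficient_pairs_and_zero_variance():
    short = _series(np.arange(10.0))
    with pytest.raises(InsufficientDataError):
        fit_city_diagnostics(short, short)
    const = _series(np.full(50, 7.0))
    obs = _series(np.arange(50.0))
    with pytest.raises(UndefinedSlopeError):
        fit_city_diagnostics(obs, const)


def test_regression_orientation_flag():
    cf = _series(np.linspace(10, 60, 100))
    diag = fit_city_diagnostics(2.0 * cf, cf, orientation="model~obs")
    assert diag.slope == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# filter window
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "slope, pcc, kept",
    [
        (1.0, 0.51, True),    # typical kept city
        (0.5, 0.9, False),    # boundary slope excluded (strict)
        (1.5, 0.9, False),
        (1.0, 0.2, False),    # boundary PCC excluded (strict)
        (0.5001, 0.2001, True),
        (1.4999, 0.9, True),
    ],
)
def test_filter_window_strict_boundaries(slope, pcc, kept):
    assert FilterWindow().keeps(slope, pcc) is kept


def test_apply_filter_partition():
    diags = [
        FitDiagnostics("a", "NO2", 1.0, 0.9, 100, True),
        FitDiagnostics("a", "O3", 1.0, 0.9, 100, True),
        FitDiagnostics("b", "NO2", 1.0, 0.9, 100, True),
        FitDiagnostics("b", "O3", 2.0, 0.9, 100, False),
        FitDiagnostics("c", "NO2", 0.4, 0.1, 100, False),
    ]
    kept, outliers = apply_filter(diags)
    assert kept == ["a"]
    assert outliers == ["b", "c"]  # union over pollutants
    assert set(kept) | set(outliers) == {"a", "b", "c"}
    assert set(kept) & set(outliers) == set()


def test_apply_filter_per_pollutant_mode_requires_single_pollutant():
    diags = [
        FitDiagnostics("a", "NO2", 1.0, 0.9, 100, True),
        FitDiagnostics("a", "O3", 1.0, 0.9, 100, True),
    ]
    with pytest.raises(ValueError):
        apply_filter(diags, mode="per_pollutant")
    kept, outliers = apply_filter([diags[0]], mode="per_pollutant")
    assert kept == ["a"] and outliers == []
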