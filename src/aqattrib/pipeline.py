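"""End-to-end orchestration: generate -> QC -> decompose -> met -> health.

A run is fully determined by a :class:`RunConfig` (which embeds the
synthetic-data study conditions and a seed); it writes CSV artifacts, a
driver-by-pollutant attribution summary, HAQI tables per standard, a JSON
manifest and a log under one output directory.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .calendar_windows import TOTAL_LOCKDOWN, CnyCalendar
from .decomposition import DRIVERS, DriverEstimate, decompose_panel
from .health import (
    RiskConfig,
    daily_with_o3_peak,
    haqi_change,
    haqi_series,
    regional_summary,
)
from .ingest import FilterWindow, apply_filter, diagnostics_frame, panel_diagnostics, read_panel
from .met import MetEffectEstimate, build_features, panel_met_effect, predict_bau, train_final
from .synthetic import POLLUTANTS, SyntheticConfig, generate_panel, write_fixture

__all__ = ["RunConfig", "run", "report_driver_table"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_dir: Optional[str] = None           # read fixture instead of generating
    pollutants: Tuple[str, ...] = ("NO2", "O3")
    health_pollutants: Tuple[str, ...] = POLLUTANTS
    standards: Tuple[str, ...] = ("WHO2021", "CAAQS_II")
    filter_window: FilterWindow = field(default_factory=FilterWindow)
    filter_mode: str = "union"
    model_params: Optional[dict] = None
    seed: int = 0
    run_met: bool = True
    run_health: bool = True
    out_dir: str = "results/run"

    def digest(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _driver_frame(estimates: Dict[str, DriverEstimate]) -> pd.DataFrame:
    rows = []
    for name, est in estimates.items():
        for city, value in sorted(est.per_city.items()):
            rows.append(
                {"driver": name, "pollutant": est.pollutant, "city_id": city, "percent": value}
            )
    return pd.DataFrame(rows, columns=["driver", "pollutant", "city_id", "percent"])


def report_driver_table(
    driver_estimates: Dict[str, Dict[str, DriverEstimate]],
    met_estimates: Dict[str, MetEffectEstimate],
) -> pd.DataFrame:
    """Driver-by-pollutant national summary mirroring the attribution table.

    One row per driver per pollutant with mean +/- SD over kept cities;
    drivers that could not be estimated are marked not-estimable.
    """
    rows = []
    pollutants = sorted(
        set(driver_estimates) | set(met_estimates), key=str
    )
    for pol in pollutants:
        per_driver = driver_estimates.get(pol, {})
        for drv in DRIVERS:
            est = per_driver.get(drv)
            rows.append(
                {
                    "driver": drv,
                    "pollutant": pol,
                    "mean_percent": est.national_mean if est else float("nan"),
                    "sd_percent": est.national_sd if est else float("nan"),
                    "n_cities": est.n_cities if est else 0,
                    "estimable": est is not None,
                }
            )
        met = met_estimates.get(pol)
        rows.append(
            {
                "driver": "Met_effect",
                "pollutant": pol,
                "mean_percent": met.national_mean if met else float("nan"),
                "sd_percent": met.national_sd if met else float("nan"),
                "n_cities": met.n_cities if met else 0,
                "estimable": met is not None,
            }
        )
    return pd.DataFrame(rows)


def _setup_logging(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("aqattrib").addHandler(handler)
    logging.getLogger("aqattrib").setLevel(logging.INFO)
    return handler


def run(config: RunConfig) -> Dict[str, object]:
    """Execute the full pipeline; returns artifact paths and key estimates."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    calendar = CnyCalendar()
    artifacts: Dict[str, object] = {"out_dir": str(out)}
    try:
        # --- data -----------------------------------------------------------
        if config.input_dir:
            logger.info("reading panel from %s", config.input_dir)
            panels = read_panel(config.input_dir)
            truths = None
        else:
            logger.info(
                "generating synthetic panel: %d cities, seed %d",
                config.synthetic.n_cities,
                config.synthetic.seed,
            )
            panels, truths = generate_panel(config.synthetic, calendar)

        # --- QC --------------------------------------------------------------
        diags = panel_diagnostics(
            panels, pollutants=config.pollutants, window=config.filter_window
        )
        kept, outliers = apply_filter(diags, mode=config.filter_mode)
        diagnostics_frame(diags).to_csv(out / "qc_diagnostics.csv", index=False)
        logger.info("QC filter: %d kept, %d outliers", len(kept), len(outliers))
        artifacts["kept"], artifacts["outliers"] = kept, outliers

        # --- decomposition ----------------------------------------------------
        driver_estimates: Dict[str, Dict[str, DriverEstimate]] = {}
        for pol in config.pollutants:
            estimates = decompose_panel(panels, pol, calendar, kept_ids=kept)
            driver_estimates[pol] = estimates
            _driver_frame(estimates).to_csv(
                out / f"drivers_{pol.replace('.', '')}.csv", index=False
            )
        artifacts["driver_estimates"] = driver_estimates

        # --- meteorology driver ----------------------------------------------
        met_estimates: Dict[str, MetEffectEstimate] = {}
        if config.run_met:
            for pol in config.pollutants:
                met_estimates[pol] = panel_met_effect(
                    panels,
                    pol,
                    calendar,
                    kept_ids=kept,
                    params=config.model_params,
                    seed=config.seed,
                )
                logger.info(
                    "met effect %s: %.2f%% over %d cities",
                    pol,
                    met_estimates[pol].national_mean,
                    met_estimates[pol].n_cities,
                )
            pd.DataFrame(
                [
                    {"pollutant": pol, "city_id": c, "percent": v}
                    for pol, est in met_estimates.items()
                    for c, v in sorted(est.per_city.items())
                ]
            ).to_csv(out / "met_effect.csv", index=False)
        artifacts["met_estimates"] = met_estimates

        driver_table = report_driver_table(driver_estimates, met_estimates)
        driver_table.to_csv(out / "driver_summary.csv", index=False)
        artifacts["driver_table"] = driver_table

        # --- health index ------------------------------------------------------
        if config.run_health:
            artifacts["haqi"] = _health_stage(panels, kept, config, calendar, out)

        # --- manifest ----------------------------------------------------------
        manifest = {
            "config": _as_jsonable(config),
            "config_digest": config.digest(),
            "seed": config.seed,
            "aqattrib_version": __version__,
            "versions": _library_versions(),
            "timestamp": dt.datetime.now().isoformat(timespec="seconds"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("run complete: %s", out)
        return artifacts
    finally:
        logging.getLogger("aqattrib").removeHandler(handler)
        handler.close()


def _library_versions() -> Dict[str, str]:
    import lightgbm
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "lightgbm": lightgbm.__version__,
    }


def _health_stage(
    panels, kept: Sequence[str], config: RunConfig, calendar: CnyCalendar, out: Path
) -> Dict[str, object]:
    """Observed-vs-BAU HAQI over the Total COVID-lockdown window of 2020.

    The BAU concentrations are per-pollutant emulator predictions for 2020
    under the actual 2020 weather (business-as-usual emissions, real
    meteorology), mirroring the observed/predicted HAQI comparison.
    """
    risk = RiskConfig()
    kept_set = set(kept)
    window_dates = pd.DatetimeIndex(
        [
            calendar.cny_date(2020) + dt.timedelta(days=o)
            for o in TOTAL_LOCKDOWN.offsets
        ]
    )
    results: Dict[str, object] = {}
    rows = []
    regions = {}
    for panel in panels:
        if panel.city_id not in kept_set:
            continue
        regions[panel.city_id] = panel.region
        observed_daily = daily_with_o3_peak(panel.observed, panel.hourly_o3)
        bau_daily = pd.DataFrame(index=window_dates)
        for pol in config.health_pollutants:
            features = build_features(panel, pol, calendar)
            train = features[features.index.year < 2020]
            emulator = train_final(train, params=config.model_params, seed=config.seed)
            feats_2020 = features.reindex(window_dates).drop(columns=["target"]).dropna()
            bau_daily[pol] = predict_bau(emulator, feats_2020).reindex(window_dates)
        for standard in config.standards:
            obs_haqi = haqi_series(
                observed_daily.reindex(window_dates)[list(config.health_pollutants)],
                risk,
                standard,
                city_id=panel.city_id,
            )["haqi"]
            bau_haqi = haqi_series(bau_daily, risk, standard, city_id=panel.city_id)[
                "haqi"
            ]
            change = haqi_change(obs_haqi, bau_haqi)
            rows.append(
                {
                    "city_id": panel.city_id,
                    "region": panel.region,
                    "standard": standard,
                    "observed_haqi": float(obs_haqi.mean()),
                    "bau_haqi": float(bau_haqi.mean()),
                    "change_percent": change,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out / "haqi_city.csv", index=False)
    summaries = {}
    for standard in config.standards:
        sub = table[table["standard"] == standard]
        changes = dict(zip(sub["city_id"], sub["change_percent"]))
        if changes:
            summary = regional_summary(changes, regions)
            summaries[standard] = summary
            pd.DataFrame(
                [
                    {"region": r, "mean_change_percent": v}
                    for r, v in summary.region_means.items()
                ]
            ).to_csv(out / f"haqi_regional_{standard}.csv", index=False)
    results["city_table"] = table
    results["regional"] = summaries
    return results
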