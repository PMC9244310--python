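#!/usr/bin/env python
"""Estimate the meteorology driver with the boosted-tree emulator contrast.

For each kept city, trains a gradient-boosted model of daily NO2 (and O3)
on 2015-2019 meteorology + calendar features, cross-validates it with the
expanding-window scheme, and contrasts 2020 predictions under actual vs
climatological weather over the Total COVID-lockdown window.
"""
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from aqattrib.ingest import apply_filter, panel_diagnostics
from aqattrib.met import build_features, panel_met_effect, rolling_cv
from aqattrib.synthetic import SyntheticConfig, generate_panel

SEED = 0
N_CITIES = 20  # a representative subset keeps this narrative script quick
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    warnings.filterwarnings("ignore")
    panels, truths = generate_panel(SyntheticConfig(seed=SEED, n_cities=N_CITIES))
    kept, _ = apply_filter(panel_diagnostics(panels))

    # cross-validation report for the first kept city, as a model sanity check
    cv = rolling_cv(build_features(panels[0], "NO2"), seed=SEED)
    RESULTS.mkdir(exist_ok=True)
    cv.frame().to_csv(RESULTS / "04_cv_report_city000_no2.csv", index=False)
    print("expanding-window CV (city000, NO2):")
    print(cv.frame().to_string(index=False))
    print(f"mean RMSE {cv.mean_rmse:.2f} ug/m3, mean PCC {cv.mean_pcc:.2f}\n")

    rows = []
    for pol, truth_key in (("NO2", "met_effect_no2_pct"), ("O3", "met_effect_o3_pct")):
        est = panel_met_effect(panels, pol, kept_ids=kept, seed=SEED)
        injected = float(np.mean([getattr(t, truth_key) for t in truths]))
        rows.append(
            {
                "pollutant": pol,
                "mean_percent": round(est.national_mean, 2),
                "sd_percent": round(est.national_sd, 2),
                "injected_mean": round(injected, 2),
                "n_cities": est.n_cities,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "04_met_effect.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nThe 2020 stagnation anomaly raises NO2 by ~8% relative to "
        "climatological weather while barely moving O3, matching the injected "
        "sensitivities."
    )


if __name__ == "__main__":
    main()
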