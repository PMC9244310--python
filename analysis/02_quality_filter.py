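#!/usr/bin/env python
"""Fit the per-city slope/PCC filter against the counterfactual series.

Regenerates the default panel (deterministic), fits observed-on-counterfactual
OLS per city and pollutant over the pre-2020 record, applies the strict
0.5 < S < 1.5, PCC > 0.2 window and writes the diagnostics table.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from aqattrib.ingest import apply_filter, diagnostics_frame, panel_diagnostics
from aqattrib.synthetic import SyntheticConfig, generate_panel

SEED = 0
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panels, _ = generate_panel(SyntheticConfig(seed=SEED))
    diags = panel_diagnostics(panels, pollutants=("NO2", "O3"))
    kept, outliers = apply_filter(diags)

    frame = diagnostics_frame(diags)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "02_qc_diagnostics.csv", index=False)

    print(f"{len(kept)} cities kept, {len(outliers)} outliers: {outliers or 'none'}")
    by_pol = frame.groupby("pollutant")[["S", "PCC"]].mean().round(3)
    print("mean diagnostics per pollutant:")
    print(by_pol.to_string())
    print(
        "\nThe synthetic counterfactual shares the true meteorology, so slopes "
        "sit near the mean anthropogenic multiplier (~0.9) and correlations are "
        "high; all cities pass the window."
    )


if __name__ == "__main__":
    main()
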