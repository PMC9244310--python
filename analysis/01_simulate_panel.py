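#!/usr/bin/env python
"""Simulate the multi-city study panel and summarise the injected truths.

Generates the default 50-city synthetic world (observed, counterfactual and
meteorological series with known holiday/policy/lockdown/meteorology
effects), writes the raw fixture under scratch/ (it is bulky and fully
reproducible from the seed) and a compact summary of the injected effect
sizes under results/.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from aqattrib.synthetic import SyntheticConfig, generate_panel, write_fixture

SEED = 0
RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "fixture"


def main() -> None:
    config = SyntheticConfig(seed=SEED)
    panels, truths = generate_panel(config)
    write_fixture(panels, truths, SCRATCH, write_hourly=False)

    table = pd.DataFrame([{"city_id": t.city_id, **t.as_dict()} for t in truths])
    summary = table.drop(columns="city_id").agg(["mean", "std"]).T.round(3)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "01_truth_summary.csv")

    print(f"wrote fixture for {len(panels)} cities to {SCRATCH}")
    print("injected effect sizes (percent), across-city mean +/- sd:")
    print(summary.to_string())
    print(
        "\nThe means sit at the configured study conditions (holiday dip -26.7, "
        "policy step -15.7, lockdown dip -11.6, extended dip -34.7, met ~+7.8)."
    )


if __name__ == "__main__":
    main()
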