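# aqattrib

Attribution of city-level air-pollutant changes during the 2020 COVID-19
lockdown in China to their overlapping drivers — the Chinese New Year (CNY)
holiday, the 2018–2020 Clean Air Plan (CAP), the lockdown itself and
meteorology — together with the excess-risk and Health-based Air Quality
Index (HAQI) machinery that turns multi-pollutant changes into health terms.

It is written for air-quality and environmental-health researchers who want
the attribution pipeline as tested, reusable code. Because the original
station, meteorological and reanalysis inputs are restricted downloads, the
package ships a synthetic multi-city generator with *known, injected*
effects, so every stage can be exercised and validated end to end.

## The method in brief

For each city, an observed concentration series is contrasted with a
counterfactual series whose emissions contain no holiday, policy or lockdown
reductions. With windows expressed in days from the CNY's day (Before CNY
−21…−8, CNY −7…+10, Extended lockdown +11…+42, Total lockdown −1…+42), the
drivers are window contrasts `100·(mean obs − mean cf)/mean cf` and their
differences:

    CNY_2020       = CNY_2020-mix − CAP_2018–2020
    COVID-lockdown = CNY_2020-mix − CNY_2015–2019 − CAP_2018–2020

The meteorology driver uses one gradient-boosted emulator per city and
pollutant (meteorology + calendar features → daily concentration, trained
2015–2019, expanding-window CV) and contrasts its 2020 predictions under
actual vs CNY-aligned climatological weather. Health effects follow
RRᵢ = exp(βᵢ(Cᵢ − C₀ᵢ)), ERᵢ = RRᵢ − 1, ER_total = Σ ERᵢ,
C*ᵢ = ln(1 + ER_total)/βᵢ + C₀ᵢ, and HAQI = max over pollutants of the AQI
sub-index of C*ᵢ, under WHO-2021 or Chinese CAAQS grade-II thresholds.
Details, defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

```python
from aqattrib.synthetic import SyntheticConfig, generate_panel
from aqattrib.ingest import panel_diagnostics, apply_filter
from aqattrib.decomposition import decompose_panel
from aqattrib.met import panel_met_effect

panels, truths = generate_panel(SyntheticConfig(seed=0))     # 50 cities
kept, outliers = apply_filter(panel_diagnostics(panels))
drivers = decompose_panel(panels, "NO2", kept_ids=kept)
for name, est in drivers.items():
    print(f"{name:24s} {est.national_mean:7.2f} +/- {est.national_sd:.2f} %")
met = panel_met_effect(panels, "NO2", kept_ids=kept, seed=0)
print(f"{'Met_effect':24s} {met.national_mean:7.2f} +/- {met.national_sd:.2f} %")
```

prints

```
CNY_2020_mix              -53.02 +/- 4.74 %
CNY_2015_2019             -26.30 +/- 3.76 %
CAP_2018_2020             -15.13 +/- 2.19 %
CNY_2020_isolated         -37.89 +/- 4.65 %
COVID_lockdown            -11.59 +/- 1.96 %
Extended_COVID_lockdown   -33.64 +/- 5.75 %
Met_effect                  8.81 +/- 2.00 %
```

Reading: the ordinary holiday dip takes NO₂ down ~26 %, the Clean-Air-Plan
step another ~15 %, and once both are removed from the mixed 2020 signal the
lockdown itself accounts for ~12 % — while stagnant 2020 weather pushed
concentrations *up* by ~8–9 % relative to climatology. The estimates sit
within a few tenths of a point of the injected truths recorded alongside the
panel (`truths`), except the met effect, whose emulator carries a known
~+1 pp bias (see the methods note).

The same stages run as numbered scripts under `analysis/`
(01 simulate → 02 quality filter → 03 decompose → 04 meteorology →
05 health index), each writing its tables under `results/`, or from the
command line:

```bash
aqattrib all --out results/run --seed 42 --n-cities 10
```

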