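# Methods

## Problem and model

During the first quarter of 2020, Chinese cities saw large NO₂ decreases and
O₃ increases. Three anthropogenic drivers overlap in that window — the
Chinese New Year (CNY) holiday shutdown that happens every year, the 2018–2020
Clean Air Plan (CAP) whose NOx reductions accumulate across years, and the
COVID-19 lockdown itself — and meteorology modulates everything on top. This
package implements the window-contrast attribution that disentangles them,
plus the excess-risk / HAQI health indices that translate multi-pollutant
changes into a single health-relevant number.

The central device is a *counterfactual* concentration series per city whose
emissions know nothing of holiday, policy or lockdown reductions (in the real
analysis, a reanalysis product; here, the synthetic generator's
business-as-usual series). All windows are expressed in days relative to the
CNY's day (offset 0), because CNY moves by up to three weeks on the Gregorian
calendar:

| window | offsets |
|---|---|
| Before CNY | −21 … −8 |
| CNY | −7 … +10 |
| Extended COVID-lockdown | +11 … +42 |
| Total COVID-lockdown | −1 … +42 |

Each driver is a percentage contrast `100·(mean(obs) − mean(cf))/mean(cf)`
over pooled window days:

* **CNY₍2020-mix₎** — CNY window, 2020: everything mixed;
* **CNY₍2015–2019₎** — CNY window pooled 2015–2019: the ordinary holiday dip;
* **CAP₍2018–2020₎** — Before-CNY window pooled 2018–2020: the policy step,
  measured where neither holiday nor lockdown reaches;
* **CNY₍2020₎** = mix − CAP; **COVID-lockdown** = mix − CNY₍2015–2019₎ − CAP
  (plain subtraction of percentages, so additivity holds exactly);
* **Extended COVID-lockdown** — +11…+42 of 2020, minus CAP;
* **Met effect** — the emulator contrast described below, over the Total
  window.

Window aggregates use the ratio of pooled means (robust to low-concentration
days); a mean-of-daily-ratios variant exists behind a flag. National numbers
are unweighted city means with sample (ddof = 1) SDs; population enters only
through the >5-million stratum mean. Cities whose counterfactual does not
track observations with near-unit gain are dropped first by the strict filter
0.5 < S < 1.5 and PCC > 0.2, with S the OLS slope of observed on
counterfactual over the 2015–2019 record (the orientation is a package
choice — the filter asks whether the counterfactual tracks reality — and is
switchable). Boundary values are excluded, and by default a city failing the
window for any analysed pollutant is an outlier for all (single combined
outlier set; per-pollutant sets are available).

## Meteorology driver

One LightGBM regressor per city and pollutant maps daily meteorology
(T, RH, WS, wind direction as sine/cosine, precipitation, pressure) plus
calendar features (Julian day, day of week, an inert constant hour-of-day
column kept for schema compatibility, a binary in-CNY-window flag, and a
running date index) to the daily concentration. Training uses 2015–2019;
validation is expanding-window time-series CV with five splits (train 2015,
2015–16, …, 2015–19; test the first three months of the following year), so
no test day ever precedes a training day. Default hyperparameters: 400
trees, learning rate 0.05, 31 leaves, min 20 samples per leaf, seeded and
single-threaded for determinism. Linear-tree leaves were evaluated and
rejected: they produced heavy-tailed per-city contrast errors.

The met effect is the contrast of the trained model's mean prediction over
the Total COVID-lockdown window of 2020 under (a) the actual 2020 weather and
(b) the 2015–2019 climatological weather, aligned at equal CNY-relative
offsets (a package choice, consistent with every other construct here; a
calendar-date mode exists). Wind direction is averaged vectorially. The
contrast is identically zero when the two feature tables coincide,
regardless of the model.

## Synthetic world

The generator replaces restricted station/reanalysis downloads with a
multi-city panel in which every effect is known:

    observed = counterfactual · (1 + cny + cap + lockdown) · exp(ε),

with each term switched on only inside its window and log-normal, mean-one
observation noise ε (σ = 0.05 by default). The counterfactual is a
seasonal × weekly baseline modulated by meteorology, and the *same*
meteorological modulation enters observed and counterfactual alike — the
counterfactual knows each year's weather, only not its emission changes.
Meteorology acts through a ventilation index
v = (WS − 2.5 m/s) − (P − 1013 hPa)/8, with a per-city sensitivity (default
6 %/unit for NO₂ and the primary pollutants, −0.12 of that for O₃); 2020
receives a calm/stagnant anomaly over the Total window whose size (1.17
index units) is calibrated so the realised national NO₂ met effect is about
+7.8 %. O₃ mirrors the NO₂ anthropogenic change with opposite sign at a
coupling of 0.9 (NO-titration phenomenology, not chemistry).

Default injected national means are the study conditions: holiday dip
−26.7 %, policy step −15.7 % from 2018 onward, 2020 lockdown dip −11.6 %
over the CNY window and −34.7 % over the extended window, with a 15 %
relative across-city scatter. Three structural choices make the truth
*exactly* the estimand of each driver contrast, so noise-free recovery is
exact rather than asymptotic:

1. effects add inside a single multiplier (matching the attribution table's
   additive algebra);
2. the CAP step is suppressed inside the CNY windows of 2018–2019 — a full
   holiday shutdown subsumes the policy reduction — and stacks inside the
   2020 windows;
3. the 2020 lockdown dip covers the whole CNY window (mobility had already
   collapsed days before the holiday), with the separate extended dip on
   +11…+42.

What the generator does **not** emulate: atmospheric chemistry, spatial
correlation between cities, reanalysis biases beyond near-unit gain, and
drivers that vary within a window. Passing recovery tests therefore shows
that the estimators measure what they claim under the assumed
data-generating structure — not that the real-world magnitudes are right.

## Health indices

Excess risk follows RRᵢ = exp(βᵢ(Cᵢ − C₀ᵢ)) above the threshold C₀ᵢ and is
zero at or below it; ERᵢ = RRᵢ − 1 and ER_total = Σ ERᵢ. β values (fractions
per µg/m³; CO per mg/m³): PM2.5 0.00038, PM10 0.00032, SO₂ 0.00081, NO₂
0.0013, O₃ 0.00048, CO 0.037. The combined risk RR* = 1 + ER_total is mapped
per pollutant to the equivalent concentration C*ᵢ = ln(RR*)/βᵢ + C₀ᵢ, each
C*ᵢ is passed through standard AQI piecewise-linear breakpoint interpolation
(HJ 633-2012 daily table; above the top row the sub-index is capped and
flagged), and the HAQI is the maximum sub-index over the pollutants actually
observed that day — so a single-pollutant day reduces to that pollutant's
plain AQI. O₃ enters as the daily 8-h peak (maximum of within-day 8-hour
moving means; ≥18 valid hours per day and ≥6 per window, common regulatory
practice). Threshold sets: WHO-2021 24-h guidelines (PM2.5 15, PM10 45, NO₂
25, SO₂ 40, O₃-8h 100 µg/m³, CO 4 mg/m³) and CAAQS grade-II daily limits
(75, 150, 80, 150, 160, 4). Thresholds and breakpoints are reconstructed
configuration defaults, all overridable.

The observed-vs-BAU HAQI change is the percent difference of window means,
negative = improvement, with the observed-period mean as the default
denominator (the convention consistent with published capital-city means;
the counterfactual-mean denominator is selectable). Window-mean-then-
difference is used rather than daily differencing.

## Numerical choices and degenerate inputs

* Percent changes are undefined for non-positive counterfactual means; such
  city-windows are dropped with a logged reason, as are windows below 50 %
  day coverage.
* A constant training target yields a constant-predictor emulator with a
  warning; negative raw predictions are clamped at zero and counted.
* All randomness flows from `numpy.random.default_rng([seed, city_index])`,
  so panels are bit-identical given (seed, index) and independent of panel
  size; LightGBM runs seeded, deterministic, single-threaded.
* CNY dates are configuration (published lunar-calendar dates for
  2015–2020), not computed astronomy. The Total-lockdown bounds (−1…+42) are
  configuration; an alternative reading of the lockdown start (−2) differs
  by one day and is reachable through `WindowSpec`.

## Known limitations

* The emulator-based met effect carries a small positive bias (~+1 pp at the
  default conditions): the holiday×policy interaction in the training years
  is partially misattributed to meteorological features by the trees. It is
  visible against the generator truth and documented rather than corrected,
  since any correction would presume knowledge of the very effects being
  estimated. Per-city contrasts have ~±1.3 pp mean absolute error; national
  means over 50 cities are much tighter.
* CV scores on the synthetic panel (e.g. mean RMSE ≈ 6.7 µg/m³, PCC ≈ 0.7
  for NO₂) describe the synthetic world only; the final split (testing
  Jan–Mar 2020) is *expected* to score poorly because the lockdown violates
  business-as-usual.
* Problem sizes used by the shipped analyses — 50 cities for generation, QC
  and decomposition, 20 for the met contrast, 10 for the six-pollutant
  health stage — were chosen as the smallest panels at which national means
  are stable against the injected truth.
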