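# hivevib

Monitoring the honeybee brood cycle from comb-embedded accelerometer
spectra.

An accelerometer pressed into the central comb of a hive records one
averaged vibrational amplitude spectrum every three minutes (0–5500 Hz at
3.125 Hz resolution, in m/s²).  As worker brood, honey and pollen fill and
empty the cells around the sensor, the comb's transfer function changes:
heavier comb attenuates the bee-generated vibration.  `hivevib` implements
the full analysis that turns this into a non-invasive brood-cycle monitor,
for researchers and tool builders working on vibrational/acoustic colony
sensing:

1. **Overnight amplitude distributions** — pool every amplitude of every
   00:00–06:00 spectrum (10–600 Hz band) into one histogram per night and
   extract its mode *A\*(t)*, the most frequent amplitude.
2. **Period spectrum** — Fourier-transform the nightly mode series; a
   healthy laying queen produces a dominant period in the 21–26 day band
   (slightly above the 21-day worker development time).  Swarming, drone
   laying, winter and colony failure have recognisable signatures.
3. **Frame-condition correlation** — regress *A\** on visually assessed
   frame condition, *A\** ~ α·brood% + β·pollen% + δ·honey% + c (OLS,
   identity-link Gaussian model).
4. **Spectral-shape discrimination** — PCA (10 scores) → multi-group Fisher
   discriminant analysis (3 functions) on 60-minute normalized spectra
   selected at the oscillation extrema of training colonies; the indicator
   **D₂/D₁** (distance to the pooled high-amplitude centroid over distance
   to the shared low-amplitude centroid) then tracks the brood cycle from a
   single hour of night data, robust to amplitude drift.

No public recordings of this kind exist, so the package includes a seeded
synthetic-apiary generator (`hivevib.synthetic`) with a retrievable
ground-truth channel; every stage is tested against the quantities the
generator actually used.  See `docs/methods.md` for the model and all
numerical choices.

## Worked example

Simulate the default colony (150 nights, 23-day brood cycle), build the
nightly amplitude distributions and recover the cycle:

```python
import hivevib as hv
from hivevib.pipeline import colony_mode_series
from hivevib.period_analysis import period_spectrum
from datetime import timedelta

scenario = hv.ColonyScenario(seed=1)   # 150 nights, 23-day brood cycle
nights = {}
for i in range(scenario.n_days):
    day = scenario.start_date + timedelta(days=i)
    frames = hv.simulate_day_window(scenario, day, hours=(0, 6))
    nights[day] = [hv.crop_band(fr, 10, 600) for fr in frames]

series, bin_width = colony_mode_series(nights)
ps = period_spectrum(series)
print(f"histogram bin width : {bin_width:.2e} m/s^2")
print(f"nightly mode range  : {series.mode_amps.min():.2e} - {series.mode_amps.max():.2e} m/s^2")
print(f"dominant period     : {ps.dominant_period:.1f} days")
print(f"clear 21-26 d peak  : {ps.has_brood_band_peak}")
```

prints

```
histogram bin width : 1.12e-08 m/s^2
nightly mode range  : 5.37e-07 - 1.84e-06 m/s^2
dominant period     : 23.1 days
clear 21-26 d peak  : True
```

The bin width was auto-tailored to the colony's strength (within the
0.1–0.4 ×10⁻⁷ m/s² range); the mode amplitude swings by a factor ~3 as
brood loads and unloads the comb, and its Fourier spectrum peaks at
23.1 days — the configured brood period recovered to the period-grid
resolution.  Running the same colony with the wall-mounted control sensor
(`sensor="wall"`, stimulus only, one order of magnitude weaker) yields
`has_brood_band_peak = False`: the cycle lives in the comb, not in the
bees' noise level.

The full pipeline — apiary simulation, histograms, period spectra,
inspection regression, discriminant training and the D₂/D₁ indicator —
runs as one call (`hivevib.run_pipeline(PipelineConfig(...))`) or from the
shell:

```sh
hivevib run-all --seed 1 --colonies 20 --nights 150 --out out/
hivevib band-sweep --lo 0:350:50        # histogram stability vs crop limit
```

`run-all` writes per-colony mode-series and period-spectrum CSVs, the fit
report, the serialized discriminant model, indicator images and a summary
table, and embeds the exact config that reproduces them.

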