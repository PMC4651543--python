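# Methods

`hivevib` re-implements, end to end, a vibration-based monitor of the
honeybee brood cycle: an accelerometer embedded in the central comb of a
hive records one amplitude spectrum every three minutes (0–5500 Hz at
3.125 Hz resolution, m/s²), and suitable processing of the night-time
spectra reveals the ~21–26-day cycle with which worker brood fills and
empties the comb around the sensor.  Because no public dataset of such
recordings exists, the package pairs the analysis chain with a synthetic
generator whose ground truth is retrievable, so every estimator is tested
against the quantity it is supposed to recover.

## The measurement model behind the generator

The comb is treated as a vibrating substrate driven by the bees.  The
generator composes four ingredients:

**Stimulus.**  A dimensionless spectral shape — a pink broadband floor
`0.8·(1+f/200 Hz)^(−0.15)` with two Gaussian harmonics at 125 Hz (gain 4.0,
σ = 12 Hz) and 250 Hz (gain 2.5, σ = 18 Hz) — scaled by the colony's
stimulus level (default 4 µm/s² at the spectral scale used here, placing
night amplitudes in the 10⁻⁶–10⁻⁵ m/s² range).  A smooth diurnal factor
`0.75 − 0.25·cos(2πh/24)` makes the night half as loud as midday, and a
log-normal night-to-night jitter (σ = 0.05) models slow variability of the
colony's activity; the magnitude of that jitter is a free parameter because
nothing pins it down, and the default is deliberately small.

**Transfer function.**  The local comb load

    L(t) = 0.6·brood(t) + 0.3·honey(t) + 0.1·pollen(t)

attenuates the measured amplitude by `1/(1 + κL)` with κ = 3 (heavier comb,
smaller acceleration at fixed drive — the Newton's-second-law surrogate),
and perturbs spectral *shape*: harmonic widths grow by 20 % and centres
shift down by 1 % per unit load.  The shape perturbation is what makes the
brood state recoverable from normalized spectra alone; the chosen forms are
the simplest ones consistent with a load-stiffened, mass-loaded substrate.

**Comb content.**  Near-sensor brood follows a raised cosine of period
23 days by default (slightly above the 21-day worker development time),
with a per-colony phase offset; honey rises slowly over the season
(0.05 → 0.15 of the frame by default; central frames rarely carry more than
20 % honey) and pollen stays low.  Colony events interrupt the cycle:
`winter` and the three weeks after a `primary_swarm` zero the brood;
`drone_laying` replaces the coherent cycle with low-amplitude jitter built
from two incommensurate slow sinusoids (locally asynchronous laying);
`failure` ramps brood to zero and decays the stimulus to 10 %.
Overlapping events of different kinds are rejected as contradictory.

**Sensors and noise.**  The comb channel applies the transfer function; the
wall channel returns the bare stimulus divided by exactly 10 with *no* load
modulation — it is the control that shows the cycle lives in the comb, not
in the stimulus.  Per-bin multiplicative log-normal noise (σ = 0.10,
mean-corrected) models averaging residue and electronics.  All randomness
derives hierarchically from `SeedSequence((colony_seed, day_index))`, so a
day simulated alone is bit-identical to the same day inside a season, and a
fixed master seed reproduces an apiary byte for byte.

**Apiary variation.**  Colonies drawn for an apiary differ in period
(21.5–25.5 d), phase, peak brood coverage (0.60–0.84), stimulus level
(log-normal, σ = 0.3) and spectral identity.  Identity has two
load-independent dimensions — the 125/250 Hz gain ratio (0.7–1.3) and an
additive linear tilt of the floor (±0.4) — laid out on a greedy-maximin
point set with seed-permuted assignment, so that no two hives coincide
spectrally by accident.  Both enter the spectrum linearly; an earlier
design that scaled the floor exponent instead traced a *curved* arc in
spectrum space, and linear projections (see the discriminant step) folded
distant identities onto each other.  The per-colony harmonic-width jitter
is kept at ±0.25 % because width is exactly the axis along which load is
read; a wide width spread would confound colony identity with brood state.

What the generator does **not** emulate: weather and temperature, swarming
dynamics beyond the brood gap, spatial structure within the frame, daytime
foraging signatures, measurement dropouts, or any bee-behavioural acoustics
(piping, tooting).  Tests passing on this generator show the *estimators*
are correct and that the pipeline recovers what the model encodes; they do
not certify performance on field recordings.

## The analysis chain

**Night window and band.**  Only spectra between 00:00 and 06:00 (half-open)
are analysed, removing foraging noise and beekeeper interventions; a full
day contributes 120 of its 480 frames.  Spectra are cropped to 10–600 Hz
(189 bins), the band in which the amplitude distribution keeps a single
pronounced mode; `band_sweep` recomputes the histograms across crop limits
to audit that choice.  Both are configurable — the upper clock limit in
particular (6 vs 7 a.m.) is not settled and the default follows the stricter
choice.

**Overnight amplitude distributions.**  All amplitudes of all night frames
are pooled into one histogram per night.  Bin edges start at 0 m/s² so that
nights share an axis; the width is tailored to colony strength as
`clip(median/100, 0.1e-7, 0.4e-7)` m/s².  The mode (most frequent
amplitude) is extracted by fitting a Gaussian to the ±5 bins around the
argmax — a local fit, because the pooled distribution is single-peaked near
its maximum but asymmetric overall — falling back to the argmax centre if
the fit fails; ties break toward lower amplitude.  Stacking per-night
max-normalized histograms column-wise gives the distribution image
(black = 0 → red = 1) whose red ridge oscillates with the brood cycle:
*high load = low mode amplitude*, so ridge valleys are brood maxima.

**Period spectrum.**  The nightly mode series (gaps ≤ 20 %, span ≥ 42
nights) is linearly interpolated, linearly detrended, zero-padded ×4 (no
taper) and Fourier transformed; magnitude is re-indexed as period =
length/k in days, restricted to ≤ 60 d so the seasonal trend cannot set the
scale, and max-normalized.  A *clear* brood-band peak is a local maximum in
21–26 d with prominence ≥ 0.3 **and** height ≥ 3× the median spectral
magnitude.  The second condition matters: after max-normalization a pure
noise spectrum always contains prominent bumps, and prominence alone flags
white noise ~35 % of the time; requiring the peak to also stand well above
the spectral floor drives the false-positive rate below 1 % while leaving
genuine cycles (peak 1.0 vs median ≪ 1/3) untouched.

**Frame-condition regression.**  Visual inspections estimate % brood,
% pollen and % honey per frame side; sides agree closely and are averaged.
The mode amplitude of the night nearest each inspection (±2 days) is
regressed on the three percentages with an intercept — an identity-link
Gaussian linear model via ordinary least squares.  Comb contents damp the
signal, so on linearized synthetic data (κL ≪ 1) all three coefficients are
negative with magnitudes ordered like the generator's attenuation
constants.  Constant predictors are dropped and reported; contributions are
ranked by |coefficient × observed range|, ties alphabetical.

**Spectral-shape discrimination.**  For each training colony, the six most
prominent maxima and minima of the 5-night-median-smoothed mode series are
labelled (low amplitude = brood present; the inversion is deliberate and
documented in the model's orientation note).  Each full 60-minute slot of a
labelled night becomes one training spectrum: the mean of 20 consecutive
frames, divided by its own maximum.  PCA keeps 10 components (SVD,
largest-|element|-positive sign convention); a multi-group Fisher
discriminant analysis — eigenvectors of `Sw⁻¹Sb`, within-scatter
regularized by 1e-8·trace if needed, axes scaled to unit within-group
variance — keeps 3 functions.  The low-amplitude spectra of *all* colonies
form one shared group; each colony's high state is its own group, so the
discriminant space encodes brood state generically and colony identity
separately.  Because both steps are linear, the three discriminant
functions live on the frequency grid and the inner product of a
mean-centred spectrum with them *is* its DF score triple — a user needs
only the curves and the centroids.

**The D2/D1 indicator.**  A projected spectrum's distance to the pooled
high-state centroid (D2) over its distance to the shared low-state centroid
(D1).  Large values mean brood present; a spectrum exactly at the low
centroid returns +inf, flagged.  Nights are summarized by the geometric
mean over their six hour slots — the indicator is a ratio, so averaging
happens on the log scale where a single near-centroid spike cannot dominate
— and tracking against the mode series is scored as the Pearson correlation
of log indicator with −log mode, the natural scale for two multiplicative
quantities.

On the five-colony training apiary the state-level separation (low vs high,
the discrimination the indicator uses) is complete at 15 minutes of
averaging and above, and training accuracy is non-decreasing in duration
over {3, 15, 30, 60} min.  Colony-identity separation between *high* clouds
is also near-perfect but not guaranteed: six clouds whose identity plane
must survive a 3-axis projection retain ~1 % mutual high-high ambiguity;
this does not affect the brood-state indicator, which only uses the pooled
centroids.

## Numerical and testing choices

* Period estimates are grid-quantized (~0.85 d near 23 d at 150 nights with
  ×4 padding); recovery tests use ±1.5 d.
* PCA and DFA are verified against brute-force eigendecompositions
  (covariance; `inv(Sw)@Sb`), OLS against the normal equations.
* Problem sizes in the test suite: one 150-night colony for period and
  wall-contrast checks; a 20-colony apiary for recovery (≥ 90 % within
  ±1.5 d); a 5-colony, 150-night apiary for discrimination; 40-permutation
  and 40-seed Monte-Carlo loops for the null checks.  These sizes already
  give stable statistics, and the full suite runs in a few minutes.
* Day files are plain text with a 17-significant-digit float format:
  read(write(x)) is bit-exact.  Files with non-canonical bin spacing are
  accepted with a warning record, never silently rewritten.
* Degenerate inputs fail loudly: empty night windows are allowed (a missing
  night is data, not an error) but empty histograms, flat mode series,
  zero-length scenarios and contradictory event overlaps raise.

## Known limitations

The generator's linear identity plane makes the discrimination problem
kinder than nature; real colonies may not be linearly separable in three
discriminant axes.  The mode extraction assumes a single-peaked amplitude
distribution, which the band sweep shows can split outside 10–600 Hz.  The
frame-condition regression identifies coefficients only when brood, honey
and pollen trajectories are not collinear over the inspection dates — with
seven visits and smooth seasonal trends this is a real constraint, and the
per-colony fits in the pipeline inherit it.  Tracking correlations are
computed on nights where both the indicator and the mode series exist; long
gaps reduce their support.
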