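# Methods

This note documents the models, parameter choices and numerical
conventions behind `veghealth`, in the spirit of a package methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Calendar and containers

All gridded fields live on a 52-week composite calendar: each year
contributes exactly 52 weekly composites (day 365/366 of the source
year is dropped). This makes the time axis uniform by construction,
lets climatology be keyed to the calendar week, and matches the 7-day
composite cadence of operational vegetation-health products. A
`WeeklyCube` carries values (time × lat × lon), per-step year and week,
and a validity mask that every downstream operation honours; weeks with
no valid pixel propagate as NaN, never as silent zeros.

## Synthetic data: what it emulates and what it does not

The generator stands in for a 1982–2016, 16-km blended AVHRR/VIIRS
weekly record over a mid-latitude agricultural window
(36.02–42.62 °N, 113.06–119.88 °E ⇒ 46 × 38 pixels at default). Each
pixel series is

seasonal harmonic + linear trend + AR(1) noise + episode anomalies
(+ index coupling for BT),

with NDVI clipped to [−1, 1] afterwards (clips are counted and logged).
Defaults, with reasoning:

| parameter | default | why |
|---|---|---|
| NDVI baseline / amplitude | 0.255 / 0.145 | winter floor ≈ 0.11, August (week 32) peak ≈ 0.40, the documented regional cycle |
| BT mean / amplitude (°C) | 12.0 / 16.5 | annual-mean ≈ 12 °C with ≈ 28 °C summer peak (week 28), winter below freezing |
| AR(1) coefficient | 0.6 | weekly composites of a slowly varying land surface are strongly autocorrelated; the real record does not publish this value, so it is one fixed plausible choice |
| noise sd (NDVI / BT) | 0.02 / 1.0 °C | a few percent of the seasonal range, typical of composite retrievals |
| ENSO-like index | AR(1) 0.95 + 4-yr sinusoid, amp 1.0, innovation sd 0.1 | zero-mean, interannual (2–7-yr band) power, anomaly scale ≈ 0.8 °C |

Episodes subtract a fixed NDVI depression and add a BT elevation over a
week range on a reproducibly drawn pixel subset; the episode, mask and
noise draws come from independent child streams of the run seed, so
adding an episode does not perturb the noise realisation (this is what
makes with/without differencing exact in the tests). The missing-data
mask invalidates exactly `round(missing_fraction · n_cells)` cells.

Not emulated: radiative-transfer effects, orbital drift, cloud
spatial structure (missingness is i.i.d. across cells), spatially
correlated noise, and double-cropping phenologies. Passing tests
therefore demonstrate the correctness of the *analysis machinery* under
the assumed statistical structure, not the fidelity of any retrieval.

## Smoothing (SMN/SMT)

The operational product's empirical noise removal is proprietary and
unpublished; the stand-in is median-of-3 despiking (removes isolated
one-week spikes exactly) followed by a centred triangular moving
average, default window 5 weeks (weights 1,2,3,2,1 / 9). The kernel is
symmetric, so linear segments pass unchanged away from the edges; at
edges the kernel is truncated and renormalized. Masked values are
excluded with weight renormalization. Consequence worth knowing: in a
noise-free record the first/last two weeks of the record are the only
places where years differ after smoothing.

## Climatology and indices

Extrema are per-pixel, per-calendar-week max/min across years (the
seasonal-anomaly reading of "multi-year absolute maximum and minimum");
a whole-record envelope is available via `per_week=False`. At least 3
distinct years are required. Degenerate pixels (max = min) are masked,
never divided. VCI/TCI are computed ratio-first (`(x/span)·100`) so the
envelope endpoints land on 0 and 100 exactly in floating point; values
outside the envelope (new data against an old climatology) are clipped
to [0, 100] and counted. VHI masks where either input is masked.

## Drought bands and events

The published band edges leave exactly 40 and 60 unassigned ("40 < VHI
< 60"); the closure here is stress = [0, 40), normal = [40, 60],
favorable = (60, 100], so the three top-level bands partition [0, 100]
and percent-areas sum to exactly 100 on fully-valid weeks. Drought
classes are cumulative intervals as printed (D1-D4 = [0, 35) etc.);
disjoint views follow by subtraction. Percent-area denominators count
valid pixels only. Events are maximal runs of regional VHI strictly
below the threshold (default 40) with inclusive duration — a dip
spanning weeks 23–32 is one 10-week event. Early warning flags weeks
with a strictly monotone TCI decline over ≥ 4 steps while VHI is still
≥ 40.

## Growing season

Fixed thresholds 0.20 (onset) and 0.25 (senescence) on one cycle of
regional SMN. The published rule states thresholds but not crossing
semantics, so two conventions are ours: onset requires the series to
hold ≥ 0.20 for at least 2 consecutive steps (no single-step false
starts), and the end is the last step at/above 0.25 *after the seasonal
peak* (a pre-season blip cannot terminate the season). Raising either
threshold can only shrink the season (tested as a property). A series
that never reaches 0.20 yields a "no growing season" result, not an
error.

## Trends

OLS is the textbook least-squares line with t in fractional years, so
all slopes are per year. Mann–Kendall uses S = Σ_{i<j} sign(y_j − y_i),
tie-corrected variance [n(n−1)(2n+5) − Σ tⱼ(tⱼ−1)(2tⱼ+5)]/18, ±1
continuity correction and a two-sided normal p-value; below 8 points it
refuses rather than degrade (configurable). No prewhitening and no
seasonal variant — the variant is documented precisely because the
source analyses leave it unstated. Sen's slope is Theil–Sen (SciPy's
`theilslopes`), checked in the tests against an exhaustive all-pairs
oracle. Per-pixel maps are tested at 5% with no multiple-testing
correction by default, matching per-grid significance-map practice; a
Benjamini–Hochberg option exists behind `fdr=True`.

## Wavelet machinery

Morlet with ω₀ = 6 throughout (Fourier period ≈ 1.033 s). The CWT is
FFT-based on a zero-padded (next power of two) series, over dyadic
scales s₀·2^(j/12) with s₀ = 2Δt and max scale n·Δt/3 by default. Input
series are linearly detrended and standardized. The COI uses the
e-folding convention: trustworthy scales at a point are those below
(distance to edge)/√2; all headline statistics are restricted to in-COI
points.

Coherence smoothing is the standard toolbox operator: a Gaussian of
width s along time (applied spectrally) composed with a boxcar of 0.6
octaves (0.6/dj bins, edge-replicated) along scale. 0.6 octaves is the
empirical scale-decorrelation length of the Morlet wavelet. With
identical smoothing in numerator and denominator, Cauchy–Schwarz pins
R² to [0, 1] (numerically to within ~1e−14, asserted in the tests) and
wtc(x, x) = 1 up to rounding at low-power edge cells (≤ 1e−5).

Significance is Monte-Carlo: AR(1) surrogate pairs matched to each
input's lag-1 autocorrelation, run through the identical estimator; a
point is significant at 5% when fewer than 5% of null values reach its
observed coherence — the rank-test equivalent of thresholding at the
per-(scale,time) 95th percentile, chosen to avoid materialising the
full null cube. Surrogate counts: 300 by default, 500 in the
calibration experiments. A degenerate lag-1 estimate ≥ 1 falls back to
0.99 with a warning. Phase is the argument of the smoothed cross
spectrum; "dominant phase" summaries take the circular mean over in-COI
points with R² > 0.5, the conventional arrow-drawing threshold.

XWT cross power is |W^X·W^Y*| with phase from the unsmoothed product;
its optional Monte-Carlo test compares cross power against AR(1)
surrogate pairs the same way.

## Teleconnection maps

Per-pixel Pearson correlation between the index and a cube restricted
to growing-season calendar weeks (detected or configured), concatenated
across years; pixels with < 3 valid pairs are masked, and summary
fractions (% positive / % negative) are taken over valid nonzero-r
pixels so they sum to 100. Weekly alignment is the default; callers can
pre-aggregate to months if desired.

## Problem sizes in tests and the acceptance script

The suite runs the full chain on compact records (typically 4–12 years
on 3×3 to 12×12 grids) and the calibration experiments at the sizes
that make them meaningful: 10,000 white-noise series of n = 35 for the
Mann–Kendall type-I error, and n = 512 with 500 surrogate pairs for the
wavelet false-positive rate. These sizes were chosen as the smallest at
which the statistical checks are sharp; the full-window default
(35 years, 46×38) runs the same code paths unchanged.

## Known limitations

* The smoother is a stand-in, not the operational noise-removal chain;
  absolute index values from real data will differ from NOAA's product.
* Time smoothing of wavelet fields is spectral (periodic on the padded
  series); surrogates traverse the identical operator, so significance
  is calibrated, but amplitudes very close to the series ends are
  attenuated toward zero.
* The scale-smoothing boxcar uses an integer bin width (7 bins at
  dj = 1/12) rather than fractional end-weights.
* Missingness is i.i.d.; spatially coherent gaps (clouds, orbit gaps)
  would stress the mask bookkeeping differently.
* Monthly index alignment for correlation maps is left to the caller;
  only the weekly path is exercised by the tests.
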