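# Methods

This note documents the models behind `spinsense`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that matter. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Conventions

Rotation frequency in Hz is `RPM / 60` everywhere; the disc produces one
sensor event (acoustic click, magnetic pulse) per revolution — no
multi-lobe features. Speed schedules are piecewise-constant
`RotationProfile`s; cumulative phase (revolutions) is the time integral
of the frequency. Images are row-major with the origin top-left,
intensities in [0, 1]; the channel mask is inclusive. All randomness
flows through one explicit integer seed per call (`numpy`
`default_rng`); identical arguments and seed give bit-identical output.

## Synthetic generators (`spinsense.synth`)

The generators are phenomenological: they produce signals with the
*structure* the estimators exploit, with ground truth known by
construction. They make no attempt at physical acoustics,
magnetostatics, colour chemistry, or sedimentation dynamics.

**Magnetometer traces.** One Gaussian field bump per revolution riding
on a constant baseline. Defaults: baseline 40 µT (typical ambient
geomagnetic magnitude), pulse amplitude 25 µT (a small neodymium magnet
several centimetres from the sensor), Gaussian sigma 10 % of the
revolution period, noise SD 0.5 µT, sampling 50 Hz (the phone
magnetometer rate). The 10 % width keeps the pulse smooth and
band-limited: harmonic k of the pulse train carries a factor
`exp(-2π²σ²k²)` (σ in revolutions), so the fundamental is always the
strongest spectral line — which is what makes the FFT tachometer's
"peak bin" reading meaningful, and what a physical magnet sweeping past
a sensor produces. Samples taken at rest carry only baseline and noise.

**Audio traces.** Default timbre is a band-limited pulse train — the
first 20 cosine harmonics of the rotation frequency with a linearly
decaying (triangular) spectral envelope — emulating one pressure event
per revolution from the disc's sound hole. A real click rolls off toward
high frequency; the decaying envelope keeps the fundamental dominant in
the spectrum while preserving a sharp time-domain pulse. A
`harmonic_tone` variant (1/k-weighted sine stack) is provided for clean
unit tests. Default window: 100 ms at 48 kHz, matching the acquisition
the acoustic tachometer uses.

**Channel images.** A U-shaped metering-channel mask (two vertical arms
joined by a bottom bend, ≈ 5.6 k pixels in a 180×120 frame). The
packed-cell region fills the channel from the radially outward closed
end — the bend — upward, covering the requested percentage of channel
pixels rounded to a whole pixel; the ground truth records the exact
rendered fraction. Rendering levels: cells 0.15, plasma 0.75, background
0.9. Optional degradations: multiplicative linear illumination tilt
across the width (fractional depth `g`), dark single-pixel stray marks
at a given density per 10⁴ background pixels, and additive Gaussian
noise. Real disc photographs additionally have lens distortion, specular
reflections, colour, and non-axis-aligned channels; a green test here
establishes the analysis chain, not robustness to those effects.

**Sedimentation series.** The apparent dark fraction at time t follows
`hct + (100 − hct)·exp(−t/τ)`: the channel starts fully dark
(unseparated whole blood) and compacts toward the true hematocrit. The
default τ = 50 s makes the fraction change fast within the first minute
and settle to within 1 % of its final value around 200 s, the observed
stabilization timescale for this kind of metering structure. Real
sedimentation is not a single exponential (hindered settling, packing);
the series is a stand-in with the right qualitative shape.

**Calibration data.** `absorbance = intercept + slope·concentration +
N(0, σ)` per replicate. Defaults — slope 0.002 AU per ng/mL, intercept
0.05 AU, σ 0.01 AU, 3 replicates over {0, 25, 50, 100, 200} ng/mL —
give absorbances spanning ≈ 0.05–0.45 AU over the assay's linear
0–200 ng/mL range, a realistic colorimetric read-out scale.

## Tachometry (`spinsense.tachometry`)

**Nyquist bound.** `nyquist_limit(rate)` returns `rate/2` Hz and its RPM
equivalent: 50 Hz sampling → 25 Hz → 1500 RPM. Magnetic estimates whose
refined RPM exceeds 95 % of that bound are flagged invalid (guard band
for the observed breakdown approaching the limit). Above the bound the
spectrum folds: rotation at f ∈ (25, 50) Hz is reported at the alias
|f − 50| Hz. The magnetometer alone cannot distinguish an aliased
high speed from a true low one; the guard band catches the approach to
the limit, and the acoustic channel covers the range above it.

**Magnetic estimator.** Latest 256 samples, mean removed, rectangular
window (mirroring the simple FFT processing a phone app applies — no
taper), magnitude spectrum, peak bin excluding DC, three-point parabolic
interpolation over adjacent bin magnitudes. Resolution is one bin,
`60·rate/n_fft` ≈ 11.7 RPM. Quality floor: the peak must be ≥ 5× the
median non-DC magnitude, which deterministically rejects constant and
noise-only windows.

**Acoustic estimator.** The published description of such apps —
autocorrelate 100 ms and take the highest peak — breaks down
quantitatively when the window holds only 2–4 revolutions: the biased
autocorrelation's linear taper and the pulse truncated at the window
edge displace the raw peak by several RPM (up to ≈ 16 RPM at 1400 RPM in
our tests — far outside a ±1 RPM requirement). The implementation
therefore uses the standard robust chain:

1. **Unbiased normalized autocorrelation** (divide lag τ by N − τ),
   which removes the taper exactly; lags are searched up to 0.8 N (too
   few overlapping samples beyond) and above `rate/200 Hz` samples
   (skips the zero-lag lobe; caps detectable fundamentals at 200 Hz =
   12 000 RPM, far above any disc speed).
2. **First-major-peak picking**: the shortest lag whose local maximum is
   within 80 % of the strongest peak. This pins the fundamental rather
   than one of its period multiples (octave-error guard).
3. **Parabolic interpolation** of the chosen peak (sub-sample lag).
4. **Harmonic least-squares refinement**: golden-section minimization,
   over f within ±3 % of the peak estimate, of the residual of fitting
   an intercept plus cosine/sine pairs at harmonics of f (up to order 24
   or 0.45·rate/f, whichever is smaller). For a noiseless periodic
   signal whose harmonics are all modelled, the minimizer is the exact
   fundamental, immune to edge truncation; with noise it is the
   maximum-likelihood refinement. Step 4 can be disabled
   (`refine=False`) to obtain the plain parabolic-peak reading.

Quality floor: normalized autocorrelation peak ≥ 0.3 — silence,
constant, and noise-only windows return `valid=False` rather than
raising. With a 100 ms window the longest measurable period is 80 ms
(≈ 750 RPM); in practice the acoustic channel is reliable above
≈ 1000 RPM, complementing the magnetometer.

**Fusion.** A single valid estimate passes through unchanged. When both
are valid and inside the overlap band [1000, 1500] RPM (the two sensors'
stated best ranges), the fused value is the inverse-resolution-weighted
mean — the simplest combiner that favours the sharper estimate; outside
the band the sensor whose range covers the reading wins (magnetic below
1000, acoustic above 1500, decided on the midpoint of the two readings).

**Tracking.** `track_rpm` slides the kind-matched estimator along the
trace (audio: the 100 ms window; magnetic: 256 samples) with a
user-chosen hop, timestamping each estimate at its window end.

## Protocol simulation (`spinsense.protocol`)

Chambers hold ordered (liquid, volume) lots; transfers move a source
chamber's entire contents at the triggering instant (no flow rates are
modelled — the platform description gives burst thresholds and step
order, not hydrodynamics; event time is the segment start time).

* A **capillary valve** opens permanently the first time the speed
  reaches its burst RPM.
* A **siphon valve** primes when its source is nonempty and the disc is
  at or below `prime_rpm_max` (default 100 RPM — capillary creep over
  the crest requires near-rest), or, when `prime_volume_ul` is set,
  whenever the source volume reaches that crest volume (liquid poured
  in above the crest level self-primes the siphon hydrostatically).
  Once primed it empties the source at any speed ≥ `transfer_rpm_min`,
  then unprimes.

The volume-priming term is what lets a wash delivered at 700 RPM run
straight through the detection chamber to waste while the smaller TMB
volume delivered at 1400 RPM stays put — the behaviour the assay
depends on. The built-in disc sets the detection chamber's crest volume
to 80 µL: above the 70 µL TMB load, below the 100 µL washes and sample.
Chamber capacities default to 1.1× the initial load for inlets (so
overflow detection is meaningful), 150 µL for the detection chamber
(one wash plus margin), and unbounded waste.

Within one instant, closed capillary valves fire in ascending burst-RPM
order, then siphons; the cascade repeats until no valve can fire, so
liquid entering a chamber whose outlet is open moves on at the same
timestamp in source-before-target order. Replays are deterministic;
total volume is conserved; a transfer into a full chamber raises an
overflow error naming the chamber. Disc configurations are validated
for referential integrity and acyclicity of the valve graph.

`verify_elisa_sequence` audits an event list for the assay's invariants:
sample evacuated before any wash arrives, wash 1 before wash 2, TMB
delivered last and never flushed, and per-liquid flow conservation.

## Hematocrit imaging (`spinsense.hct`)

* **Grayscale**: BT.709 luminance (scikit-image weights), integer input
  scaled by dtype range; idempotent on grayscale float input.
* **Background correction**: stray marks are background pixels deviating
  more than 3 SD from a 3×3 median of a background-only view (the
  channel is filled with the global background median first, so border
  pixels are judged against background neighbours); marks are replaced
  by the local median. A 2nd-order polynomial surface is then fitted to
  the cleaned background by least squares and *divided* out (illumination
  tilt is multiplicative), rescaled by the surface mean so a clean flat
  image passes through unchanged, and clipped to [0, 1].
* **Profile flattening**: mean channel intensity per longitudinal
  (radial) position, smoothed by a Savitzky–Golay filter, default
  window 11, order 3 — small enough to shift a cell/plasma step edge by
  under half a window, and exact on polynomial segments up to cubic.
  The flattened profile serves QC and edge localization; the hematocrit
  fraction itself is computed on the corrected 2-D pixels (flattening a
  1-D profile loses the per-pixel counts the fraction is defined on).
* **Threshold**: Otsu's criterion (maximum between-class variance) on a
  256-bin histogram of the channel pixels. When the cell and plasma
  populations are separated by an empty intensity gap, every cut inside
  the gap maximizes the criterion; ties are broken at the midpoint of
  the maximizing plateau, which is the gap centre for a symmetric
  bimodal histogram (and makes the threshold a deterministic, scale-
  covariant function of the histogram). A constant channel raises a
  degenerate-histogram error. A manual threshold can be supplied.
* **Quantification**: hematocrit % = 100 × (channel pixels strictly
  below threshold) / (channel pixels); ties fall to plasma.
* **Stabilization**: a sample is *settled* when its change from the
  previous sample is below ε (default 1 percentage point); the series is
  declared stable at the first settled sample of the first run of ≥ k
  (default 3) consecutive settled samples, and the stable value is that
  run's mean. On an exponential series with τ = 50 s sampled every 20 s
  this declares stability at 180 s — within one sampling interval of
  the ≈ 200 s plateau the generator emulates. Requiring k consecutive
  small steps makes the detector robust to a single noisy frame;
  decreasing ε can only delay (never advance) the declared time.

## ELISA statistics (`spinsense.elisa`)

Unweighted ordinary least squares of absorbance on concentration
(replicates enter individually, equivalent to count-weighting);
residual SD uses n − 2 degrees of freedom; slope/intercept standard
errors are the usual OLS ones. The LOD is `k · SD_blank / slope` with
the conventional k = 3 (≈ 99 % one-sided confidence against blank);
k is exposed because conventions differ (3, 3.3, or inverse-prediction
variants), and the result records the formula used. Inverse prediction
clamps negative concentrations to zero with a below-blank flag.

## Known limitations

* Generators are stated worlds, not physics: no acoustic timbre model,
  no magnet field law, no capillary burst-pressure or sedimentation
  dynamics, no TMB colour chemistry.
* The protocol simulator has no partial transfers, mixing, or flow
  rates; burst/prime thresholds are configuration, not predictions from
  channel geometry.
* The imaging pipeline assumes a supplied ROI; it does not segment the
  channel from a raw disc photograph or correct lens distortion.
* The magnetometer estimator cannot flag an alias that lands inside its
  valid band; disambiguation above 1500 RPM relies on the acoustic
  channel.
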