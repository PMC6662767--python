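# Methods

This note documents the models, defaults and numerical choices behind
`vocalshift`, and what the synthetic-data validation does and does not
establish about real recordings.

## Noise stimuli

A noise condition is defined by its spectral tilt *s* in dB per octave.
The target magnitude response is 0 dB at the lower band edge and falls by
*s* per frequency doubling up to the upper band edge; outside the band the
response is held flat (a design choice — the band edges of the original
playback conditions describe where energy is concentrated, not filter
corners, so no particular roll-off is implied). The FIR impulse response
is designed by frequency sampling (`scipy.signal.firwin2`, linear phase,
default 4097 taps at 192 kHz) and convolved with white Gaussian noise.

`measure_spectral_tilt` averages the Welch PSD inside each full octave of
the analysis band and regresses band power in dB on log2 of the octave's
geometric center. For an exact power-law spectrum the octave-band means
lie on a line with the same per-octave slope, so the estimator is unbiased
by construction; round-trip error for tilts in {0, −3, −6, −12} is below
0.05 dB/octave on 10 s of noise. A spectrum whose octave bands differ by
more than ~120 dB (e.g. a pure tone) is rejected as degenerate.

## Synthetic sessions

A session is a continuous float32 waveform at 192 kHz (the acquisition
rate of the target experiments) containing `n_baseline + n_post` harmonic
calls over a Gaussian noise floor, plus cage-noise transients, plus a
ground-truth table.

**Calls** are harmonic stacks: fundamental f0 with 16 harmonics whose
amplitudes follow a per-harmonic tilt in dB per octave, shaped by
raised-cosine onset/offset ramps of 10 % of the call duration each.
The true spectral centroid of the designed line spectrum is
Σ f_k·P_k / Σ P_k, strictly increasing in the tilt, so the generator can
invert it: per call, the tilt reproducing a target centroid is found by
Brent root-finding. Durations are Gaussian (35 ± 8 ms, clipped to
15–120 ms); inter-call gaps uniform in 40–120 ms, so calls never overlap.

**Parameter drift.** Per-call true centroids follow a stationary Gaussian
AR(1) process (default ρ = 0.4, inside the 0.206–0.523 range reported for
per-parameter series in this paradigm; marginal SD 1.5 kHz) around a
condition mean: 15 kHz in baseline, raised by the injected shift
(default 3.0 kHz) in the post condition. The shift moves the *mean of the
process*, not individual calls, so bin-level statistics see realistic
variance. Fundamentals follow an independent AR(1) (2.5 ± 0.3 kHz,
clipped to 1.2–4.5 kHz, safely inside the 0.5–5 kHz validity gate).
Call RMS sits `snr_db` (default 30 dB) above the −50 dBFS noise floor
with 1.5 dB log-normal scatter.

**Cage noise** (default 10 events/min, placed only in gaps): broadband
clicks of 0.5–4 ms, which the minimum-duration gate must reject, and
low-frequency 120–350 Hz thumps of 15–40 ms, which pass the duration gate
but fail the fundamental validity gate — true negatives for both stages.

Identical `SessionSpec` (including seed) ⇒ bit-identical audio and truth.

What the generator does *not* emulate: the species' actual call types and
their diversity, overlapping calls, reverberation, speaker/microphone
responses, SPL calibration, and diurnal call-rate structure. Passing
tests therefore demonstrate that the pipeline recovers known structure
under the stated noise model, not that thresholds transfer unchanged to
real recordings (the original duration/RMS trigger constants were never
published; defaults here are expressed relative to the session noise
floor so they transfer across synthetic SNRs).

## Detection

Candidates are cut where the smoothed envelope — magnitude of the
analytic (Hilbert) signal, moving-averaged over 2 ms — exceeds
`envelope_threshold` (default 4) times the session noise floor, defined
as the median envelope; runs closer than 15 ms are merged. Validation
re-checks duration (10–200 ms), RMS (≥ 3× floor) and a refined duration:
the time the segment's own envelope spends above 10 % of its peak must
also pass the duration window. The default 90 kHz low-pass is an
anti-alias guard; at cutoffs above 45 % of the sample rate it is treated
as a pass-through (nothing in band is affected) rather than paying for a
near-identity `filtfilt`. Long sessions are processed in 4M-sample
chunks with 4096-sample overlap, each padded to an FFT-friendly length;
envelopes inherit float32 from float32 input to bound memory.

On default synthetic sessions the detector scores precision = recall = 1.0
against ground truth (the acceptance checks require ≥ 0.95).

## Features

Each validated segment is Hamming-windowed before any spectral
computation (FFT zero-padded to the next power of two). Eleven
parameters: duration, RMS, time-signal entropy, peak frequency, min/max
frequency at the outermost −25 dB crossings around the peak, bandwidth
(max − min), spectral centroid restricted to 0.5–60 kHz (0.5–40 kHz as
the narrow-range alternative), autocorrelation fundamental searched in
0.5–10 kHz, Wiener entropy and Shannon entropy; peak-to-peak amplitude is
carried as an auxiliary column. Centroid, fundamental and the entropies
are medians over snippets of 10 % of the call length hopped by 9 %.

Numerical choices worth knowing:

* *Centroid* is the standard power-weighted mean frequency ("spectral
  center of mass"); the verbal definition it implements is ambiguous in
  its source, and this reading matches the center-of-mass gloss.
* *±25 dB cutoffs* are read as −25 dB relative to the peak magnitude on
  each side (a +25 dB point cannot exist), taking the outermost crossings.
* *Pitch* takes, among autocorrelation local peaks within 10 % of the
  maximum, the smallest lag — the standard guard against octave-down
  errors for near-periodic snippets; snippets whose maximum normalized
  autocorrelation is below 0.3 are unvoiced (NaN → call invalid).
* *Wiener entropy* (geometric/arithmetic mean of the power spectrum) is
  computed on a 16-bin boxcar-smoothed spectrum: the raw periodogram of
  even perfectly white noise has flatness ≈ 0.56 because of bin-to-bin
  variance, while the smoothed version approaches 1 as expected.
* *Shannon entropy* uses the normalized power distribution (−Σ p log₂ p)
  rather than an unnormalized signal-energy convention, so it is
  amplitude-invariant and comparable across conditions — a deliberate
  deviation from the MATLAB `wentropy` default.
* Both a spectrum-based and a time-signal entropy are provided, since
  the source battery lists "entropy" computed over both.

## Binning and normalization

Bins are means over exactly `bin_size` consecutive calls (70 default; 50
for half data sets; 35 for context-stratified sets); the incomplete tail
is dropped, reproducing the published arithmetic (6348 calls → 90 bins;
5000 → 71). Binning restarts at every group/condition boundary, so bins
are condition-pure. One printed bin count (398 for one group/condition)
exceeds the floor arithmetic by one; the package reproduces the floor
value and does not force agreement. Normalization subtracts the
baseline-bin mean and divides by the maximum absolute centered baseline
value, mapping the baseline to mean 0 and max |value| 1. The Lilliefors
test (statsmodels) is exposed to verify approximate bin-level normality.

## Statistics

**AR(1) z-test** (two time series with common variance and lag-1
autocorrelation): r1 is the length-weighted pool of each series' sample
lag-1 autocorrelation after separate demeaning; the pooled-SD standard
error is inflated by √((1+r1)/(1−r1)). At r1 = 0 this is exactly the
classical pooled z-test. Null calibration at ρ = 0.4 with 90 bins per
series: rejection ≈ 0.06 at α = 0.05 where the naive z-test rejects
≈ 0.19.

**SMA** simulates Gaussian AR(1) null datasets with the estimated common
mean, variance and r1 and reports the proportion of simulated |mean
difference| ≥ observed (strict ≥, no plus-one term). Because sample r1
and variance are biased toward zero in short series — which would make
the simulated null under-dispersed — r1 gets the first-order bias
correction solved at its fixed point, (r + 1/n)/(1 − 3/n), and the
variance the matching AR(1) small-sample inflation. Null p-values are
near-uniform from ~100 bins per series; below a few dozen bins the test
remains mildly anti-conservative (plug-in estimation noise), a known
property of this class of Monte-Carlo procedure. The innovation model is
Gaussian — the choice is a documented assumption, not an estimate.

**Mixed model**: y = β₀ + β₁·condition + b_group + ε with b_group a
random intercept and ε sharing variance σ² and AR(1) correlation within
each group×condition series. Fitted by REML (per-group Cholesky;
Nelder-Mead over (atanh ρ, log σ², log τ²) from two starts). The
implementation matches `nlme::lme(correlation = corAR1())` to four
decimals on a fixture, and that cross-check is part of the test suite.
Denominator degrees of freedom use the Satterthwaite approximation
(numeric gradient/Hessian) rather than Kenward-Roger: the KR covariance
adjustment is heavy to re-derive and the package validates the test by
coverage simulation (95 % CIs cover a true 3-unit effect at nominal rate)
rather than by df equality.

**Slopes**: per-parameter OLS slope of bin value on bin index; condition
differences across groups enter a randomized complete block ANOVA
(groups = random blocks, parameters = fixed factor, block×treatment
interaction as error). Per-parameter CIs are at level 1 − α/k
(99.55 % for k = 11 at α = 0.05, matching the reported rounding).

**Day-wise matrix**: Wilcoxon rank-sum (normal approximation with tie
correction) of each day's bins against every day of the other and of the
same condition, counting significant cells at the configured α.

All stochastic procedures take explicit seeds and are reproducible.

## Classifier

Bagged decision trees (100 bootstrap trees) on the 11-parameter bin
means, scored per class by stratified 5-fold cross-validation so every
bin is predicted exactly once by a model that never saw it (out-of-fold
rather than out-of-bag, for deterministic fold assignment under a seed).
The classifier treats bins as independent although consecutive bins are
autocorrelated; that independence violation is preserved deliberately,
mirroring how such classifiers are applied to summarized call data.
Context stratification uses 35-call bins and falls back from the AR(1)
z-test to SMA when either side has fewer than 30 bins.

## Validation sizes

The test suite and the acceptance script validate at sizes chosen to
exercise each claim while staying desk-scale: the full-pipeline recovery
run uses 2000 calls per condition (28 bins of 70 calls per condition);
the zero-shift negative control runs ten 600+600-call sessions through
the complete audio pipeline; AR(1) z-test calibration uses 2000 null
replicates of 90-bin series; SMA uniformity uses 500 replicates of
200-bin series at 2000 iterations (200 bins is inside the 81–505-bin
range of the real per-condition series; see the SMA note above for why
very short series are not the calibration regime).

## Known limitations

* Absolute SPL is out of scope; amplitudes are linear full-scale units.
* The detector's thresholds were tuned on synthetic sessions only; the
  original trigger constants are unpublished.
* Kenward-Roger df is approximated by Satterthwaite (see above).
* The SMA empirical p is mildly liberal below a few dozen bins.
* The generator's AR(1) drift is specified at the per-call level;
  70-call bin means of a ρ = 0.4 call process are themselves only weakly
  autocorrelated. Bin-level serial correlation comparable to real data
  would require much longer call-level correlation; the statistical
  battery is therefore additionally calibrated directly on simulated
  bin-level AR(1) series.
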