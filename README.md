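# vocalshift

Analysis pipeline for measuring **persistent vocal plasticity**: do animals
shift spectral parameters of their vocalizations after exposure to tilted
background noise, and does the shift outlast the noise?

The package targets the experimental design used with Egyptian fruit bats
(*Rousettus aegyptiacus*): groups of bats are recorded continuously at
192 kHz, exposed for two weeks to broadband noise whose spectrum falls off
by a fixed number of dB per octave, and their social communication calls are
compared between the silent baseline and the silent week *after* noise
cessation. Because no recordings are publicly deposited for this paradigm,
the package ships a fully ground-truthed **synthetic session generator**
that emulates the statistical structure of such data — harmonic calls with
AR(1)-drifting parameters, an injected condition shift, cage-noise
transients — so every stage of the pipeline can be validated against known
truth.

## What it does

1. **Stimulus synthesis** — FIR impulse responses with a prescribed spectral
   tilt (−3/−6/−12 dB per octave), convolved with white noise; a
   `measure_spectral_tilt` oracle closes the loop.
2. **Call detection** — two-pass: smoothed analytic-signal envelope above a
   noise-floor-relative threshold cuts candidates; duration, RMS and a
   refined envelope-duration gate validate them.
3. **Acoustic features** — 11 parameters per call: duration, RMS, entropy,
   peak/minimum/maximum frequency (±25 dB cutoffs around the peak),
   bandwidth, spectral centroid `Σ f·P(f) / Σ P(f)`, fundamental
   (autocorrelation pitch), Wiener entropy (spectral flatness) and Shannon
   entropy — centroid, fundamental and entropies as medians over 10 %-length
   call snippets slid by 9 %. Validity gate: centroid < 80 kHz and
   fundamental in 0.5–5 kHz.
4. **Binning** — means over every 70 consecutive calls (50/35 for smaller
   sets) form the observation bins on which all inference runs; baseline
   normalization and sliding-window trajectories included.
5. **Statistics** — z-test for two AR(1) time series with corrected standard
   error `s·√(1/n₁+1/n₂)·√((1+r₁)/(1−r₁))`; Simulation Modelling Analysis
   (SMA) for short series; REML mixed model with group random intercepts and
   AR(1) residuals (Satterthwaite df); per-parameter slope comparison via
   randomized complete block ANOVA; Bonferroni α = 0.05/11 = 0.0045;
   day-wise Wilcoxon rank-sum matrices.
6. **Classification** — bagged decision trees assign observation bins to
   baseline vs post-noise, scored per class by stratified cross-validation.

## Worked example

`examples/05_full_pipeline.py` generates a 400+400-call session with a
3 kHz injected centroid shift and runs everything:

```
detection: precision 1.000 recall 1.000
centroid shift +3.200 kHz (SE 0.184), z 17.42, p 5.68e-68; alpha 0.0045

per-parameter shifts (post - baseline):
      parameter       shift            p  significant
     duration_s    0.000356 4.007001e-01        False
            rms    0.000229 8.654304e-01        False
   entropy_time    0.020437 4.240867e-01        False
   peak_freq_hz 3413.595779 3.320472e-08         True
    min_freq_hz   21.702516 3.635903e-01        False
    max_freq_hz  322.646104 4.009534e-01        False
   bandwidth_hz  300.943588 4.035295e-01        False
    centroid_hz 3200.353149 5.678575e-68         True
 fundamental_hz   18.633807 4.386314e-01        False
 wiener_entropy    0.001926 1.334598e-02        False
shannon_entropy    0.155201 4.844572e-13         True

classifier per-class accuracy: {'baseline': 1.0, 'post': 1.0}
```

The detector finds every injected call, the recovered centroid shift
(+3.20 kHz) brackets the injected 3.0 kHz within its corrected standard
error, the parameters that were never shifted stay non-significant at the
Bonferroni level, and the bin classifier separates the conditions. The
spectrally coupled parameters (peak frequency, Shannon entropy) shift
along with the centroid, as they must for a harmonic call whose energy
moved upward.

The other examples each exercise one capability: `01` stimulus tilts,
`02` session generation + detection scoring, `03` single-call features,
`04` AR(1) z-test vs SMA vs naive z-test on simulated bins.

A thin CLI mirrors the stages:

```bash
vocalshift synth --config session.yaml --out session.wav --truth truth.csv --seed 17
vocalshift features session.wav --out features.csv
vocalshift bin features.csv --bin-size 70 --out bins.csv
vocalshift stats bins.csv --out results.json
vocalshift run config.yaml --outdir out/
```

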