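"""Synthetic stimuli and fully ground-truthed recording sessions.

Two things are generated here:

1. *Noise stimuli* — broadband noise with a prescribed spectral tilt
   (a level decrease of s dB per octave), built by designing a finite
   impulse response with the target tilt and convolving it with white
   noise.  Tilts of -3, -6 and -12 dB/octave span the shallow-to-steep
   range used for acoustic-perturbation playback.

2. *Recording sessions* — continuous audio containing a train of brief
   harmonic social calls over a noise floor, together with a ground-truth
   table of every call's interval and true acoustic parameters.  Per-call
   parameters (spectral centroid, fundamental) evolve as lag-1
   autocorrelated (AR(1)) processes, and a post-condition elevates the
   *mean* of the centroid process by a configurable shift, so that
   bin-level statistics downstream see realistic serial correlation and
   variance rather than a deterministic offset.  Cage-noise transients
   (sub-5-ms broadband clicks and low-frequency thumps) are inserted so
   the detector's duration gates and the feature-validity filter have
   true negatives to reject.

Calls are harmonic stacks: a fundamental f0 with n harmonics whose
amplitudes follow a per-octave tilt, shaped by raised-cosine onset/offset
ramps of 10% of the call duration each.  The true spectral centroid of
such a stack has the closed form sum(f_k * P_k) / sum(P_k) over the
designed line spectrum, which makes the generator invertible: the tilt
required to hit a target centroid is found by root-finding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import brentq

from .audio import AudioRecording

logger = logging.getLogger(__name__)

#: power-law exponent per dB/octave of (power) spectral tilt
_DB_PER_OCT_TO_EXP = 1.0 / (10.0 * np.log10(2.0))

DEFAULT_CONTEXTS = ("perch_aggression", "not_classifiable")
DEFAULT_CONTEXT_PROBS = (0.82, 0.18)


# ---------------------------------------------------------------------------
# specs


@dataclass
class NoiseStimulusSpec:
    """Design parameters for one tilted-noise condition.

    slope_db_per_octave <= 0 corresponds to the playback conditions
    (energy concentrated toward low frequencies); 0 is white within band.
    """

    slope_db_per_octave: float = -6.0
    band_low_hz: float = 1000.0
    band_high_hz: float = 48000.0
    level_db: float = -20.0           # RMS re full scale
    ir_length: int = 4097
    sample_rate_hz: float = 192000.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz <= self.sample_rate_hz / 2):
            raise ValueError("require 0 < band_low < band_high <= Nyquist")
        if self.ir_length < 64:
            raise ValueError("ir_length must be >= 64")


@dataclass
class CallSpec:
    """One synthetic social call: a tilted harmonic stack."""

    onset_s: float = 0.0
    duration_s: float = 0.035
    fundamental_hz: float = 2500.0
    n_harmonics: int = 16
    harmonic_tilt_db_per_octave: float = 0.0
    amplitude: float = 0.1            # linear RMS of the un-ramped stack
    context_label: str = "not_classifiable"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


@dataclass
class SessionSpec:
    """Conditions for one synthetic recording session.

    The centroid of successive calls follows an AR(1) process with
    coefficient ``ar1_rho`` and marginal standard deviation
    ``drift_sd_khz``; the post-condition mean is elevated by
    ``centroid_shift_khz``.  ``snr_db`` is the call RMS above the
    session noise floor.
    """

    n_calls_baseline: int = 2000
    n_calls_post: int = 2000
    centroid_shift_khz: float = 3.0
    baseline_centroid_khz: float = 15.0
    ar1_rho: float = 0.4
    drift_sd_khz: float = 1.5
    fundamental_mean_khz: float = 2.5
    fundamental_sd_khz: float = 0.3
    n_harmonics: int = 16
    cage_noise_rate_per_min: float = 10.0
    snr_db: float = 30.0
    noise_floor_db: float = -50.0     # RMS re full scale
    seed: int = 0
    sample_rate_hz: float = 192000.0
    mean_call_duration_s: float = 0.035
    call_duration_sd_s: float = 0.008
    mean_gap_s: float = 0.08
    context_labels: tuple = DEFAULT_CONTEXTS
    context_probs: tuple = DEFAULT_CONTEXT_PROBS

    def __post_init__(self) -> None:
        if self.n_calls_baseline < 0 or self.n_calls_post < 0:
            raise ValueError("call counts must be >= 0")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if abs(sum(self.context_probs) - 1.0) > 1e-9:
            raise ValueError("context_probs must sum to 1")


# ---------------------------------------------------------------------------
# tilted noise


def make_tilt_impulse_response(spec: NoiseStimulusSpec) -> np.ndarray:
    """Design an FIR impulse response with a prescribed in-band spectral tilt.

    The target magnitude response is 0 dB at ``band_low_hz``, decreases
    (or increases) by ``slope_db_per_octave`` per frequency doubling up
    to ``band_high_hz``, and is held flat outside the band — a documented
    design choice; only the in-band tilt is contractual.  Design is by
    frequency sampling (``scipy.signal.firwin2``), linear phase.
    """
    nyq = spec.sample_rate_hz / 2.0
    ntaps = spec.ir_length | 1        # type-I FIR needs odd length
    # dense log-spaced grid inside the band, flat extensions outside
    f_in = np.geomspace(spec.band_low_hz, spec.band_high_hz, 256)
    gain_db = spec.slope_db_per_octave * np.log2(f_in / spec.band_low_hz)
    freqs = np.concatenate(([0.0], f_in, [nyq]))
    gains_db = np.concatenate(([gain_db[0]], gain_db, [gain_db[-1]]))
    # guard strictly increasing frequency grid for firwin2
    if spec.band_high_hz >= nyq:
        freqs = freqs[:-1]
        gains_db = gains_db[:-1]
        freqs[-1] = nyq
    gains = 10.0 ** (gains_db / 20.0)
    if not np.all(np.isfinite(gains)):
        raise ValueError("degenerate tilt design (non-finite target gains)")
    ir = signal.firwin2(ntaps, freqs, gains, fs=spec.sample_rate_hz)
    if not np.all(np.isfinite(ir)):
        raise ValueError("impulse-response design failed (non-finite taps)")
    return ir


def synthesize_noise(spec: NoiseStimulusSpec, duration_s: float,
                     seed: int) -> AudioRecording:
    """White noise convolved with the tilt impulse response, RMS-scaled.

    Reproducible: the same spec, duration and seed yield bit-identical
    sample arrays.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * spec.sample_rate_hz))
    white = rng.standard_normal(n)
    ir = make_tilt_impulse_response(spec)
    shaped = signal.fftconvolve(white, ir, mode="same")
    rms = np.sqrt(np.mean(shaped ** 2))
    target = 10.0 ** (spec.level_db / 20.0)
    shaped *= target / rms
    return AudioRecording(samples=shaped, sample_rate_hz=spec.sample_rate_hz,
                          meta={"slope_db_per_octave": spec.slope_db_per_octave})


def measure_spectral_tilt(recording: AudioRecording,
                          band: tuple[float, float],
                          nperseg: int = 8192) -> float:
    """Least-squares spectral tilt in dB per octave over octave-spaced bands.

    The Welch PSD is averaged inside each full octave [f0, 2 f0] within
    ``band``; band-mean power in dB is regressed on log2 of the octave's
    geometric center.  For a power-law spectrum the octave-band means lie
    exactly on a line of the same per-octave slope, so no correction for
    in-band curvature is needed.

    Raises ``ValueError`` if the band exceeds Nyquist, covers fewer than
    two octaves, or the spectrum is degenerate (e.g. a pure tone leaving
    octave bands essentially empty).
    """
    low, high = band
    nyq = recording.sample_rate_hz / 2.0
    if not (0 < low < high <= nyq):
        raise ValueError("band must satisfy 0 < low < high <= Nyquist")
    n_oct = int(np.floor(np.log2(high / low)))
    if n_oct < 2:
        raise ValueError("band must span at least two full octaves")
    if recording.n_samples < 2 * nperseg:
        raise ValueError("recording shorter than analysis window")
    freqs, psd = signal.welch(recording.samples, fs=recording.sample_rate_hz,
                              nperseg=nperseg)
    band_db = []
    band_log2_center = []
    for k in range(n_oct):
        f0, f1 = low * 2.0 ** k, low * 2.0 ** (k + 1)
        mask = (freqs >= f0) & (freqs < f1)
        power = float(np.mean(psd[mask]))
        band_db.append(power)
        band_log2_center.append(np.log2(np.sqrt(f0 * f1)))
    band_db = np.asarray(band_db)
    if np.any(band_db <= 0) or band_db.max() / max(band_db.min(), 1e-300) > 1e12:
        raise ValueError("degenerate spectrum: octave-band tilt undefined "
                         "(single-band energy?)")
    band_db = 10.0 * np.log10(band_db)
    slope, _ = np.polyfit(band_log2_center, band_db, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# harmonic-stack calls


def _harmonic_line_spectrum(fundamental_hz: float, n_harmonics: int,
                            tilt_db_per_octave: float,
                            nyquist_hz: float | None = None):
    """Designed line spectrum (freqs, linear amplitudes) of a call."""
    k = np.arange(1, n_harmonics + 1)
    freqs = k * fundamental_hz
    if nyquist_hz is not None:
        keep = freqs <= nyquist_hz
        if not np.all(keep):
            logger.info("dropping %d harmonics above Nyquist",
                        int((~keep).sum()))
        k, freqs = k[keep], freqs[keep]
        if len(k) == 0:
            raise ValueError("fundamental above Nyquist")
    amps = 10.0 ** (tilt_db_per_octave * np.log2(k) / 20.0)
    return freqs, amps


def true_centroid(fundamental_hz: float, n_harmonics: int,
                  tilt_db_per_octave: float,
                  nyquist_hz: float | None = None) -> float:
    """Closed-form spectral centroid of the designed harmonic line spectrum."""
    freqs, amps = _harmonic_line_spectrum(fundamental_hz, n_harmonics,
                                          tilt_db_per_octave, nyquist_hz)
    power = amps ** 2
    return float(np.sum(freqs * power) / np.sum(power))


def tilt_for_centroid(target_hz: float, fundamental_hz: float,
                      n_harmonics: int,
                      nyquist_hz: float | None = None) -> float:
    """Invert :func:`true_centroid`: tilt (dB/oct) giving a target centroid.

    The centroid is strictly increasing in the tilt, so the root is
    bracketed and unique; the target is clipped to the attainable range.
    """
    lo_tilt, hi_tilt = -60.0, 60.0
    lo = true_centroid(fundamental_hz, n_harmonics, lo_tilt, nyquist_hz)
    hi = true_centroid(fundamental_hz, n_harmonics, hi_tilt, nyquist_hz)
    target = float(np.clip(target_hz, lo * 1.001, hi * 0.999))
    return float(brentq(
        lambda t: true_centroid(fundamental_hz, n_harmonics, t, nyquist_hz)
        - target, lo_tilt, hi_tilt, xtol=1e-6))


def synthesize_call(call: CallSpec, sample_rate_hz: float,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one harmonic-stack call with raised-cosine on/off ramps.

    Harmonic phases are randomized when a generator is supplied (fixed
    zero phase otherwise); harmonics above Nyquist are dropped with a log
    notice.  The un-ramped stack is scaled to RMS ``call.amplitude``.
    """
    nyq = sample_rate_hz / 2.0
    freqs, amps = _harmonic_line_spectrum(
        call.fundamental_hz, call.n_harmonics,
        call.harmonic_tilt_db_per_octave, nyq)
    n = int(round(call.duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    phases = (rng.uniform(0, 2 * np.pi, size=len(freqs))
              if rng is not None else np.zeros(len(freqs)))
    wave = np.zeros(n)
    for f, a, ph in zip(freqs, amps, phases):
        wave += a * np.sin(2 * np.pi * f * t + ph)
    # scale to target RMS before ramping (sinusoid RMS = a/sqrt(2))
    stack_rms = np.sqrt(np.sum(amps ** 2) / 2.0)
    wave *= call.amplitude / stack_rms
    ramp_len = max(1, int(round(0.10 * n)))
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_len) / ramp_len))
    env = np.ones(n)
    env[:ramp_len] = ramp
    env[-ramp_len:] = ramp[::-1]
    return wave * env


# ---------------------------------------------------------------------------
# AR(1) parameter drift


def ar1_series(n: int, rho: float, marginal_sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean Gaussian AR(1) series of length n.

    Innovation variance is (1 - rho^2) * marginal_sd^2 so the marginal
    standard deviation equals ``marginal_sd`` from the first sample.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n == 0:
        return np.zeros(0)
    innov = rng.standard_normal(n) * marginal_sd * np.sqrt(1.0 - rho ** 2)
    innov[0] = rng.standard_normal() * marginal_sd
    # x_t = rho x_{t-1} + e_t  via an IIR filter
    return signal.lfilter([1.0], [1.0, -rho], innov)


# ---------------------------------------------------------------------------
# full sessions


def _insert(buffer: np.ndarray, start_idx: int, snippet: np.ndarray) -> None:
    end = min(len(buffer), start_idx + len(snippet))
    if end > start_idx >= 0:
        buffer[start_idx:end] += snippet[: end - start_idx]


def generate_session(spec: SessionSpec) -> tuple[AudioRecording, pd.DataFrame]:
    """Generate a continuous session and its ground-truth call table.

    Returns the audio (float32) and a DataFrame with one row per call:
    onset_s, offset_s, condition ('baseline'/'post'), context_label,
    true_centroid_khz, true_fundamental_khz, true_rms, amplitude,
    duration_s, tilt_db_per_octave.  Same seed, same spec: bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate_hz
    nyq = fs / 2.0
    n_total = spec.n_calls_baseline + spec.n_calls_post

    # -- call timeline: jittered gaps, non-overlapping by construction
    durations = np.clip(
        rng.normal(spec.mean_call_duration_s, spec.call_duration_sd_s, n_total),
        0.015, 0.120)
    gaps = rng.uniform(0.5 * spec.mean_gap_s, 1.5 * spec.mean_gap_s, n_total)
    onsets = np.empty(n_total)
    t = 1.0                           # lead-in second
    for i in range(n_total):
        onsets[i] = t
        t += durations[i] + gaps[i]
    session_len_s = t + 1.0
    n_samples = int(round(session_len_s * fs))

    # -- per-call true parameters (AR(1) drift around condition means)
    condition = np.array(["baseline"] * spec.n_calls_baseline
                         + ["post"] * spec.n_calls_post)
    centroid_mean = np.where(condition == "post",
                             spec.baseline_centroid_khz + spec.centroid_shift_khz,
                             spec.baseline_centroid_khz)
    centroid_khz = centroid_mean + ar1_series(n_total, spec.ar1_rho,
                                              spec.drift_sd_khz, rng)
    f0_khz = np.clip(
        spec.fundamental_mean_khz
        + ar1_series(n_total, spec.ar1_rho, spec.fundamental_sd_khz, rng),
        1.2, 4.5)
    call_rms = 10.0 ** ((spec.noise_floor_db + spec.snr_db) / 20.0)
    amplitudes = call_rms * 10.0 ** (rng.normal(0.0, 1.5, n_total) / 20.0)
    contexts = rng.choice(spec.context_labels, size=max(n_total, 1),
                          p=spec.context_probs)[:n_total]

    # -- render audio (float32 throughout: a long 192-kHz session is large)
    audio = np.zeros(n_samples, dtype=np.float32)
    tilts = np.empty(n_total)
    for i in range(n_total):
        tilts[i] = tilt_for_centroid(centroid_khz[i] * 1000.0,
                                     f0_khz[i] * 1000.0,
                                     spec.n_harmonics, nyq)
        call = CallSpec(onset_s=onsets[i], duration_s=durations[i],
                        fundamental_hz=f0_khz[i] * 1000.0,
                        n_harmonics=spec.n_harmonics,
                        harmonic_tilt_db_per_octave=tilts[i],
                        amplitude=amplitudes[i],
                        context_label=str(contexts[i]))
        wave = synthesize_call(call, fs, rng)
        _insert(audio, int(round(onsets[i] * fs)), wave)
        # keep the realized centroid as truth (clipping may move the target)
        centroid_khz[i] = true_centroid(f0_khz[i] * 1000.0, spec.n_harmonics,
                                        tilts[i], nyq) / 1000.0

    # -- cage-noise transients in the gaps between calls
    n_noise = rng.poisson(spec.cage_noise_rate_per_min * session_len_s / 60.0)
    intervals = np.column_stack([onsets - 0.02, onsets + durations + 0.02]) \
        if n_total else np.zeros((0, 2))
    placed = 0
    attempts = 0
    while placed < n_noise and attempts < 20 * max(n_noise, 1):
        attempts += 1
        t0 = rng.uniform(0.2, session_len_s - 0.2)
        if n_total and np.any((t0 > intervals[:, 0] - 0.05)
                              & (t0 < intervals[:, 1] + 0.05)):
            continue
        if rng.random() < 0.5:        # broadband click, < 5 ms
            dur = rng.uniform(0.0005, 0.004)
            m = max(8, int(round(dur * fs)))
            burst = rng.standard_normal(m) * call_rms * 3.0
            burst *= np.hanning(m)
        else:                         # low-frequency thump
            dur = rng.uniform(0.015, 0.040)
            m = int(round(dur * fs))
            tt = np.arange(m) / fs
            f_thump = rng.uniform(120.0, 350.0)
            burst = np.sin(2 * np.pi * f_thump * tt) * call_rms * 2.0
            burst *= np.hanning(m)
        _insert(audio, int(round(t0 * fs)), burst)
        placed += 1

    # -- session noise floor
    floor = 10.0 ** (spec.noise_floor_db / 20.0)
    # chunked to keep peak memory down on long sessions
    chunk = 1 << 22
    for i0 in range(0, n_samples, chunk):
        i1 = min(n_samples, i0 + chunk)
        audio[i0:i1] += (rng.standard_normal(i1 - i0) * floor
                         ).astype(np.float32)

    truth = pd.DataFrame({
        "onset_s": onsets,
        "offset_s": onsets + durations,
        "condition": condition,
        "context_label": contexts,
        "true_centroid_khz": centroid_khz,
        "true_fundamental_khz": f0_khz,
        "amplitude": amplitudes,
        "duration_s": durations,
        "tilt_db_per_octave": tilts,
    })
    rec = AudioRecording(samples=audio, sample_rate_hz=fs,
                         meta={"seed": spec.seed})
    return rec, truth
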