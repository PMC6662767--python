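"""Two-pass call detection: envelope segmentation, then duration/RMS gating.

The first pass low-pass filters the recording, computes a smoothed
amplitude envelope (magnitude of the analytic signal, moving-average
smoothed) and cuts candidate segments wherever the envelope exceeds a
threshold expressed relative to the session noise floor (the median
envelope).  The second pass re-checks each candidate: its duration must
fall in a configured window, its RMS must clear a floor-relative
threshold, and a refined duration — the time the segment's envelope
spends above 10% of its own peak — must pass the duration gate a second
time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft, ndimage, signal

from .audio import AudioRecording

# chunk size for streaming envelope computation on long sessions
_CHUNK = 1 << 22
_OVERLAP = 1 << 12


@dataclass
class DetectionParams:
    """Segmentation and gating thresholds.

    ``envelope_threshold`` and ``rms_threshold`` are linear factors
    relative to the session noise floor (median envelope), so defaults
    transfer across recordings with different absolute levels.
    """

    lowpass_cutoff_hz: float = 90000.0
    envelope_smooth_ms: float = 2.0
    envelope_threshold: float = 4.0
    min_duration_ms: float = 10.0
    max_duration_ms: float = 200.0
    rms_threshold: float = 3.0
    merge_gap_ms: float = 15.0
    refine_frac: float = 0.10         # envelope fraction for refined duration

    def __post_init__(self) -> None:
        if not self.min_duration_ms < self.max_duration_ms:
            raise ValueError("min_duration_ms must be < max_duration_ms")
        if self.envelope_threshold <= 0 or self.rms_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CallSegment:
    """A detected call interval with its (detrended) waveform."""

    start_s: float
    end_s: float
    waveform: np.ndarray
    peak_envelope: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.waveform.astype(np.float64) ** 2)))


def _smooth(env: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return env
    # streaming moving average: O(n), no FFT workspace, dtype-preserving
    return ndimage.uniform_filter1d(env, size=win, mode="nearest")


def compute_envelope(waveform: np.ndarray, params: DetectionParams,
                     sample_rate_hz: float) -> np.ndarray:
    """Smoothed amplitude envelope (|analytic signal|, moving average).

    Processed in overlapping chunks so multi-minute 192-kHz sessions do
    not materialize a full complex spectrum at once; a float32 input
    yields a float32 envelope to halve the footprint.  Same length as
    the input, non-negative, and linear in the input amplitude.
    """
    if len(waveform) == 0:
        raise ValueError("empty waveform")
    x = np.asarray(waveform)
    out_dtype = np.float32 if x.dtype == np.float32 else np.float64
    x = (x - x.mean(dtype=np.float64)).astype(out_dtype, copy=False)
    win = max(1, int(round(params.envelope_smooth_ms * 1e-3 * sample_rate_hz)))
    n = len(x)

    def _analytic_abs(seg: np.ndarray) -> np.ndarray:
        # zero-pad to an FFT-friendly length; the pad only perturbs the
        # last few samples, which chunk overlaps (or the signal edge) absorb
        m = len(seg)
        nfft = fft.next_fast_len(m)
        return np.abs(signal.hilbert(seg.astype(np.float64), N=nfft)[:m])

    if n <= _CHUNK:
        return _smooth(_analytic_abs(x).astype(out_dtype), win)
    env = np.empty(n, dtype=out_dtype)
    for i0 in range(0, n, _CHUNK):
        lo = max(0, i0 - _OVERLAP)
        hi = min(n, i0 + _CHUNK + _OVERLAP)
        chunk_env = _analytic_abs(x[lo:hi])
        env[i0:min(n, i0 + _CHUNK)] = chunk_env[i0 - lo:i0 - lo + _CHUNK]
    return _smooth(env, win)


def _lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    # the default 90-kHz cutoff is an anti-alias guard; at 192 kHz it
    # removes only the top sliver of the band, so near-Nyquist cutoffs
    # are treated as pass-through rather than paying for filtfilt copies
    if cutoff_hz >= 0.45 * fs:
        return x
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x).astype(x.dtype, copy=False)


def noise_floor(envelope: np.ndarray) -> float:
    """Session noise floor: the median of the smoothed envelope."""
    return float(np.median(envelope))


def _segment(recording: AudioRecording,
             params: DetectionParams) -> tuple[list[CallSegment], float]:
    """Envelope segmentation; returns (segments, session noise floor)."""
    fs = recording.sample_rate_hz
    win = max(1, int(round(params.envelope_smooth_ms * 1e-3 * fs)))
    if recording.n_samples < win or recording.n_samples == 0:
        return [], 0.0
    x = np.asarray(recording.samples)
    dtype = np.float32 if x.dtype == np.float32 else np.float64
    x = (x - x.mean(dtype=np.float64)).astype(dtype, copy=False)
    x = _lowpass(x, params.lowpass_cutoff_hz, fs)
    env = compute_envelope(x, params, fs)
    floor = noise_floor(env)
    above = env > params.envelope_threshold * floor
    if not np.any(above):
        return [], floor
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    # merge runs separated by less than merge_gap_ms
    gap = int(round(params.merge_gap_ms * 1e-3 * fs))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    segments = []
    for s, e in merged:
        seg = CallSegment(start_s=s / fs, end_s=e / fs,
                          waveform=x[s:e],
                          peak_envelope=float(env[s:e].max()))
        segments.append(seg)
    return segments, floor


def detect_candidates(recording: AudioRecording,
                      params: DetectionParams) -> list[CallSegment]:
    """First-pass segmentation: envelope threshold crossings, gap-merged.

    Returns time-ordered, non-overlapping segments; a recording shorter
    than one envelope smoothing window yields an empty list.
    """
    return _segment(recording, params)[0]


def refined_duration_s(segment: CallSegment, params: DetectionParams,
                       sample_rate_hz: float) -> float:
    """Time the segment envelope spends above ``refine_frac`` of its peak."""
    env = compute_envelope(segment.waveform, params, sample_rate_hz)
    peak = env.max()
    if peak <= 0:
        return 0.0
    return float(np.sum(env > params.refine_frac * peak) / sample_rate_hz)


def validate_call(segment: CallSegment, params: DetectionParams,
                  sample_rate_hz: float, floor: float = 0.0) -> bool:
    """Second-pass gate: duration window, RMS floor, refined duration.

    ``floor`` is the session noise floor (from :func:`noise_floor`);
    the RMS threshold is ``params.rms_threshold`` times it.
    """
    if len(segment.waveform) == 0:
        return False
    dur_ms = segment.duration_s * 1e3
    if not params.min_duration_ms <= dur_ms <= params.max_duration_ms:
        return False
    if segment.rms < params.rms_threshold * floor:
        return False
    ref_ms = refined_duration_s(segment, params, sample_rate_hz) * 1e3
    return params.min_duration_ms <= ref_ms <= params.max_duration_ms


def extract_calls(recording: AudioRecording,
                  params: DetectionParams | None = None) -> list[CallSegment]:
    """Full two-pass detection: candidates, then duration/RMS validation."""
    if params is None:
        params = DetectionParams()
    if recording.n_samples == 0:
        return []
    candidates, floor = _segment(recording, params)
    fs = recording.sample_rate_hz
    return [seg for seg in candidates
            if validate_call(seg, params, fs, floor)]
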