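"""Per-call acoustic parameters and the call-validity filter.

Eleven parameters are computed for every validated call: duration, RMS,
entropy (time signal), peak frequency, minimum and maximum frequencies,
frequency bandwidth, spectral centroid, fundamental, Wiener entropy
(spectral flatness) and Shannon entropy (spectrum); peak-to-peak
amplitude is carried as a twelfth, auxiliary measure.

Centroid, fundamental and the two entropies are computed as the median
over call snippets of 10% of the call length, advanced by a sliding
window of 9% of the call length.  Minimum/maximum frequencies are the
outermost points where the call's magnitude spectrum crosses 25 dB below
its peak; their difference is the bandwidth.  A call is *valid* when its
centroid lies below 80 kHz and its fundamental between 0.5 and 5 kHz —
a gate that rejects residual cage noise.

Segments are Hamming-windowed before any spectral computation.  Features
that cannot be evaluated (zero spectrum, aperiodic snippet) come back as
NaN and force ``is_valid = False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import CallSegment

logger = logging.getLogger(__name__)

#: the 11 acoustic parameters used in binning, statistics and classification
FEATURE_COLUMNS = [
    "duration_s", "rms", "entropy_time", "peak_freq_hz", "min_freq_hz",
    "max_freq_hz", "bandwidth_hz", "centroid_hz", "fundamental_hz",
    "wiener_entropy", "shannon_entropy",
]

#: auxiliary measures carried alongside the 11 parameters
EXTRA_COLUMNS = ["peak_to_peak", "entropy_spectrum"]


@dataclass
class FeatureParams:
    """Analysis ranges and snippet geometry.

    ``centroid_range_hz`` defaults to 0.5–60 kHz (the wide-range setup);
    0.5–40 kHz is the narrow-range alternative.  ``bandwidth_cutoff_db``
    is the drop below the spectral peak that defines the min/max
    frequency crossings.
    """

    centroid_range_hz: tuple[float, float] = (500.0, 60000.0)
    fundamental_search_hz: tuple[float, float] = (500.0, 10000.0)
    snippet_frac: float = 0.10
    hop_frac: float = 0.09
    bandwidth_cutoff_db: float = 25.0
    valid_centroid_max_hz: float = 80000.0
    valid_fundamental_hz: tuple[float, float] = (500.0, 5000.0)
    fft_size: int | None = None       # None: next power of two >= length
    voicing_floor: float = 0.3        # min normalized autocorr for a pitch
    flatness_smooth_bins: int = 16

    def __post_init__(self) -> None:
        if not 0 < self.hop_frac <= self.snippet_frac < 1:
            raise ValueError("require 0 < hop_frac <= snippet_frac < 1")
        for rng in (self.centroid_range_hz, self.fundamental_search_hz,
                    self.valid_fundamental_hz):
            if not rng[0] < rng[1]:
                raise ValueError("frequency ranges must be ordered")


@dataclass
class CallFeatures:
    """The per-call parameter vector plus the validity flag."""

    duration_s: float
    rms: float
    peak_to_peak: float
    entropy_time: float
    entropy_spectrum: float
    peak_freq_hz: float
    min_freq_hz: float
    max_freq_hz: float
    bandwidth_hz: float
    centroid_hz: float
    fundamental_hz: float
    wiener_entropy: float
    shannon_entropy: float
    is_valid: bool
    start_s: float = np.nan
    end_s: float = np.nan

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                FEATURE_COLUMNS + EXTRA_COLUMNS + ["is_valid", "start_s", "end_s"]}


# ---------------------------------------------------------------------------
# spectral primitives


def magnitude_spectrum(segment: np.ndarray, sample_rate_hz: float,
                       fft_size: int | None = None):
    """One-sided magnitude spectrum of a Hamming-windowed segment.

    Returns (freqs, magnitudes).  ``fft_size`` defaults to the next
    power of two at or above the segment length (zero-padded).
    """
    x = np.asarray(segment, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("empty segment")
    if fft_size is None:
        fft_size = 1 << int(np.ceil(np.log2(max(len(x), 2))))
    windowed = x * np.hamming(len(x))
    mags = np.abs(np.fft.rfft(windowed, n=fft_size))
    freqs = np.fft.rfftfreq(fft_size, d=1.0 / sample_rate_hz)
    return freqs, mags


def peak_min_max_bandwidth(freqs: np.ndarray, mags: np.ndarray,
                           cutoff_db: float = 25.0):
    """Peak frequency and the outermost -cutoff_db crossings around it.

    Returns (peak_hz, fmin_hz, fmax_hz, bandwidth_hz); all NaN for a
    flat zero spectrum.  The DC bin is excluded from the peak search.
    """
    mags = np.asarray(mags, dtype=np.float64)
    if len(mags) < 2 or not np.any(mags[1:] > 0):
        return (np.nan,) * 4
    ipeak = 1 + int(np.argmax(mags[1:]))
    peak_mag = mags[ipeak]
    thresh = peak_mag * 10.0 ** (-cutoff_db / 20.0)
    above = np.flatnonzero(mags >= thresh)
    fmin = float(freqs[above[0]])
    fmax = float(freqs[above[-1]])
    return float(freqs[ipeak]), fmin, fmax, fmax - fmin


def spectral_centroid(freqs: np.ndarray, mags: np.ndarray,
                      centroid_range: tuple[float, float]) -> float:
    """Power-weighted mean frequency over a set range (center of mass)."""
    power = np.asarray(mags, dtype=np.float64) ** 2
    mask = (freqs >= centroid_range[0]) & (freqs <= centroid_range[1])
    total = float(np.sum(power[mask]))
    if total <= 0:
        return np.nan
    return float(np.sum(freqs[mask] * power[mask]) / total)


def fundamental_autocorr(snippet: np.ndarray, sample_rate_hz: float,
                         search_hz: tuple[float, float] = (500.0, 10000.0),
                         voicing_floor: float = 0.3) -> float:
    """Pitch from the maximum of the normalized autocorrelation.

    The candidate lag range corresponds to ``search_hz``.  For a
    periodic snippet every integer multiple of the true period ties near
    the autocorrelation maximum, so among local peaks within 10% of the
    maximum the *smallest* lag wins — the standard guard against
    subharmonic (octave-down) errors.  Returns NaN when the snippet is
    aperiodic (normalized autocorrelation below ``voicing_floor``
    everywhere in range).
    """
    x = np.asarray(snippet, dtype=np.float64)
    x = x - x.mean()
    n = len(x)
    lag_min = max(1, int(np.floor(sample_rate_hz / search_hz[1])))
    lag_max = min(n - 1, int(np.ceil(sample_rate_hz / search_hz[0])))
    if lag_max <= lag_min:
        return np.nan
    full = np.correlate(x, x, mode="full")[n - 1:]
    energy = full[0]
    if energy <= 0:
        return np.nan
    # normalized by the overlapping-window energies at each lag
    cumsq = np.concatenate([[0.0], np.cumsum(x * x)])
    lags = np.arange(lag_min, lag_max + 1)
    e_head = cumsq[n - lags] - cumsq[0]
    e_tail = cumsq[n] - cumsq[lags]
    denom = np.sqrt(e_head * e_tail)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, full[lag_min:lag_max + 1] / denom, 0.0)
    best = int(np.argmax(r))
    if r[best] < voicing_floor:
        return np.nan
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(r)
    near_max = peaks[r[peaks] >= 0.9 * r[best]] if len(peaks) else []
    if len(near_max):
        best = int(near_max[0])
    return float(sample_rate_hz / lags[best])


def wiener_entropy(mags: np.ndarray, smooth_bins: int = 16) -> float:
    """Spectral flatness: geometric / arithmetic mean of the power spectrum.

    The raw periodogram of even a perfectly flat noise source has high
    bin-to-bin variance that biases its geometric mean low, so the power
    spectrum is first smoothed with a short boxcar across frequency bins;
    the result lies in [0, 1] (1 for white noise, near 0 for a tone) and
    is invariant to amplitude scaling.
    """
    power = np.asarray(mags, dtype=np.float64) ** 2
    power = power[1:]                 # drop DC
    if len(power) == 0 or not np.any(power > 0):
        return np.nan
    m = max(1, min(smooth_bins, len(power) // 4))
    if m > 1:
        kernel = np.ones(m) / m
        power = np.convolve(power, kernel, mode="valid")
    power = np.maximum(power, 1e-300)
    geo = np.exp(np.mean(np.log(power)))
    return float(geo / np.mean(power))


def shannon_entropy(values: np.ndarray) -> float:
    """Entropy (bits) of the distribution obtained by normalizing ``values``.

    Non-negative inputs are normalized to sum to one; zero bins
    contribute nothing.  All-zero input is undefined (NaN).
    """
    v = np.asarray(values, dtype=np.float64)
    total = v.sum()
    if total <= 0 or len(v) == 0:
        return np.nan
    p = v / total
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# snippet machinery


def snippet_windows(n: int, snippet_frac: float, hop_frac: float):
    """Start indices and window length for the snippet grid over n samples."""
    w = max(1, int(round(snippet_frac * n)))
    h = max(1, int(round(hop_frac * n)))
    if n < w:
        return np.array([0]), n
    count = (n - w) // h + 1
    return np.arange(count) * h, w


def snippet_median(segment: np.ndarray, per_snippet_fn,
                   snippet_frac: float = 0.10,
                   hop_frac: float = 0.09) -> float:
    """Median of ``per_snippet_fn`` over the sliding snippet grid.

    Windows are 10% of the call length by default, advanced by 9% of the
    call length; a segment shorter than one snippet falls back to a
    whole-call evaluation (with a log notice).  NaN snippet values are
    excluded from the median; all-NaN gives NaN.
    """
    x = np.asarray(segment)
    n = len(x)
    starts, w = snippet_windows(n, snippet_frac, hop_frac)
    if n < max(1, int(round(snippet_frac * n))):
        logger.info("segment shorter than one snippet; whole-call fallback")
        return per_snippet_fn(x)
    vals = np.array([per_snippet_fn(x[s:s + w]) for s in starts], dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return np.nan
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# per-call composition


def compute_features(segment: CallSegment, sample_rate_hz: float,
                     params: FeatureParams | None = None) -> CallFeatures:
    """All parameters for one validated call segment, plus the validity flag.

    ``is_valid`` requires centroid < ``valid_centroid_max_hz`` and
    fundamental inside ``valid_fundamental_hz``; an undefined centroid or
    fundamental makes the call invalid.
    """
    if params is None:
        params = FeatureParams()
    x = np.asarray(segment.waveform, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("empty segment")

    dur = segment.duration_s
    rms = float(np.sqrt(np.mean(x ** 2)))
    ptp = float(x.max() - x.min())

    freqs_call, mags_call = magnitude_spectrum(x, sample_rate_hz,
                                               params.fft_size)
    peak, fmin, fmax, bw = peak_min_max_bandwidth(
        freqs_call, mags_call, params.bandwidth_cutoff_db)
    entropy_spec = shannon_entropy(mags_call[1:] ** 2)
    entropy_time = shannon_entropy(x ** 2)

    def _centroid(snip):
        f, m = magnitude_spectrum(snip, sample_rate_hz, params.fft_size)
        return spectral_centroid(f, m, params.centroid_range_hz)

    def _fundamental(snip):
        return fundamental_autocorr(snip, sample_rate_hz,
                                    params.fundamental_search_hz,
                                    params.voicing_floor)

    def _flatness(snip):
        _, m = magnitude_spectrum(snip, sample_rate_hz, params.fft_size)
        return wiener_entropy(m, params.flatness_smooth_bins)

    def _shannon(snip):
        _, m = magnitude_spectrum(snip, sample_rate_hz, params.fft_size)
        return shannon_entropy(m[1:] ** 2)

    centroid = snippet_median(x, _centroid, params.snippet_frac,
                              params.hop_frac)
    fundamental = snippet_median(x, _fundamental, params.snippet_frac,
                                 params.hop_frac)
    flatness = snippet_median(x, _flatness, params.snippet_frac,
                              params.hop_frac)
    shannon = snippet_median(x, _shannon, params.snippet_frac,
                             params.hop_frac)

    valid = (np.isfinite(centroid) and np.isfinite(fundamental)
             and centroid < params.valid_centroid_max_hz
             and params.valid_fundamental_hz[0] <= fundamental
             <= params.valid_fundamental_hz[1])

    return CallFeatures(
        duration_s=dur, rms=rms, peak_to_peak=ptp,
        entropy_time=entropy_time, entropy_spectrum=entropy_spec,
        peak_freq_hz=peak, min_freq_hz=fmin, max_freq_hz=fmax,
        bandwidth_hz=bw, centroid_hz=centroid, fundamental_hz=fundamental,
        wiener_entropy=flatness, shannon_entropy=shannon,
        is_valid=bool(valid), start_s=segment.start_s, end_s=segment.end_s)


def features_table(segments: list[CallSegment], sample_rate_hz: float,
                   params: FeatureParams | None = None,
                   valid_only: bool = False) -> pd.DataFrame:
    """Feature rows for a list of segments, ordered by start time."""
    rows = [compute_features(s, sample_rate_hz, params).as_dict()
            for s in segments]
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("start_s").reset_index(drop=True)
        df.insert(0, "call_id", np.arange(len(df)))
        if valid_only:
            df = df[df["is_valid"]].reset_index(drop=True)
    return df
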