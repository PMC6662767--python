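"""Audio containers and WAV I/O.

A recording is a single-channel float waveform with its sample rate. Amplitudes
are linear full-scale units (no SPL calibration constant is carried); dB values
elsewhere in the package are therefore always relative, e.g. dB re full scale
or dB re a spectral peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile


@dataclass
class AudioRecording:
    """A sampled single-channel waveform.

    Parameters
    ----------
    samples : ndarray
        1-D float array of linear amplitudes.
    sample_rate_hz : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError("AudioRecording requires a 1-D waveform")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def time_axis(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz

    def slice_seconds(self, start_s: float, end_s: float) -> np.ndarray:
        """Return the samples between two time points (clipped to bounds)."""
        i0 = max(0, int(round(start_s * self.sample_rate_hz)))
        i1 = min(len(self.samples), int(round(end_s * self.sample_rate_hz)))
        return self.samples[i0:i1]


def read_wav(path) -> AudioRecording:
    """Read a mono WAV file into an :class:`AudioRecording`.

    Integer PCM is rescaled to [-1, 1); float data is passed through.
    """
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioRecording(samples=data, sample_rate_hz=float(rate))


def write_wav(path, recording: AudioRecording, dtype: str = "float32") -> None:
    """Write a recording as WAV (float32 by default, or 16-bit PCM)."""
    if dtype == "float32":
        wavfile.write(path, int(recording.sample_rate_hz),
                      recording.samples.astype(np.float32))
    elif dtype == "int16":
        clipped = np.clip(recording.samples, -1.0, 1.0 - 2.0 ** -15)
        wavfile.write(path, int(recording.sample_rate_hz),
                      np.round(clipped * 2 ** 15).astype(np.int16))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
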