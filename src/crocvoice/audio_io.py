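"""Audio I/O and call segmentation.

Carries recorded or synthesized calls as :class:`Waveform` objects, reads and
writes RIFF WAV files (16-bit PCM and 32-bit float), and segments a continuous
recording into individual call intervals with a relative-level envelope
detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

__all__ = ["Waveform", "read_wav", "write_wav", "segment_calls"]

#: Lowest sample rate accepted for analysis: the 0-5 kHz analysis band must sit
#: below Nyquist with margin.
MIN_SAMPLE_RATE = 10_000


@dataclass
class Waveform:
    """A mono audio signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude samples, nominally in [-1, 1].
    sample_rate : int
        Sampling frequency in Hz; must be >= 10 kHz.
    label : str
        Free-text label (file stem, stimulus name, ...).
    """

    samples: np.ndarray
    sample_rate: int
    label: str = field(default="")

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if self.samples.size < 1:
            raise ValueError("Waveform must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform contains non-finite samples")
        if self.sample_rate < MIN_SAMPLE_RATE:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz is below the {MIN_SAMPLE_RATE} Hz "
                "floor required for a 5 kHz analysis band"
            )

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (first sample at t=0)."""
        return np.arange(self.samples.size) / self.sample_rate

    def slice(self, start_s: float, end_s: float, label: str | None = None) -> "Waveform":
        """Extract the sub-waveform between two times (seconds)."""
        i0 = max(0, int(round(start_s * self.sample_rate)))
        i1 = min(self.samples.size, int(round(end_s * self.sample_rate)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start_s}, {end_s}] s")
        return Waveform(self.samples[i0:i1], self.sample_rate,
                        label if label is not None else self.label)


def read_wav(path: str | Path) -> Waveform:
    """Read a WAV file into a mono, [-1, 1]-scaled :class:`Waveform`.

    Integer PCM samples are rescaled by the full-scale value of their dtype;
    float samples pass through unchanged.  Multichannel input is averaged to
    mono (single-microphone field recordings occasionally end up in stereo
    containers).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        sr, data = wavfile.read(str(path))
    except Exception as exc:  # unreadable/corrupt container
        raise ValueError(f"unreadable WAV file: {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty WAV file: {path}")
    if data.ndim > 1:
        data = data.astype(np.float64).mean(axis=1)
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64 or already averaged
        samples = np.asarray(data, dtype=np.float64)
    return Waveform(samples, int(sr), label=path.stem)


def write_wav(waveform: Waveform, path: str | Path, encoding: str = "pcm16") -> None:
    """Write a :class:`Waveform` to disk.

    encoding: ``"pcm16"`` (16-bit integer, quantization error < 2**-15) or
    ``"float32"``/``"float64"`` for lossless round trips.
    """
    path = Path(path)
    if encoding == "pcm16":
        clipped = np.clip(waveform.samples, -1.0, 1.0)
        data = np.round(clipped * 32767.0).astype(np.int16)
    elif encoding == "float32":
        data = waveform.samples.astype(np.float32)
    elif encoding == "float64":
        data = waveform.samples.astype(np.float64)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    try:
        wavfile.write(str(path), waveform.sample_rate, data)
    except OSError as exc:
        raise OSError(f"cannot write WAV file {path}: {exc}") from exc


def amplitude_envelope(waveform: Waveform, smooth_s: float = 0.005) -> np.ndarray:
    """Rectified amplitude envelope, smoothed with a moving-average window."""
    width = max(1, int(round(smooth_s * waveform.sample_rate)))
    return uniform_filter1d(np.abs(waveform.samples), size=width, mode="nearest")


def segment_calls(
    waveform: Waveform,
    threshold_db: float = -25.0,
    min_gap_s: float = 0.05,
    min_dur_s: float = 0.03,
    smooth_s: float = 0.005,
) -> list[tuple[float, float]]:
    """Find call intervals as runs where the envelope exceeds a relative level.

    The threshold is ``threshold_db`` decibels below the envelope peak, so the
    result is invariant to global gain.  Sub-threshold gaps shorter than
    ``min_gap_s`` are merged; segments shorter than ``min_dur_s`` are dropped.

    Returns a time-ordered list of disjoint ``(start_s, end_s)`` intervals;
    silence yields an empty list.
    """
    env = amplitude_envelope(waveform, smooth_s)
    peak = env.max()
    if peak <= 0:
        return []
    mask = env >= peak * 10.0 ** (threshold_db / 20.0)
    # run-length boundaries of the boolean mask
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    sr = waveform.sample_rate
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) / sr < min_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        (s / sr, e / sr) for s, e in merged if (e - s) / sr >= min_dur_s
    ]
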