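"""Synthesis of playback stimuli and harmonic juvenile-call mimics.

The experimental stimuli are frequency-modulated pure tones specified only by
their start, mean and end pitch and their duration.  Those three anchors do
not fix a contour, so the contour family is a modeling choice: a rise from
``f_start`` to a peak at ``peak_time_fraction * duration`` followed by a
descent to ``f_end``, each segment shaped as a symmetric smoothstep ramp.
A symmetric ramp averages to the midpoint of its endpoints, exactly as a
straight line does, so the peak frequency solves in closed form from the
target mean:

    f_peak = 2 f_mean - p f_start - (1 - p) f_end,   p = peak_time_fraction.

Unlike a straight line, a smoothstep segment is flat (zero slope and
curvature) at its endpoints, so the first and last analysis frames of a
pitch tracker see a locally constant frequency and the design anchors
survive a synthesis-to-tracking round trip.

Harmonic-stack mimics add partials at integer multiples of the contour with a
per-harmonic spectral tilt, emulating the harmonic structure of natural
juvenile calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .audio_io import Waveform

__all__ = [
    "ContourSpec",
    "HarmonicCallSpec",
    "design_contour",
    "synth_fm_tone",
    "synth_harmonic_call",
    "build_playback_series",
]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Seventh-order smoothstep: s(0)=0, s(1)=1, derivatives up to third
    order vanish at both ends, and s(u) + s(1-u) = 1 so the time-average over
    [0, 1] is exactly 1/2 (same as a straight line)."""
    return u**4 * (35.0 - 84.0 * u + 70.0 * u**2 - 20.0 * u**3)


@dataclass
class ContourSpec:
    """A rise-then-fall F0 trajectory pinned at start, peak and end.

    ``f_peak`` is derived by :func:`design_contour`; for a degenerate
    (single-segment) contour ``feasible`` is False and ``f_mean`` holds the
    achievable mean.
    """

    f_start: float
    f_mean: float
    f_end: float
    duration: float
    peak_time_fraction: float = 0.25
    f_peak: float = field(default=0.0)
    feasible: bool = True

    def __post_init__(self) -> None:
        if min(self.f_start, self.f_mean, self.f_end) <= 0:
            raise ValueError("contour frequencies must be positive")
        if self.duration <= 0:
            raise ValueError("contour duration must be positive")
        if not 0.0 < self.peak_time_fraction < 1.0:
            raise ValueError("peak_time_fraction must lie strictly in (0, 1)")

    @property
    def f_max(self) -> float:
        return max(self.f_start, self.f_peak, self.f_end)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous frequency (Hz) at times ``t`` in [0, duration]."""
        t = np.asarray(t, dtype=np.float64)
        t_peak = self.peak_time_fraction * self.duration
        f = np.empty_like(t)
        rising = t <= t_peak
        with np.errstate(invalid="ignore"):
            u_r = np.where(rising, t / t_peak, 0.0)
            u_f = np.where(rising, 0.0, (t - t_peak) / (self.duration - t_peak))
        s_r = _smoothstep(np.clip(u_r, 0.0, 1.0))
        s_f = _smoothstep(np.clip(u_f, 0.0, 1.0))
        f[rising] = self.f_start + (self.f_peak - self.f_start) * s_r[rising]
        f[~rising] = self.f_peak + (self.f_end - self.f_peak) * s_f[~rising]
        return f


@dataclass
class HarmonicCallSpec:
    """A harmonic stack riding on a :class:`ContourSpec`.

    spectral_tilt is the amplitude decrement per harmonic step in dB
    (positive = falling spectrum); amplitude_envelope is the onset/offset
    ramp length in seconds.
    """

    contour: ContourSpec
    n_harmonics: int = 10
    spectral_tilt: float = 6.0
    amplitude_envelope: float = 0.005

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


def design_contour(
    f_start: float,
    f_mean: float,
    f_end: float,
    duration: float,
    peak_time_fraction: float = 0.25,
) -> ContourSpec:
    """Solve the contour peak so the trajectory's time-average equals f_mean.

    The rise segment (fraction p of the duration) averages
    (f_start + f_peak)/2 and the fall averages (f_peak + f_end)/2, so

        f_mean = p (f_start + f_peak)/2 + (1-p)(f_peak + f_end)/2
        f_peak = 2 f_mean - p f_start - (1-p) f_end.

    If the solved peak falls below both anchors the rise-fall family cannot
    reach the requested mean; the contour degenerates to a single monotone
    segment from f_start to f_end and the achievable mean is reported (with a
    warning).  A non-positive solved peak is a design error.
    """
    p = peak_time_fraction
    f_peak = 2.0 * f_mean - p * f_start - (1.0 - p) * f_end
    if f_peak <= 0:
        raise ValueError(
            f"infeasible contour: target mean {f_mean} Hz requires a non-positive "
            f"peak ({f_peak:.1f} Hz)"
        )
    if f_peak < max(f_start, f_end):
        achievable = 0.5 * (f_start + f_end)
        warnings.warn(
            "requested mean below the rise-fall family; falling back to a single "
            f"segment with achievable mean {achievable:.1f} Hz",
            stacklevel=2,
        )
        # single raised-cosine segment start -> end: collapse the rise segment
        # to a vanishing fraction of the duration
        return ContourSpec(f_start, achievable, f_end, duration, 1e-9,
                           f_peak=f_start, feasible=False)
    return ContourSpec(f_start, f_mean, f_end, duration, p, f_peak=f_peak)


def _amplitude_ramp(n: int, sample_rate: float, ramp_s: float) -> np.ndarray:
    """Raised-cosine onset/offset envelope of length n."""
    env = np.ones(n)
    n_ramp = int(round(ramp_s * sample_rate))
    if n_ramp > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] *= r
        env[-n_ramp:] *= r[::-1]
    return env


def synth_fm_tone(
    spec: ContourSpec,
    sample_rate: int = 44100,
    amplitude: float = 0.8,
    ramp_s: float = 0.005,
) -> Waveform:
    """Render a contour as a pure tone with phase-continuous FM.

    The phase is the cumulative integral of the instantaneous frequency, so
    there are no phase discontinuities; raised-cosine onset/offset ramps of
    ``ramp_s`` remove clicks.  The sample count is ``round(duration * sr)`` so
    the duration is exactly recoverable.
    """
    if spec.f_max >= sample_rate / 2:
        raise ValueError("contour exceeds Nyquist at this sample rate")
    if ramp_s > spec.duration / 2:
        raise ValueError("ramp_s longer than half the stimulus duration")
    n = int(round(spec.duration * sample_rate))
    t = np.arange(n) / sample_rate
    freq = spec.evaluate(t)
    phase = 2.0 * np.pi * cumulative_trapezoid(freq, t, initial=0.0)
    samples = _amplitude_ramp(n, sample_rate, ramp_s) * np.sin(phase)
    peak = np.abs(samples).max()
    if peak > 0:
        samples *= amplitude / peak
    return Waveform(samples, sample_rate, label="fm_tone")


def synth_harmonic_call(spec: HarmonicCallSpec, sample_rate: int = 44100,
                        amplitude: float = 0.8) -> Waveform:
    """Render a harmonic stack: partials at k*F0(t) tilted by spectral_tilt.

    Partial k (k = 1..n_harmonics) has amplitude 10**(-tilt (k-1) / 20); all
    partials share the contour's phase integral scaled by k and a common
    onset/offset envelope.  Peak amplitude is normalized to ``amplitude``.
    """
    contour = spec.contour
    if spec.n_harmonics * contour.f_max >= sample_rate / 2:
        raise ValueError(
            f"{spec.n_harmonics} harmonics of a {contour.f_max:.0f} Hz peak exceed "
            f"Nyquist at {sample_rate} Hz"
        )
    n = int(round(contour.duration * sample_rate))
    t = np.arange(n) / sample_rate
    phase = 2.0 * np.pi * cumulative_trapezoid(contour.evaluate(t), t, initial=0.0)
    k = np.arange(1, spec.n_harmonics + 1)
    weights = 10.0 ** (-spec.spectral_tilt * (k - 1) / 20.0)
    samples = np.sin(np.outer(k, phase)).T @ weights
    samples *= _amplitude_ramp(n, sample_rate, spec.amplitude_envelope)
    peak = np.abs(samples).max()
    if peak > 0:
        samples *= amplitude / peak
    return Waveform(samples, sample_rate, label="harmonic_call")


def build_playback_series(
    call: Waveform,
    n_calls: int,
    gap_s: float,
    jitter_s: float = 0.0,
    seed: int = 0,
) -> Waveform:
    """Concatenate ``n_calls`` copies of a call separated by jittered silences.

    Gap lengths are ``gap_s`` plus uniform jitter in [-jitter_s, +jitter_s]
    (seeded); a jittered gap that would be negative is clipped to zero with a
    warning.
    """
    if n_calls < 1:
        raise ValueError("n_calls must be >= 1")
    if gap_s < 0:
        raise ValueError("gap_s must be >= 0")
    rng = np.random.default_rng(seed)
    gaps = gap_s + rng.uniform(-jitter_s, jitter_s, size=max(0, n_calls - 1))
    if np.any(gaps < 0):
        warnings.warn("negative jittered gap clipped to 0", stacklevel=2)
        gaps = np.clip(gaps, 0.0, None)
    pieces = [call.samples]
    for g in gaps:
        pieces.append(np.zeros(int(round(g * call.sample_rate))))
        pieces.append(call.samples)
    return Waveform(np.concatenate(pieces), call.sample_rate,
                    label=f"{call.label}_series")
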