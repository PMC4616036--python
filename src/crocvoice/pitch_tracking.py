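"""Fundamental-frequency (F0) contour extraction and pitch descriptors.

A frame-based normalized-autocorrelation tracker: for each analysis frame the
highest autocorrelation peak with lag in [1/fmax, 1/fmin] gives the F0
candidate, the frame is voiced if the normalized peak value clears a
threshold, and the lag is refined by parabolic interpolation.  Frames are
centered on a regular grid that starts at t=0 and ends at the signal end, so
the first and last voiced frames probe the very beginning and end of the
call; overhanging frames use a window tapered over the in-signal support,
with the window's own autocorrelation divided out so the estimate stays
unbiased.  A deterministic median-continuity rule
replaces interactive octave-jump correction: a voiced frame sitting at twice
or half the local median of its voiced neighbours is folded back by an
octave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import Waveform

__all__ = [
    "PitchContour",
    "PitchSummary",
    "extract_f0_contour",
    "correct_octave_jumps",
    "summarize_contour",
]


class UnvoicedCallError(ValueError):
    """Raised when no frame of a call passes the voicing threshold."""


@dataclass
class PitchContour:
    """Per-frame F0 track: frame-center times (s), f0 (Hz) and voicing flags."""

    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.f0 = np.asarray(self.f0, dtype=np.float64)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if not (self.times.size == self.f0.size == self.voiced.size):
            raise ValueError("times, f0 and voiced must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())

    def to_frame(self):
        """Two-column table (time_s, f0_hz); unvoiced rows carry NaN."""
        import pandas as pd

        f0 = np.where(self.voiced, self.f0, np.nan)
        return pd.DataFrame({"time_s": self.times, "f0_hz": f0})


@dataclass
class PitchSummary:
    """The five pitch descriptors of one call (all Hz)."""

    start_pitch: float
    max_pitch: float
    min_pitch: float
    mean_pitch: float
    end_pitch: float


def _frame_matrix(samples: np.ndarray, centers: np.ndarray, half: int) -> np.ndarray:
    """Extract zero-padded frames of length 2*half centered on given samples."""
    n = samples.size
    frame_len = 2 * half
    frames = np.zeros((centers.size, frame_len))
    for i, c in enumerate(centers):
        lo, hi = c - half, c + half
        src_lo, src_hi = max(lo, 0), min(hi, n)
        frames[i, src_lo - lo : src_hi - lo] = samples[src_lo:src_hi]
    return frames


def extract_f0_contour(
    waveform: Waveform,
    fmin: float = 100.0,
    fmax: float = 1200.0,
    frame_s: float = 0.02,
    hop_s: float = 0.005,
    voicing_threshold: float = 0.45,
    octave_bias: float = 0.01,
) -> PitchContour:
    """Track F0 by frame-wise normalized autocorrelation.

    Per frame, the autocorrelation of the Hann-weighted signal is divided by
    the autocorrelation of the weighting itself (the window times the
    in-signal mask, so zero-padded edge frames are handled exactly):

        r(tau) = [A(tau) / A(0)] / [W(tau) / W(0)]

    which for a locally stationary tone peaks at the period with value ~1,
    free of taper- and padding-induced bias.  Candidate lags span
    [sr/fmax, sr/fmin]; the best candidate maximizes
    r(tau) - octave_bias * log2(tau * fmax / sr), a slight preference for
    shorter lags that breaks the tie between a period and its octave.  The
    frame is voiced iff the winning r >= voicing_threshold; the lag is refined
    by parabolic interpolation over its two neighbours.

    Raises :class:`UnvoicedCallError` if no frame is voiced.
    """
    sr = waveform.sample_rate
    if not (0 < fmin < fmax <= sr / 4):
        raise ValueError("need 0 < fmin < fmax <= sample_rate/4")
    half = max(2, int(round(frame_s * sr / 2)))
    frame_len = 2 * half
    hop = max(1, int(round(hop_s * sr)))
    lag_min = max(1, int(np.floor(sr / fmax)))
    lag_max = int(np.ceil(sr / fmin))
    if lag_max >= frame_len - 2:
        raise ValueError("frame_s too short to resolve fmin")
    if waveform.samples.size < hop:
        raise ValueError("waveform shorter than one hop")

    samples = waveform.samples - waveform.samples.mean()
    n_samples = samples.size
    centers = np.arange(0, n_samples + 1, hop)
    frames = _frame_matrix(samples, centers, half)
    mask = _frame_matrix(np.ones_like(samples), centers, half)
    window = np.hanning(frame_len)
    a = frames * window
    m = mask * window
    # Frames overhanging the signal edge: re-shape the window to taper over
    # the actual in-signal support.  An abruptly truncated window leaves an
    # oscillatory residual in the autocorrelation that biases the edge lag
    # estimates; the mask-normalization below makes the estimate itself
    # window-shape independent, so the support-fitted taper costs nothing.
    for i in np.flatnonzero(~mask.all(axis=1)):
        sup = np.flatnonzero(mask[i])
        if sup.size < 4:
            continue
        shaped = np.zeros(frame_len)
        shaped[sup[0] : sup[-1] + 1] = np.hanning(sup.size)
        a[i] = frames[i] * shaped
        m[i] = shaped

    # autocorrelations via FFT, per frame
    nfft = 1 << int(np.ceil(np.log2(2 * frame_len)))
    spec_a = np.fft.rfft(a, nfft, axis=1)
    acorr = np.fft.irfft(spec_a * np.conj(spec_a), nfft, axis=1)[:, :frame_len]
    spec_m = np.fft.rfft(m, nfft, axis=1)
    wcorr = np.fft.irfft(spec_m * np.conj(spec_m), nfft, axis=1)[:, :frame_len]

    total = acorr[:, :1]  # A(0) = frame energy
    wnorm = wcorr / np.maximum(wcorr[:, :1], 1e-300)
    # weighting autocorrelation too small -> estimator unreliable at that lag
    usable = wnorm > 0.05
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(usable & (total > 0), acorr / np.maximum(total, 1e-300) / wnorm, -1.0)

    band = r[:, lag_min : lag_max + 1]
    penalty = octave_bias * np.log2(np.arange(lag_min, lag_max + 1) * fmax / sr)
    score = band - penalty
    best = np.argmax(score, axis=1) + lag_min

    f0 = np.zeros(centers.size)
    voiced = np.zeros(centers.size, dtype=bool)
    for i, tau in enumerate(best):
        if total[i, 0] <= 0 or r[i, tau] < voicing_threshold:
            continue
        # parabolic refinement of the peak lag
        if 1 <= tau < frame_len - 1:
            y0, y1, y2 = r[i, tau - 1], r[i, tau], r[i, tau + 1]
            denom_p = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom_p if denom_p != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        est = sr / (tau + delta)
        if fmin <= est <= fmax:
            f0[i] = est
            voiced[i] = True
    if not voiced.any():
        raise UnvoicedCallError("unvoiced call: no frame passed the voicing threshold")
    return PitchContour(centers / sr, f0, voiced)


def correct_octave_jumps(contour: PitchContour, ratio_tol: float = 0.15) -> PitchContour:
    """Fold octave outliers back onto the local contour.

    A voiced frame whose f0 is within ``ratio_tol`` (relative) of exactly 2x
    or 0.5x the median of its 5 nearest voiced neighbours is replaced by
    f0/2 or f0*2.  The rule is iterated to a fixed point, so the operation is
    idempotent.
    """
    if contour.n_voiced < 1:
        raise ValueError("contour has no voiced frame")
    f0 = contour.f0.copy()
    vidx = np.flatnonzero(contour.voiced)
    for _ in range(8):  # fixed point reached in 1-2 passes in practice
        changed = False
        for j, i in enumerate(vidx):
            neighbours = vidx[np.argsort(np.abs(vidx - i), kind="stable")]
            neighbours = [k for k in neighbours if k != i][:5]
            if not neighbours:
                continue
            med = float(np.median(f0[neighbours]))
            if med <= 0:
                continue
            ratio = f0[i] / med
            if abs(ratio / 2.0 - 1.0) <= ratio_tol:
                f0[i] /= 2.0
                changed = True
            elif abs(ratio * 2.0 - 1.0) <= ratio_tol:
                f0[i] *= 2.0
                changed = True
        if not changed:
            break
    return PitchContour(contour.times.copy(), f0, contour.voiced.copy())


def summarize_contour(contour: PitchContour) -> PitchSummary:
    """The five pitch descriptors: start, max, min, mean, end over voiced frames.

    Start/end are the F0 of the first/last voiced frame; the mean is the
    arithmetic mean over voiced frames (unvoiced frames carry no F0).
    """
    if contour.n_voiced < 1:
        raise ValueError("contour has no voiced frame")
    v = contour.f0[contour.voiced]
    return PitchSummary(
        start_pitch=float(v[0]),
        max_pitch=float(v.max()),
        min_pitch=float(v.min()),
        mean_pitch=float(v.mean()),
        end_pitch=float(v[-1]),
    )
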