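"""Silence trimming, minimum-length filtering and background removal.

A triggered recording contains a short flight surrounded by near-silent
margins. Trimming keeps the span of samples whose absolute amplitude exceeds
a fixed background threshold (0.0061 AAU), after discarding supra-threshold
indices that are *temporal* outliers — isolated noise spikes far from the
flight, identified as indices more than ``iqr_multiplier`` interquartile
ranges beyond the quartiles of the supra-threshold index set (the whiskers
of a boxplot on the time axis).

Trimmed flights shorter than 128 samples carry too little signal for
spectral work and are excluded from feature extraction.

Background variation is then reduced with a short-time Fourier transform
(Hanning window): a robust broadband noise floor is estimated from the frame
magnitudes and subtracted before resynthesis by overlap-add.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .audio_io import AudioRecording

__all__ = [
    "TrimmedAudio",
    "NoSignalError",
    "trim_silence",
    "min_length_filter",
    "background_filter",
    "SILENCE_THRESHOLD",
    "MIN_LENGTH",
]

#: Background-noise amplitude threshold in AAU.
SILENCE_THRESHOLD = 0.0061
#: Minimum retained flight length in samples.
MIN_LENGTH = 128


class NoSignalError(ValueError):
    """The recording never exceeds the background threshold."""


@dataclass
class TrimmedAudio:
    """A trimmed (and optionally background-filtered) flight segment.

    ``start_index``/``end_index`` are 0-based inclusive positions in the
    parent recording; ``duration`` is the inclusive span in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    start_index: int
    end_index: int
    parent_id: str = ""
    species: str | None = None
    temperature: float | None = None
    humidity: float | None = None

    def __post_init__(self):
        if self.start_index > self.end_index:
            raise ValueError("start_index must not exceed end_index")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return (self.end_index - self.start_index + 1) / self.sample_rate

    @property
    def too_short(self) -> bool:
        return self.n < MIN_LENGTH


def trim_silence(
    rec: AudioRecording,
    threshold: float = SILENCE_THRESHOLD,
    iqr_multiplier: float = 3.0,
) -> TrimmedAudio:
    """Trim a recording to its flight using the threshold + outlier rule.

    Let ``S`` be the set of sample indices with ``|a(t)| > threshold``.
    Indices beyond ``q3 + m*IQR`` or below ``q1 - m*IQR`` (quartiles of S,
    linear-interpolation quantiles) are treated as stochastic noise spikes;
    the recording is trimmed to the [min, max] span of the survivors.

    Raises
    ------
    NoSignalError
        If no sample exceeds the threshold.
    """
    supra = np.flatnonzero(np.abs(rec.samples) > threshold)
    if supra.size == 0:
        raise NoSignalError(f"recording {rec.id!r} never exceeds {threshold} AAU")
    q1, q3 = np.quantile(supra, [0.25, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
    keep = supra[(supra >= lo) & (supra <= hi)]
    start, end = int(keep[0]), int(keep[-1])
    return TrimmedAudio(
        samples=rec.samples[start : end + 1].copy(),
        sample_rate=rec.sample_rate,
        start_index=start,
        end_index=end,
        parent_id=rec.id,
        species=rec.species,
        temperature=rec.temperature,
        humidity=rec.humidity,
    )


def min_length_filter(trimmed: TrimmedAudio, min_length: int = MIN_LENGTH) -> TrimmedAudio | None:
    """Return ``trimmed`` if it is long enough for feature extraction, else None.

    Rejection (``None``) is a normal outcome for flights that barely crossed
    the sensor; callers count and log it rather than treating it as an error.
    """
    if trimmed.n < min_length:
        return None
    return trimmed


def background_filter(
    trimmed: TrimmedAudio,
    window_length: int = 128,
    floor: str = "broadband",
) -> TrimmedAudio:
    """Reduce stationary background noise by STFT spectral subtraction.

    The signal is decomposed into 50%-overlapping Hanning-windowed frames of
    ``window_length`` samples. A noise floor is estimated from the frame
    magnitudes and subtracted (clipped at zero, phases preserved) before
    least-squares overlap-add resynthesis. Output length equals input length.

    ``floor`` selects the estimator:

    - ``"broadband"`` (default): the median across frequency bins of each
      bin's median magnitude over frames — a single robust broadband level
      that cannot swallow a stationary wingbeat harmonic;
    - ``"per_bin"``: each bin's own median over frames (classical spectral
      subtraction; aggressive on stationary tones).

    Signals shorter than ``window_length`` are passed through unchanged with
    a warning.
    """
    x = trimmed.samples
    if x.size < window_length:
        warnings.warn(
            f"recording {trimmed.parent_id!r}: length {x.size} < window "
            f"{window_length}; background filter skipped"
        )
        return trimmed
    hop = window_length // 2
    stft = ShortTimeFFT(hann(window_length, sym=False), hop=hop, fs=trimmed.sample_rate)
    Z = stft.stft(x)
    mag = np.abs(Z)
    per_bin = np.median(mag, axis=1, keepdims=True)
    if floor == "broadband":
        noise_floor = np.median(per_bin)
    elif floor == "per_bin":
        noise_floor = per_bin
    else:
        raise ValueError(f"unknown floor estimator {floor!r}")
    scale = np.ones_like(mag)
    np.divide(np.maximum(mag - noise_floor, 0.0), mag, out=scale, where=mag > 0)
    y = stft.istft(Z * scale, k1=x.size)[: x.size]
    return replace(trimmed, samples=y)
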