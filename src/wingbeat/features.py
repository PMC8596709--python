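"""The 52 bioacoustic features of a wingbeat recording.

Features are computed in seven stages on a trimmed, background-filtered
recording and on its detrended counterpart (the signal minus the
penalized-spline flight trend, marked ``(g)`` / ``_g``):

1. amplitude and energy statistics of the filtered trimmed audio;
2. envelope statistics (amplitude index, temporal entropy) of the
   zero-padded audio;
3. spectral features (bioacoustic indices, spectral and acoustic entropy,
   dominant frequency, ten harmonic peaks) of the mean STFT magnitude
   spectrum of the zero-padded audio;
4-6. the same three stages on the detrended signal, plus the trend's own
   peak-to-trough range;
7. the fundamental (wingbeat) frequency from the autocorrelation of the
   detrended signal.

Storage transformations follow the feature table: energy-type statistics,
the amplitude index and the fundamental frequency are natural-logged, the
dominant frequency is square-rooted, and entropies, bioacoustic indices and
harmonic peak positions are stored untransformed. Undefined computations
(e.g. the log of a zero amplitude range) yield missing values (NaN), never
sentinels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, hilbert
from scipy.signal.windows import hann

from .audio_io import AudioRecording
from .detrend import DetrendError, fit_trend
from .preprocess import TrimmedAudio, background_filter, min_length_filter, trim_silence

__all__ = [
    "FeatureSpec",
    "FEATURE_SCHEMA",
    "FEATURE_COLUMNS",
    "METADATA_COLUMNS",
    "Spectrum",
    "HarmonicSet",
    "FundamentalEstimate",
    "PAD_LENGTH",
    "SPECTRUM_WINDOW",
    "amplitude_energy_stats",
    "hilbert_envelope",
    "temporal_entropy",
    "envelope_stats",
    "zero_pad",
    "mean_spectrum",
    "bioacoustic_indices",
    "spectral_entropy",
    "harmonic_peaks",
    "fundamental_frequency",
    "extract_features",
    "extract_corpus",
]

#: Zero-padding target for envelope and spectral stages, in samples.
PAD_LENGTH = 8192
#: STFT window length for the mean magnitude spectrum, in samples.
SPECTRUM_WINDOW = 128
#: Frequency bands (Hz) of the four bioacoustic indices.
BIOACOUSTIC_BANDS = ((0.0, 1000.0), (50.0, 1000.0), (50.0, 300.0), (200.0, 3000.0))

#: Minimum normalized-ACF peak height accepted as a wingbeat period.
ACF_MIN_PEAK_HEIGHT = 0.3
#: Minimum separation between ACF peaks, in samples.
ACF_MIN_PEAK_DISTANCE = 10
#: Plausibility band for the fundamental frequency, Hz.
F0_RANGE = (20.0, 2000.0)


@dataclass(frozen=True)
class FeatureSpec:
    key: str
    stage: int
    transform: str  # "log" | "sqrt" | "none"
    detrended: bool
    kind: str


def _build_schema() -> list[FeatureSpec]:
    energy = [
        ("max_amplitude", "log"),
        ("amplitude_range", "log"),
        ("amplitude_iqr", "log"),
        ("power", "log"),
        ("rms", "log"),
        ("crest_factor", "log"),
    ]
    schema: list[FeatureSpec] = []
    for g in (False, True):
        suffix = "_g" if g else ""
        stage = 4 if g else 1
        if g:
            schema.append(FeatureSpec("gam_amplitude_range", 4, "log", True, "trend"))
        for key, tr in energy:
            schema.append(FeatureSpec(key + suffix, stage, tr, g, "energy"))
        stage = 5 if g else 2
        schema.append(FeatureSpec("amplitude_index" + suffix, stage, "log", g, "envelope"))
        schema.append(FeatureSpec("temporal_entropy" + suffix, stage, "none", g, "envelope"))
        stage = 6 if g else 3
        for i in range(1, 5):
            schema.append(FeatureSpec(f"bioacoustic_index_{i}{suffix}", stage, "none", g, "bioacoustic"))
        schema.append(FeatureSpec("spectral_entropy" + suffix, stage, "none", g, "spectral_entropy"))
        schema.append(FeatureSpec("acoustic_entropy" + suffix, stage, "none", g, "acoustic_entropy"))
        schema.append(FeatureSpec("dominant_frequency" + suffix, stage, "sqrt", g, "dominant"))
        for i in range(1, 11):
            schema.append(FeatureSpec(f"harmonic_{i}{suffix}", stage, "none", g, "harmonic"))
    schema.append(FeatureSpec("fundamental_frequency_g", 7, "log", True, "fundamental"))
    return schema


FEATURE_SCHEMA: list[FeatureSpec] = _build_schema()
FEATURE_COLUMNS: list[str] = [f.key for f in FEATURE_SCHEMA]
METADATA_COLUMNS = ["id", "species", "temperature", "humidity", "duration"]
assert len(FEATURE_COLUMNS) == 52

_TRANSFORMS = {f.key: f.transform for f in FEATURE_SCHEMA}


def apply_transform(key: str, value: float) -> float:
    """Apply the storage transformation of feature ``key`` to a raw value."""
    if value is None or not np.isfinite(value):
        return np.nan
    tr = _TRANSFORMS[key]
    if tr == "log":
        return np.log(value) if value > 0 else np.nan
    if tr == "sqrt":
        return np.sqrt(value) if value >= 0 else np.nan
    return value


def invert_transform(key: str, value: float) -> float:
    """Map a stored feature value back to its original scale."""
    tr = _TRANSFORMS[key]
    if tr == "log":
        return np.exp(value)
    if tr == "sqrt":
        return value**2
    return value


# ---------------------------------------------------------------------------
# stages 1 / 4: amplitude and energy statistics


def amplitude_energy_stats(x: np.ndarray) -> dict[str, float]:
    """Six amplitude/energy statistics of an amplitude series (untransformed).

    max amplitude ``max|x|``, amplitude range ``max x - min x``, amplitude
    IQR ``q3 - q1``, power ``mean(x^2)``, RMS ``sqrt(power)`` and crest
    factor ``max|x| / RMS`` (NaN for an all-zero series).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("amplitude series is empty")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    peak = float(np.max(np.abs(x)))
    power = float(np.mean(x**2))
    rms = float(np.sqrt(power))
    return {
        "max_amplitude": peak,
        "amplitude_range": float(x.max() - x.min()),
        "amplitude_iqr": float(q3 - q1),
        "power": power,
        "rms": rms,
        "crest_factor": peak / rms if rms > 0 else np.nan,
    }


# ---------------------------------------------------------------------------
# stages 2 / 5: Hilbert envelope statistics


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal: the amplitude envelope a*(t)."""
    return np.abs(hilbert(np.asarray(x, dtype=float)))


def temporal_entropy(envelope: np.ndarray) -> float:
    """Shannon evenness of the unit-sum normalized envelope, in [0, 1].

    ``Ht = -(1/log n) * sum p(t) log p(t)`` with ``0 log 0 := 0``. 1 for a
    perfectly uniform envelope, 0 when all amplitude sits in one sample.
    """
    env = np.asarray(envelope, dtype=float)
    total = env.sum()
    if env.size < 2 or total <= 0:
        return np.nan
    p = env / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(env.size))


def envelope_stats(x: np.ndarray) -> tuple[float, float]:
    """Amplitude index (median envelope, untransformed) and temporal entropy."""
    env = hilbert_envelope(x)
    if not env.sum() > 0:
        return np.nan, np.nan
    return float(np.median(env)), temporal_entropy(env)


# ---------------------------------------------------------------------------
# stages 3 / 6: mean spectrum and spectral features


def zero_pad(x: np.ndarray, target: int = PAD_LENGTH) -> np.ndarray:
    """Pad with trailing zeros to ``target`` samples; longer inputs pass through."""
    x = np.asarray(x, dtype=float)
    if x.size >= target:
        return x
    return np.concatenate([x, np.zeros(target - x.size)])


@dataclass
class Spectrum:
    """Mean STFT magnitude spectrum with its frequency axis."""

    freqs: np.ndarray
    mean_mag: np.ndarray
    sample_rate: float

    def __post_init__(self):
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency axis must be strictly ascending")

    @property
    def normalized(self) -> np.ndarray:
        """Unit-sum probability version of the mean magnitude spectrum."""
        total = self.mean_mag.sum()
        return self.mean_mag / total if total > 0 else np.zeros_like(self.mean_mag)


def mean_spectrum(
    x: np.ndarray, sample_rate: float, window_length: int = SPECTRUM_WINDOW
) -> Spectrum:
    """Mean magnitude spectrum over non-overlapping Hanning windows.

    The input is zero-padded to :data:`PAD_LENGTH` samples first (inputs
    already longer are used as-is, dropping the final partial frame).
    Frequency bins sit at multiples of ``sample_rate / window_length``.
    """
    x = zero_pad(x)
    n_frames = x.size // window_length
    frames = x[: n_frames * window_length].reshape(n_frames, window_length)
    win = hann(window_length, sym=False)
    mag = np.abs(np.fft.rfft(frames * win, axis=1))
    freqs = np.fft.rfftfreq(window_length, d=1.0 / sample_rate)
    return Spectrum(freqs=freqs, mean_mag=mag.mean(axis=0), sample_rate=sample_rate)


def bioacoustic_indices(spectrum: Spectrum) -> dict[str, float]:
    """Band sums of the mean spectrum over the four fixed frequency bands.

    A band lying entirely above Nyquist yields a missing value.
    """
    out = {}
    for i, (lo, hi) in enumerate(BIOACOUSTIC_BANDS, start=1):
        mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
        out[f"bioacoustic_index_{i}"] = float(spectrum.mean_mag[mask].sum()) if mask.any() else np.nan
    return out


def spectral_entropy(spectrum: Spectrum) -> float:
    """Shannon evenness of the normalized mean spectrum over its m bins."""
    p = spectrum.normalized
    if not p.sum() > 0:
        return np.nan
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


@dataclass
class HarmonicSet:
    """Frequencies of the ten tallest spectral peaks and the dominant peak.

    ``harmonics[i]`` is the (i+1)-th tallest strict local maximum of the mean
    spectrum, ties broken toward lower frequency; entries beyond the number
    of available peaks are NaN. ``dominant`` is the tallest peak strictly
    above 50 Hz (NaN if none).
    """

    harmonics: list[float] = field(default_factory=lambda: [np.nan] * 10)
    dominant: float = np.nan


def harmonic_peaks(spectrum: Spectrum) -> HarmonicSet:
    """Extract the top-10 spectral peaks by height and the dominant frequency."""
    mag = spectrum.mean_mag
    idx, _ = find_peaks(mag)  # strict local maxima, plateau-aware
    if idx.size == 0:
        return HarmonicSet()
    # sort by descending height; np.argsort is stable, so ascending-frequency
    # order in `idx` breaks ties toward the lower frequency
    order = idx[np.argsort(-mag[idx], kind="stable")]
    top = spectrum.freqs[order[:10]]
    harmonics = [float(f) for f in top] + [np.nan] * (10 - top.size)
    above = order[spectrum.freqs[order] > 50.0]
    dominant = float(spectrum.freqs[above[0]]) if above.size else np.nan
    return HarmonicSet(harmonics=harmonics, dominant=dominant)


# ---------------------------------------------------------------------------
# stage 7: fundamental frequency


@dataclass
class FundamentalEstimate:
    """Wingbeat period and frequency from the first autocorrelation peak."""

    period: float
    f0: float
    acf_peak_lag: int


def fundamental_frequency(
    x: np.ndarray,
    sample_rate: float,
    min_distance: int = ACF_MIN_PEAK_DISTANCE,
    min_height: float = ACF_MIN_PEAK_HEIGHT,
) -> FundamentalEstimate | None:
    """Estimate the wingbeat frequency of a detrended amplitude series.

    Peaks of the normalized autocorrelation are located with a minimum
    separation of ``min_distance`` samples; the fundamental is the inverse
    of the lag of the first (smallest-lag) peak. Half-period modulus peaks
    (negated troughs of the ACF) are excluded so that a pure tone yields its
    full period. Returns ``None`` (a missing feature) when no peak of
    normalized height ``min_height`` exists at a plausible lag, e.g. for
    noise-like input.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 or not np.any(x):
        return None
    # biased ACF via FFT, normalized to acf[0] = 1
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    acf = np.fft.irfft(np.abs(np.fft.rfft(x, nfft)) ** 2)[:n]
    if acf[0] <= 0:
        return None
    acf = acf / acf[0]
    idx, _ = find_peaks(acf, distance=min_distance, height=min_height)
    idx = idx[idx >= min_distance]
    if idx.size == 0:
        return None
    lag = int(idx[0])
    f0 = sample_rate / lag
    if not (F0_RANGE[0] <= f0 <= F0_RANGE[1]):
        return None
    return FundamentalEstimate(period=lag / sample_rate, f0=f0, acf_peak_lag=lag)


# ---------------------------------------------------------------------------
# the full per-recording pipeline


def _stage_236(x: np.ndarray, sample_rate: float, suffix: str) -> dict[str, float]:
    """Envelope + spectral features of a (possibly detrended) trimmed signal."""
    padded = zero_pad(x)
    amp_index, ht = envelope_stats(padded)
    spec = mean_spectrum(padded, sample_rate)
    feats = {f"amplitude_index{suffix}": amp_index, f"temporal_entropy{suffix}": ht}
    if spec.mean_mag.sum() > 0:
        feats.update({k + suffix: v for k, v in bioacoustic_indices(spec).items()})
        hf = spectral_entropy(spec)
        feats[f"spectral_entropy{suffix}"] = hf
        feats[f"acoustic_entropy{suffix}"] = ht * hf if np.isfinite(ht) and np.isfinite(hf) else np.nan
        peaks = harmonic_peaks(spec)
        feats[f"dominant_frequency{suffix}"] = peaks.dominant
        for i in range(1, 11):
            feats[f"harmonic_{i}{suffix}"] = peaks.harmonics[i - 1]
    return feats


def extract_features(
    rec: AudioRecording | TrimmedAudio,
    threshold: float | None = None,
    transform: bool = True,
) -> pd.Series:
    """Run the full seven-stage feature extraction on one recording.

    Accepts either a raw :class:`AudioRecording` (which is trimmed and
    background-filtered first) or an already prepared :class:`TrimmedAudio`.
    Returns a Series with exactly the 52 feature slots (NaN where a feature
    is undefined for this recording) plus ``id``/``species``/covariate/
    ``duration`` metadata. With ``transform=False`` the raw, untransformed
    values are returned instead.

    Raises
    ------
    NoSignalError
        If the recording never exceeds the background threshold.
    ValueError
        If the trimmed flight is shorter than the minimum length.
    """
    if isinstance(rec, TrimmedAudio):
        trimmed = rec
    else:
        kwargs = {} if threshold is None else {"threshold": threshold}
        trimmed = background_filter(trim_silence(rec, **kwargs))
    if min_length_filter(trimmed) is None:
        raise ValueError(
            f"recording {trimmed.parent_id!r}: trimmed length {trimmed.n} below minimum"
        )
    sr = trimmed.sample_rate
    x = trimmed.samples

    raw: dict[str, float] = dict.fromkeys(FEATURE_COLUMNS, np.nan)
    raw.update(amplitude_energy_stats(x))
    raw.update(_stage_236(x, sr, ""))

    try:
        trend = fit_trend(trimmed)
    except (DetrendError, ValueError) as exc:
        warnings.warn(f"recording {trimmed.parent_id!r}: detrending failed ({exc}); "
                      "trend-dependent features set to missing")
        trend = None
    if trend is not None:
        xg = trend.residuals
        raw["gam_amplitude_range"] = trend.gam_amplitude_range
        raw.update({k + "_g": v for k, v in amplitude_energy_stats(xg).items()})
        raw.update(_stage_236(xg, sr, "_g"))
        est = fundamental_frequency(xg, sr)
        if est is not None:
            raw["fundamental_frequency_g"] = est.f0

    values = {k: apply_transform(k, raw[k]) if transform else raw[k] for k in FEATURE_COLUMNS}
    meta = {
        "id": trimmed.parent_id,
        "species": trimmed.species,
        "temperature": trimmed.temperature,
        "humidity": trimmed.humidity,
        "duration": trimmed.duration,
    }
    return pd.Series({**meta, **values})


def extract_corpus(recordings, threshold: float | None = None, transform: bool = True):
    """Extract features for a batch of recordings.

    Returns ``(features, rejections)``: a DataFrame with one row per
    retained recording, and a DataFrame logging each rejected recording
    with the reason (``no_signal`` or ``too_short``).
    """
    from .preprocess import NoSignalError

    rows, rejected = [], []
    for rec in recordings:
        try:
            rows.append(extract_features(rec, threshold=threshold, transform=transform))
        except NoSignalError:
            rejected.append({"id": rec.id, "reason": "no_signal"})
        except ValueError:
            rejected.append({"id": rec.id, "reason": "too_short"})
    features = pd.DataFrame(rows).reset_index(drop=True) if rows else pd.DataFrame(
        columns=METADATA_COLUMNS + FEATURE_COLUMNS
    )
    return features, pd.DataFrame(rejected, columns=["id", "reason"])
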