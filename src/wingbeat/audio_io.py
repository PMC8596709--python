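"""Reading and writing wingbeat recordings.

Recordings are mono PCM WAV files. Raw integer samples are rescaled to
arbitrary amplitude units (AAU) by dividing by ``0.5 * 2**b`` for bit depth
``b``, which makes amplitudes comparable across recordings captured at
different bit depths: the full-scale negative integer maps to -1 AAU.

Species labels and environmental covariates travel in a sidecar CSV with
columns ``id, species, temperature, humidity``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioRecording",
    "AudioFormatError",
    "scale_to_aau",
    "load_recording",
    "save_recording",
    "load_sidecar",
    "load_corpus",
]


class AudioFormatError(ValueError):
    """Raised when a WAV file is not mono integer PCM."""


_DTYPE_BITS = {np.dtype(np.uint8): 8, np.dtype(np.int16): 16, np.dtype(np.int32): 32}


@dataclass
class AudioRecording:
    """A single flight recording in arbitrary amplitude units.

    Attributes
    ----------
    samples : ndarray
        Amplitude series in AAU, within [-1, 1].
    sample_rate : float
        Sampling rate in Hz.
    bit_depth : int
        Bit depth ``b`` of the source integers.
    species : str or None
        Species label; ``None`` for unlabelled / unknown recordings.
    temperature, humidity : float or None
        Environmental covariates at recording time (degC, %RH).
    id : str
        Opaque recording identifier (defaults to the file stem).
    """

    samples: np.ndarray
    sample_rate: float
    bit_depth: int
    species: str | None = None
    temperature: float | None = None
    humidity: float | None = None
    id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total recording length in seconds."""
        return self.n / self.sample_rate


def scale_to_aau(raw: np.ndarray, bit_depth: int) -> np.ndarray:
    """Convert signed integer PCM samples to arbitrary amplitude units.

    ``out[i] = raw[i] / (0.5 * 2**bit_depth)``, so the most negative
    representable integer maps to exactly -1.0.
    """
    if bit_depth <= 0:
        raise ValueError(f"bit_depth must be positive, got {bit_depth}")
    raw = np.asarray(raw)
    half_scale = 0.5 * 2.0**bit_depth
    if raw.size and (raw.max(initial=0) >= half_scale or raw.min(initial=0) < -half_scale):
        raise ValueError(f"raw values not representable in {bit_depth} signed bits")
    return raw / half_scale


def load_recording(path, metadata: pd.Series | dict | None = None) -> AudioRecording:
    """Load a mono PCM WAV file and scale it to AAU.

    Parameters
    ----------
    path : path-like
        WAV file (RIFF, integer PCM, single channel).
    metadata : mapping, optional
        Sidecar row carrying ``species``, ``temperature``, ``humidity``
        and optionally ``id``.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # unreadable container
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise AudioFormatError(f"{path} has {data.shape[1]} channels; mono PCM required")
    if data.dtype not in _DTYPE_BITS:
        raise AudioFormatError(f"{path} has dtype {data.dtype}; integer PCM required")
    if data.size == 0:
        raise AudioFormatError(f"{path} contains no samples")
    bits = _DTYPE_BITS[data.dtype]
    if data.dtype == np.uint8:  # RIFF stores 8-bit audio unsigned; re-centre
        data = data.astype(np.int16) - 128
    samples = scale_to_aau(data, bits)

    meta = dict(metadata) if metadata is not None else {}

    def _num(key):
        v = meta.get(key)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    return AudioRecording(
        samples=samples,
        sample_rate=float(rate),
        bit_depth=bits,
        species=meta.get("species"),
        temperature=_num("temperature"),
        humidity=_num("humidity"),
        id=str(meta.get("id", path.stem)),
    )


def save_recording(path, samples: np.ndarray, sample_rate: float, bit_depth: int = 16) -> None:
    """Quantize an AAU series to integer PCM and write a mono WAV file."""
    if bit_depth not in (8, 16, 32):
        raise ValueError("bit_depth must be 8, 16 or 32 for WAV output")
    half_scale = 0.5 * 2.0**bit_depth
    raw = np.clip(np.rint(np.asarray(samples, dtype=float) * half_scale), -half_scale, half_scale - 1)
    if bit_depth == 8:
        out = (raw + 128).astype(np.uint8)
    elif bit_depth == 16:
        out = raw.astype(np.int16)
    else:
        out = raw.astype(np.int32)
    wavfile.write(Path(path), int(sample_rate), out)


def load_sidecar(path) -> pd.DataFrame:
    """Read the label/covariate sidecar CSV, indexed by recording id."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"sidecar {path} lacks an 'id' column")
    return df.set_index("id", drop=False)


def load_corpus(wav_dir, sidecar_path=None):
    """Yield :class:`AudioRecording` objects for every WAV file in a directory.

    Files that fail to parse are reported as ``(path, exception)`` through the
    warning system and skipped, so one corrupt file does not abort a batch.
    """
    wav_dir = Path(wav_dir)
    sidecar = load_sidecar(sidecar_path) if sidecar_path is not None else None
    for path in sorted(wav_dir.glob("*.wav")):
        row = None
        if sidecar is not None and path.stem in sidecar.index:
            row = sidecar.loc[path.stem]
        try:
            yield load_recording(path, row)
        except AudioFormatError as exc:
            warnings.warn(f"skipping {path.name}: {exc}")
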