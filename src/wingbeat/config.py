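"""Declarative pipeline configuration.

All defaults are the pipeline's published constants: trim threshold 0.0061
AAU with a 3x IQR temporal-outlier fence, a 128-sample minimum length, a
128-sample STFT window, zero-padding to 8192 samples, spline basis
``max(10, n/50)``, a 10-sample minimum ACF peak separation, and the
balanced-forest preset (1000 trees, 10 variables per split, the tuned
per-class bootstrap sizes). A config round-trips losslessly through JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    threshold: float = 0.0061          # AAU
    iqr_multiplier: float = 3.0
    min_length: int = 128              # samples
    stft_window: int = 128             # samples
    pad_length: int = 8192             # samples
    gam_basis_floor: int = 10
    gam_basis_divisor: int = 50        # k = max(floor, n // divisor)
    acf_min_distance: int = 10         # samples
    acf_min_height: float = 0.3
    n_trees: int = 1000
    vars_per_split: int = 10
    train_fraction: float = 0.7
    classifier_preset: str = "impute"  # "impute" | "omit"
    seed: int = 0
    class_sample_sizes: dict | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        """Load from a JSON string or file path; unknown keys are rejected."""
        text = source
        p = Path(str(source))
        if p.exists():
            text = p.read_text()
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
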