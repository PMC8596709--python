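"""End-to-end batch orchestration: WAV directory -> features -> classifier."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .audio_io import load_corpus
from .classify import evaluate, impute_median, scaled_sample_sizes, split_train_validation, train_balanced_rf
from .config import PipelineConfig
from .features import FEATURE_COLUMNS, METADATA_COLUMNS, extract_features
from .preprocess import NoSignalError, trim_silence

log = logging.getLogger("wingbeat")

__all__ = ["extract_directory", "run_pipeline"]


def extract_directory(wav_dir, sidecar=None, config: PipelineConfig | None = None):
    """Trim, filter and extract features for every WAV file in a directory.

    Returns ``(features, trim_report)``. The trim report has one row per
    input recording: trim bounds, duration and whether it was retained
    (rejections are normal outcomes, counted not raised).
    """
    config = config or PipelineConfig()
    rows, report = [], []
    for rec in load_corpus(wav_dir, sidecar):
        entry = {"id": rec.id, "start": None, "end": None, "duration": None, "retained": False,
                 "reason": ""}
        try:
            trimmed = trim_silence(rec, config.threshold, config.iqr_multiplier)
            entry.update(start=trimmed.start_index, end=trimmed.end_index,
                         duration=trimmed.duration)
            if trimmed.n < config.min_length:
                entry["reason"] = "too_short"
            else:
                rows.append(extract_features(rec, threshold=config.threshold))
                entry.update(retained=True)
        except NoSignalError:
            entry["reason"] = "no_signal"
        except ValueError as exc:
            entry["reason"] = f"error: {exc}"
        report.append(entry)
        log.info("processed %s (%s)", rec.id, "ok" if entry["retained"] else entry["reason"])
    features = pd.DataFrame(rows).reset_index(drop=True) if rows else pd.DataFrame(
        columns=METADATA_COLUMNS + FEATURE_COLUMNS)
    return features, pd.DataFrame(report)


def run_pipeline(wav_dir, sidecar, out_dir, config: PipelineConfig | None = None):
    """Full run: extract, split, impute, train, evaluate; persist artifacts.

    Writes ``trim_report.csv``, ``features.csv``, ``report.json`` and a run
    ``manifest.json`` (config hash + package version) under ``out_dir``.
    Returns the classification report.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    features, trim_report = extract_directory(wav_dir, sidecar, config)
    trim_report.to_csv(out_dir / "trim_report.csv", index=False)
    features.to_csv(out_dir / "features.csv", index=False)
    n_removed = int((~trim_report["retained"]).sum()) if len(trim_report) else 0
    log.info("%d removed, %d retained", n_removed, len(features))

    report = None
    if len(features) and features["species"].nunique() >= 2:
        train, validation = split_train_validation(features, config.train_fraction, config.seed)
        train, validation = impute_median(train, validation)
        sizes = config.class_sample_sizes or scaled_sample_sizes(train["species"])
        model = train_balanced_rf(train, sizes, config.n_trees, config.vars_per_split, config.seed)
        report = evaluate(model, validation)
        summary = {
            "n_recordings": int(len(features)),
            "n_removed": n_removed,
            "oob_error": model.oob_error_,
            "validation_accuracy": report.accuracy,
            "per_class": report.per_class.to_dict(orient="index"),
            "confusion": report.confusion.to_dict(),
        }
        (out_dir / "report.json").write_text(json.dumps(summary, indent=2, default=float))
    else:
        log.warning("no classifiable data extracted; classification skipped")

    cfg_text = config.to_json()
    manifest = {
        "version": __version__,
        "config": json.loads(cfg_text),
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "inputs": str(wav_dir),
        "n_features": len(FEATURE_COLUMNS),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def setup_logging(verbose: bool = True):
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
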