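"""The eight feature subsets used for classifier comparison.

Sets 1-5 are defined structurally from the feature schema (all features;
raw-only; detrended-only; harmonic peaks; harmonics plus frequency-spectrum
indices). Sets 6-8 are data-driven minimal sets: hierarchical clustering
with complete linkage on ``1 - r`` (Pearson correlation of standardized
features) cut into 3, 5 and 14 clusters, keeping the feature closest to
each cluster centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .classify import evaluate, impute_median, scaled_sample_sizes, split_train_validation, train_balanced_rf
from .features import FEATURE_COLUMNS, FEATURE_SCHEMA

__all__ = ["FeatureSetDefinition", "structural_sets", "cluster_representatives",
           "all_feature_sets", "compare_feature_sets"]


@dataclass(frozen=True)
class FeatureSetDefinition:
    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        unknown = set(self.members) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValueError(f"feature set {self.name!r} references unknown features: {sorted(unknown)}")


_FREQ_INDEX_KINDS = {"bioacoustic", "spectral_entropy", "acoustic_entropy", "dominant", "fundamental"}


def structural_sets() -> dict[str, FeatureSetDefinition]:
    """Sets 1-5, derived from the schema so they cannot drift from it."""
    all_keys = tuple(FEATURE_COLUMNS)
    raw = tuple(f.key for f in FEATURE_SCHEMA if not f.detrended)
    detrended = tuple(f.key for f in FEATURE_SCHEMA if f.detrended)
    harmonics = tuple(f.key for f in FEATURE_SCHEMA if f.kind == "harmonic")
    freq_indices = tuple(f.key for f in FEATURE_SCHEMA if f.kind in _FREQ_INDEX_KINDS)
    return {
        "set1_all": FeatureSetDefinition("set1_all", all_keys),
        "set2_raw": FeatureSetDefinition("set2_raw", raw),
        "set3_detrended": FeatureSetDefinition("set3_detrended", detrended),
        "set4_harmonics": FeatureSetDefinition("set4_harmonics", harmonics),
        "set5_harmonics_plus_indices": FeatureSetDefinition(
            "set5_harmonics_plus_indices", harmonics + freq_indices
        ),
    }


def cluster_representatives(features: pd.DataFrame, k: int) -> FeatureSetDefinition:
    """Representative features from correlation clustering.

    Features are standardized (zero mean, unit variance); the distance
    between two features is ``1 - r`` with ``r`` their pairwise-complete
    Pearson correlation. Complete-linkage clustering is cut into ``k``
    groups and each group's representative is the member closest (Euclidean
    over observations, after mean-imputing residual missing values) to the
    group's centroid; ties break alphabetically. Constant or empty features
    are excluded with a warning.
    """
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    table = features[cols]
    sd = table.std()
    dead = [c for c in cols if not np.isfinite(sd[c]) or sd[c] == 0]
    if dead:
        warnings.warn(f"constant/empty features excluded from clustering: {dead}")
        table = table.drop(columns=dead)
    if table.shape[1] < k:
        raise ValueError(f"need at least k={k} usable features, have {table.shape[1]}")
    z = (table - table.mean()) / table.std()
    corr = z.corr(min_periods=2)  # pairwise-complete Pearson r
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    tree = linkage(squareform(dist, checks=False), method="complete")
    groups = fcluster(tree, t=k, criterion="maxclust")

    zf = z.fillna(0.0)  # standardized scale: 0 is the column mean
    reps = []
    for gid in np.unique(groups):
        members = sorted(z.columns[groups == gid])  # alphabetical tie-break
        centroid = zf[members].mean(axis=1)
        dists = [np.linalg.norm(zf[m] - centroid) for m in members]
        reps.append(members[int(np.argmin(dists))])
    return FeatureSetDefinition(f"set_cluster_{k}", tuple(sorted(reps)))


def all_feature_sets(features: pd.DataFrame) -> dict[str, FeatureSetDefinition]:
    """All eight sets: the five structural ones plus k = 3, 5, 14 cluster sets."""
    sets = structural_sets()
    for k, name in ((3, "set6_cluster3"), (5, "set7_cluster5"), (14, "set8_cluster14")):
        rep = cluster_representatives(features, k)
        sets[name] = FeatureSetDefinition(name, rep.members)
    return sets


def compare_feature_sets(features: pd.DataFrame, n_estimators: int = 1000,
                         max_features: int = 10, fraction: float = 0.7, seed: int = 0,
                         sets: dict | None = None) -> pd.DataFrame:
    """Balanced-RF accuracy for every feature set under both missing policies.

    One forest per set per policy (``impute``: training-median imputation;
    ``omit``: drop rows with any missing value in the set). Returns a table
    with one row per (set, policy): overall OOB error, validation accuracy
    and the member count.
    """
    sets = sets or all_feature_sets(features)
    train, validation = split_train_validation(features, fraction, seed)
    rows = []
    for name, definition in sets.items():
        cols = list(definition.members)
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise ValueError(f"feature set {name!r} references absent columns: {missing}")
        mf = min(max_features, len(cols))
        for policy in ("impute", "omit"):
            if policy == "impute":
                tr, va = impute_median(train, validation, columns=cols)
            else:
                tr = train.dropna(subset=cols)
                va = validation.dropna(subset=cols)
            if tr["species"].nunique() < 2 or len(va) == 0:
                warnings.warn(f"{name}/{policy}: not enough data after filtering; skipped")
                continue
            model = train_balanced_rf(tr, scaled_sample_sizes(tr["species"]),
                                      n_estimators, mf, seed, feature_columns=cols)
            report = evaluate(model, va, feature_columns=cols)
            rows.append({
                "set": name, "policy": policy, "n_features": len(cols),
                "oob_error": model.oob_error_, "validation_accuracy": report.accuracy,
                "n_train": len(tr), "n_validation": len(va),
            })
    return pd.DataFrame(rows)
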