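"""Balanced random-forest species classification.

The corpus is heavily imbalanced (the commonest species outnumbers the
rarest ~30:1), so each tree of the forest is grown on a bootstrap that
draws a *fixed, configured* number of observations (with replacement) from
every class rather than a uniform bootstrap of the pooled data. Class
probabilities are vote fractions across trees; out-of-bag (OOB) estimates
use only the trees for which an observation was not drawn.

Per-class performance is reported as the true positive rate (TPR), true
negative rate (TNR), weighted accuracy ``wAcc = 0.5*TNR + 0.5*TPR`` and
class error ``clErr = 1 - TPR``. Feature importance is the permutation mean
decrease in accuracy (per class, averaged for the overall measure) and the
mean decrease in Gini impurity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_COLUMNS

__all__ = [
    "BalancedRandomForestClassifier",
    "ClassificationReport",
    "ImportanceTable",
    "STUDY_SAMPLE_SIZES",
    "split_train_validation",
    "impute_median",
    "scaled_sample_sizes",
    "train_balanced_rf",
    "evaluate",
    "importance",
    "leave_one_species_out",
    "subtask_classify",
    "SUBTASKS",
]

#: Tuned per-tree class sample sizes from the study, by missing-value policy.
STUDY_SAMPLE_SIZES = {
    "impute": {
        "A_fabae": 75, "P_chrysocephala": 75, "S_avenae": 120,
        "P_testudinaceus": 50, "B_aeneus": 120, "D_platanoidis": 300,
    },
    "omit": {
        "A_fabae": 60, "P_chrysocephala": 60, "S_avenae": 96,
        "P_testudinaceus": 40, "B_aeneus": 96, "D_platanoidis": 240,
    },
}


class BalancedRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest with fixed per-class bootstrap counts per tree.

    Parameters
    ----------
    n_estimators : int
        Number of trees (study default 1000).
    max_features : int or "sqrt"
        Variables tried at each split (study default 10).
    class_sample_sizes : dict, float, or None
        Per-tree bootstrap count for each class. A dict maps class label to
        count; a float in (0, 1] draws that fraction of the *smallest*
        class size from every class (balanced); None uses the smallest
        class size for every class.
    random_state : int
        Seed for resampling and tree growth; mandatory for reproducibility.

    Attributes
    ----------
    classes_ : ndarray of class labels.
    estimators_ : list of fitted decision trees.
    estimators_samples_ : list of bootstrap index arrays, one per tree.
    oob_decision_function_ : (n_samples, n_classes) OOB vote fractions.
    oob_score_ : overall OOB accuracy.
    oob_error_ : ``1 - oob_score_``.
    feature_names_in_ : column names when fitted from a DataFrame.
    """

    def __init__(
        self,
        n_estimators: int = 1000,
        max_features: int | str = 10,
        class_sample_sizes: dict | float | None = None,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.class_sample_sizes = class_sample_sizes
        self.random_state = random_state

    def _resolve_sizes(self, y: np.ndarray) -> dict:
        classes, counts = np.unique(y, return_counts=True)
        sizes = self.class_sample_sizes
        if isinstance(sizes, dict):
            missing = [c for c in classes if c not in sizes]
            if missing:
                raise ValueError(f"no sample size configured for classes {missing}")
            return {c: int(sizes[c]) for c in classes}
        base = counts.min()
        frac = 1.0 if sizes is None else float(sizes)
        if not 0 < frac <= 1:
            raise ValueError("fractional class_sample_sizes must lie in (0, 1]")
        n = max(int(round(base * frac)), 1)
        return {c: n for c in classes}

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] == 0:
            raise ValueError("X must be 2-D with one label per row")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute or omit them first")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        sizes = self._resolve_sizes(y)
        self.class_sample_sizes_ = sizes
        y_enc = np.searchsorted(self.classes_, y)
        class_indices = [np.flatnonzero(y_enc == k) for k in range(self.classes_.size)]

        max_feat = self.max_features
        if isinstance(max_feat, int):
            max_feat = min(max_feat, X.shape[1])

        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        votes = np.zeros((n, self.classes_.size))
        self.estimators_ = []
        self.estimators_samples_ = []
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.n_estimators)
        for seed in tree_seeds:
            boot = np.concatenate(
                [rng.choice(idx, size=sizes[self.classes_[k]], replace=True)
                 for k, idx in enumerate(class_indices)]
            )
            tree = DecisionTreeClassifier(max_features=max_feat, random_state=int(seed))
            tree.fit(X[boot], y_enc[boot])
            self.estimators_.append(tree)
            self.estimators_samples_.append(boot)
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            if oob.any():
                # every class appears in every bootstrap, so tree labels are
                # the full encoded label set
                pred = tree.predict(X[oob])
                votes[np.flatnonzero(oob), pred] += 1

        with np.errstate(invalid="ignore", divide="ignore"):
            self.oob_decision_function_ = votes / votes.sum(axis=1, keepdims=True)
        seen = votes.sum(axis=1) > 0
        if not seen.all():
            warnings.warn(f"{(~seen).sum()} observations were never out of bag")
        oob_pred = self.classes_[np.argmax(votes, axis=1)]
        self.oob_score_ = float(np.mean(oob_pred[seen] == y[seen])) if seen.any() else np.nan
        self.oob_error_ = 1.0 - self.oob_score_
        self._X_fit_shape = X.shape
        return self

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict_proba(self, X) -> np.ndarray:
        """Class-probability estimates as vote fractions across trees."""
        check_is_fitted(self, "estimators_")
        X = self._as_array(X)
        votes = np.zeros((X.shape[0], self.classes_.size))
        for tree in self.estimators_:
            votes[np.arange(X.shape[0]), tree.predict(X)] += 1
        return votes / len(self.estimators_)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# data handling


def split_train_validation(features: pd.DataFrame, fraction: float = 0.7, seed: int = 0):
    """Random 70:30 split by recording (plain, unstratified)."""
    if len(features) == 0:
        raise ValueError("empty feature table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(features))
    n_train = int(round(fraction * len(features)))
    if n_train == len(features):
        warnings.warn("fraction leaves an empty validation set")
    train = features.iloc[np.sort(order[:n_train])]
    validation = features.iloc[np.sort(order[n_train:])]
    return train, validation


def impute_median(train: pd.DataFrame, validation: pd.DataFrame | None = None, columns=None):
    """Replace missing feature values by the *training* medians.

    Validation rows are imputed with training medians too (never their
    own), preventing information leakage. Features that are entirely
    missing in training are dropped from both tables with a warning.
    """
    columns = [c for c in (columns or FEATURE_COLUMNS) if c in train.columns]
    medians = train[columns].median()
    dead = medians.index[medians.isna()].tolist()
    if dead:
        warnings.warn(f"features entirely missing in training dropped: {dead}")
        train = train.drop(columns=dead)
        if validation is not None:
            validation = validation.drop(columns=[c for c in dead if c in validation.columns])
        medians = medians.drop(dead)
    train = train.copy()
    train[medians.index] = train[medians.index].fillna(medians)
    if validation is None:
        return train
    validation = validation.copy()
    validation[medians.index] = validation[medians.index].fillna(medians)
    return train, validation


def scaled_sample_sizes(y, preset: dict | None = None) -> dict:
    """Adapt the study's per-class bootstrap sizes to a (smaller) corpus.

    Each class gets ``min(its size, round(preset_ratio * n_class))`` where
    the preset ratio is the study size divided by the study class count;
    classes absent from the preset default to 60% of their size.
    """
    preset = preset or STUDY_SAMPLE_SIZES["impute"]
    study_counts = {
        "A_fabae": 161, "P_chrysocephala": 186, "S_avenae": 274,
        "P_testudinaceus": 113, "B_aeneus": 848, "D_platanoidis": 3323,
    }
    classes, counts = np.unique(np.asarray(y), return_counts=True)
    sizes = {}
    for c, n in zip(classes, counts):
        if c in preset and c in study_counts:
            ratio = preset[c] / study_counts[c]
        else:
            ratio = 0.6
        sizes[c] = max(min(int(round(ratio * n)), int(n)), 1)
    return sizes


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ClassificationReport:
    """Confusion matrix and the per-class TPR/TNR/wAcc/clErr summary."""

    confusion: pd.DataFrame
    per_class: pd.DataFrame
    accuracy: float
    oob_error: float | None = None
    class_probabilities: pd.DataFrame | None = None
    max_class_probability: pd.Series | None = None


def _per_class_metrics(confusion: pd.DataFrame) -> pd.DataFrame:
    total = confusion.to_numpy().sum()
    rows = {}
    for c in confusion.index:
        tp = confusion.loc[c, c]
        fn = confusion.loc[c].sum() - tp
        fp = confusion[c].sum() - tp
        tn = total - tp - fn - fp
        tpr = tp / (tp + fn) if tp + fn > 0 else np.nan
        tnr = tn / (tn + fp) if tn + fp > 0 else np.nan
        rows[c] = {"TPR": tpr, "TNR": tnr, "wAcc": 0.5 * tnr + 0.5 * tpr, "clErr": 1 - tpr}
    return pd.DataFrame(rows).T


def evaluate(model: BalancedRandomForestClassifier, validation: pd.DataFrame,
             feature_columns=None) -> ClassificationReport:
    """Score a fitted forest on a validation table with labels in ``species``.

    Classes present in validation but unknown to the model are kept in the
    confusion matrix (all their predictions count as errors) and flagged.
    """
    cols = [c for c in (feature_columns or FEATURE_COLUMNS) if c in validation.columns]
    y = validation["species"].to_numpy()
    proba = model.predict_proba(validation[cols])
    pred = model.classes_[np.argmax(proba, axis=1)]
    labels = list(model.classes_)
    unknown = sorted(set(y) - set(labels))
    if unknown:
        warnings.warn(f"classes absent from the model counted as always wrong: {unknown}")
    all_labels = labels + unknown
    confusion = pd.DataFrame(0, index=all_labels, columns=all_labels, dtype=int)
    for t, p in zip(y, pred):
        confusion.loc[t, p] += 1
    probs = pd.DataFrame(proba, columns=labels, index=validation.index)
    return ClassificationReport(
        confusion=confusion,
        per_class=_per_class_metrics(confusion),
        accuracy=float(np.mean(pred == y)),
        oob_error=getattr(model, "oob_error_", None),
        class_probabilities=probs,
        max_class_probability=probs.max(axis=1),
    )


def train_balanced_rf(train: pd.DataFrame, class_sample_sizes=None, n_estimators: int = 1000,
                      max_features: int = 10, seed: int = 0, feature_columns=None,
                      ) -> BalancedRandomForestClassifier:
    """Fit a balanced forest on a feature table with labels in ``species``."""
    cols = [c for c in (feature_columns or FEATURE_COLUMNS) if c in train.columns]
    if class_sample_sizes is None:
        class_sample_sizes = scaled_sample_sizes(train["species"])
    model = BalancedRandomForestClassifier(
        n_estimators=n_estimators, max_features=max_features,
        class_sample_sizes=class_sample_sizes, random_state=seed,
    )
    return model.fit(train[cols], train["species"].to_numpy())


# ---------------------------------------------------------------------------
# importance


@dataclass
class ImportanceTable:
    """Permutation (mean decrease in accuracy) and Gini importances.

    ``mda`` columns: one per class plus ``overall`` (the mean of the
    per-class columns). ``gini``: mean decrease in node impurity per
    feature, averaged over trees.
    """

    mda: pd.DataFrame
    gini: pd.Series


def importance(model: BalancedRandomForestClassifier, X, y, seed: int = 0) -> ImportanceTable:
    """Permutation importance over each tree's out-of-bag samples.

    For every tree and feature, the feature column is permuted among the
    tree's OOB rows and the decrease in OOB accuracy recorded — overall
    accuracy per class, then averaged across trees; the overall MDA is the
    unweighted mean of the per-class MDAs.
    """
    check_is_fitted(model, "estimators_")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X[list(getattr(model, "feature_names_in_", X.columns))].to_numpy(dtype=float)
        names = list(getattr(model, "feature_names_in_", names))
    else:
        X = np.asarray(X, dtype=float)
        names = [f"feature_{j}" for j in range(X.shape[1])]
    y_enc = np.searchsorted(model.classes_, np.asarray(y))
    n, p = X.shape
    k = model.classes_.size
    rng = np.random.default_rng(seed)
    # accumulated per-class accuracy decreases, and tree counts per class
    dec = np.zeros((p, k))
    tree_counts = np.zeros(k)
    gini = np.zeros(p)
    for tree, boot in zip(model.estimators_, model.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        gini += tree.tree_.compute_feature_importances(normalize=False)
        if not oob.any():
            continue
        rows = np.flatnonzero(oob)
        Xo, yo = X[rows], y_enc[rows]
        base_pred = tree.predict(Xo)
        class_present = np.zeros(k, dtype=bool)
        base_acc = np.zeros(k)
        for c in range(k):
            m = yo == c
            if m.any():
                class_present[c] = True
                base_acc[c] = np.mean(base_pred[m] == c)
        tree_counts += class_present
        for j in range(p):
            saved = Xo[:, j].copy()
            Xo[:, j] = rng.permutation(saved)
            perm_pred = tree.predict(Xo)
            Xo[:, j] = saved
            for c in np.flatnonzero(class_present):
                m = yo == c
                dec[j, c] += base_acc[c] - np.mean(perm_pred[m] == c)
    with np.errstate(invalid="ignore", divide="ignore"):
        mda_per_class = dec / tree_counts
    mda = pd.DataFrame(mda_per_class, index=names, columns=list(model.classes_))
    mda["overall"] = mda[list(model.classes_)].mean(axis=1)
    gini_series = pd.Series(gini / len(model.estimators_), index=names, name="gini")
    return ImportanceTable(mda=mda, gini=gini_series)


# ---------------------------------------------------------------------------
# protocols


def leave_one_species_out(features: pd.DataFrame, excluded: str, class_sample_sizes=None,
                          n_estimators: int = 1000, max_features: int = 10, seed: int = 0,
                          feature_columns=None):
    """Train without one species and profile how its recordings are absorbed.

    The excluded species' observations form the validation set; the return
    value is ``(allocation, max_probabilities, model)`` where ``allocation``
    maps each remaining class to the proportion of excluded recordings
    assigned to it (summing to 1).
    """
    mask = features["species"] == excluded
    if not mask.any():
        raise ValueError(f"species {excluded!r} not present in the data")
    train = features[~mask]
    held_out = features[mask]
    cols = [c for c in (feature_columns or FEATURE_COLUMNS) if c in features.columns]
    train, held_out = impute_median(train, held_out, columns=cols)
    if class_sample_sizes is None:
        class_sample_sizes = scaled_sample_sizes(train["species"])
    model = train_balanced_rf(train, class_sample_sizes, n_estimators, max_features, seed,
                              feature_columns=cols)
    proba = model.predict_proba(held_out[cols])
    pred = model.classes_[np.argmax(proba, axis=1)]
    allocation = pd.Series(
        [np.mean(pred == c) for c in model.classes_], index=list(model.classes_),
        name=f"allocation_of_{excluded}",
    )
    return allocation, pd.Series(proba.max(axis=1), index=held_out.index), model


#: Label mappings of the sub-classification tasks (None = use species labels).
SUBTASKS = {
    "all-species": None,
    "aphid-vs-beetle": {
        "A_fabae": "Hemiptera", "S_avenae": "Hemiptera", "P_testudinaceus": "Hemiptera",
        "D_platanoidis": "Hemiptera", "M_persicae": "Hemiptera", "R_padi": "Hemiptera",
        "P_chrysocephala": "Coleoptera", "B_aeneus": "Coleoptera",
    },
    "within-aphids": ["A_fabae", "S_avenae", "P_testudinaceus", "D_platanoidis"],
    "within-beetles": ["P_chrysocephala", "B_aeneus"],
}


def subtask_classify(features: pd.DataFrame, task: str = "all-species", fraction: float = 0.7,
                     n_estimators: int = 1000, max_features: int = 10, seed: int = 0,
                     class_sample_sizes=None, feature_columns=None):
    """Run one of the study's classification tasks with a fresh 70:30 split.

    ``task`` is one of ``all-species``, ``aphid-vs-beetle``,
    ``within-aphids`` (restrict to aphid species), ``within-beetles``.
    Returns ``(report, importance_table, model)``.
    """
    if task not in SUBTASKS:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(SUBTASKS)}")
    spec = SUBTASKS[task]
    data = features.copy()
    if isinstance(spec, dict):
        known = data["species"].isin(spec)
        data = data[known]
        data["species"] = data["species"].map(spec)
    elif isinstance(spec, list):
        data = data[data["species"].isin(spec)]
    if data["species"].nunique() < 2:
        raise ValueError(f"task {task!r} leaves fewer than two classes")
    cols = [c for c in (feature_columns or FEATURE_COLUMNS) if c in data.columns]
    train, validation = split_train_validation(data, fraction, seed)
    train, validation = impute_median(train, validation, columns=cols)
    if class_sample_sizes is None:
        class_sample_sizes = scaled_sample_sizes(train["species"])
    model = train_balanced_rf(train, class_sample_sizes, n_estimators, max_features, seed,
                              feature_columns=cols)
    report = evaluate(model, validation, feature_columns=cols)
    imp = importance(model, train[cols], train["species"].to_numpy(), seed=seed)
    return report, imp, model
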