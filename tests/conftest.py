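import numpy as np
import pandas as pd
import pytest

from wingbeat.classify import impute_median
from wingbeat.features import extract_corpus
from wingbeat.simulate import (
    SimulationConfig,
    separable_templates,
    simulate_corpus,
    study_templates,
)


@pytest.fixture(scope="session")
def separable_corpus():
    """Six well-separated classes (fundamentals 10 Hz apart, sd 3 Hz).

    Returns (features, truth, recordings); shared across the suite because
    feature extraction for 360 recordings is the expensive step.
    """
    templates = separable_templates()
    config = SimulationConfig(
        templates=templates, counts={t.name: 60 for t in templates}, seed=20260927
    )
    recordings, truth = simulate_corpus(config)
    features, rejected = extract_corpus(recordings)
    assert len(rejected) == 0
    return features, truth.reset_index(drop=True), recordings


@pytest.fixture(scope="session")
def separable_features(separable_corpus):
    """Median-imputed feature table of the separable corpus."""
    features, _, _ = separable_corpus
    return impute_median(features)


@pytest.fixture(scope="session")
def study_corpus():
    """A small corpus from the six study-species templates (with covariates)."""
    templates = study_templates()
    config = SimulationConfig(
        templates=templates, counts={t.name: 30 for t in templates}, seed=1234
    )
    recordings, truth = simulate_corpus(config)
    features, _ = extract_corpus(recordings)
    return features, truth.reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def gaussian_species_table():
    """Feature-space stand-in corpus: three separable Gaussian species.

    Synthetic by construction (no audio involved); used where only the
    classifier machinery is under test.
    """
    rng = np.random.default_rng(42)
    from wingbeat.features import FEATURE_COLUMNS

    frames = []
    for i, name in enumerate(["sp_a", "sp_b", "sp_c"]):
        X = rng.normal(0.0, 1.0, size=(120, 52))
        X[:, :6] += 4.0 * i
        df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        df["species"] = name
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table["id"] = [f"r{i}" for i in range(len(table))]
    return table
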