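import numpy as np
import pytest

from chemxplain import (
    CorpusIndex,
    SyntheticSpec,
    fit_surrogate,
    generate_synthetic,
    generate_synthetic_corpus,
)


@pytest.fixture(scope="session")
def regression_table():
    """Noiseless planted linear table: y = 2*x1 - 1.5*x4 + x6."""
    spec = SyntheticSpec(
        n=400,
        d=8,
        planted_support=[1, 4, 6],
        planted_weights=[2.0, -1.5, 1.0],
        noise_sd=0.0,
        task_kind="regression",
        seed=11,
    )
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def classification_table():
    spec = SyntheticSpec(
        n=400,
        d=6,
        planted_support=[0, 3],
        planted_weights=[3.0, -3.0],
        task_kind="classification",
        seed=5,
    )
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def fitted_regression(regression_table):
    model, report = fit_surrogate(regression_table, split_seed=1)
    return model, report


@pytest.fixture(scope="session")
def fitted_classification(classification_table):
    model, report = fit_surrogate(classification_table, split_seed=1)
    return model, report


@pytest.fixture(scope="session")
def toy_corpus_dir(tmp_path_factory):
    """Synthetic literature corpus with one directional claim per planted
    feature plus off-topic filler."""
    d = tmp_path_factory.mktemp("corpus")
    generate_synthetic_corpus(
        [("f1", "positive"), ("f4", "negative"), ("f6", "positive")],
        "solubility",
        d,
        n_filler=2,
        seed=3,
    )
    return d


@pytest.fixture(scope="session")
def toy_index(toy_corpus_dir):
    return CorpusIndex.from_directory(toy_corpus_dir)


class LinearMarginModel:
    """Tiny stand-in exposing predict_margin for attribution oracles."""

    def __init__(self, fn, d):
        self.fn = fn
        self.feature_names_ = [f"f{j}" for j in range(d)]

    def predict_margin(self, rows):
        rows = np.asarray(rows, dtype=float)
        return np.apply_along_axis(self.fn, 1, rows).astype(float)


@pytest.fixture
def margin_model_factory():
    return LinearMarginModel
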