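import numpy as np
import pytest

from leakage_lab import (
    ClassifierSpec,
    FeatureMatrix,
    GaussianGridSpec,
    VoteParams,
    generate_gaussian_features,
    make_cv_plan,
)


@pytest.fixture(scope="session")
def small_null_matrix() -> FeatureMatrix:
    """300 no-signal features, 20 samples per class."""
    spec = GaussianGridSpec(n_features=300, n_per_class=20, per_class_draw=False, seed=101)
    return generate_gaussian_features(spec)


@pytest.fixture(scope="session")
def planted_matrix() -> FeatureMatrix:
    """Noise features plus one overwhelming feature (class means 0 vs 5, SD 0.1)."""
    rng = np.random.default_rng(7)
    n, d = 20, 50
    values = rng.normal(0.0, 1.0, size=(2 * n, d))
    values[:n, 0] = rng.normal(0.0, 0.1, size=n)
    values[n:, 0] = rng.normal(5.0, 0.1, size=n)
    return FeatureMatrix(
        values,
        np.repeat([0, 1], n),
        [f"f{i}" for i in range(d)],
        [f"s{i}" for i in range(2 * n)],
    )


@pytest.fixture()
def fast_vote_params() -> VoteParams:
    return VoteParams(n_reps=30, seed=11)


@pytest.fixture()
def small_plan(small_null_matrix):
    return make_cv_plan(small_null_matrix.labels, n_folds=5, n_repetitions=2, seed=5)


@pytest.fixture(scope="session")
def both_classifiers():
    return (ClassifierSpec("svm"), ClassifierSpec("rlda"))
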