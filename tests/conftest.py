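import numpy as np
import pytest

from prforest import (
    Hyperparameters,
    LabelPolicy,
    SyntheticConfig,
    UncertainDataset,
    apply_policy,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default 142-subject cohort (seed 0)."""
    return generate_cohort(SyntheticConfig(), seed=0)


@pytest.fixture(scope="session")
def naive_dataset(default_cohort):
    return apply_policy(default_cohort.dataset, LabelPolicy("naive"))


@pytest.fixture(scope="session")
def probabilistic_dataset(default_cohort):
    return apply_policy(default_cohort.dataset, LabelPolicy("probabilistic"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_dataset(X, labels, *, DX=None, PMF=None, confirmed=None, class_names=("a", "b")):
    """Terse constructor for hand-built test datasets."""
    return UncertainDataset(
        np.asarray(X, dtype=float),
        np.asarray(labels, dtype=int),
        DX=None if DX is None else np.asarray(DX, dtype=float),
        PMF=None if PMF is None else np.asarray(PMF, dtype=float),
        confirmed=confirmed,
        class_names=class_names,
    )


@pytest.fixture()
def separable_1d():
    """Four points on one feature, perfectly separable at 2.5."""
    return make_dataset([[1.0], [2.0], [3.0], [4.0]], [0, 0, 1, 1])


@pytest.fixture(scope="session")
def small_hp():
    return Hyperparameters(n_trees=5, seed=7)
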