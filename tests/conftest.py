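import warnings

import numpy as np
import pytest

from actitag import evaluate as ev
from actitag import features as ft
from actitag import synthdata as sd
from actitag.tags import TAG_ORDER


@pytest.fixture(autouse=True)
def _quiet_sklearn():
    # zero-variance descriptors inside tiny CV folds trip benign NB warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.filterwarnings("ignore", message="The least populated class")
        yield


@pytest.fixture(scope="session")
def mini_cohort():
    """3 patients + 3 controls; small enough for per-module tests."""
    return sd.generate_cohort(3, 3, master_seed=11)


@pytest.fixture(scope="session")
def mini_features(mini_cohort):
    return ft.cohort_feature_table(mini_cohort)


@pytest.fixture(scope="session")
def separable_clusters():
    """One tight Gaussian cluster per tag: trivially separable 10-class data."""
    rng = np.random.default_rng(3)
    centers = rng.normal(size=(10, 12)) * 5
    X, y = [], []
    for i, tag in enumerate(TAG_ORDER):
        X.append(centers[i] + rng.normal(0, 0.01, size=(25, 12)))
        y += [tag] * 25
    return np.vstack(X), y


@pytest.fixture(scope="session")
def fast_pipeline_cfg():
    from actitag.dmf import DMFConfig

    return ev.PipelineConfig(
        dmf=DMFConfig(n_trees=30, sffs_max_features=3), rng_seed=5
    )
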