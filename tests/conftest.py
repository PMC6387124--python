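"""Shared fixtures: seeded synthetic scenes and a trained pipeline.

The expensive artefacts (training scenes, feature table, I-RELIEF weights,
trained RVM) are session-scoped so the whole suite trains the pipeline only
once.  All seeds are fixed module constants; nothing here touches the
filesystem outside pytest tmp dirs.
"""

from __future__ import annotations

import numpy as np
import pytest

import tomatoseg as ts
from tomatoseg.synthetic import subsample_balanced, sunny_and_shadow_specs

TRAIN_BASE_SEED = 100
EVAL_BASE_SEED = 5000
SUBSAMPLE_SEED = 1
MAX_TRAIN = 600


@pytest.fixture(scope="session")
def training_scenes():
    """Five training scenes: three sunny, two shadow."""
    return [ts.generate_scene(s) for s in sunny_and_shadow_specs(3, 2, TRAIN_BASE_SEED)]


@pytest.fixture(scope="session")
def training_table(training_scenes):
    X, y, stats = ts.build_training_table(training_scenes)
    return X, y, stats


@pytest.fixture(scope="session")
def training_subsample(training_table):
    X, y, _ = training_table
    return subsample_balanced(X, y, MAX_TRAIN, SUBSAMPLE_SEED)


@pytest.fixture(scope="session")
def feature_weights(training_subsample):
    Xf, yf = training_subsample
    return ts.irelief_weights(Xf, yf)


@pytest.fixture(scope="session")
def trained_model(training_table, training_subsample, feature_weights):
    _, _, stats = training_table
    Xf, yf = training_subsample
    return ts.train_rvm(Xf, yf, feature_weights, normalization=stats)


@pytest.fixture(scope="session")
def eval_scenes():
    """Twenty held-out scenes: ten sunny, ten shadow."""
    return [ts.generate_scene(s) for s in sunny_and_shadow_specs(10, 10, EVAL_BASE_SEED)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
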