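from __future__ import annotations

import numpy as np
import pytest

from ectopy import ClassifierConfig, QuadrantGeometry, WindowFeatures


@pytest.fixture
def geom() -> QuadrantGeometry:
    return QuadrantGeometry()


@pytest.fixture
def cfg() -> ClassifierConfig:
    return ClassifierConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_features(**kwargs) -> WindowFeatures:
    """WindowFeatures with quiet-window defaults, overridable per test."""
    return WindowFeatures(**kwargs)


@pytest.fixture
def features_factory():
    return make_features
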