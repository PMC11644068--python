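import datetime as dt
import warnings

import numpy as np
import pytest

from agbfusion.pipeline import build_feature_table
from agbfusion.synthetic_scene import SceneConfig


@pytest.fixture(scope="session")
def default_config() -> SceneConfig:
    return SceneConfig()


@pytest.fixture(scope="session")
def feature_table(default_config):
    """Full 376-row feature table of the default study (seed 7), no texture."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_table(default_config, seed=7, include_texture=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def july_date() -> dt.date:
    return dt.date(2023, 7, 15)
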