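import numpy as np
import pandas as pd
import pytest

from middencache import ScenarioConfig, add_derived_columns, generate_dataset
from middencache.synthetic import retained_frame


@pytest.fixture(scope="session")
def default_config() -> ScenarioConfig:
    return ScenarioConfig(seed=0)


@pytest.fixture(scope="session")
def study_frame(default_config) -> pd.DataFrame:
    """Retained middens of one default synthetic study, with derived columns."""
    ds = generate_dataset(default_config)
    return add_derived_columns(retained_frame(ds))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150824)
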