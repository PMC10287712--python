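import pandas as pd
import pytest

from chillqy import TrueModel
from chillqy.experiments import simulate_seasons


@pytest.fixture(scope="session")
def truth() -> TrueModel:
    return TrueModel.default()


@pytest.fixture(scope="session")
def home_data(truth):
    """Three training seasons of synthetic record + biweekly observations."""
    series, obs = simulate_seasons(seed=1, n_seasons=3, truth=truth)
    return series, obs


@pytest.fixture(scope="session")
def train_design(home_data, truth):
    from chillqy import assemble_design, compute_cu

    series, obs = home_data
    cu = compute_cu(series, truth.cu_config)
    return assemble_design(cu, obs)
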