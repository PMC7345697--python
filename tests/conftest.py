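import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import qsrrkit as qk

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fast_cfg():
    """Small search settings for contract tests (speed, not study conditions)."""
    return qk.SearchConfig(rf_trees=30, seed=0)


@pytest.fixture(scope="session")
def linear_matrix():
    """Small planted-signal matrix: 3 informative + 9 noise features, low noise."""
    X, y, truth = qk.gen_matrix(
        qk.MatrixSpec(n_compounds=60, n_noise_features=12, noise_sd=0.05, seed=11)
    )
    return X, y, truth


@pytest.fixture(scope="session")
def alkanol_table():
    return qk.gen_series(qk.SeriesSpec(chain_min=2, chain_max=31, noise_sd=0.1, seed=7))


@pytest.fixture
def write_csv(tmp_path):
    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
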