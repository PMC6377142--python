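import numpy as np
import pytest

from dyde.data_model import AnalysisConfig, ExpressionDataset


@pytest.fixture
def times12():
    """12 samples at 4 h, the reference sampling regime."""
    return 4.0 * np.arange(12)


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def cfg_fast():
    """Config with fewer optimizer restarts for test-suite speed."""
    return AnalysisConfig(n_restarts=2)


@pytest.fixture
def tiny_dataset(times12):
    rng = np.random.default_rng(0)
    values = rng.normal(5.0, 1.0, size=(2, 2, times12.size))
    return ExpressionDataset(("g1", "g2"), times12, values, condition="untreated")
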