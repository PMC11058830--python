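import numpy as np
import pytest

from hydroscale.core import MonthlyTimeSeries, YearMonth
from hydroscale.synthetic import default_coupled_config, gen_coupled_system


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_series():
    return MonthlyTimeSeries(start=YearMonth(2002, 1),
                             values=np.arange(24, dtype=float), name="ramp")


@pytest.fixture(scope="session")
def coupled_system():
    """One seeded realization of the reference coupled system (n=480)."""
    cfg = default_coupled_config(n_months=480, seed=7)
    series, truth = gen_coupled_system(cfg)
    return cfg, series, truth
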