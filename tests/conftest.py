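import numpy as np
import pytest

from chronopain.vonfrey import FilamentSeries, load_k_table


@pytest.fixture(scope="session")
def k_table():
    return load_k_table()


@pytest.fixture(scope="session")
def uniform_series():
    """Filament series exactly 0.3 log10 apart, matching the threshold
    formula's step assumption."""
    return FilamentSeries(tuple(10.0 ** (-1.5 + 0.3 * i) for i in range(8)))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
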