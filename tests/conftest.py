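import numpy as np
import pytest

from urbanaudit.datasets import (
    auditor_weight_vectors,
    item_weight_table,
    mean_weight_vector,
    neighbourhood_scores_by_season,
    ssoi_instrument,
)


@pytest.fixture(scope="session")
def instrument():
    return ssoi_instrument()


@pytest.fixture(scope="session")
def weight_table():
    return item_weight_table()


@pytest.fixture(scope="session")
def auditor_vectors():
    return auditor_weight_vectors()


@pytest.fixture(scope="session")
def printed_mean_weights():
    return mean_weight_vector()


@pytest.fixture(scope="session")
def season_scores():
    """The 15 neighbourhoods' Q_s in both field seasons (2 dp)."""
    return neighbourhood_scores_by_season()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
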