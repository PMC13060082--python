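import numpy as np
import pytest

from risefall.connectome import Connectome
from risefall.synthetic import make_study


@pytest.fixture(scope="session")
def small_study():
    """A 16-region synthetic study shared by read-only tests."""
    return make_study(rng_seed=11, n_regions_per_hemisphere=8,
                      n_genes=300, n_sets=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_conn():
    W = np.array(
        [
            [0.0, 1.0, 0.5, 0.0],
            [2.0, 0.0, 0.0, 0.3],
            [0.0, 0.7, 0.0, 1.1],
            [0.4, 0.0, 0.9, 0.0],
        ]
    )
    coords = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 2.0, 0.0], [1.0, 2.0, 1.0]]
    )
    return Connectome(
        region_ids=["A_ipsi", "B_ipsi", "A_contra", "B_contra"],
        W=W,
        coords=coords,
    )
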