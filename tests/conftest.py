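import numpy as np
import pytest

from plastiscan.synthetic import default_archetypes, make_design, simulate_counts


@pytest.fixture(scope="session")
def full_design():
    """The 108-sample study design: 2 cultivars x 2 tissues x 3 stages x
    3 soils x 3 replicates."""
    return make_design({"cultivar": 2, "tissue": 2, "stage": 3, "soil": 3},
                       replicates=3)


@pytest.fixture(scope="session")
def benchmark_counts(full_design):
    """Six-archetype benchmark: fold-change 4, NB dispersion 0.05,
    300 genes per archetype (drivers: stage, cultivar, tissue, soil,
    stage x soil, none)."""
    return simulate_counts(full_design, default_archetypes(4.0, 0.05),
                           300, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
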