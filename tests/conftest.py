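import numpy as np
import pytest

from crowdfba.core import SolverConfig
from crowdfba.crowding import (
    CrowdingAssignment,
    CrowdingDistribution,
    build_distribution,
    build_kcat_table,
)
from crowdfba.efm import enumerate_elementary_modes
from crowdfba.model_io import build_simplified_network
from crowdfba.synthetic_data import SyntheticKcatSpec, generate_kcat_table


@pytest.fixture(scope="session")
def simplified():
    return build_simplified_network()


@pytest.fixture(scope="session")
def simplified_modes(simplified):
    return enumerate_elementary_modes(simplified)


@pytest.fixture(scope="session")
def moderate_dist():
    """Coefficients spread over two decades around 0.1; keeps LP objectives O(1)."""
    rng = np.random.default_rng(12345)
    return CrowdingDistribution(10.0 ** rng.uniform(-2.0, 0.0, size=200))


@pytest.fixture(scope="session")
def synthetic_dist():
    """Distribution built the production way from a synthetic turnover table."""
    raw = generate_kcat_table(SyntheticKcatSpec(seed=7))
    return build_distribution(build_kcat_table(raw))


@pytest.fixture()
def config():
    return SolverConfig(v_prot=0.2)


def uniform_assignment(model, c=1.0):
    """Coefficient c on every enzymatic reaction, 0 elsewhere."""
    return CrowdingAssignment(
        {r.id: (c if r.enzymatic and not r.exchange else 0.0) for r in model.reactions}
    )
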