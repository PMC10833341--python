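import numpy as np
import pytest

from ncs_hetero.synthetic import (
    build_contact_lattice,
    build_loop_templates,
    build_two_chain_asu,
    default_two_chain_spec,
)

STUDY_SEED = 1


@pytest.fixture(scope="session")
def two_chain():
    """Default synthetic two-chain asymmetric unit plus its ground truth."""
    return build_two_chain_asu(default_two_chain_spec(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def two_chain_model(two_chain):
    return two_chain[0]


@pytest.fixture(scope="session")
def two_chain_truth(two_chain):
    return two_chain[1]


@pytest.fixture(scope="session")
def contact_fixture():
    """Single chain in a P1 cell with engineered terminal lattice contacts."""
    return build_contact_lattice(seed=0)


@pytest.fixture(scope="session")
def loop_templates():
    """Closed / open / extra-open loop chains with known opening margins."""
    return build_loop_templates()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
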