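import pytest

from gapsmith.fixtures import make_toy_organism, make_toy_world
from gapsmith.pipeline import run_organism
from gapsmith.universal import build_universal_model


@pytest.fixture(scope="session")
def world():
    return make_toy_world(seed=0)


@pytest.fixture(scope="session")
def universal(world):
    return build_universal_model(world.db)


@pytest.fixture(scope="session")
def fermenter_org(world):
    return make_toy_organism(world, "fermenter", seed=1)


@pytest.fixture(scope="session")
def fermenter_result(world, fermenter_org):
    return run_organism(world, fermenter_org)


@pytest.fixture(scope="session")
def fermenter_model(fermenter_result):
    """Fully gap-filled fermenter model. Treat as read-only; copy before
    mutating."""
    return fermenter_result.filled


@pytest.fixture(scope="session")
def single_gap_result(world):
    org = make_toy_organism(world, "single_gap", seed=1)
    return org, run_organism(world, org)


@pytest.fixture(scope="session")
def auxotroph_result(world):
    org = make_toy_organism(world, "auxotroph", seed=1)
    return org, run_organism(world, org)
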