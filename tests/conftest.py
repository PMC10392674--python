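import numpy as np
import pytest

from gpcrforge.forcefield import ForceFieldParams
from gpcrforge.fixtures import make_bundle, make_complex, make_salt_bridge_pair


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def planted_bundle():
    """3-helix bundle with a planted orientation combination (seed 1)."""
    bundle, truth = make_bundle(n_helices=3, length=16, seed=1)
    return bundle, truth


@pytest.fixture(scope="session")
def planted_complex():
    """Receptor pocket + toy ligand + search-defined planted pose."""
    receptor, ligand, planted, truth = make_complex(seed=0)
    return receptor, ligand, planted, truth


@pytest.fixture()
def salt_bridge_pair():
    return make_salt_bridge_pair(3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
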