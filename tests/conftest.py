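import numpy as np
import pytest

from omrex.simulate import SimulationParams, simulate_bundle


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic experiment bundle shared across tests."""
    return simulate_bundle(SimulationParams(), seed=7)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    bundle.write(d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
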