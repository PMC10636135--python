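import numpy as np
import pytest

from enzysite import active_site, fixtures


@pytest.fixture(scope="session")
def model():
    return active_site.default_model()


@pytest.fixture(scope="session")
def toy_scaffold(model):
    """One planted-site toy scaffold shared by read-only tests."""
    return fixtures.make_toy_scaffold(seed=1, n_decoy_residues=8, model=model)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
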