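import numpy as np
import pytest

from hyperpol import synthetic


@pytest.fixture(scope="session")
def fixture():
    """Printed reference values (loaded once per session)."""
    return synthetic.load_reference_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def molecule():
    return synthetic.make_model_molecule(7, n_blobs=2)
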