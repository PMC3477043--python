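import numpy as np
import pytest

import pocketpca as pp


@pytest.fixture(scope="session")
def records():
    return pp.load_bundled_dataset(include_isotypes=True)


@pytest.fixture(scope="session")
def cross_species_records():
    return pp.load_bundled_dataset(include_isotypes=False)


@pytest.fixture(scope="session")
def reproduction():
    """One full default reproduction run shared by the suite."""
    return pp.run_reproduction()


@pytest.fixture(scope="session")
def helix12():
    model, text = pp.generate_structure_fixture("ideal-helix", n_residues=12)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(20120801)


@pytest.fixture()
def random_rotation(rng):
    """A proper rotation matrix plus a translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t
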