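import numpy as np
import pytest

from idpmech import SyntheticSpec, build_toy_complex, native_contacts

# one small, fast toy complex shared across the suite
SMALL_TOY = dict(
    seed=11,
    chain_lengths=(26, 24),
    helix_segments=(((4, 13),), ((3, 11),)),
    n_frames=30,
    unfold_n_frames=150,
    cluster_n_frames=120,
)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(**SMALL_TOY)


@pytest.fixture(scope="session")
def toy(small_spec):
    return build_toy_complex(small_spec)


@pytest.fixture(scope="session")
def toy_system(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_reference(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_native(toy_system):
    return native_contacts(toy_system.reference_coords, toy_system)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
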