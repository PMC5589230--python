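import numpy as np
import pytest

from birw import AssociationRecord, BlockModelSpec, build_adjacency, generate_block_association


@pytest.fixture
def toy_records():
    """2x2 identity-patterned network."""
    return [AssociationRecord("d1", "m1"), AssociationRecord("d2", "m2")]


@pytest.fixture
def toy_matrix(toy_records):
    return build_adjacency(toy_records)


@pytest.fixture
def block_records():
    """Small planted-structure network with recoverable ranking."""
    spec = BlockModelSpec(n_diseases=9, n_microbes=24, n_blocks=3, p_in=0.9, p_out=0.05, seed=7)
    return generate_block_association(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_association_matrix(rng, nd, nm, density=0.3):
    """Random binary adjacency with at least one 1 per side overall."""
    while True:
        A = (rng.random((nd, nm)) < density).astype(np.int8)
        if A.sum() >= 2:
            return A
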