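import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from fragssl import (
    EncoderConfig,
    PretrainConfig,
    ToyLibrarySpec,
    brics_partition,
    generate_library,
    parse_smiles,
)
from fragssl.pretrain import init_params


@pytest.fixture(scope="session")
def toy_library():
    """100 deterministic fixture molecules with family labels."""
    return generate_library(ToyLibrarySpec(n_molecules=100, seed=11, family_labels=True))


@pytest.fixture(scope="session")
def toy_graphs(toy_library):
    return [parse_smiles(s) for s in toy_library.smiles]


@pytest.fixture(scope="session")
def toy_assignments(toy_graphs):
    return [brics_partition(g) for g in toy_graphs]


@pytest.fixture
def tiny_config():
    """Desk-scale config: small width/depth so forward passes are instant."""
    return PretrainConfig(
        batch_size=8,
        epochs=2,
        seed=123,
        encoder=EncoderConfig(num_layers=2, hidden_dim=12),
    )


@pytest.fixture
def tiny_params(tiny_config):
    return init_params(tiny_config, np.random.default_rng(0))


def numeric_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an ndarray."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
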