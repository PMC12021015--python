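import numpy as np
import pytest

from ddgraph.graphs import ContactMap
from ddgraph.synthetic import SyntheticEnergyModel, generate_dataset


@pytest.fixture(scope="session")
def energy_model():
    return SyntheticEnergyModel.random(seed=7)


@pytest.fixture(scope="session")
def small_corpus(energy_model):
    """120 mixed-type synthetic records over a small protein pool."""
    return generate_dataset(120, length_range=(20, 40), model=energy_model, seed=7, n_proteins=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_contact_map(n, rng, density=0.3):
    """Random symmetric zero-diagonal probability matrix (test helper)."""
    p = rng.random((n, n)) * (rng.random((n, n)) < density)
    p = np.triu(p, k=1)
    p = p + p.T
    return ContactMap(p)


def random_graph(n, rng, f=8, density=0.4):
    cm = random_contact_map(n, rng, density)
    feats = rng.standard_normal((n, f))
    from ddgraph.graphs import ProteinGraph, threshold_contacts

    edges, weights = threshold_contacts(cm, 0.1)
    return ProteinGraph(node_features=feats, edges=edges, edge_weights=weights)
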