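import numpy as np
import pytest
from hypothesis import settings

import skillnet as sn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_spec():
    return sn.default_skill_spec()


@pytest.fixture(scope="session")
def panel5000(default_spec):
    """A structured 5000-row panel shared by the slower estimation tests."""
    return sn.sample_panel(default_spec, 5000, seed=11)


@pytest.fixture
def toy_graph():
    """3-node line: w12=0.5, w13=0.25, w23=0; communities {1,2} vs {3}."""
    W = np.array([[0.0, 0.5, 0.25], [0.5, 0.0, 0.0], [0.25, 0.0, 0.0]])
    return sn.NetworkGraph(
        W=W, labels=("a", "b", "c"), community_of={"a": "Ls", "b": "Ls", "c": "Bs"}
    )


def random_graph(rng, p, edge_prob=0.5):
    """Random signed weighted graph with a random 2-community split."""
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_prob:
                w = rng.uniform(0.1, 1.0) * (1 if rng.random() < 0.7 else -1)
                W[i, j] = W[j, i] = w
    labels = tuple(f"n{i}" for i in range(p))
    # random split with both communities nonempty
    while True:
        comm = rng.integers(0, 2, size=p)
        if 0 < comm.sum() < p:
            break
    community_of = {labels[i]: ("A" if comm[i] == 0 else "B") for i in range(p)}
    return sn.NetworkGraph(W=W, labels=labels, community_of=community_of)
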