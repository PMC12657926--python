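import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def path3():
    return nx.path_graph(3)


@pytest.fixture
def cycle4():
    return nx.cycle_graph(4)


@pytest.fixture
def k2():
    return nx.complete_graph(2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_connected_graphs(n_graphs, v_lo, v_hi, seed):
    """Seeded stream of small random connected simple graphs."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_graphs:
        v = int(rng.integers(v_lo, v_hi + 1))
        p = float(rng.uniform(0.15, 0.6))
        g = nx.gnp_random_graph(v, p, seed=int(rng.integers(2**31)))
        if g.number_of_nodes() >= 2 and nx.is_connected(g):
            out.append(g)
    return out


def random_trees(n_trees, v_lo, v_hi, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        v = int(rng.integers(v_lo, v_hi + 1))
        if v <= 2:
            out.append(nx.path_graph(v))
        else:
            seq = rng.integers(0, v, size=v - 2).tolist()
            out.append(nx.from_prufer_sequence(seq))
    return out
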