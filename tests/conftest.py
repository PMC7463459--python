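import numpy as np
import pytest

from bhlhfam.domain import calibrate_threshold, load_packaged_profile
from bhlhfam.synth import default_clade_spec, make_family


@pytest.fixture(scope="session")
def profile():
    return load_packaged_profile()


@pytest.fixture(scope="session")
def threshold(profile):
    return calibrate_threshold(profile, seed=0)


@pytest.fixture(scope="session")
def family98():
    """The standard synthetic study family: 98 proteins, 18 clades, seed 42."""
    return make_family(98, default_clade_spec(), mutation_rate=0.05, seed=42)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths, plus its
    patristic distance matrix — an independent oracle for NJ consistency.

    The tree is grown by attaching each new leaf to a uniformly chosen
    existing edge; distances are path sums over an explicit graph.
    """
    import networkx as nx

    G = nx.Graph()
    G.add_edge("t0", "t1", length=float(rng.uniform(0.05, 0.5)))
    next_internal = 0
    for i in range(2, n_taxa):
        u, v = list(G.edges())[rng.integers(0, G.number_of_edges())]
        w = G[u][v]["length"]
        G.remove_edge(u, v)
        mid = f"x{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        G.add_edge(u, mid, length=w * split)
        G.add_edge(mid, v, length=w * (1 - split))
        G.add_edge(mid, f"t{i}", length=float(rng.uniform(0.05, 0.5)))
    labels = [f"t{i}" for i in range(n_taxa)]
    paths = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
    D = np.array([[paths[a][b] for b in labels] for a in labels])
    return G, labels, D


def tree_bipartitions_from_graph(G, labels) -> set:
    """Leaf bipartitions of a networkx tree (independent of the package)."""
    import networkx as nx

    universe = frozenset(labels)
    out = set()
    for u, v in G.edges():
        H = G.copy()
        H.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(H, u) if x in universe)
        if 1 < len(side) < len(universe) - 1:
            other = universe - side
            canon = side if len(side) < len(other) else other
            if len(side) == len(other):
                canon = min(side, other, key=lambda s: sorted(s))
            out.add(canon)
    return out
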