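import networkx as nx
import numpy as np
import pandas as pd
import pytest

from revnet import OmicsMatrix


@pytest.fixture
def small_matrix():
    """6 samples (2 groups x 3), 4 features, hand-set log2 values."""
    values = pd.DataFrame(
        {
            "c1": [4.0, 5.0, 1.0, 7.0],
            "c2": [4.2, 5.1, 2.0, 7.1],
            "c3": [3.8, 4.9, 3.0, 6.9],
            "m1": [6.0, 5.0, 4.0, 7.0],
            "m2": [6.2, 5.2, 5.0, 7.2],
            "m3": [5.8, 4.8, 6.0, 6.8],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    groups = pd.Series(
        ["control"] * 3 + ["model"] * 3, index=list(values.columns)
    )
    return OmicsMatrix(values=values, groups=groups, layer="transcript")


@pytest.fixture
def path6():
    """Path graph 1-2-3-4-5-6 with string node ids."""
    g = nx.path_graph(6)
    return nx.relabel_nodes(g, {i: str(i + 1) for i in range(6)})


def random_graph(rng, n_max=8, p=0.4):
    """Small random simple graph with string ids (shared test helper)."""
    n = int(rng.integers(2, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(str(i) for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(str(i), str(j))
    return g


def bfs_oracle(g, source):
    """Brute-force breadth-first distances, independent of networkx paths."""
    dist = {source: 0}
    queue = [source]
    while queue:
        nxt = []
        for v in queue:
            for u in g[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    nxt.append(u)
        queue = nxt
    return dist
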