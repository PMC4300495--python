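"""Shared fixtures: small graphs and generated tables used across suites."""

import networkx as nx
import numpy as np
import pytest

from modcore import simulate


def relabel(graph: nx.Graph, prefix: str = "g") -> nx.Graph:
    return nx.relabel_nodes(graph, {v: f"{prefix}{v}" for v in graph.nodes()})


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two disjoint triangles."""
    g = nx.Graph()
    g.add_edges_from([("a0", "a1"), ("a1", "a2"), ("a0", "a2"),
                      ("b0", "b1"), ("b1", "b2"), ("b0", "b2")])
    return g


@pytest.fixture
def bridged_triangles(two_triangles) -> nx.Graph:
    """Two triangles joined by one bridge edge."""
    g = two_triangles.copy()
    g.add_edge("a0", "b0")
    return g


@pytest.fixture
def two_cliques_bridge() -> nx.Graph:
    """Two 6-cliques joined by a single bridge edge."""
    return relabel(nx.barbell_graph(6, 0))


@pytest.fixture
def planted_graph():
    """10 blocks of 30, p_in=0.3, p_out=0.005, with its planted labels."""
    graph, truth = simulate.gen_modular_network(10, 30, 0.3, 0.005, seed=0)
    return graph, truth.planted["partition"]


@pytest.fixture
def annotation_frame():
    genes = [f"G{i:05d}" for i in range(800)]
    ann, truth = simulate.gen_gene_annotation(
        genes, confound_factor=1.0, disease_set_size=80, seed=3
    )
    return ann, truth


def naive_kcore(graph: nx.Graph) -> dict:
    """Brute-force coreness oracle by iterative peeling."""
    core = {}
    k = 1
    g = graph.copy()
    while g.number_of_nodes():
        while True:
            low = [v for v in g.nodes() if g.degree(v) < k]
            if not low:
                break
            for v in low:
                core[v] = k - 1
            g.remove_nodes_from(low)
        k += 1
    return core


def max_modularity_exhaustive(graph: nx.Graph) -> tuple[float, dict]:
    """Exhaustive search over all set partitions (restricted growth strings),
    maintaining intra-edge counts and degree sums incrementally."""
    nodes = sorted(graph.nodes())
    n = len(nodes)
    m = graph.number_of_edges()
    two_m = 2 * m
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [[idx[u] for u in graph[v]] for v in nodes]
    deg = [graph.degree(v) for v in nodes]
    best = [-2.0, None]
    assign = [0] * n

    def rec(i, nblocks, e, d):
        if i == n:
            q = sum(ec / m for ec in e[:nblocks]) - sum(
                (dc / two_m) ** 2 for dc in d[:nblocks])
            if q > best[0]:
                best[0], best[1] = q, assign[:]
            return
        for b in range(nblocks + 1):
            w = sum(1 for u in adj[i] if u < i and assign[u] == b)
            assign[i] = b
            if b == nblocks:
                e.append(w); d.append(deg[i])
                rec(i + 1, nblocks + 1, e, d)
                e.pop(); d.pop()
            else:
                e[b] += w; d[b] += deg[i]
                rec(i + 1, nblocks, e, d)
                e[b] -= w; d[b] -= deg[i]

    rec(0, 0, [], [])
    return best[0], {nodes[i]: b for i, b in enumerate(best[1])}


def ari(labels_a, labels_b) -> float:
    from sklearn.metrics import adjusted_rand_score
    return adjusted_rand_score(list(labels_a), list(labels_b))
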