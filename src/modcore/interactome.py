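"""Interactome graph model: edge-list I/O, modularity decomposition, nulls, k-cores.

The interactome is an undirected simple graph over gene symbols (a
:class:`networkx.Graph`), with the cleaning conventions used for curated
physical-interaction databases: self-interactions dropped, duplicate and
reversed-duplicate edges collapsed, isolated nodes removed.

Community structure is found by maximizing Newman-Girvan modularity

    Q = sum_c [ e_c / m - (d_c / 2m)^2 ]

with the *first level* of the multilevel (Louvain-style) heuristic: nodes are
repeatedly moved, one at a time and in seeded random order, to the adjacent
community with the largest modularity gain, until no single-node move
improves Q.  No aggregation/coarsening pass follows, so small dense
communities are never merged into larger ones.  Because a single local-move
phase is only a local optimum, the phase is restarted ``restarts`` times with
seed-derived node orders and the highest-Q partition is kept (still a
first-level partition).

Statistical significance of the observed modularity is assessed against
degree-preserving rewired graphs (double-edge-swap null model).
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("modcore")

__all__ = [
    "ModulePartition",
    "NullEnsembleSummary",
    "read_edge_list",
    "write_edge_list",
    "modularity",
    "louvain_partition",
    "degree_preserving_rewire",
    "modularity_null_test",
    "kcore_decompose",
    "subcluster_module",
    "write_partition",
    "read_partition",
    "write_coreness",
    "read_coreness",
]

# Column names accepted as an edge-list header line.
_HEADER_TOKENS = {
    "interactor_a", "interactor_b", "gene_a", "gene_b", "symbol_a",
    "symbol_b", "source", "target", "gene1", "gene2",
    "official_symbol_interactor_a", "official_symbol_interactor_b",
}


@dataclass(frozen=True)
class ModulePartition:
    """Assignment of every node of a graph to a module.

    Module ids are contiguous small integers starting at 0, ordered by
    decreasing module size (ties broken by the lexicographically smallest
    member gene), so the labelling is deterministic for a given assignment.
    """

    assignment: Mapping[str, int]
    q: float
    level: int = 1
    seed: int | None = None

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = defaultdict(set)
        for gene, mid in self.assignment.items():
            out[mid].add(gene)
        return dict(out)

    def module_genes(self, module_id: int) -> set[str]:
        return {g for g, m in self.assignment.items() if m == module_id}


@dataclass(frozen=True)
class NullEnsembleSummary:
    """Observed modularity against a degree-preserving rewiring ensemble."""

    q_observed: float
    q_null: tuple[float, ...]
    n_random: int
    p_empirical: float


def _canonical_labels(assignment: Mapping[str, int]) -> dict[str, int]:
    """Relabel module ids contiguously from 0, largest module first."""
    groups: dict[int, list[str]] = defaultdict(list)
    for g, m in assignment.items():
        groups[m].append(g)
    order = sorted(groups, key=lambda m: (-len(groups[m]), min(groups[m])))
    remap = {old: new for new, old in enumerate(order)}
    return {g: remap[m] for g, m in assignment.items()}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path,
    *,
    col_a: int = 0,
    col_b: int = 1,
    directed_input_ok: bool = True,
) -> nx.Graph:
    """Read a two-column (or wider) edge-list TSV into a simple graph.

    Lines are split on whitespace/tabs; columns beyond ``col_a``/``col_b``
    are ignored.  A header line is auto-detected when its two mapped tokens
    match common column names.  Self-loops are dropped; duplicate and
    reversed-duplicate edges collapse (``directed_input_ok`` documents that
    A-B and B-A are the same interaction).

    Raises ``ValueError`` for an empty file or a line with too few columns
    (naming the line number).
    """
    path = Path(path)
    graph = nx.Graph()
    n_self = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) <= max(col_a, col_b):
                raise ValueError(
                    f"{path}: line {lineno}: expected at least "
                    f"{max(col_a, col_b) + 1} columns, got {len(parts)}"
                )
            a, b = parts[col_a].strip(), parts[col_b].strip()
            if lineno == 1 and {a.lower(), b.lower()} & _HEADER_TOKENS:
                continue  # header
            n_lines += 1
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b)
    if n_lines == 0:
        raise ValueError(f"{path}: no edges found (empty edge list)")
    if graph.number_of_edges() == 0:
        raise ValueError(f"{path}: all records were self-interactions")
    logger.info(
        "read_edge_list(%s): %d nodes, %d edges (%d data lines, %d self-loops dropped)",
        path.name, graph.number_of_nodes(), graph.number_of_edges(), n_lines, n_self,
    )
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write the graph as a sorted two-column TSV (round-trips through
    :func:`read_edge_list`)."""
    with open(path, "w") as fh:
        fh.write("interactor_a\tinteractor_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def write_partition(part: ModulePartition, path: str | Path) -> None:
    """Write gene→module TSV with a JSON sidecar carrying q/level/seed."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene\tmodule_id\n")
        for gene in sorted(part.assignment):
            fh.write(f"{gene}\t{part.assignment[gene]}\n")
    sidecar = {
        "q": round(float(part.q), 10),
        "level": part.level,
        "seed": part.seed,
        "n_nodes": len(part.assignment),
        "n_modules": part.n_modules,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_partition(path: str | Path) -> ModulePartition:
    path = Path(path)
    assignment: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene"):
            raise ValueError(f"{path}: expected 'gene\\tmodule_id' header")
        for line in fh:
            gene, mid = line.split("\t")
            assignment[gene] = int(mid)
    sidecar = path.with_suffix(path.suffix + ".json")
    q, level, seed = math.nan, 1, None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        q, level, seed = meta.get("q", math.nan), meta.get("level", 1), meta.get("seed")
    return ModulePartition(assignment=assignment, q=q, level=level, seed=seed)


def write_coreness(coreness: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tK\n")
        for gene in sorted(coreness):
            fh.write(f"{gene}\t{coreness[gene]}\n")


def read_coreness(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gene, k = line.split("\t")
            out[gene] = int(k)
    return out


# ---------------------------------------------------------------------------
# Modularity and its maximization
# ---------------------------------------------------------------------------

def modularity(partition: ModulePartition | Mapping[str, int], graph: nx.Graph) -> float:
    """Newman-Girvan modularity of a partition, recomputed from scratch.

    Q = sum_c [ e_c/m - (d_c/2m)^2 ], with m the edge count, e_c the number
    of intra-module edges of module c and d_c its degree sum.
    """
    assignment = partition.assignment if isinstance(partition, ModulePartition) else partition
    missing = [v for v in graph.nodes() if v not in assignment]
    if missing:
        raise ValueError(f"partition is missing {len(missing)} graph nodes, e.g. {missing[:3]}")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    intra: dict[int, int] = defaultdict(int)
    dsum: dict[int, int] = defaultdict(int)
    for u, v in graph.edges():
        if assignment[u] == assignment[v]:
            intra[assignment[u]] += 1
    for v in graph.nodes():
        dsum[assignment[v]] += graph.degree(v)
    two_m = 2.0 * m
    return sum(intra[c] / m for c in intra) - sum((d / two_m) ** 2 for d in dsum.values())


def _local_move_phase(
    nodes: list[str],
    adj: list[list[int]],
    deg: np.ndarray,
    m: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One complete level-1 local-move phase; returns the community index array.

    Ties (zero or negative gain) keep the node in its current community.
    """
    n = len(nodes)
    comm = np.arange(n)
    ctot = deg.astype(float).copy()  # degree sum per community
    two_m = 2.0 * m
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            nbr_w: dict[int, int] = {}
            for j in adj[i]:
                cj = comm[j]
                nbr_w[cj] = nbr_w.get(cj, 0) + 1
            ctot[ci] -= deg[i]
            base = nbr_w.get(ci, 0) - ctot[ci] * deg[i] / two_m
            best_c, best_gain = ci, 0.0
            for c, w in nbr_w.items():
                if c == ci:
                    continue
                gain = (w - ctot[c] * deg[i] / two_m) - base
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            comm[i] = best_c
            ctot[best_c] += deg[i]
            if best_c != ci:
                improved = True
    return comm


def louvain_partition(
    graph: nx.Graph,
    seed: int,
    *,
    restarts: int = 8,
) -> ModulePartition:
    """First-level modularity-maximizing partition (no coarsening pass).

    The local-move phase is run ``restarts`` times with node orders drawn
    from a generator seeded by ``seed``; the partition with the highest Q is
    returned.  Deterministic given ``seed`` and independent of the input
    node order (nodes are processed from a sorted index).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("louvain_partition: empty graph")
    nodes = sorted(graph.nodes())
    if graph.number_of_edges() == 0:
        assignment = _canonical_labels({v: i for i, v in enumerate(nodes)})
        return ModulePartition(assignment=assignment, q=0.0, level=1, seed=seed)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [[index[u] for u in graph[v]] for v in nodes]
    deg = np.array([graph.degree(v) for v in nodes])
    m = graph.number_of_edges()
    rng = np.random.default_rng(seed)
    best_q, best_comm = -2.0, None
    for _ in range(max(1, restarts)):
        comm = _local_move_phase(nodes, adj, deg, m, rng)
        q = modularity({v: int(comm[i]) for v, i in index.items()}, graph)
        if q > best_q:
            best_q, best_comm = q, comm
    assignment = _canonical_labels({v: int(best_comm[index[v]]) for v in nodes})
    return ModulePartition(assignment=assignment, q=best_q, level=1, seed=seed)


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------

def degree_preserving_rewire(
    graph: nx.Graph,
    n_swap_multiplier: float = 10.0,
    seed: int = 0,
) -> nx.Graph:
    """Randomize edges by double-edge swaps, preserving every node's degree.

    ``ceil(n_swap_multiplier * |E|)`` swaps are attempted; a swap is rejected
    when it would create a self-loop or a duplicate edge.  If no attempted
    swap succeeds the input is returned unchanged (copied) with a warning.
    """
    if graph.number_of_edges() < 2:
        raise ValueError("degree_preserving_rewire: need at least 2 edges")
    rng = np.random.default_rng(seed)
    out = graph.copy()
    edges = [tuple(e) for e in out.edges()]
    n_attempts = math.ceil(n_swap_multiplier * len(edges))
    n_success = 0
    n_edges = len(edges)
    picks = rng.integers(0, n_edges, size=(n_attempts, 2))
    flips = rng.integers(0, 2, size=n_attempts)
    for t in range(n_attempts):
        i, j = picks[t]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flips[t]:
            c, d = d, c
        # propose (a, c) and (b, d)
        if a == c or b == d:
            continue
        if out.has_edge(a, c) or out.has_edge(b, d):
            continue
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(a, c)
        out.add_edge(b, d)
        edges[i] = (a, c)
        edges[j] = (b, d)
        n_success += 1
    if n_success == 0:
        logger.warning(
            "degree_preserving_rewire: no legal swap found in %d attempts; "
            "returning the input graph unchanged", n_attempts,
        )
    return out


def modularity_null_test(
    graph: nx.Graph,
    n_random: int = 100,
    seed: int = 0,
    *,
    n_swap_multiplier: float = 10.0,
    restarts: int = 8,
) -> NullEnsembleSummary:
    """Compare the graph's maximized modularity against rewired replicas.

    Each replica is rewired, partitioned with :func:`louvain_partition`, and
    its Q recorded; the empirical p-value uses the add-one convention
    ``(1 + #{Q_null >= Q_obs}) / (1 + n_random)`` so it is never zero.
    """
    if n_random < 1:
        raise ValueError("modularity_null_test: n_random must be >= 1")
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_random + 1)]
    q_obs = louvain_partition(graph, child[0], restarts=restarts).q
    q_null = []
    for r in range(n_random):
        rewired = degree_preserving_rewire(
            graph, n_swap_multiplier=n_swap_multiplier, seed=child[1 + 2 * r]
        )
        q_null.append(louvain_partition(rewired, child[2 + 2 * r], restarts=restarts).q)
    exceed = sum(1 for q in q_null if q >= q_obs)
    p = (1 + exceed) / (1 + n_random)
    return NullEnsembleSummary(
        q_observed=q_obs, q_null=tuple(q_null), n_random=n_random, p_empirical=p
    )


# ---------------------------------------------------------------------------
# k-core layering and sub-clustering
# ---------------------------------------------------------------------------

def kcore_decompose(graph: nx.Graph) -> dict[str, int]:
    """Coreness K(v): the largest k such that v survives iterative deletion
    of all nodes of degree < k."""
    if graph.number_of_nodes() == 0:
        raise ValueError("kcore_decompose: empty graph")
    return dict(nx.core_number(graph))


def subcluster_module(
    graph: nx.Graph,
    module_genes: Iterable[str],
    seed: int,
    *,
    restarts: int = 8,
) -> ModulePartition:
    """Recursive decomposition step: partition the subgraph induced by a
    module's genes.  Genes left without edges become singleton sub-clusters."""
    genes = set(module_genes)
    extra = genes - set(graph.nodes())
    if extra:
        raise ValueError(f"subcluster_module: genes not in graph: {sorted(extra)[:3]}")
    sub = graph.subgraph(genes).copy()
    if sub.number_of_nodes() == 0:
        raise ValueError("subcluster_module: empty induced subgraph")
    if sub.number_of_edges() == 0:
        logger.warning(
            "subcluster_module: induced subgraph has no edges; "
            "every gene becomes its own sub-cluster"
        )
    return louvain_partition(sub, seed, restarts=restarts)
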