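"""Node-type-normalized shortest-path distance in a heterogeneous knowledge graph.

The graph mixes node types (Gene, Pathway, GOTerm, ProteinFamily, Complex,
Disease, TissueCoexpCluster, ...) connected by unit-weight edges (PPI,
membership, coexpression, sequence similarity, ...).  The distance between
two gene nodes is the shortest-path edge count divided by the number of
distinct node types occurring on the path, endpoints included — so two
genes co-member of one pathway score 2 edges / 2 types = 1, and a direct
PPI pair scores 1 edge / 1 type = 1.  When several shortest paths exist
the reported value is the minimum over them (the path with the most
distinct types).
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

KNOWN_NODE_TYPES = frozenset(
    {"Gene", "Pathway", "GOTerm", "ProteinFamily", "Complex", "Disease",
     "TissueCoexpCluster"}
)


class GraphFormatError(ValueError):
    pass


def build_graph(
    nodes: Iterable[tuple[str, str]],
    edges: Iterable[tuple[str, str, str]],
    strict_types: bool = True,
) -> nx.Graph:
    """Assemble a validated typed graph from (id, type) and (u, v, relation).

    Duplicate edges collapse; self-loops and edges touching undeclared
    nodes are rejected.
    """
    g = nx.Graph()
    for node_id, node_type in nodes:
        if strict_types and node_type not in KNOWN_NODE_TYPES:
            raise GraphFormatError(f"unknown node_type {node_type!r} for node {node_id!r}")
        g.add_node(node_id, node_type=node_type)
    for u, v, relation in edges:
        for end in (u, v):
            if end not in g:
                raise GraphFormatError(f"edge ({u!r}, {v!r}) references undeclared node {end!r}")
        if u == v:
            raise GraphFormatError(f"self-loop on node {u!r}")
        g.add_edge(u, v, relation=relation)
    return g


def load_graph(node_path, edge_path, strict_types: bool = True) -> nx.Graph:
    """Load the graph from the node TSV (node_id, node_type) and edge TSV
    (node_id_1, node_id_2, relation)."""
    nodes = pd.read_csv(node_path, sep="\t", dtype=str)
    edges = pd.read_csv(edge_path, sep="\t", dtype=str)
    for frame, cols, what in (
        (nodes, ("node_id", "node_type"), "node"),
        (edges, ("node_id_1", "node_id_2", "relation"), "edge"),
    ):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise GraphFormatError(f"{what} TSV missing columns {sorted(missing)}")
    return build_graph(
        nodes[["node_id", "node_type"]].itertuples(index=False, name=None),
        edges[["node_id_1", "node_id_2", "relation"]].itertuples(index=False, name=None),
        strict_types=strict_types,
    )


def _require_gene(g: nx.Graph, node: str) -> None:
    if node not in g:
        raise KeyError(f"node {node!r} not in graph")
    if g.nodes[node].get("node_type") != "Gene":
        raise ValueError(f"node {node!r} is not Gene-typed")


def kg_distance(g: nx.Graph, gene1: str, gene2: str) -> float:
    """Normalized knowledge-graph distance between two gene nodes.

    Returns ``math.inf`` when the genes are disconnected and 0.0 when
    ``gene1 == gene2``.  Among paths of minimum edge count, the one with
    the largest number of distinct node types defines the value.
    """
    _require_gene(g, gene1)
    _require_gene(g, gene2)
    if gene1 == gene2:
        return 0.0
    try:
        length = nx.shortest_path_length(g, gene1, gene2)
    except nx.NetworkXNoPath:
        return math.inf
    max_types = _max_distinct_types(g, gene1, gene2, length)
    return length / max_types


def _shortest_path_dag(g: nx.Graph, source: str, target: str, length: int):
    """Predecessor map of the BFS shortest-path DAG from source to target."""
    dist = nx.single_source_shortest_path_length(g, source, cutoff=length)
    pred: dict[str, list[str]] = {source: []}
    for node, d in dist.items():
        if node == source:
            continue
        pred[node] = [nb for nb in g.neighbors(node) if dist.get(nb, math.inf) == d - 1]
    return pred


def _max_distinct_types(g: nx.Graph, source: str, target: str, length: int) -> int:
    """Maximum distinct-type count over all minimum-edge-count paths.

    Dynamic program over the BFS shortest-path DAG: each node keeps the
    set of attainable type-sets from the source, pruned of dominated
    (subset) entries, which bounds the state space on the graphs this
    package targets.
    """
    pred = _shortest_path_dag(g, source, target, length)
    ntype = lambda n: g.nodes[n].get("node_type")

    memo: dict[str, set[frozenset]] = {source: {frozenset([ntype(source)])}}

    def typesets(node: str) -> set[frozenset]:
        if node in memo:
            return memo[node]
        t = ntype(node)
        collected: set[frozenset] = set()
        for p in pred[node]:
            for s in typesets(p):
                collected.add(s | {t})
        # prune dominated sets: keep maximal ones only
        maximal = {s for s in collected if not any(s < o for o in collected)}
        memo[node] = maximal
        return maximal

    return max(len(s) for s in typesets(target))


def enumerate_shortest_paths(
    g: nx.Graph, n1: str, n2: str, max_paths: int = 10_000
) -> list[list[str]]:
    """All minimum-edge-count node paths, deterministically ordered.

    Test oracle for small graphs; raises ``RuntimeError`` past the
    explosion guard.  Returns ``[]`` for a disconnected pair and the
    singleton path for ``n1 == n2``.
    """
    if n1 not in g or n2 not in g:
        raise KeyError("endpoint not in graph")
    if not nx.has_path(g, n1, n2):
        return []
    paths = []
    for path in nx.all_shortest_paths(g, n1, n2):
        paths.append(list(path))
        if len(paths) > max_paths:
            raise RuntimeError(f"more than {max_paths} shortest paths")
    return sorted(paths)


def pair_distances(
    g: nx.Graph, pairs: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """Normalized distance for each gene pair; inf rendered as missing."""
    rows = []
    for gene1, gene2 in pairs:
        d: Optional[float] = kg_distance(g, gene1, gene2)
        rows.append({
            "gene1": gene1,
            "gene2": gene2,
            "kg_distance": None if math.isinf(d) else d,
        })
    return pd.DataFrame(rows, columns=["gene1", "gene2", "kg_distance"])
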