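"""Candidate-gene subnetwork extraction from global interaction graphs.

Given a genome-scale genetic or physical interaction graph and a candidate
gene list, the extracted subnetwork keeps every direct candidate-candidate
edge and admits a non-candidate "linker" gene only when it directly connects
at least two distinct candidates — i.e. every candidate-to-candidate path in
the output has length one or two, bridged by at most one gene outside the
candidate list. A non-candidate adjacent to a single candidate bridges
nothing and is excluded.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "graph_from_edges",
    "extract_subnetwork",
    "summarize_network",
]


def graph_from_edges(edges: pd.DataFrame, edge_type: str | None = None) -> nx.Graph:
    """Undirected graph from a (gene_a, gene_b, type) edge list.

    Self-loops are dropped and duplicate edges (ignoring orientation)
    collapse to one. ``edge_type`` restricts to 'genetic' or 'physical'.
    """
    if edge_type is not None:
        edges = edges[edges["type"] == edge_type]
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        if row.gene_a == row.gene_b:
            continue
        g.add_edge(row.gene_a, row.gene_b, type=row.type)
    return g


def extract_subnetwork(graph: nx.Graph, candidates: set, allow_missing: int = 1) -> nx.Graph:
    """One-linker candidate subnetwork.

    Keeps all candidate-candidate edges; with ``allow_missing = 1`` also
    keeps every non-candidate node adjacent to >= 2 distinct candidates,
    together with exactly its edges to candidates. Nodes carry a
    ``candidate`` attribute.
    """
    if allow_missing not in (0, 1):
        raise ValueError("allow_missing must be 0 or 1")
    cand = set(candidates)
    sub = nx.Graph()
    for u, v, data in graph.edges(data=True):
        if u in cand and v in cand:
            sub.add_edge(u, v, **data)
    if allow_missing:
        for node in graph.nodes:
            if node in cand:
                continue
            cand_neighbors = [nb for nb in graph.neighbors(node) if nb in cand]
            if len(set(cand_neighbors)) >= 2:
                for nb in cand_neighbors:
                    sub.add_edge(node, nb, **graph.edges[node, nb])
    nx.set_node_attributes(sub, {n: (n in cand) for n in sub.nodes}, "candidate")
    return sub


def summarize_network(sub: nx.Graph, candidates: set) -> dict:
    """Counts and component membership of an extracted subnetwork."""
    cand = set(candidates)
    components = [sorted(c) for c in nx.connected_components(sub)]
    components.sort(key=lambda c: (-len(c), c))
    return {
        "n_candidates": sum(1 for n in sub.nodes if n in cand),
        "n_genes": sub.number_of_nodes(),
        "n_linkers": sum(1 for n in sub.nodes if n not in cand),
        "n_edges": sub.number_of_edges(),
        "n_components": len(components),
        "components": components,
    }
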