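"""Protein–protein interaction network topology metrics.

Operates on a weighted undirected graph built from an edge list
(nodeA, nodeB, confidence in [0, 1]), the shape of a STRING export.
Singleton nodes are first-class: confidence filtering never drops nodes,
because isolated proteins with crucial metabolic functions are still
candidate targets.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import networkx as nx
import pandas as pd


def build_graph(edges: Iterable[tuple[str, str, float]] | pd.DataFrame) -> nx.Graph:
    """Build an undirected confidence-weighted graph from an edge list.

    Accepts (nodeA, nodeB, score) triples or a DataFrame with columns
    node_a, node_b, score.  Self-loops are rejected; duplicate edges keep
    the highest score.
    """
    if isinstance(edges, pd.DataFrame):
        edges = list(edges[["node_a", "node_b", "score"]].itertuples(index=False, name=None))
    graph = nx.Graph()
    for a, b, score in edges:
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"confidence score {score} outside [0, 1] for edge {a}-{b}")
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        if graph.has_edge(a, b):
            score = max(score, graph.edges[a, b]["confidence"])
        graph.add_edge(a, b, confidence=score)
    return graph


def filter_edges(graph: nx.Graph, min_confidence: float = 0.70) -> nx.Graph:
    """Keep edges with confidence >= min_confidence; keep every node."""
    for _, _, data in graph.edges(data=True):
        if not 0.0 <= data["confidence"] <= 1.0:
            raise ValueError("confidence score outside [0, 1]")
    out = nx.Graph()
    out.add_nodes_from(graph.nodes(data=True))
    out.add_edges_from(
        (a, b, data)
        for a, b, data in graph.edges(data=True)
        if data["confidence"] >= min_confidence
    )
    return out


def topology_summary(graph: nx.Graph) -> dict[str, float]:
    """Node/edge counts, average degree (2E/N) and mean local clustering.

    The clustering coefficient is the mean of local coefficients over all
    nodes, with degree < 2 nodes contributing 0 (the Cytoscape/STRING
    summary convention).  An empty graph yields zeros with a warning.
    """
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    if n == 0:
        warnings.warn("empty graph: topology summary is all zeros")
        return {"n_nodes": 0, "n_edges": 0, "average_degree": 0.0, "clustering_coefficient": 0.0}
    return {
        "n_nodes": n,
        "n_edges": e,
        "average_degree": 2.0 * e / n,
        "clustering_coefficient": nx.average_clustering(graph),
    }


def hub_candidates(graph: nx.Graph, top_fraction: float = 0.20) -> pd.DataFrame:
    """Degree-ranked nodes with a hub flag.

    Nodes are sorted by descending degree (ties broken by id).  A node is a
    hub when its degree is at or above the (1 - top_fraction) quantile of
    the degree distribution, i.e. the default flags the top 20%.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    degrees = dict(graph.degree())
    if not degrees:
        return pd.DataFrame(columns=["node", "degree", "hub"])
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    series = pd.Series([d for _, d in ranked], dtype=float)
    cutoff = series.quantile(1.0 - top_fraction)
    return pd.DataFrame(
        {
            "node": [n for n, _ in ranked],
            "degree": [d for _, d in ranked],
            "hub": [d >= cutoff for _, d in ranked],
        }
    )
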