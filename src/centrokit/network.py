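"""Protein-protein interaction network metrics.

Degree, local clustering coefficient and betweenness centrality on the
undirected simple graph of known interactions.  Betweenness follows the
shortest-path counting definition: for each unordered pair of other nodes,
a node is credited the fraction of shortest paths between the pair that
pass through it (endpoints excluded); on disconnected graphs pairs in
different components contribute nothing.  The average clustering
coefficient is the mean of local values over ALL nodes, counting nodes of
degree < 2 as 0 (one of the two standard conventions).

The customary "average degree" is ambiguous about its denominator, so
both variants are reported: over the interacting nodes of the graph and
over a caller-supplied total protein count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx

from .records import EdgeList


@dataclass
class NetworkMetrics:
    degree: dict
    betweenness: dict        # unnormalized, unordered pairs
    clustering: dict
    n_nodes: int
    n_edges: int
    average_degree: float    # 2|E| / |V| over graph nodes
    average_clustering: float
    average_degree_over_total: Optional[float] = None
    betweenness_normalized: dict = field(default_factory=dict)


def _to_graph(edges: EdgeList) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(edges.node_ids)
    g.add_edges_from(edges.edges)
    return g


def graph_metrics(edges: EdgeList,
                  total_proteins: Optional[int] = None) -> NetworkMetrics:
    """Compute per-node and per-graph metrics from an edge list.

    ``total_proteins`` optionally supplies the size of the full protein
    set (interacting or not) for the second average-degree convention.
    An empty graph is an error.
    """
    if edges.n_nodes == 0:
        raise ValueError("empty graph")
    g = _to_graph(edges)
    degree = {n: d for n, d in g.degree()}
    clustering = nx.clustering(g)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    betweenness_norm = nx.betweenness_centrality(g, normalized=True)
    n, m = g.number_of_nodes(), g.number_of_edges()
    return NetworkMetrics(
        degree=degree,
        betweenness=betweenness,
        clustering=clustering,
        n_nodes=n,
        n_edges=m,
        average_degree=2 * m / n,
        average_clustering=sum(clustering.values()) / n,
        average_degree_over_total=(2 * m / total_proteins
                                   if total_proteins else None),
        betweenness_normalized=betweenness_norm,
    )


def centrality_report(metrics: NetworkMetrics,
                      disorder_fractions: Optional[Mapping[str, float]] = None
                      ) -> list[dict]:
    """Nodes ranked by betweenness, annotated with degree and disorder.

    Ties in betweenness are broken by degree (descending) then node id
    (ascending); nodes without a disorder record are annotated as absent
    (None), never as 0.
    """
    disorder_fractions = disorder_fractions or {}
    rows = []
    for node in metrics.betweenness:
        rows.append({
            "protein_id": node,
            "betweenness": metrics.betweenness[node],
            "degree": metrics.degree[node],
            "clustering": metrics.clustering[node],
            "disorder_fraction": disorder_fractions.get(node),
        })
    rows.sort(key=lambda r: (-r["betweenness"], -r["degree"], r["protein_id"]))
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
    return rows
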