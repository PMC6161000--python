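"""Betweenness prioritization of dark-area metabolites and clustering
characterization of dark vs covered areas.

Betweenness centrality counts how often a node lies on shortest paths
between other node pairs, with even splitting across equal-length paths.
A high-betweenness metabolite inside the poorly covered area is a bridge:
acquiring its reference spectrum covers, by structural similarity, the
largest number of unmapped neighbors.  Centrality is computed on the FULL
graph and only the ranking is restricted to the dark area — a dark node's
bridging role is defined by the whole network, not the dark subgraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .community_lpa import LpaResult, UNCOVERED

__all__ = [
    "betweenness",
    "rank_dark_by_betweenness",
    "clustering_comparison",
    "ClusteringComparison",
]

log = logging.getLogger(__name__)


def betweenness(graph: nx.Graph) -> pd.DataFrame:
    """Exact unweighted betweenness (Brandes accumulation) per node.

    Both the raw pair count and the ``2/((n-1)(n-2))``-normalized value are
    reported; rankings are identical, comparisons here use raw.  Edge
    weights on the compound graph are ignored: path length is the number of
    reactions traversed.
    """
    raw = nx.betweenness_centrality(graph, normalized=False, weight=None)
    normed = nx.betweenness_centrality(graph, normalized=True, weight=None)
    return pd.DataFrame(
        {
            "node": list(raw),
            "betweenness": [raw[n] for n in raw],
            "betweenness_normalized": [normed[n] for n in raw],
        }
    )


def rank_dark_by_betweenness(
    graph: nx.Graph,
    result: LpaResult,
    k: int = 20,
    extra_attrs: tuple[str, ...] = ("name", "first_block", "pubchem_cid"),
) -> pd.DataFrame:
    """Top-``k`` dark-area nodes by full-graph betweenness.

    Ties are broken by node id so the ranking is deterministic given an
    :class:`LpaResult`.  Requested node attributes present on the graph
    (name, identifiers) are carried along for the report.
    """
    if not result.dark_nodes:
        return pd.DataFrame(columns=["rank", "node", "betweenness"])
    if k > len(result.dark_nodes):
        log.warning("k=%d exceeds dark-area size %d; returning all", k, len(result.dark_nodes))
        k = len(result.dark_nodes)
    bt = betweenness(graph).set_index("node")
    dark = sorted(
        (n for n in result.dark_nodes if n in bt.index),
        key=lambda n: (-bt.loc[n, "betweenness"], n),
    )[:k]
    rows = []
    for rank, node in enumerate(dark, start=1):
        row = {
            "rank": rank,
            "node": node,
            "betweenness": float(bt.loc[node, "betweenness"]),
            "betweenness_normalized": float(bt.loc[node, "betweenness_normalized"]),
        }
        data = graph.nodes[node]
        for attr in extra_attrs:
            if attr in data:
                row[attr] = data[attr]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClusteringComparison:
    per_node: pd.DataFrame          # node, area, local_clustering (main component)
    summary: pd.DataFrame           # mean/quartiles per area
    edges_within_covered: int
    edges_within_dark: int
    edges_between: int


def clustering_comparison(graph: nx.Graph, result: LpaResult) -> ClusteringComparison:
    """Local clustering coefficients of dark vs covered areas.

    Restricted to the main (largest) connected component.  Degree-<2 nodes
    have coefficient 0.  Also counts edges within each area versus between
    areas — sparse inter-area linking means the dark region is nearly
    disconnected from well-covered metabolism.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    main = max(nx.connected_components(graph), key=len)
    sub = graph.subgraph(main)
    coeffs = nx.clustering(sub)
    area = {
        n: ("dark" if result.aggregate.get(n) == UNCOVERED else "covered")
        for n in sub.nodes
    }
    per_node = pd.DataFrame(
        {
            "node": list(sub.nodes),
            "area": [area[n] for n in sub.nodes],
            "local_clustering": [coeffs[n] for n in sub.nodes],
        }
    )
    summary = (
        per_node.groupby("area")["local_clustering"]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .reset_index()
    )
    within_cov = within_dark = between = 0
    for u, v in graph.edges:
        a_u = result.aggregate.get(u) == UNCOVERED
        a_v = result.aggregate.get(v) == UNCOVERED
        if a_u and a_v:
            within_dark += 1
        elif not a_u and not a_v:
            within_cov += 1
        else:
            between += 1
    return ClusteringComparison(
        per_node=per_node,
        summary=summary,
        edges_within_covered=within_cov,
        edges_within_dark=within_dark,
        edges_between=between,
    )
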