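"""Per-node network context metrics for candidate proteins.

Reports, for each queried node: degree, normalized shortest-path
betweenness (Brandes, pair-count denominator (n-1)(n-2)/2 for undirected
graphs), local clustering coefficient, and the known-positive neighbor
ratio — the fraction of a node's neighbors that carry a positive disease
label. Together these place a candidate as hub, bridge, or peripheral
relative to the known disease module.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import pandas as pd

from .graph import LabelSet, PPINetwork

__all__ = ["topology_report"]


def topology_report(net: PPINetwork, labels: LabelSet,
                    query_nodes: Sequence[str] | None = None) -> pd.DataFrame:
    """Topology metrics for ``query_nodes`` (default: every node).

    Betweenness uses Brandes' algorithm with fractional splitting of
    shortest-path ties and normalization by (n-1)(n-2)/2; clustering is the
    local transitivity (0 for degree < 2).
    """
    g = net.to_networkx()
    if query_nodes is None:
        query_nodes = net.node_ids
    unknown = [q for q in query_nodes if q not in g]
    if unknown:
        raise ValueError(f"query nodes not in the network: {unknown[:10]}")
    betweenness = nx.betweenness_centrality(g, normalized=True)
    clustering = nx.clustering(g)
    positive_ids = {net.node_ids[i] for i in labels.positives}
    rows = []
    for node in query_nodes:
        neighbors = list(g.neighbors(node))
        degree = len(neighbors)
        known = sum(1 for nb in neighbors if nb in positive_ids)
        rows.append({
            "node": node,
            "degree": degree,
            "betweenness": betweenness[node],
            "clustering": clustering[node],
            "known_neighbors": known,
            "neighbor_ratio": known / degree if degree else 0.0,
        })
    return pd.DataFrame(rows)
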