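"""Gene-set similarity network from shared parent GO terms.

Two gene sets are connected when the Jaccard index of their parent-term
sets strictly exceeds a threshold (0.5 by default); clusters are the
connected components of the thresholded graph, and only components holding
strictly more than ``min_cluster_size`` sets (9 by default) are retained
for display.  The parent table is used exactly as supplied — no ancestor
closure over the GO DAG is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

__all__ = ["parent_jaccard", "build_and_cluster", "GeneSetNetwork"]


def parent_jaccard(term_a: str, term_b: str, parent_table: dict) -> float:
    """|parents(a) & parents(b)| / |parents(a) | parents(b)|; 0 when the
    union is empty (terms missing from the table have no parents)."""
    pa = set(parent_table.get(term_a, ()))
    pb = set(parent_table.get(term_b, ()))
    union = pa | pb
    if not union:
        return 0.0
    return len(pa & pb) / len(union)


@dataclass
class GeneSetNetwork:
    """Thresholded similarity graph over signature gene sets."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    clusters: dict[str, str]  # node -> cluster id (smallest member id)
    retained: dict[str, bool]

    @property
    def retained_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.retained[n]]

    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cid in self.clusters.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        return sizes

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges, weight="jaccard")
        return g


def build_and_cluster(
    hits,
    parent_table: dict,
    jaccard_min: float = 0.5,
    min_cluster_size: int = 9,
) -> GeneSetNetwork:
    """Build the parent-Jaccard network over ``hits`` and cluster it.

    Edges require Jaccard strictly greater than ``jaccard_min``; clusters
    are connected components with deterministic ids (the smallest member's
    id); a node is retained only when its component holds strictly more
    than ``min_cluster_size`` members.
    """
    nodes = sorted(set(hits))
    if not nodes:
        raise ValueError("no gene sets supplied")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    edges = []
    for a, b in combinations(nodes, 2):
        j = parent_jaccard(a, b, parent_table)
        if j > jaccard_min:
            g.add_edge(a, b, jaccard=j)
            edges.append((a, b, j))
    clusters: dict[str, str] = {}
    retained: dict[str, bool] = {}
    for comp in nx.connected_components(g):
        cid = min(comp)
        keep = len(comp) > min_cluster_size
        for node in comp:
            clusters[node] = cid
            retained[node] = keep
    return GeneSetNetwork(nodes=nodes, edges=edges, clusters=clusters,
                          retained=retained)
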