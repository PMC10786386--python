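"""Centrality, global efficiency and community structure of interaction networks.

Definitions (unweighted, undirected):

* degree          k_i = sum_j a_ij
* closeness       c_i = (n-1) / sum_j d_ij, with the Wasserman-Faust scaling
                  (within-component closeness times the reachable fraction)
                  on disconnected graphs, so values stay finite and comparable
                  after node removal; an isolated node has closeness 0
* betweenness     b_i = sum_{j<k, i not in {j,k}} sigma(j,k|i)/sigma(j,k),
                  normalized by (n-1)(n-2)/2, the number of node pairs a node
                  could lie between
* global efficiency g = 1/(n(n-1)) sum_{i != j} 1/d_ij with 1/inf := 0

Shortest-path multiplicities are counted exactly (Brandes accumulation via
networkx).  Communities come from greedy (agglomerative) modularity
maximization, which is deterministic for a given input graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "centrality_table",
    "global_efficiency",
    "CommunityPartition",
    "detect_communities",
]


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Raw degree k_i (edge count) per node."""
    return dict(net.degree())


def closeness_centrality(net: nx.Graph) -> dict[str, float]:
    """Closeness c_i in [0, 1]; Wasserman-Faust scaled if disconnected."""
    return nx.closeness_centrality(net, wf_improved=True)


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Pair-dependency betweenness normalized to [0, 1] (0 for n < 3)."""
    return nx.betweenness_centrality(net, normalized=True)


def centrality_table(net: nx.Graph) -> pd.DataFrame:
    """All three centralities as one DataFrame indexed by node."""
    df = pd.DataFrame(
        {
            "degree": pd.Series(degree_centrality(net)),
            "closeness": pd.Series(closeness_centrality(net)),
            "betweenness": pd.Series(betweenness_centrality(net)),
        }
    )
    df.index.name = "node"
    return df


def global_efficiency(net: nx.Graph) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    1 on a complete graph, 0 on an edgeless one; unreachable pairs contribute
    0.  Undefined (raises) for fewer than two nodes.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("global efficiency is undefined for fewer than 2 nodes")
    return nx.global_efficiency(net)


@dataclass
class CommunityPartition:
    """A node partition with its modularity score."""

    communities: tuple[frozenset, ...]
    membership: dict[str, int]
    modularity: float

    def __len__(self) -> int:
        return len(self.communities)


def detect_communities(net: nx.Graph) -> CommunityPartition:
    """Greedy modularity maximization (Clauset-Newman-Moore agglomeration)."""
    comms = nx.community.greedy_modularity_communities(net)
    communities = tuple(frozenset(c) for c in comms)
    membership = {node: idx for idx, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(net, communities)
    return CommunityPartition(communities, membership, q)
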