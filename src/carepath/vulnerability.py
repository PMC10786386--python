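"""Vulnerability analysis of the clinical interaction network.

Three instruments:

1. A *constrained connected double-edge swap* null model.  Each attempt picks
   two distinct edges (i, j) and (u, v) uniformly at random (with random
   orientation) and proposes rewiring them to (i, u) and (j, v).  The swap is
   applied only if no self-loop or duplicate edge arises, neither proposed
   edge is forbidden by operational policy, and the graph stays connected;
   otherwise the graph is left unchanged and the attempt counts as a failure.
   Every ensemble member therefore has exactly the original degree sequence.
   A node's observed betweenness is then located as a percentile within its
   own ensemble distribution (midpoint handling of exact ties); above the
   95th percentile is flagged as higher than expected by chance.

2. *Node-removal impact*: the percent change in global efficiency, and the
   change in closeness of every doctor, when one node is removed.

3. *Greedy edge restoration*: after removing a compromised node, candidate
   edges are added one at a time, each time choosing an edge that maximizes
   the gain in global efficiency.  Greedy choice is no longer guaranteed
   optimal once a tie occurs, so on the first tie all orderings of the
   remaining candidates are examined and the complete set of sequences
   attaining the step-wise maximal efficiency trace is returned, together
   with the tied edge group at each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .eventlog import AgentCatalog
from .netbuild import forbidden_pairs, is_forbidden
from .netstats import betweenness_centrality, closeness_centrality, global_efficiency

__all__ = [
    "ShuffleEnsemble",
    "PercentileResult",
    "RemovalImpact",
    "RestorationTrace",
    "attempt_constrained_swap",
    "shuffle_network",
    "shuffle_ensemble",
    "betweenness_percentile_test",
    "node_removal_impact",
    "default_restoration_candidates",
    "greedy_edge_restoration",
]


def _swap_once(G: nx.Graph, edges: list, forbidden: frozenset, rng: np.random.Generator) -> bool:
    """One swap attempt, mutating ``G`` and ``edges`` in place on success."""
    m = len(edges)
    if m < 2:
        return False
    e1 = int(rng.integers(m))
    e2 = int(rng.integers(m - 1))
    if e2 >= e1:
        e2 += 1
    i, j = edges[e1]
    u, v = edges[e2]
    if rng.integers(2):
        i, j = j, i
    if rng.integers(2):
        u, v = v, u
    if len({i, j, u, v}) < 4:
        return False
    if G.has_edge(i, u) or G.has_edge(j, v):
        return False
    if frozenset((i, u)) in forbidden or frozenset((j, v)) in forbidden:
        return False
    G.remove_edge(i, j)
    G.remove_edge(u, v)
    G.add_edge(i, u)
    G.add_edge(j, v)
    # the swap can only disconnect the graph if i and j end up in different
    # components; every other node still reaches one of {i, j, u, v}
    if not nx.has_path(G, i, j):
        G.remove_edge(i, u)
        G.remove_edge(j, v)
        G.add_edge(i, j)
        G.add_edge(u, v)
        return False
    edges[e1] = (i, u)
    edges[e2] = (j, v)
    return True


def attempt_constrained_swap(
    net: nx.Graph, catalog: AgentCatalog, rng: np.random.Generator
) -> tuple[nx.Graph, bool]:
    """Attempt one constrained swap, mutating ``net`` in place.

    Returns ``(net, success)``; a failed attempt leaves the graph unchanged
    and is a normal outcome, not an error.
    """
    edges = [tuple(e) for e in net.edges()]
    forbidden = forbidden_pairs(net.nodes(), catalog)
    return net, _swap_once(net, edges, forbidden, rng)


def shuffle_network(
    net: nx.Graph,
    catalog: AgentCatalog,
    attempts: int,
    rng: np.random.Generator,
) -> tuple[nx.Graph, int]:
    """Apply ``attempts`` sequential swap attempts to a copy of ``net``.

    Returns the shuffled graph and the number of successful swaps.  Failed
    attempts count toward ``attempts``.
    """
    if net.number_of_nodes() and not nx.is_connected(net):
        raise ValueError("the shuffle null model requires a connected network")
    G = net.copy()
    edges = [tuple(e) for e in G.edges()]
    forbidden = forbidden_pairs(G.nodes(), catalog)
    n_success = 0
    for _ in range(attempts):
        if _swap_once(G, edges, forbidden, rng):
            n_success += 1
    return G, n_success


@dataclass
class ShuffleEnsemble:
    """Degree-preserving null ensemble and its per-node betweenness values.

    ``betweenness`` is an (n_shuffles, n_nodes) array aligned with ``nodes``.
    Per-shuffle RNG streams are spawned from one master seed, so ensembles
    are bit-reproducible.
    """

    nodes: tuple[str, ...]
    betweenness: np.ndarray
    swap_successes: np.ndarray
    attempts: int
    seed: int
    networks: list[nx.Graph] | None = field(default=None, repr=False)

    @property
    def n_shuffles(self) -> int:
        return self.betweenness.shape[0]

    def node_distribution(self, node: str) -> np.ndarray:
        return self.betweenness[:, self.nodes.index(node)]


def shuffle_ensemble(
    net: nx.Graph,
    catalog: AgentCatalog,
    n_shuffles: int = 1000,
    attempts: int = 20000,
    seed: int = 0,
    keep_networks: bool = False,
) -> ShuffleEnsemble:
    """Generate ``n_shuffles`` independently shuffled networks.

    Each shuffle starts from the observed network and runs ``attempts``
    constrained swap attempts with its own RNG stream spawned from ``seed``.
    """
    nodes = tuple(net.nodes())
    bet = np.empty((n_shuffles, len(nodes)))
    successes = np.empty(n_shuffles, dtype=int)
    kept = [] if keep_networks else None
    children = np.random.SeedSequence(seed).spawn(n_shuffles)
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        G, n_succ = shuffle_network(net, catalog, attempts, rng)
        b = betweenness_centrality(G)
        bet[s] = [b[v] for v in nodes]
        successes[s] = n_succ
        if kept is not None:
            kept.append(G)
    return ShuffleEnsemble(nodes, bet, successes, attempts, seed, kept)


@dataclass
class PercentileResult:
    node: str
    observed: float
    percentile: float
    flagged: bool


def betweenness_percentile_test(
    net: nx.Graph, node: str, ensemble: ShuffleEnsemble
) -> PercentileResult:
    """Percentile of a node's observed betweenness within its null distribution.

    Exact ties get midpoint (average-rank) handling to avoid flag flips from
    floating-point equality.  ``flagged`` means strictly above the 95th
    percentile.
    """
    if node not in ensemble.nodes:
        raise AssertionError(f"{node!r} missing from the ensemble node set")
    observed = betweenness_centrality(net)[node]
    dist = ensemble.node_distribution(node)
    pct = 100.0 * ((dist < observed).sum() + 0.5 * (dist == observed).sum()) / len(dist)
    return PercentileResult(node, observed, float(pct), pct > 95.0)


@dataclass
class RemovalImpact:
    """Effect of removing one node: Δg% and per-doctor closeness change."""

    node: str
    g_before: float
    g_after: float
    delta_g_percent: float
    delta_closeness: dict[str, float]


def node_removal_impact(net: nx.Graph, node: str) -> RemovalImpact:
    """Percent change in global efficiency and doctors' closeness change.

    Closeness after removal uses the Wasserman-Faust convention, so the
    measure stays defined if the removal disconnects the graph.  Doctors are
    nodes with role attribute ``doctor``.
    """
    if node not in net:
        raise KeyError(f"{node!r} not in network")
    if net.number_of_nodes() < 3:
        raise ValueError("removal impact needs at least 3 nodes")
    g_before = global_efficiency(net)
    close_before = closeness_centrality(net)
    reduced = net.copy()
    reduced.remove_node(node)
    g_after = global_efficiency(reduced)
    close_after = closeness_centrality(reduced)
    doctors = [
        v for v, data in net.nodes(data=True) if data.get("role") == "doctor" and v != node
    ]
    delta_close = {v: close_after[v] - close_before[v] for v in doctors}
    return RemovalImpact(
        node=node,
        g_before=g_before,
        g_after=g_after,
        delta_g_percent=100.0 * (g_after - g_before) / g_before,
        delta_closeness=delta_close,
    )


def default_restoration_candidates(
    net: nx.Graph, catalog: AgentCatalog, removed: str | None = None
) -> list[tuple[str, str]]:
    """Absent doctor-doctor pairs spanning the two ED teams.

    The restoration strategy targets links between doctors of the Emergency
    Medical and Emergency Psychiatry teams; any other candidate set can be
    passed to :func:`greedy_edge_restoration` directly.
    """
    em = [v for v in net if v != removed and catalog[v].team == "emergency_medical" and catalog[v].role == "doctor"]
    ep = [v for v in net if v != removed and catalog[v].team == "emergency_psychiatry" and catalog[v].role == "doctor"]
    out = []
    for a in em:
        for b in ep:
            pair = tuple(sorted((a, b)))
            if not net.has_edge(*pair) and not is_forbidden(*pair, catalog):
                out.append(pair)
    return sorted(set(out))


@dataclass
class RestorationTrace:
    """Result of greedy edge restoration after a node removal.

    ``sequence`` is the canonical (lexicographically smallest) optimal order;
    ``g_trace`` holds global efficiency before any addition and after each
    one; ``tie_groups[t]`` is the tuple of edges tied for the best gain at
    step t; ``optimal_sequences`` is the complete set of orderings attaining
    the step-wise maximal efficiency trace (possibly truncated at
    ``max_sequences``, in which case ``truncated`` is set).
    """

    removed: str
    candidates: tuple[tuple[str, str], ...]
    sequence: tuple[tuple[str, str], ...]
    g_trace: tuple[float, ...]
    tie_groups: tuple[tuple[tuple[str, str], ...], ...]
    optimal_sequences: tuple[tuple[tuple[str, str], ...], ...]
    truncated: bool = False


def greedy_edge_restoration(
    net: nx.Graph,
    removed: str,
    candidates,
    tol: float = 1e-12,
    max_sequences: int = 5000,
) -> RestorationTrace:
    """Remove ``removed`` then add candidate edges greedily by efficiency gain.

    Candidates must be valid pairs of remaining nodes and absent from the
    post-removal network (validated).  All candidates end up added, so the
    final efficiency is sequence-independent; what the trace resolves is the
    best achievable efficiency after each individual addition.
    """
    base = net.copy()
    if removed in base:
        base.remove_node(removed)
    candidates = tuple(tuple(sorted(e)) for e in candidates)
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate edges")
    for a, b in candidates:
        if a not in base or b not in base:
            raise ValueError(f"candidate edge ({a}, {b}) has an endpoint outside the network")
        if base.has_edge(a, b):
            raise ValueError(f"candidate edge ({a}, {b}) already present")

    cache: dict[frozenset, float] = {}

    def g_of(added: frozenset) -> float:
        if added not in cache:
            base.add_edges_from(added)
            cache[added] = global_efficiency(base)
            base.remove_edges_from(added)
        return cache[added]

    g0 = g_of(frozenset())
    # breadth-first branching over tied best choices: after each step the
    # frontier holds exactly the prefixes attaining the lexicographically
    # maximal efficiency trace so far
    frontier: list[tuple[tuple[str, str], ...]] = [()]
    g_trace = [g0]
    tie_groups: list[tuple[tuple[str, str], ...]] = []
    truncated = False
    for _ in range(len(candidates)):
        best = -np.inf
        nxt: list[tuple[tuple[str, str], ...]] = []
        step_edges: set[tuple[str, str]] = set()
        for seq in frontier:
            placed = set(seq)
            for e in candidates:
                if e in placed:
                    continue
                val = g_of(frozenset(placed | {e}))
                if val > best + tol:
                    best = val
                    nxt = [seq + (e,)]
                    step_edges = {e}
                elif val >= best - tol:
                    nxt.append(seq + (e,))
                    step_edges.add(e)
        if len(nxt) > max_sequences:
            nxt = nxt[:max_sequences]
            truncated = True
        frontier = nxt
        g_trace.append(best)
        tie_groups.append(tuple(sorted(step_edges)))
    frontier = sorted(set(frontier))
    return RestorationTrace(
        removed=removed,
        candidates=candidates,
        sequence=frontier[0] if frontier else (),
        g_trace=tuple(g_trace),
        tie_groups=tuple(tie_groups),
        optimal_sequences=tuple(frontier),
        truncated=truncated,
    )
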