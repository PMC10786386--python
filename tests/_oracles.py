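"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: shortest paths by exhaustive simple-
path enumeration, naive Bayes by explicit probability products, restoration
by trying every candidate ordering, modularity by scanning all partitions.
None of it shares code with the package.
"""

from __future__ import annotations

from itertools import combinations, permutations

import networkx as nx
import numpy as np


def _all_simple_paths(adj: dict, s, t):
    """Yield every simple path from s to t by depth-first enumeration."""
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nbr in adj[node]:
            if nbr not in path:
                stack.append((nbr, path + [nbr]))


def shortest_path_census(G: nx.Graph):
    """d[s][t], sigma[s][t] and per-interior-node counts by enumeration."""
    adj = {v: sorted(G.neighbors(v)) for v in G}
    nodes = sorted(G)
    dist: dict = {s: {} for s in nodes}
    sigma: dict = {s: {} for s in nodes}
    interior: dict = {s: {} for s in nodes}
    for s, t in combinations(nodes, 2):
        paths = list(_all_simple_paths(adj, s, t))
        if not paths:
            continue
        d = min(len(p) - 1 for p in paths)
        shortest = [p for p in paths if len(p) - 1 == d]
        dist[s][t] = dist.setdefault(t, {})[s] = d
        sigma[s][t] = sigma.setdefault(t, {})[s] = len(shortest)
        counts: dict = {}
        for p in shortest:
            for v in p[1:-1]:
                counts[v] = counts.get(v, 0) + 1
        interior[s][t] = counts
    return dist, sigma, interior


def closeness_oracle(G: nx.Graph) -> dict:
    dist, _, _ = shortest_path_census(G)
    n = G.number_of_nodes()
    out = {}
    for v in G:
        reach = dist.get(v, {})
        r = len(reach)
        if r == 0 or n < 2:
            out[v] = 0.0
            continue
        within = r / sum(reach.values())
        out[v] = within * (r / (n - 1))
    return out


def betweenness_oracle(G: nx.Graph) -> dict:
    n = G.number_of_nodes()
    out = {v: 0.0 for v in G}
    if n < 3:
        return out
    dist, sigma, interior = shortest_path_census(G)
    for s, t in combinations(sorted(G), 2):
        if t not in sigma.get(s, {}):
            continue
        for v, cnt in interior[s][t].items():
            out[v] += cnt / sigma[s][t]
    norm = (n - 1) * (n - 2) / 2.0
    return {v: val / norm for v, val in out.items()}


def efficiency_oracle(G: nx.Graph) -> float:
    dist, _, _ = shortest_path_census(G)
    n = G.number_of_nodes()
    total = 0.0
    for s in G:
        for t, d in dist.get(s, {}).items():
            total += 1.0 / d
    return total / (n * (n - 1))


def nb_posterior_oracle(X, y, query, alpha=1.0):
    """P(class | query) by explicit products over features; classes {0, 1}."""
    X = np.asarray(X)
    y = np.asarray(y)
    post = []
    for c in (0, 1):
        rows = X[y == c]
        prior = len(rows) / len(y)
        p = prior
        for f in range(X.shape[1]):
            pf = (rows[:, f].sum() + alpha) / (len(rows) + 2 * alpha)
            p *= pf if query[f] else (1.0 - pf)
        post.append(p)
    total = sum(post)
    return [p / total for p in post]


def restoration_oracle(G_after_removal: nx.Graph, candidates):
    """All candidate orderings attaining the step-wise maximal g trace."""
    def g(graph):
        return nx.global_efficiency(graph)

    traces = {}
    for order in permutations(candidates):
        H = G_after_removal.copy()
        trace = [g(H)]
        for e in order:
            H.add_edge(*e)
            trace.append(g(H))
        traces[order] = trace
    best = max(traces.values(), key=lambda tr: tuple(round(x, 12) for x in tr))
    key = tuple(round(x, 12) for x in best)
    optimal = sorted(
        order for order, tr in traces.items()
        if tuple(round(x, 12) for x in tr) == key
    )
    return optimal, best


def _partitions(items):
    """All set partitions (Bell-number enumeration; fine for n <= 8)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def max_modularity_partition(G: nx.Graph):
    """Exhaustive modularity maximization over every partition."""
    best_q, best_part = -np.inf, None
    for part in _partitions(sorted(G)):
        q = nx.community.modularity(G, [set(p) for p in part])
        if q > best_q:
            best_q, best_part = q, part
    return [frozenset(p) for p in best_part], best_q


def random_connected_graph(seed: int, n_min: int = 3, n_max: int = 8) -> nx.Graph:
    """Seeded random connected graph with between n_min and n_max nodes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.3, 0.9))
    while True:
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if G.number_of_nodes() >= 2 and nx.is_connected(G):
            return nx.relabel_nodes(G, {i: f"n{i}" for i in G})
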