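import networkx as nx
import numpy as np
import pytest

from carepath import netstats, synthdata, vulnerability
from carepath.eventlog import AgentCatalog, AgentEntry
from carepath.netbuild import build_interaction_network
from carepath.vulnerability import (
    ShuffleEnsemble,
    attempt_constrained_swap,
    betweenness_percentile_test,
    default_restoration_candidates,
    greedy_edge_restoration,
    node_removal_impact,
    shuffle_ensemble,
    shuffle_network,
    _swap_once,
)

from ._oracles import random_connected_graph, restoration_oracle


def _plain_catalog(names):
    """Catalog of plain agents (no systems), so no pair is forbidden."""
    return AgentCatalog([AgentEntry(n, "clinical_staff", "none", "none") for n in names])


class _ScriptedRNG:
    """Replays a fixed sequence of integers() draws."""

    def __init__(self, draws):
        self._draws = list(draws)

    def integers(self, *_args, **_kwargs):
        return self._draws.pop(0)


class TestConstrainedSwap:
    def test_path_swap_rewires_as_expected(self):
        G = nx.path_graph(["a", "b", "c", "d"])
        edges = [tuple(e) for e in G.edges()]  # [(a,b), (b,c), (c,d)]
        # pick edge 0 and edge 2, no orientation flips -> propose (a,c), (b,d)
        rng = _ScriptedRNG([0, 1, 0, 0])
        ok = _swap_once(G, edges, frozenset(), rng)
        assert ok
        assert {tuple(sorted(e)) for e in G.edges()} == {("a", "c"), ("b", "c"), ("b", "d")}
        assert dict(G.degree()) == {"a": 1, "b": 2, "c": 2, "d": 1}

    def test_forbidden_proposal_leaves_graph_unchanged(self):
        G = nx.path_graph(["a", "b", "c", "d"])
        edges = [tuple(e) for e in G.edges()]
        rng = _ScriptedRNG([0, 1, 0, 0])
        forbidden = frozenset({frozenset(("a", "c"))})
        ok = _swap_once(G, edges, forbidden, rng)
        assert not ok
        assert {tuple(sorted(e)) for e in G.edges()} == {("a", "b"), ("b", "c"), ("c", "d")}

    def test_triangle_never_swaps(self, catalog):
        G = nx.complete_graph(["Nurse", "Patient", "Consultant"])
        rng = np.random.default_rng(0)
        for _ in range(50):
            _, ok = attempt_constrained_swap(G, catalog, rng)
            assert not ok
        assert G.number_of_edges() == 3

    def test_disconnecting_swap_is_reverted(self):
        # bowtie: two triangles sharing node x; swapping the only inter-lobe
        # path edges could disconnect, so any applied swap must stay connected
        G = nx.Graph([("a", "b"), ("b", "x"), ("a", "x"), ("x", "c"), ("x", "d"), ("c", "d")])
        rng = np.random.default_rng(3)
        cat = _plain_catalog(list(G.nodes()))
        for _ in range(200):
            attempt_constrained_swap(G, cat, rng)
            assert nx.is_connected(G)


class TestShuffleNetwork:
    def test_zero_attempts_is_identity(self, catalog):
        G = nx.path_graph(["Nurse", "Patient", "Consultant", "RMO"])
        out, n_succ = shuffle_network(G, catalog, 0, np.random.default_rng(0))
        assert n_succ == 0
        assert set(out.edges()) == set(G.edges())

    def test_degree_sequence_preserved(self, ed_log):
        G = build_interaction_network(ed_log)
        out, n_succ = shuffle_network(G, ed_log.catalog, 2000, np.random.default_rng(1))
        assert dict(out.degree()) == dict(G.degree())
        assert n_succ > 0
        assert set(out.edges()) != set(G.edges())

    def test_disconnected_input_rejected(self, catalog):
        G = nx.Graph([("Nurse", "Patient"), ("RMO", "Consultant")])
        with pytest.raises(ValueError, match="connected"):
            shuffle_network(G, catalog, 10, np.random.default_rng(0))


class TestEnsemble:
    @pytest.fixture(scope="class")
    def net_and_catalog(self):
        log = synthdata.study_scale_fixture()
        from carepath.eventlog import exclude_mhoa_only_patients

        ed = exclude_mhoa_only_patients(log)
        return build_interaction_network(ed), ed.catalog

    def test_members_preserve_invariants(self, net_and_catalog):
        G, cat = net_and_catalog
        from carepath.netbuild import is_forbidden

        ens = shuffle_ensemble(G, cat, n_shuffles=5, attempts=2000, seed=11,
                               keep_networks=True)
        for H in ens.networks:
            assert dict(H.degree()) == dict(G.degree())
            assert nx.is_connected(H)
            for i, j in H.edges():
                assert not is_forbidden(i, j, cat)

    def test_seeded_ensemble_is_bit_reproducible(self, net_and_catalog):
        G, cat = net_and_catalog
        a = shuffle_ensemble(G, cat, n_shuffles=4, attempts=1000, seed=5,
                             keep_networks=True)
        b = shuffle_ensemble(G, cat, n_shuffles=4, attempts=1000, seed=5,
                             keep_networks=True)
        assert np.array_equal(a.betweenness, b.betweenness)
        assert np.array_equal(a.swap_successes, b.swap_successes)
        for H1, H2 in zip(a.networks, b.networks):
            assert set(H1.edges()) == set(H2.edges())


class TestPercentileTest:
    def _ensemble(self, values):
        return ShuffleEnsemble(
            nodes=("x",),
            betweenness=np.array(values, dtype=float).reshape(-1, 1),
            swap_successes=np.zeros(len(values), dtype=int),
            attempts=0,
            seed=0,
        )

    def test_value_above_all_shuffles_is_percentile_100(self, monkeypatch):
        ens = self._ensemble(np.linspace(0, 0.5, 100))
        G = nx.path_graph(["a", "x", "b"])  # x has betweenness 1
        res = betweenness_percentile_test(G, "x", ens)
        assert res.percentile == 100.0
        assert res.flagged

    def test_value_at_ensemble_median_is_about_50_and_unflagged(self):
        # middle node of a 3-path has betweenness exactly 1.0
        values = [0.5] * 50 + [1.0] * 9 + [1.5] * 50
        ens = self._ensemble(values)
        G = nx.path_graph(["a", "x", "b"])
        res = betweenness_percentile_test(G, "x", ens)
        assert res.percentile == pytest.approx(50.0, abs=2.0)
        assert not res.flagged

    def test_node_missing_from_ensemble_asserts(self):
        ens = self._ensemble([0.1])
        G = nx.path_graph(["a", "y", "b"])
        with pytest.raises(AssertionError):
            betweenness_percentile_test(G, "y", ens)


class TestNodeRemoval:
    def test_star_center_removal_zeroes_efficiency(self):
        G = nx.star_graph(4)
        impact = node_removal_impact(G, 0)
        assert impact.g_before == pytest.approx(0.7)
        assert impact.g_after == 0.0
        assert impact.delta_g_percent == pytest.approx(-100.0)

    def test_star_leaf_removal_raises_efficiency(self):
        G = nx.star_graph(4)
        impact = node_removal_impact(G, 1)
        assert impact.g_after == pytest.approx(0.75)
        assert impact.delta_g_percent == pytest.approx(100 * (0.75 - 0.7) / 0.7)

    def test_doctor_closeness_reported_with_disconnection_convention(self):
        G = nx.path_graph(["a", "b", "c", "d", "e"])
        nx.set_node_attributes(G, {v: "doctor" for v in "ade"}, "role")
        impact = node_removal_impact(G, "c")
        assert set(impact.delta_closeness) == {"a", "d", "e"}
        assert all(np.isfinite(v) for v in impact.delta_closeness.values())

    def test_hub_removal_dominates_leaf_removal(self, fixture_log_with_truth):
        from carepath.eventlog import exclude_mhoa_only_patients

        log, truth = fixture_log_with_truth
        G = build_interaction_network(exclude_mhoa_only_patients(log))
        hub = truth["hub"]
        d_hub = abs(node_removal_impact(G, hub).delta_g_percent)
        d_leaf = abs(node_removal_impact(G, "Intern").delta_g_percent)
        assert d_hub > d_leaf


class TestGreedyRestoration:
    def test_single_candidate_strictly_improves(self):
        G = nx.path_graph(["a", "b", "c", "d", "e", "x"])
        trace = greedy_edge_restoration(G, "x", [("a", "e")])
        assert trace.sequence == (("a", "e"),)
        assert trace.g_trace[1] > trace.g_trace[0]

    def test_candidate_already_present_rejected(self):
        G = nx.path_graph(["a", "b", "c", "x"])
        with pytest.raises(ValueError, match="already present"):
            greedy_edge_restoration(G, "x", [("a", "b")])

    def test_two_triangles_bridge_matches_exhaustive(self):
        G = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])
        G.add_node("hub")
        G.add_edges_from([("hub", "a"), ("hub", "f")])
        candidates = [("a", "d"), ("b", "e"), ("a", "f")]
        trace = greedy_edge_restoration(G, "hub", candidates)
        H = G.copy()
        H.remove_node("hub")
        optimal, best = restoration_oracle(H, candidates)
        assert tuple(trace.sequence) in set(optimal)
        assert trace.g_trace == pytest.approx(best)
        assert set(trace.optimal_sequences) == {tuple(o) for o in optimal}

    def test_automorphic_candidates_form_one_tie_group(self):
        G = nx.star_graph(4)  # removing the center isolates the leaves
        candidates = [(1, 2), (3, 4)]
        trace = greedy_edge_restoration(G, 0, candidates)
        assert trace.tie_groups[0] == ((1, 2), (3, 4))
        assert len(trace.optimal_sequences) == 2
        traces = {
            tuple(np.round(trace.g_trace, 12)) for _ in trace.optimal_sequences
        }
        assert len(traces) == 1  # identical efficiency trajectory

    @pytest.mark.parametrize("seed", range(12))
    def test_random_graphs_match_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        G = random_connected_graph(seed + 1000, n_min=5, n_max=8)
        removed = sorted(G)[int(rng.integers(G.number_of_nodes()))]
        H = G.copy()
        H.remove_node(removed)
        if H.number_of_nodes() < 3:
            return
        absent = [
            (u, v) for u in sorted(H) for v in sorted(H)
            if u < v and not H.has_edge(u, v)
        ]
        k = min(len(absent), int(rng.integers(1, 5)))
        if k == 0:
            return
        idx = rng.choice(len(absent), size=k, replace=False)
        candidates = [absent[i] for i in idx]
        trace = greedy_edge_restoration(G, removed, candidates)
        optimal, best = restoration_oracle(H, candidates)
        assert trace.g_trace == pytest.approx(best)
        assert set(trace.optimal_sequences) == {tuple(o) for o in optimal}
        diffs = np.diff(trace.g_trace)
        assert (diffs >= -1e-12).all()

    def test_final_efficiency_independent_of_sequence(self):
        G = nx.star_graph(5)
        candidates = [(1, 2), (2, 3), (4, 5)]
        trace = greedy_edge_restoration(G, 0, candidates)
        H = G.copy()
        H.remove_node(0)
        H.add_edges_from(candidates)
        assert trace.g_trace[-1] == pytest.approx(nx.global_efficiency(H))


class TestDefaultCandidates:
    def test_cross_team_doctor_pairs_absent_from_network(self, ed_log):
        G = build_interaction_network(ed_log)
        cands = default_restoration_candidates(G, ed_log.catalog, "Psychiatric Liaison Nurse")
        assert cands
        for a, b in cands:
            assert not G.has_edge(a, b)
            teams = {ed_log.catalog[a].team, ed_log.catalog[b].team}
            assert teams == {"emergency_medical", "emergency_psychiatry"}
            assert ed_log.catalog[a].role == ed_log.catalog[b].role == "doctor"
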