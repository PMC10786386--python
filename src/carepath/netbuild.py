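"""Build the two network views of an event log.

*Clinical interaction network* — an undirected simple graph over agents and
information systems; an edge means the pair was observed interacting at least
once across the combined trajectories.  Operational policy makes some pairs
impossible regardless of what a multi-party record might suggest (a patient
never writes to the patient file directly); these *forbidden edges* are
excluded by construction:

(a) between two information systems;
(b) between an information system and anyone who is not clinical staff;
(c) between a psychiatry-restricted information system and any member of
    staff outside the Emergency Psychiatry team.

*Patient trajectory network* — a directed graph over presentation modes,
clinical teams and discharge modes; an edge means at least one observed
transition of that type.

Records list two or more parties per interaction; the interaction network
expands each record to the clique over its agents plus all agent-system
pairs, with forbidden pairs removed.
"""

from __future__ import annotations

import warnings
from itertools import combinations, product

import networkx as nx

from .eventlog import AgentCatalog, EventLog, EventRecord

__all__ = [
    "is_forbidden",
    "forbidden_pairs",
    "edges_from_interaction",
    "build_interaction_network",
    "build_trajectory_network",
    "DEFAULT_SETTING_TEAMS",
]

# team a patient is implicitly under on entry to each care setting, used when
# no referral action has named a team yet
DEFAULT_SETTING_TEAMS = {"ED": "Emergency Medical", "MHOA": "MHOA"}

REFERRAL_PREFIX = "Referral to "
DISCHARGE_PREFIX = "Discharge"


def is_forbidden(i: str, j: str, catalog: AgentCatalog) -> bool:
    """True if the pair (i, j) is excluded by operational policy (rules a-c)."""
    a, b = catalog[i], catalog[j]
    a_sys = a.category == "information_system"
    b_sys = b.category == "information_system"
    if a_sys and b_sys:
        return True
    if a_sys != b_sys:
        system, other = (a, b) if a_sys else (b, a)
        if other.category != "clinical_staff":
            return True
        if system.psychiatry_restricted and other.team != "emergency_psychiatry":
            return True
    return False


def forbidden_pairs(nodes, catalog: AgentCatalog) -> frozenset[frozenset]:
    """All forbidden unordered pairs among ``nodes`` (for fast membership tests)."""
    nodes = list(nodes)
    return frozenset(
        frozenset((i, j))
        for i, j in combinations(nodes, 2)
        if is_forbidden(i, j, catalog)
    )


def edges_from_interaction(rec: EventRecord, catalog: AgentCatalog) -> set[tuple[str, str]]:
    """Unordered node pairs implied by one record, forbidden pairs removed.

    Clique over the record's agents, plus every (agent, system) pair.
    System-system pairs are forbidden by rule (a) and never produced.
    Pairs are returned as sorted 2-tuples.
    """
    agents = sorted(set(rec.agents))
    systems = sorted(set(rec.info_systems))
    pairs = set()
    for i, j in combinations(agents, 2):
        if not is_forbidden(i, j, catalog):
            pairs.add((i, j))
    for a, s in product(agents, systems):
        if not is_forbidden(a, s, catalog):
            pairs.add(tuple(sorted((a, s))))
    return pairs


def build_interaction_network(log: EventLog) -> nx.Graph:
    """Union of per-record edge sets over every record of every patient.

    Nodes are exactly the agents/systems appearing in at least one record and
    carry catalog attributes plus ``frequency`` (number of records listing the
    node, kept as reporting metadata only — edges stay unweighted).  Callers
    analysing the ED system should exclude MHOA-only patients first.
    """
    G = nx.Graph(kind="clinical_interaction")
    if not log.records:
        warnings.warn("building an interaction network from an empty event log")
        return G
    catalog = log.catalog
    for rec in log.records:
        for name in list(rec.agents) + list(rec.info_systems):
            if name not in G:
                entry = catalog[name]
                G.add_node(
                    name,
                    category=entry.category,
                    team=entry.team,
                    role=entry.role,
                    psychiatry_restricted=entry.psychiatry_restricted,
                    frequency=0,
                )
        for name in set(rec.agents) | set(rec.info_systems):
            G.nodes[name]["frequency"] += 1
        G.add_edges_from(edges_from_interaction(rec, catalog))
    return G


def _referral_target(action: str | None) -> str | None:
    if action and action.startswith(REFERRAL_PREFIX):
        return action[len(REFERRAL_PREFIX):].strip()
    return None


def build_trajectory_network(log: EventLog) -> nx.DiGraph:
    """Directed presentation → teams → discharge transition graph.

    Uses the combined data from all patients and settings.  Per patient:
    presentation mode → first team (the target of the first referral action,
    else the setting's default team); team → team on each referral action;
    team → MHOA on a setting change into the observation area; team →
    discharge node on a ``Discharge...`` action.  Edges are unweighted; a
    referral to the team already treating is ignored with a warning.  Node
    attribute ``kind`` is one of ``presentation``/``team``/``discharge``.
    """
    G = nx.DiGraph(kind="patient_trajectory")

    def add(src: str, dst: str, src_kind: str, dst_kind: str) -> None:
        G.add_node(src, kind=src_kind)
        G.add_node(dst, kind=dst_kind)
        G.add_edge(src, dst)

    for pid in log.patients:
        recs = log.records_for(pid)
        presentation = next((r.presentation_mode for r in recs if r.presentation_mode), None)
        current: str | None = None
        for rec in recs:
            setting_team = DEFAULT_SETTING_TEAMS[rec.setting]
            if current is not None and setting_team == "MHOA" and current != "MHOA":
                add(current, "MHOA", "team", "team")
                current = "MHOA"
            target = _referral_target(rec.action)
            if current is None:
                current = target or setting_team
                if presentation:
                    add(presentation, current, "presentation", "team")
                else:
                    G.add_node(current, kind="team")
            elif target is not None:
                if target == current:
                    warnings.warn(
                        f"patient {pid}: referral to {target!r} while already under that team"
                    )
                else:
                    add(current, target, "team", "team")
                    current = target
            if rec.action and rec.action.startswith(DISCHARGE_PREFIX):
                add(current, rec.action, "team", "discharge")
    return G
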