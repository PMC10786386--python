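"""Synthetic clinical event logs with planted network structure.

No observational event log is publicly deposited, so this module generates
logs with the statistical structure the downstream analysis assumes, at the
level the analysis actually measures — not clinical content:

* two clinical teams (Emergency Medical, Emergency Psychiatry) whose staff
  interact mostly within-team, giving the interaction network a planted
  two-community structure;
* a hub liaison agent (the Psychiatric Liaison Nurse) through whom
  cross-team information flow is routed with probability
  ``hub_mediation_prob``, planting the high-betweenness bridge;
* referral events emitted at a specific interaction signature (by default a
  Registrar accessing the Patient File, or a Consultant seeing the Patient),
  planting a recoverable trigger for the referral classifier;
* trajectory-level statistics (interaction counts with median 5 on a 2-12
  range, exponential inter-interaction gaps) emulating the observed cohort.

The shipped default catalog is a reconstruction of a plausible ED staffing
roster and is synthetic, not a transcription of any real department.

:func:`study_scale_fixture` pins the cohort bookkeeping exactly: 43
trajectories with 272 interactions, of which 36 trajectories / 213
interactions are in the ED (the rest only in the short-stay observation
area), and 20 referred patients contributing 87 pre-referral network states.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .eventlog import AgentCatalog, AgentEntry, EventLog, EventRecord

__all__ = [
    "SimConfig",
    "default_catalog",
    "generate_event_log",
    "study_scale_fixture",
    "HUB",
    "REFERRAL_ACTION",
]

HUB = "Psychiatric Liaison Nurse"
REFERRAL_ACTION = "Referral to Emergency Psychiatry"

_CATALOG_ROWS = [
    # name, category, team, role, restricted
    ("Patient", "patient", "none", "none", False),
    ("Associate", "associate", "none", "none", False),
    ("Paramedic", "external_service", "none", "none", False),
    ("Police", "external_service", "none", "none", False),
    ("Security Officer", "support_service", "none", "none", False),
    ("Triage Nurse", "clinical_staff", "emergency_medical", "nurse", False),
    ("Nurse", "clinical_staff", "emergency_medical", "nurse", False),
    ("Consultant", "clinical_staff", "emergency_medical", "doctor", False),
    ("Registrar", "clinical_staff", "emergency_medical", "doctor", False),
    ("RMO", "clinical_staff", "emergency_medical", "doctor", False),
    ("Intern", "clinical_staff", "emergency_medical", "doctor", False),
    (HUB, "clinical_staff", "emergency_psychiatry", "nurse", False),
    ("Psychiatry Consultant", "clinical_staff", "emergency_psychiatry", "doctor", False),
    ("Psychiatry Registrar", "clinical_staff", "emergency_psychiatry", "doctor", False),
    ("Psychiatry RMO", "clinical_staff", "emergency_psychiatry", "doctor", False),
    ("Mental Health Nurse", "clinical_staff", "emergency_psychiatry", "nurse", False),
    ("Social Worker", "clinical_staff", "emergency_psychiatry", "allied", False),
    ("MHOA Nurse", "clinical_staff", "mhoa", "nurse", False),
    ("MHOA Doctor", "clinical_staff", "mhoa", "doctor", False),
    ("EDIS", "information_system", "none", "none", False),
    ("Patient File", "information_system", "none", "none", False),
    ("PSOLIS", "information_system", "none", "none", True),
    ("EDYHO", "information_system", "none", "none", True),
]


def default_catalog() -> AgentCatalog:
    """The synthetic reconstruction of an ED agent roster (see module docs)."""
    return AgentCatalog(
        AgentEntry(name, category, team, role, restricted)
        for name, category, team, role, restricted in _CATALOG_ROWS
    )


# Each patient is treated by a small care team: the triage and ward nurses,
# one junior doctor, one senior doctor, and (once referred) the liaison hub
# plus one psychiatry colleague.  Interaction templates are drawn against
# that roster, which keeps the number of distinct staff per trajectory low,
# as observed.  Templates never pair an information system with a record
# lacking staff entitled to access it, and the referral trigger signatures
# (Registrar-Patient File, Consultant-Patient) appear only in referral
# records: senior doctors interact with the patient and the file only at the
# referral decision itself.
_JUNIOR_DOCTORS = ["RMO", "Intern"]
_SENIOR_DOCTORS = ["Registrar", "Consultant"]
_PSYCH_COLLEAGUES = [
    "Psychiatry Registrar",
    "Psychiatry Consultant",
    "Psychiatry RMO",
    "Mental Health Nurse",
    "Social Worker",
]

_MHOA_POOL = [
    (("MHOA Nurse", "Patient"), (), 0.35),
    (("MHOA Doctor", "Patient"), ("Patient File",), 0.25),
    (("MHOA Nurse",), ("Patient File",), 0.15),
    (("MHOA Doctor", "MHOA Nurse"), (), 0.15),
    (("MHOA Nurse", "MHOA Doctor"), ("Patient File",), 0.10),
]


def _med_routine_pool(junior: str, senior: str, escorts: tuple[str, ...] = ()) -> list:
    # senior doctors never meet the patient or the file in routine care; the
    # referral decision itself is where those signatures appear.  A Registrar
    # reviews the patient with EDIS, a Consultant reviews the written file.
    if senior == "Registrar":
        senior_contact = ((senior, "Patient"), ("EDIS",))
        bedside = ((senior, junior, "Nurse", "Patient"), ())
    else:
        senior_contact = ((senior,), ("Patient File",))
        bedside = ((junior, "Nurse", "Patient"), ("Patient File",))
    return [
        (("Nurse", "Patient"), (), 0.11),
        (("Nurse", "Patient"), ("Patient File",), 0.07),
        (("Triage Nurse", "Patient"), ("EDIS",), 0.05),
        ((junior, "Patient"), ("Patient File",), 0.10),
        (bedside[0], bedside[1], 0.10),
        ((senior, junior, "Nurse"), ("EDIS",), 0.08),  # ward round
        (("Triage Nurse", junior), ("EDIS",), 0.05),
        (("Triage Nurse", senior), ("EDIS",), 0.04),
        (("Nurse", junior), (), 0.06),
        (("Triage Nurse",), ("Patient File",), 0.04),
        (senior_contact[0], senior_contact[1], 0.06),
        ((junior,), ("EDIS",), 0.04),
        (("Nurse",), ("EDIS",), 0.05),
        (("Nurse", "Security Officer"), (), 0.04),
        (("Nurse", "Associate"), (), 0.04),
        ((junior, "Associate"), (), 0.04),
        ((junior, senior), (), 0.03),
    ] + [
        # ambulance crews also hand over to the treating doctor, so the
        # triage nurse is not the escorts' only link into the department
        ((junior, "Paramedic"), (), 0.05) for _ in ("x",) if "Paramedic" in escorts
    ] + [
        (("Security Officer", "Police"), (), 0.05) for _ in ("x",) if "Police" in escorts
    ]


def _psych_pool(colleague: str, hub_mediation_prob: float) -> list:
    # with high mediation the liaison hub is the psychiatry team's
    # patient-facing agent; without it the assigned colleague sees the
    # patient directly and the hub is an ordinary team member
    second = "Psychiatry Registrar" if colleague != "Psychiatry Registrar" else "Psychiatry RMO"
    p = hub_mediation_prob
    return [
        ((HUB, "Patient"), (), 0.24 * p),
        ((colleague, "Patient"), (), 0.24 * (1 - p)),
        ((HUB,), ("PSOLIS",), 0.16 * p),
        ((colleague,), ("PSOLIS",), 0.16 * (1 - p)),
        ((HUB, colleague), ("EDYHO",), 0.14 * p),
        ((colleague, second), ("EDYHO",), 0.14 * (1 - p)),
        ((HUB, colleague), (), 0.10),
        ((colleague, second), ("PSOLIS",), 0.06),
        ((colleague,), ("PSOLIS",), 0.10),
        ((HUB, "Patient"), ("EDYHO",), 0.10 * p),
        ((colleague, "Patient"), ("PSOLIS",), 0.10 * (1 - p)),
        ((colleague,), ("EDYHO",), 0.10),
    ]

# who appears in the arrival record; a combined ambulance+police arrival is
# handed over through the ambulance crew
_ESCORTS = {
    "Ambulance": ("Paramedic",),
    "Police": ("Police",),
    "Ambulance+Police": ("Paramedic",),
    "Associate": ("Associate",),
    "Self": (),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate the observed ED cohort.

    ``interaction_count_probs`` is the per-trajectory interaction-count
    distribution (median 5, support 2-12).  ``hub_mediation_prob`` is the
    probability that a cross-team interaction is routed through the liaison
    hub rather than occurring doctor-to-doctor; high by default to plant the
    bridge structure.  ``referral_triggers`` are the interaction signatures
    whose first occurrence precipitates a referral.  Inter-interaction gaps
    are exponential with mean ``mean_gap_minutes``, capped so a trajectory
    never crosses midnight.
    """

    seed: int = 0
    n_ed_patients: int = 36
    n_mhoa_only_patients: int = 7
    interaction_count_probs: tuple[tuple[int, float], ...] = (
        (2, 0.08), (3, 0.12), (4, 0.15), (5, 0.20), (6, 0.12), (7, 0.09),
        (8, 0.07), (9, 0.06), (10, 0.05), (11, 0.03), (12, 0.03),
    )
    presentation_probs: tuple[tuple[str, float], ...] = (
        ("Ambulance", 0.30), ("Police", 0.15), ("Ambulance+Police", 0.12),
        ("Self", 0.25), ("Associate", 0.18),
    )
    referral_prob: float = 20 / 36
    hub_mediation_prob: float = 0.9
    cross_team_prob: float = 0.45
    referral_triggers: tuple[tuple[str, str], ...] = (
        ("Registrar", "Patient File"),
        ("Consultant", "Patient"),
    )
    mean_gap_minutes: float = 24.0
    max_gap_minutes: float = 45.0
    discharge_prob: float = 0.75

    def __post_init__(self) -> None:
        for _, p in self.interaction_count_probs + self.presentation_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for p in (self.hub_mediation_prob, self.cross_team_prob,
                  self.referral_prob, self.discharge_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _weighted_choice(rng: np.random.Generator, items: list, weights=None):
    w = np.array([it[-1] for it in items] if weights is None else weights, dtype=float)
    idx = rng.choice(len(items), p=w / w.sum())
    return items[int(idx)]


def _trigger_record(trigger: tuple[str, str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    a, b = trigger
    agents = tuple(x for x in (a, b) if x not in ("Patient File", "EDIS", "PSOLIS", "EDYHO"))
    systems = tuple(x for x in (a, b) if x in ("Patient File", "EDIS", "PSOLIS", "EDYHO"))
    return agents, systems


def _cross_team_record(
    cfg: SimConfig, junior: str, senior: str, colleague: str, rng: np.random.Generator
) -> tuple[tuple[str, ...], tuple[str, ...], bool]:
    """One cross-team interaction; mediated through the hub or direct."""
    if rng.random() < cfg.hub_mediation_prob:
        med = str(rng.choice(["Nurse", junior, senior]))
        systems = ("EDIS",) if rng.random() < 0.3 else ()
        return (HUB, med), systems, True
    direct = colleague if colleague in ("Psychiatry Registrar", "Psychiatry Consultant") else "Psychiatry Registrar"
    return (str(rng.choice([junior, senior])), direct), (), False


def _timestamps(cfg: SimConfig, n: int, rng: np.random.Generator) -> list[datetime]:
    day = int(rng.integers(0, 28))
    start = datetime(2018, 7, 1 + day, int(rng.integers(8, 15)), int(rng.integers(0, 60)))
    stamps = [start]
    for _ in range(n - 1):
        gap = min(rng.exponential(cfg.mean_gap_minutes), cfg.max_gap_minutes)
        stamps.append(stamps[-1] + timedelta(minutes=round(gap)))
    return stamps


def _ed_trajectory(
    cfg: SimConfig,
    pid: str,
    n: int,
    referral_step: int | None,
    rng: np.random.Generator,
) -> tuple[list[EventRecord], tuple[str, str] | None]:
    presentation = _weighted_choice(rng, list(cfg.presentation_probs))[0]
    stamps = _timestamps(cfg, n, rng)
    junior = str(rng.choice(_JUNIOR_DOCTORS))
    senior = str(rng.choice(_SENIOR_DOCTORS))
    colleague = str(rng.choice(_PSYCH_COLLEAGUES))
    routine_pool = _med_routine_pool(junior, senior, _ESCORTS[presentation])
    psych_pool = _psych_pool(colleague, cfg.hub_mediation_prob)
    records: list[EventRecord] = []
    trigger_used: tuple[str, str] | None = None
    for t in range(1, n + 1):
        action = None
        if t == 1:
            # arrival at triage: escorted patients are clerked through the
            # escort's handover; walk-ins are triaged directly
            escort = _ESCORTS[presentation]
            if escort and escort != ("Associate",):
                agents = ("Triage Nurse",) + escort
                if "Police" in escort:
                    agents = agents + ("Security Officer",)
            elif escort:
                agents = ("Triage Nurse", "Patient", "Associate")
            else:
                agents = ("Triage Nurse", "Patient")
            systems = ("EDIS",)
            action = "Referral to Emergency Medical"
        elif referral_step is not None and t == referral_step:
            # the referral decision is made by the patient's senior doctor,
            # so the planted signature follows that doctor
            trigger_used = next(
                (trig for trig in cfg.referral_triggers if trig[0] == senior),
                cfg.referral_triggers[int(rng.integers(len(cfg.referral_triggers)))],
            )
            agents, systems = _trigger_record(trigger_used)
            action = REFERRAL_ACTION
        elif referral_step is not None and t > referral_step:
            if rng.random() < cfg.cross_team_prob:
                agents, systems, _ = _cross_team_record(cfg, junior, senior, colleague, rng)
            else:
                agents, systems, _w = _weighted_choice(rng, psych_pool)
        else:
            agents, systems, _w = _weighted_choice(rng, routine_pool)
        if t == n and action is None and rng.random() < cfg.discharge_prob:
            if referral_step is not None:
                action = str(rng.choice(["Discharge Home", "Discharge to Inpatient Unit"]))
            else:
                action = str(
                    rng.choice(
                        ["Discharge Home", "Discharge Home", "Discharge Against Medical Advice"]
                    )
                )
        records.append(
            EventRecord(
                patient_id=pid,
                setting="ED",
                presentation_mode=presentation,
                timestamp=stamps[t - 1],
                agents=agents,
                info_systems=systems,
                action=action,
            )
        )
    return records, trigger_used


def _mhoa_trajectory(
    cfg: SimConfig, pid: str, n: int, rng: np.random.Generator
) -> list[EventRecord]:
    presentation = _weighted_choice(rng, list(cfg.presentation_probs))[0]
    stamps = _timestamps(cfg, n, rng)
    records = []
    for t in range(1, n + 1):
        if t == 1:
            agents, systems = ("MHOA Nurse", "Patient"), ()
        else:
            agents, systems, _w = _weighted_choice(rng, _MHOA_POOL)
        action = None
        if t == n and rng.random() < cfg.discharge_prob:
            action = str(rng.choice(["Discharge Home", "Discharge to Inpatient Unit"]))
        records.append(
            EventRecord(
                patient_id=pid,
                setting="MHOA",
                presentation_mode=presentation,
                timestamp=stamps[t - 1],
                agents=agents,
                info_systems=systems,
                action=action,
            )
        )
    return records


def _generate(
    cfg: SimConfig,
    ed_counts: list[int] | None = None,
    mhoa_counts: list[int] | None = None,
    referral_plan: dict[str, int] | None = None,
) -> tuple[EventLog, dict]:
    if cfg.hub_mediation_prob > 0 and HUB not in [r[0] for r in _CATALOG_ROWS]:
        raise ValueError("hub mediation requested but the hub agent is not in the roster")
    rng = np.random.default_rng(cfg.seed)
    catalog = default_catalog()
    counts_items = list(cfg.interaction_count_probs)
    records: list[EventRecord] = []
    truth: dict = {
        "hub": HUB,
        "teams": {e.name: e.team for e in catalog if e.category == "clinical_staff"},
        "referral_step": {},
        "trigger_used": {},
        "triggers": list(cfg.referral_triggers),
    }
    for k in range(cfg.n_ed_patients):
        pid = f"ED-{k + 1:02d}"
        if ed_counts is not None:
            n = ed_counts[k]
        else:
            n = _weighted_choice(rng, counts_items)[0]
        if referral_plan is not None:
            referral_step = referral_plan.get(pid)
        elif n >= 2 and rng.random() < cfg.referral_prob:
            referral_step = int(rng.integers(2, n + 1))
        else:
            referral_step = None
        recs, trigger = _ed_trajectory(cfg, pid, n, referral_step, rng)
        records.extend(recs)
        if referral_step is not None:
            truth["referral_step"][pid] = referral_step
            truth["trigger_used"][pid] = trigger
    for k in range(cfg.n_mhoa_only_patients):
        pid = f"MH-{k + 1:02d}"
        if mhoa_counts is not None:
            n = mhoa_counts[k]
        else:
            n = _weighted_choice(rng, counts_items)[0]
        records.extend(_mhoa_trajectory(cfg, pid, n, rng))
    log = EventLog(records, catalog)
    log.validate()
    return log, truth


def generate_event_log(cfg: SimConfig) -> tuple[EventLog, dict]:
    """Generate a validated event log plus a ground-truth record.

    The ground truth lists the planted hub identity, staff team memberships,
    each referred patient's true referral step and the trigger signature
    used.  Deterministic for a given config (including its seed).
    """
    return _generate(cfg)


# Hand-pinned per-trajectory interaction counts reproducing the cohort
# bookkeeping exactly: the ED multiset has 36 entries on [2, 12] with median 5
# summing to 213; the observation-area multiset has 7 entries summing to 59.
# The paired referral steps (None = not referred) put the 20 referrals on the
# mid-length trajectories — referred patients are handed over and leave the
# ED, while the longest stays are non-referred observation cases; steps sum
# to the 87 pre-referral states (13 x 4 + 7 x 5).
_FIXTURE_ED_PLAN = [
    (12, None), (11, None), (10, None), (10, None),
    (9, 5), (9, 5), (9, 5),
    (8, 5), (8, 5), (8, 5),
    (7, 5), (7, 4), (7, 4), (7, 4),
    (6, 4), (6, 4), (6, 4),
    (5, 4), (5, 4), (5, 4), (5, 4), (5, 4), (5, 4), (5, 4),
    (4, None), (4, None), (4, None), (4, None), (4, None),
    (3, None), (3, None), (3, None), (3, None),
    (2, None), (2, None), (2, None),
]
_FIXTURE_ED_COUNTS = [n for n, _ in _FIXTURE_ED_PLAN]
_FIXTURE_MHOA_COUNTS = [7, 8, 8, 8, 9, 9, 10]

_FIXTURE_SEED = 20180712


def study_scale_fixture(with_truth: bool = False):
    """Deterministic log matching the study's reported sample sizes exactly.

    43 patients / 272 interactions; 36 ED patients / 213 ED interactions
    (the other 7 patients appear only in the short-stay observation area);
    20 referred patients whose pre-referral trajectories comprise 87 network
    states.
    """
    cfg = SimConfig(seed=_FIXTURE_SEED)
    plan = {
        f"ED-{k + 1:02d}": step
        for k, (_, step) in enumerate(_FIXTURE_ED_PLAN)
        if step is not None
    }
    log, truth = _generate(
        cfg,
        ed_counts=_FIXTURE_ED_COUNTS,
        mhoa_counts=_FIXTURE_MHOA_COUNTS,
        referral_plan=plan,
    )
    assert len(log.records) == 272 and len(log.patients) == 43
    assert sum(1 for r in log.records if r.setting == "ED") == 213
    assert len(plan) == 20 and sum(plan.values()) == 87
    return (log, truth) if with_truth else log
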