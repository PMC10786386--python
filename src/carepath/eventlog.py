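"""Clinical event logs: reading, validation, filtering and trajectory statistics.

The observational unit is one clinical *interaction*: a timestamped record of
the agents involved (patient, clinicians, emergency services, ...), the
information systems accessed during the interaction, and any resulting action
(a referral between teams, a discharge).  A patient *trajectory* is the
ordered sequence of that patient's interactions from presentation onwards.

Logs are exchanged as plain CSV with one row per interaction and
semicolon-delimited multi-value fields::

    patient,setting,presentation,date,time,agents,information_systems,action

Agents and information systems must resolve in an :class:`AgentCatalog`, the
registry that also carries the attributes (category, team, role, restricted
system or not) that downstream modules use to decide which network edges are
operationally impossible.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "AgentEntry",
    "AgentCatalog",
    "EventRecord",
    "EventLog",
    "TrajectorySummary",
    "EventLogError",
    "ValidationError",
    "ParseError",
    "read_event_log",
    "write_event_log",
    "read_catalog",
    "write_catalog",
    "exclude_mhoa_only_patients",
    "trajectory_statistics",
]

CATEGORIES = frozenset(
    {
        "patient",
        "associate",
        "clinical_staff",
        "support_service",
        "external_service",
        "information_system",
    }
)
TEAMS = frozenset({"emergency_medical", "emergency_psychiatry", "mhoa", "none"})
ROLES = frozenset({"doctor", "nurse", "allied", "other", "none"})
SETTINGS = ("ED", "MHOA")

TIMESTAMP_FORMAT = "%d/%m/%Y %H:%M"

LOG_COLUMNS = [
    "patient",
    "setting",
    "presentation",
    "date",
    "time",
    "agents",
    "information_systems",
    "action",
]
CATALOG_COLUMNS = ["name", "category", "team", "role", "psychiatry_restricted"]


class EventLogError(ValueError):
    """Base class for event-log problems."""


class ValidationError(EventLogError):
    """A record or catalog entry violates an invariant."""


class ParseError(EventLogError):
    """A file could not be parsed in the documented dialect."""


@dataclass(frozen=True)
class AgentEntry:
    """One agent or information system in the catalog.

    ``team`` is meaningful only for clinical staff; ``psychiatry_restricted``
    marks information systems that only the Emergency Psychiatry team may
    access (PSOLIS, EDYHO in the default catalog).
    """

    name: str
    category: str
    team: str = "none"
    role: str = "none"
    psychiatry_restricted: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("agent name must be non-empty")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r} for {self.name!r}")
        if self.team not in TEAMS:
            raise ValidationError(f"unknown team {self.team!r} for {self.name!r}")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for {self.name!r}")
        if self.psychiatry_restricted and self.category != "information_system":
            raise ValidationError(
                f"{self.name!r}: psychiatry_restricted is only valid for information systems"
            )
        if self.team != "none" and self.category != "clinical_staff":
            raise ValidationError(
                f"{self.name!r}: team membership is only valid for clinical staff"
            )


class AgentCatalog:
    """Registry of agents and information systems keyed by unique name."""

    def __init__(self, entries: Iterable[AgentEntry]):
        self._entries: dict[str, AgentEntry] = {}
        for entry in entries:
            if entry.name in self._entries:
                raise ValidationError(f"duplicate catalog entry {entry.name!r}")
            self._entries[entry.name] = entry

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> AgentEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(f"unknown agent or information system {name!r}") from None

    def __iter__(self) -> Iterator[AgentEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def is_system(self, name: str) -> bool:
        return self[name].category == "information_system"

    def staff_names(self, team: str | None = None, role: str | None = None) -> list[str]:
        """Clinical staff names, optionally filtered by team and/or role."""
        out = []
        for e in self:
            if e.category != "clinical_staff":
                continue
            if team is not None and e.team != team:
                continue
            if role is not None and e.role != role:
                continue
            out.append(e.name)
        return out


@dataclass(frozen=True)
class EventRecord:
    """One observed interaction (one event-log row)."""

    patient_id: str
    setting: str
    presentation_mode: str
    timestamp: datetime
    agents: tuple[str, ...]
    info_systems: tuple[str, ...] = ()
    action: str | None = None

    def validate(self, catalog: AgentCatalog, row: int | None = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if self.setting not in SETTINGS:
            raise ValidationError(f"unknown setting {self.setting!r}{where}")
        if not self.agents:
            raise ValidationError(f"record with no agents{where}")
        for name in self.agents:
            if name not in catalog:
                raise ValidationError(f"unknown agent {name!r}{where}")
            if catalog.is_system(name):
                raise ValidationError(
                    f"information system {name!r} listed in the agents column{where}"
                )
        for name in self.info_systems:
            if name not in catalog:
                raise ValidationError(f"unknown information system {name!r}{where}")
            if not catalog.is_system(name):
                raise ValidationError(
                    f"{name!r} in the information-systems column is not an information system{where}"
                )


@dataclass
class EventLog:
    """An ordered collection of event records plus the catalog they resolve in.

    Records are kept sorted by (patient id, timestamp); per-patient sequences
    are therefore non-decreasing in time.
    """

    records: list[EventRecord]
    catalog: AgentCatalog

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.patient_id, r.timestamp)
        )

    def validate(self) -> None:
        for i, rec in enumerate(self.records, start=1):
            rec.validate(self.catalog, row=i)
        # a patient's presentation mode is a property of the trajectory:
        # it is taken from the first record and later non-empty values must agree
        for pid in self.patients:
            modes = [r.presentation_mode for r in self.records_for(pid) if r.presentation_mode]
            if modes and any(m != modes[0] for m in modes[1:]):
                raise ValidationError(
                    f"patient {pid!r}: inconsistent presentation modes {sorted(set(modes))}"
                )

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.patient_id, None)
        return list(seen)

    def records_for(self, patient_id: str) -> list[EventRecord]:
        return [r for r in self.records if r.patient_id == patient_id]

    def __len__(self) -> int:
        return len(self.records)


def _split_multi(raw: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in raw.split(";") if part.strip())


def read_catalog(path: str | Path) -> AgentCatalog:
    """Read an agent catalog CSV (name,category,team,role,psychiatry_restricted)."""
    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != CATALOG_COLUMNS:
            raise ParseError(
                f"catalog header {reader.fieldnames} does not match {CATALOG_COLUMNS}"
            )
        for row in reader:
            entries.append(
                AgentEntry(
                    name=row["name"].strip(),
                    category=row["category"].strip(),
                    team=row["team"].strip() or "none",
                    role=row["role"].strip() or "none",
                    psychiatry_restricted=row["psychiatry_restricted"].strip().lower()
                    in ("1", "true", "yes"),
                )
            )
    return AgentCatalog(entries)


def write_catalog(catalog: AgentCatalog, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CATALOG_COLUMNS)
        for e in catalog:
            writer.writerow(
                [e.name, e.category, e.team, e.role, str(e.psychiatry_restricted).lower()]
            )


def read_event_log(path: str | Path, catalog: AgentCatalog) -> EventLog:
    """Read and validate an event-log CSV against ``catalog``.

    Raises :class:`ParseError` on malformed headers or timestamps and
    :class:`ValidationError` (naming the offending row) when a record violates
    an invariant, e.g. an agent missing from the catalog or an information
    system listed in the agents column.
    """
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != LOG_COLUMNS:
            raise ParseError(f"header {reader.fieldnames} does not match {LOG_COLUMNS}")
        for row_no, row in enumerate(reader, start=1):
            stamp_raw = f"{row['date'].strip()} {row['time'].strip()}"
            try:
                stamp = datetime.strptime(stamp_raw, TIMESTAMP_FORMAT)
            except ValueError as exc:
                raise ParseError(f"row {row_no}: cannot parse timestamp {stamp_raw!r}") from exc
            rec = EventRecord(
                patient_id=row["patient"].strip(),
                setting=row["setting"].strip(),
                presentation_mode=row["presentation"].strip(),
                timestamp=stamp,
                agents=_split_multi(row["agents"]),
                info_systems=_split_multi(row["information_systems"]),
                action=row["action"].strip() or None,
            )
            rec.validate(catalog, row=row_no)
            records.append(rec)
    log = EventLog(records, catalog)
    log.validate()
    return log


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write ``log`` in the CSV dialect accepted by :func:`read_event_log`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_COLUMNS)
        for rec in log.records:
            writer.writerow(
                [
                    rec.patient_id,
                    rec.setting,
                    rec.presentation_mode,
                    rec.timestamp.strftime("%d/%m/%Y"),
                    rec.timestamp.strftime("%H:%M"),
                    "; ".join(rec.agents),
                    "; ".join(rec.info_systems),
                    rec.action or "",
                ]
            )


def exclude_mhoa_only_patients(log: EventLog) -> EventLog:
    """Drop patients observed only in the MHOA (keep every record of the rest).

    The short-stay observation area serves a different function from the rest
    of the department, so trajectory statistics and the interaction network
    are computed on patients with at least one ED record.  Patients seen in
    both settings keep all their records.  Idempotent.
    """
    ed_patients = {r.patient_id for r in log.records if r.setting == "ED"}
    kept = [r for r in log.records if r.patient_id in ed_patients]
    return EventLog(kept, log.catalog)


@dataclass
class TrajectorySummary:
    """Per-patient trajectory statistics with cohort medians and 95% intervals.

    ``per_patient`` has one row per patient with columns ``presentation_mode``,
    ``trajectory_hours``, ``n_interactions`` and ``n_staff_types``.  Intervals
    are the empirical 2.5th-97.5th percentiles of the per-patient values.
    """

    per_patient: pd.DataFrame
    medians: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    presentation_counts: pd.Series = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_patients": int(len(self.per_patient)),
            "medians": {k: float(v) for k, v in self.medians.items()},
            "intervals": {k: [float(lo), float(hi)] for k, (lo, hi) in self.intervals.items()},
            "presentation_counts": {str(k): int(v) for k, v in self.presentation_counts.items()},
        }


_STAT_COLUMNS = ("trajectory_hours", "n_interactions", "n_staff_types")


def trajectory_statistics(log: EventLog) -> TrajectorySummary:
    """Summarize trajectories: duration, interaction count, distinct staff.

    Trajectory time is last minus first observation (0 for single-record
    trajectories, which is a valid degenerate case, not an error).  "Staff
    types" counts distinct clinical-staff catalog names seen along the
    trajectory.  Callers analysing the ED cohort should apply
    :func:`exclude_mhoa_only_patients` first.
    """
    if not log.records:
        raise EventLogError("cannot summarize an empty event log")
    rows = []
    for pid in log.patients:
        recs = log.records_for(pid)
        hours = (recs[-1].timestamp - recs[0].timestamp).total_seconds() / 3600.0
        staff = {
            a
            for rec in recs
            for a in rec.agents
            if log.catalog[a].category == "clinical_staff"
        }
        presentation = next((r.presentation_mode for r in recs if r.presentation_mode), "")
        rows.append(
            {
                "patient_id": pid,
                "presentation_mode": presentation,
                "trajectory_hours": hours,
                "n_interactions": len(recs),
                "n_staff_types": len(staff),
            }
        )
    per_patient = pd.DataFrame(rows).set_index("patient_id")
    medians = {c: float(np.median(per_patient[c])) for c in _STAT_COLUMNS}
    intervals = {
        c: tuple(np.percentile(per_patient[c], [2.5, 97.5])) for c in _STAT_COLUMNS
    }
    counts = per_patient["presentation_mode"].value_counts()
    return TrajectorySummary(per_patient, medians, intervals, counts)
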