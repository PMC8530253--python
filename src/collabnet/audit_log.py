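"""Reading, validation and period partitioning of EHR action logs.

The atomic input is an *action event*: one clinician touching one patient's
chart at one timestamp, tagged with an action category (condition,
procedure, medication, note, order, measurement).  Events are carried as a
pandas DataFrame with the canonical column set in :data:`EVENT_COLUMNS`;
:class:`ActionEvent` is the row-level record type used for construction and
validation.  Downstream stages work on *patient-day units*: the set of
distinct (clinician, patient, calendar day) triples, which is the unit of
co-occurrence from which collaboration ties are counted.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The six recognised action categories.
ACTION_CATEGORIES: tuple[str, ...] = (
    "condition",
    "procedure",
    "medication",
    "note",
    "order",
    "measurement",
)

#: Canonical event-frame columns (``day`` is derived from ``timestamp``).
EVENT_COLUMNS: tuple[str, ...] = (
    "clinician_id",
    "specialty",
    "patient_id",
    "timestamp",
    "action_category",
)

PATIENT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "admit_date",
    "discharge_date",
    "sex",
    "race",
    "ethnicity",
    "age_days",
    "disposition",
    "excluded",
)

SEX_VALUES = ("female", "male", "unknown")
RACE_VALUES = ("white", "african_american", "asian", "other")
ETHNICITY_VALUES = ("non_hispanic", "latino", "unknown")
DISPOSITION_VALUES = ("home", "expired", "hospice", "short_term_hospital", "other")


class AuditLogError(ValueError):
    """Hard validation failure in audit-log input."""


@dataclass(frozen=True)
class ActionEvent:
    """One clinician action on one patient's record at one timestamp."""

    clinician_id: str
    specialty: str
    patient_id: str
    timestamp: dt.datetime
    action_category: str

    def __post_init__(self) -> None:
        if not self.clinician_id:
            raise AuditLogError("clinician_id must be non-empty")
        if not self.patient_id:
            raise AuditLogError("patient_id must be non-empty")
        if self.action_category not in ACTION_CATEGORIES:
            raise AuditLogError(
                f"unknown action_category {self.action_category!r}; "
                f"expected one of {ACTION_CATEGORIES}"
            )

    @property
    def day(self) -> dt.date:
        return self.timestamp.date()


@dataclass(frozen=True)
class PatientRecord:
    """Admission-level patient demographics and outcome."""

    patient_id: str
    admit_date: dt.date
    discharge_date: dt.date
    sex: str = "unknown"
    race: str = "other"
    ethnicity: str = "unknown"
    age_days: int = 0
    disposition: str = "home"
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.discharge_date < self.admit_date:
            raise AuditLogError(
                f"patient {self.patient_id}: discharge_date precedes admit_date"
            )
        if self.age_days < 0:
            raise AuditLogError(f"patient {self.patient_id}: negative age_days")

    @property
    def los_days(self) -> int:
        """Length of stay in days (discharge minus admission)."""
        return (self.discharge_date - self.admit_date).days


@dataclass(frozen=True)
class StudyPeriod:
    """A labelled inclusive date window (e.g. the pre-disruption period)."""

    label: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise AuditLogError(
                f"period {self.label!r}: end {self.end} precedes start {self.start}"
            )

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.end

    def overlaps(self, other: "StudyPeriod") -> bool:
        return self.start <= other.end and other.start <= self.end


#: The shipped default study windows (four months each, with a gap between).
DEFAULT_PERIODS: tuple[StudyPeriod, StudyPeriod] = (
    StudyPeriod("pre", dt.date(2019, 9, 1), dt.date(2019, 12, 31)),
    StudyPeriod("intra", dt.date(2020, 3, 1), dt.date(2020, 6, 30)),
)


@dataclass
class ParseReport:
    """Line-numbered account of accepted and rejected rows."""

    path: str = ""
    n_read: int = 0
    n_accepted: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"{self.path}: {self.n_read} rows read, "
            f"{self.n_accepted} accepted, {self.n_rejected} rejected"
        ]
        lines += [f"  line {ln}: {reason}" for ln, reason in self.rejects]
        return "\n".join(lines)


DEFAULT_EVENT_SCHEMA: dict[str, str] = {c: c for c in EVENT_COLUMNS}


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AuditLogError(f"{path}: missing required column(s) {missing}")


def read_events(
    path: str,
    schema: Mapping[str, str] | None = None,
    timezone: str | None = None,
) -> tuple[pd.DataFrame, ParseReport]:
    """Read an action-event CSV.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Optional mapping from canonical column name to the column name used
        in the file (identity by default).
    timezone
        If given and the timestamps carry UTC offsets, convert to this zone
        before binning into calendar days; naive timestamps are taken as
        already local.

    Returns
    -------
    events, report
        ``events`` is the canonical event frame sorted by
        ``(day, clinician_id, patient_id)`` with a derived ``day`` column;
        ``report`` lists every rejected row with its 1-based line number.
        A missing required column is a hard error; a malformed row
        (unparseable timestamp, unknown category, empty id) is rejected and
        counted, never silently dropped.
    """
    colmap = dict(DEFAULT_EVENT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, colmap.values(), str(path))
    df = raw.rename(columns={v: k for k, v in colmap.items()})[list(EVENT_COLUMNS)]

    report = ParseReport(path=str(path), n_read=len(df))
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601",
                        utc=False)
    if getattr(ts.dt, "tz", None) is not None:
        ts = ts.dt.tz_convert(timezone or "UTC").dt.tz_localize(None)

    bad_ts = ts.isna()
    bad_cat = ~df["action_category"].isin(ACTION_CATEGORIES)
    bad_id = (df["clinician_id"].str.len() == 0) | (df["patient_id"].str.len() == 0)
    for idx in df.index[bad_ts | bad_cat | bad_id]:
        line = int(idx) + 2  # header is line 1
        if bad_id[idx]:
            report.rejects.append((line, "empty clinician_id or patient_id"))
        elif bad_ts[idx]:
            report.rejects.append(
                (line, f"unparseable timestamp {df.at[idx, 'timestamp']!r}")
            )
        else:
            report.rejects.append(
                (line, f"unknown category {df.at[idx, 'action_category']!r}")
            )

    keep = ~(bad_ts | bad_cat | bad_id)
    events = df.loc[keep].copy()
    events["timestamp"] = ts[keep]
    events["day"] = events["timestamp"].dt.date
    events = events.sort_values(
        ["day", "clinician_id", "patient_id", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    report.n_accepted = len(events)
    validate_events(events)
    return events, report


def validate_events(events: pd.DataFrame) -> None:
    """Check frame-level invariants; raises :class:`AuditLogError`.

    The one cross-row invariant is that a clinician id maps to exactly one
    specialty within a dataset.
    """
    _require_columns(events, EVENT_COLUMNS, "<events>")
    nspec = events.groupby("clinician_id")["specialty"].nunique()
    multi = nspec[nspec > 1]
    if len(multi):
        raise AuditLogError(
            "clinician(s) mapped to multiple specialties: "
            + ", ".join(multi.index[:10])
        )


def events_frame(events: Iterable[ActionEvent]) -> pd.DataFrame:
    """Build a canonical event frame from :class:`ActionEvent` records."""
    rows = [dataclasses.asdict(e) for e in events]
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["day"] = df["timestamp"].dt.date
    return df.sort_values(
        ["day", "clinician_id", "patient_id", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)


def write_events(events: pd.DataFrame, path: str) -> None:
    """Write the canonical five-column event CSV (ISO-8601 timestamps)."""
    out = events[list(EVENT_COLUMNS)].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)


def read_patients(path: str) -> tuple[pd.DataFrame, ParseReport]:
    """Read the patient table CSV; malformed rows are rejected and counted."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, PATIENT_COLUMNS[:-1], str(path))  # `excluded` optional
    df = raw.copy()
    if "excluded" not in df.columns:
        df["excluded"] = "0"
    report = ParseReport(path=str(path), n_read=len(df))

    admit = pd.to_datetime(df["admit_date"], errors="coerce").dt.date
    disch = pd.to_datetime(df["discharge_date"], errors="coerce").dt.date
    age = pd.to_numeric(df["age_days"], errors="coerce")
    bad = pd.Series(False, index=df.index)
    for idx in df.index:
        if pd.isna(admit[idx]) or pd.isna(disch[idx]):
            report.rejects.append((int(idx) + 2, "unparseable admit/discharge date"))
            bad[idx] = True
        elif disch[idx] < admit[idx]:
            report.rejects.append((int(idx) + 2, "discharge precedes admission"))
            bad[idx] = True
        elif pd.isna(age[idx]) or age[idx] < 0:
            report.rejects.append((int(idx) + 2, "invalid age_days"))
            bad[idx] = True

    out = df.loc[~bad].copy()
    out["admit_date"] = admit[~bad]
    out["discharge_date"] = disch[~bad]
    out["age_days"] = age[~bad].astype(int)
    out["excluded"] = out["excluded"].isin(("1", "true", "True", "yes"))
    out["los_days"] = [
        (d - a).days for a, d in zip(out["admit_date"], out["discharge_date"])
    ]
    out = out.reset_index(drop=True)
    report.n_accepted = len(out)
    return out, report


def write_patients(patients: pd.DataFrame, path: str) -> None:
    cols = [c for c in PATIENT_COLUMNS if c in patients.columns]
    out = patients[cols].copy()
    out["excluded"] = out["excluded"].astype(int)
    out.to_csv(path, index=False)


def check_periods(periods: Sequence[StudyPeriod]) -> None:
    labels = [p.label for p in periods]
    if len(set(labels)) != len(labels):
        raise AuditLogError(f"duplicate period labels: {labels}")
    for i, a in enumerate(periods):
        for b in periods[i + 1 :]:
            if a.overlaps(b):
                raise AuditLogError(
                    f"periods {a.label!r} ({a.start}..{a.end}) and "
                    f"{b.label!r} ({b.start}..{b.end}) overlap"
                )


def partition_by_period(
    events: pd.DataFrame,
    periods: Sequence[StudyPeriod] = DEFAULT_PERIODS,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Assign events to study periods by calendar date (inclusive bounds).

    Returns the per-period frames and the frame of dropped events (those
    falling in no window, e.g. the gap between the two default windows).
    Overlapping periods are a hard error.
    """
    check_periods(periods)
    day = events["day"]
    assigned: dict[str, pd.DataFrame] = {}
    taken = pd.Series(False, index=events.index)
    for p in periods:
        mask = day.map(p.contains)
        assigned[p.label] = events.loc[mask].reset_index(drop=True)
        taken |= mask
    dropped = events.loc[~taken].reset_index(drop=True)
    if len(dropped):
        logger.info("partition_by_period: dropped %d events outside all windows",
                    len(dropped))
    return assigned, dropped


def to_patient_days(events: pd.DataFrame) -> pd.DataFrame:
    """Reduce events to the set of distinct (clinician, patient, day) units.

    The reduction is a set, not a multiset: any number of actions by one
    clinician on one patient within one calendar day collapses to a single
    patient-day unit.  Idempotent and order-invariant.
    """
    units = (
        events[["clinician_id", "patient_id", "day"]]
        .drop_duplicates()
        .sort_values(["day", "clinician_id", "patient_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return units


def filter_patients(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    on_unknown: str = "warn",
) -> tuple[pd.DataFrame, int]:
    """Drop all events of patients flagged ``excluded`` in the patient table.

    ``on_unknown`` controls events whose patient is absent from the table:
    ``"warn"`` (default) keeps them with a warning, ``"drop"`` removes them,
    ``"error"`` raises.  Returns the filtered events and the number of
    excluded patients that had events removed.
    """
    if on_unknown not in ("warn", "drop", "error"):
        raise ValueError(f"on_unknown must be warn|drop|error, got {on_unknown!r}")
    flagged = set(patients.loc[patients["excluded"].astype(bool), "patient_id"])
    known = set(patients["patient_id"])
    unknown_mask = ~events["patient_id"].isin(known)
    n_unknown = int(unknown_mask.sum())
    if n_unknown:
        msg = f"{n_unknown} events reference patients absent from the patient table"
        if on_unknown == "error":
            raise AuditLogError(msg)
        warnings.warn(msg, stacklevel=2)
    keep = ~events["patient_id"].isin(flagged)
    if on_unknown == "drop":
        keep &= ~unknown_mask
    removed_patients = len(flagged & set(events.loc[~keep, "patient_id"]))
    if flagged and removed_patients == len(set(events["patient_id"])):
        warnings.warn("all patients with events were excluded", stacklevel=2)
    return events.loc[keep].reset_index(drop=True), removed_patients


def roster_from_events(events: pd.DataFrame) -> dict[str, str]:
    """Extract the clinician→specialty mapping carried in an event frame."""
    pairs = events[["clinician_id", "specialty"]].drop_duplicates()
    return dict(zip(pairs["clinician_id"], pairs["specialty"]))
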