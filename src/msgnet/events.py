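"""Message event-log IO, validation, and role/location categorization.

A message event is one row of a dyadic secure-messaging log: who sent a
message to whom, in which conversation, when it was sent, when (if ever)
it was read, and how many characters it carried.  Raw professional roles
(health systems typically track dozens) are collapsed to eight analysis
categories, and raw practice locations to inpatient/outpatient.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: The eight analysis role categories.
ROLE_PHYSICIAN = "physician"
ROLE_NURSE = "nurse"
ROLE_PHARMACIST = "pharmacist"
ROLE_APP = "APP"
ROLE_THERAPIST = "therapist"
ROLE_MEDICAL_ASSISTANT = "medical_assistant_or_technician"
ROLE_SOCIAL_WORK = "social_work_or_case_management"
ROLE_OTHER = "other"

ROLE_CATEGORIES = (
    ROLE_PHYSICIAN,
    ROLE_NURSE,
    ROLE_PHARMACIST,
    ROLE_APP,
    ROLE_THERAPIST,
    ROLE_MEDICAL_ASSISTANT,
    ROLE_SOCIAL_WORK,
    ROLE_OTHER,
)

LOCATION_INPATIENT = "inpatient"
LOCATION_OUTPATIENT = "outpatient"
LOCATIONS = (LOCATION_INPATIENT, LOCATION_OUTPATIENT)

_COLUMNS = (
    "conversation_id",
    "sender_id",
    "receiver_id",
    "sent_at",
    "read_at",
    "char_length",
    "sender_role_raw",
    "receiver_role_raw",
    "sender_location_raw",
    "receiver_location_raw",
)

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


@dataclass(frozen=True)
class MessageEvent:
    """One message: sender -> receiver inside a dyadic conversation.

    Timestamps are timezone-naive at second resolution in one declared
    zone.  ``char_length`` counts characters including internal spaces
    but excluding trailing spaces.
    """

    conversation_id: str
    sender_id: str
    receiver_id: str
    sent_at: datetime
    read_at: Optional[datetime]
    char_length: int
    sender_role_raw: str = ""
    receiver_role_raw: str = ""
    sender_location_raw: str = ""
    receiver_location_raw: str = ""

    def validate(self) -> None:
        if self.sender_id == self.receiver_id:
            raise ValueError("self-message: sender_id == receiver_id")
        if self.read_at is not None and self.read_at < self.sent_at:
            raise ValueError("read_at precedes sent_at")
        if self.char_length < 0:
            raise ValueError("negative char_length")


@dataclass(frozen=True)
class Professional:
    """A network participant with one role category and one location."""

    id: str
    role: str
    location: str

    def __post_init__(self) -> None:
        if self.role not in ROLE_CATEGORIES:
            raise ValueError(f"unknown role category: {self.role!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location: {self.location!r}")


@dataclass
class EventLogReadResult:
    """Parsed events plus a count of rejected (invalid) rows."""

    events: list[MessageEvent]
    n_rejected: int
    messages: list[str]


def measure_char_length(text: str) -> int:
    """Character count of a message: trailing whitespace is dropped,
    leading and internal whitespace is counted."""
    return len(text.rstrip())


def _parse_ts(value: str) -> Optional[datetime]:
    if value is None or value == "":
        return None
    return datetime.fromisoformat(value).replace(microsecond=0, tzinfo=None)


def read_event_log(path, *, delimiter: str = ",") -> EventLogReadResult:
    """Read a delimited event log (header row, ISO-8601 timestamps).

    Rows violating the event invariants (self-message, read before
    sent, negative length, unparseable timestamp) are rejected with a
    warning; a missing required column is fatal.  Input order is
    preserved.
    """
    events: list[MessageEvent] = []
    messages: list[str] = []
    n_rejected = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise ValueError(f"event log missing required columns: {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                event = MessageEvent(
                    conversation_id=row["conversation_id"],
                    sender_id=row["sender_id"],
                    receiver_id=row["receiver_id"],
                    sent_at=_parse_ts(row["sent_at"]),
                    read_at=_parse_ts(row["read_at"]),
                    char_length=int(row["char_length"]),
                    sender_role_raw=row["sender_role_raw"],
                    receiver_role_raw=row["receiver_role_raw"],
                    sender_location_raw=row["sender_location_raw"],
                    receiver_location_raw=row["receiver_location_raw"],
                )
                if event.sent_at is None:
                    raise ValueError("missing sent_at")
                event.validate()
            except (ValueError, KeyError) as exc:
                n_rejected += 1
                messages.append(f"line {i}: rejected ({exc})")
                continue
            events.append(event)
    for msg in messages:
        warnings.warn(msg, stacklevel=2)
    return EventLogReadResult(events=events, n_rejected=n_rejected, messages=messages)


def write_event_log(events: Iterable[MessageEvent], path, *, delimiter: str = ",") -> None:
    """Write events as CSV in the dialect :func:`read_event_log` expects."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_COLUMNS)
        for e in events:
            writer.writerow(
                [
                    e.conversation_id,
                    e.sender_id,
                    e.receiver_id,
                    e.sent_at.strftime(_TS_FORMAT),
                    e.read_at.strftime(_TS_FORMAT) if e.read_at is not None else "",
                    e.char_length,
                    e.sender_role_raw,
                    e.receiver_role_raw,
                    e.sender_location_raw,
                    e.receiver_location_raw,
                ]
            )


def read_role_map(path) -> dict[str, str]:
    """Read a two-column CSV ``raw_role,category`` into a mapping."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["raw_role", "category"]:
            raise ValueError("role map must have header 'raw_role,category'")
        for row in reader:
            if not row:
                continue
            mapping[row[0]] = row[1]
    return mapping


def categorize_roles(
    events: Sequence[MessageEvent],
    role_map: Mapping[str, str],
    *,
    location_map: Optional[Mapping[str, str]] = None,
    location_tiebreak: str = LOCATION_INPATIENT,
) -> dict[str, Professional]:
    """Build the professional roster from the event stream.

    Each id receives its most recent raw role (by send timestamp,
    whether observed as sender or receiver) mapped through ``role_map``,
    and its most common practice location across events.  Unmapped raw
    roles fall back to ``other`` with a warning; location ties go to
    ``location_tiebreak`` (inpatient by default).  Ids with zero events
    simply never appear.
    """
    if location_map is None:
        location_map = {LOCATION_INPATIENT: LOCATION_INPATIENT,
                        LOCATION_OUTPATIENT: LOCATION_OUTPATIENT}
    latest_role: dict[str, tuple[datetime, int, str]] = {}
    location_votes: dict[str, Counter] = {}
    unmapped: set[str] = set()

    def observe(pid: str, when: datetime, order: int, raw_role: str, raw_loc: str) -> None:
        key = (when, order, raw_role)
        if pid not in latest_role or key[:2] >= latest_role[pid][:2]:
            latest_role[pid] = key
        loc = location_map.get(raw_loc)
        if loc is None:
            loc = LOCATION_OUTPATIENT if "out" in raw_loc.lower() else LOCATION_INPATIENT
        location_votes.setdefault(pid, Counter())[loc] += 1

    for order, e in enumerate(events):
        observe(e.sender_id, e.sent_at, order, e.sender_role_raw, e.sender_location_raw)
        observe(e.receiver_id, e.sent_at, order, e.receiver_role_raw, e.receiver_location_raw)

    roster: dict[str, Professional] = {}
    for pid in sorted(latest_role):
        raw_role = latest_role[pid][2]
        role = role_map.get(raw_role)
        if role is None:
            unmapped.add(raw_role)
            role = ROLE_OTHER
        votes = location_votes[pid]
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            location = location_tiebreak
        else:
            location = top[0][0]
        roster[pid] = Professional(id=pid, role=role, location=location)
    for raw in sorted(unmapped):
        warnings.warn(f"raw role {raw!r} not in role map; categorized as 'other'", stacklevel=2)
    return roster


@dataclass
class CleanedEvents:
    """Deduplicated events, split into the set used for edge weighting
    (zero-length messages removed, since a weight-0 edge breaks
    inverse-weight distances) and the full set used for message-count
    behaviors."""

    for_weighting: list[MessageEvent]
    for_counts: list[MessageEvent]


def _sort_key(e: MessageEvent):
    # total order over all fields so dedup + sort is input-order invariant
    return (
        e.sent_at,
        e.conversation_id,
        e.sender_id,
        e.receiver_id,
        e.char_length,
        e.read_at or e.sent_at,
        e.sender_role_raw,
        e.receiver_role_raw,
        e.sender_location_raw,
        e.receiver_location_raw,
    )


def clean_events(events: Iterable[MessageEvent]) -> CleanedEvents:
    """Drop exact duplicate rows; order output by (sent_at, ids).

    The output is invariant to input order.  Zero-length messages stay
    in ``for_counts`` but are excluded from ``for_weighting``.
    """
    deduped = sorted(set(events), key=_sort_key)
    return CleanedEvents(
        for_weighting=[e for e in deduped if e.char_length > 0],
        for_counts=deduped,
    )


def events_frame(events: Sequence[MessageEvent]) -> pd.DataFrame:
    """Events as a DataFrame (one row per message), for tabular work."""
    return pd.DataFrame(
        {
            "conversation_id": [e.conversation_id for e in events],
            "sender_id": [e.sender_id for e in events],
            "receiver_id": [e.receiver_id for e in events],
            "sent_at": pd.to_datetime([e.sent_at for e in events]),
            "read_at": pd.to_datetime([e.read_at for e in events]),
            "char_length": [e.char_length for e in events],
        }
    )
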