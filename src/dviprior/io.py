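"""Domain types and delimited-text I/O for victim rosters.

A roster describes one mass-fatality event: an :class:`EventSpec` with the
event date ``T_e`` and death toll ``n_e``, plus one :class:`VictimRecord`
per person.  Records split into the candidate set ``V`` (possible victims,
reported kidnapped or missing strictly before ``T_e``) and the set ``D`` of
already-identified (solved) cases that the model learns from.

Files are UTF-8, comma-delimited with a header row and ISO-8601 dates::

    victim_id,kidnap_date,geo_area,political_group,status,sex,age_min,age_max

``status`` is ``candidate`` or ``identified``; the empty string marks a
missing value.  Missing categorical values are mapped to the reserved label
``UNKNOWN`` so that they form their own cells instead of being dropped,
which would silently break the normalization of cell probabilities over V.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import (
    ProfileError,
    RosterIntegrityError,
    RosterParseError,
    RosterSchemaError,
)

#: Reserved category label for missing geographic / political values.
UNKNOWN = "UNKNOWN"

ROSTER_COLUMNS = (
    "victim_id",
    "kidnap_date",
    "geo_area",
    "political_group",
    "status",
    "sex",
    "age_min",
    "age_max",
)

_STATUSES = ("candidate", "identified")


@dataclass(frozen=True)
class EventSpec:
    """A well-delimited mass-fatality event.

    Parameters
    ----------
    event_id
        Free-text label for the event.
    event_date
        Date of the event, ``T_e``.  All candidate victims must have been
        kidnapped or reported missing strictly before this date.
    n_e
        Total number of people killed in the event (``n_e >= 1``).
    description
        Optional free text.
    """

    event_id: str
    event_date: _dt.date
    n_e: int
    description: str = ""

    def __post_init__(self):
        if not isinstance(self.event_date, _dt.date):
            raise TypeError("event_date must be a datetime.date")
        if self.n_e < 1:
            raise ValueError(f"n_e must be >= 1, got {self.n_e}")


@dataclass(frozen=True)
class VictimRecord:
    """One person: a candidate victim or an already-identified case."""

    victim_id: str
    kidnap_date: _dt.date
    geo_area: str = UNKNOWN
    political_group: str = UNKNOWN
    status: str = "candidate"
    sex: Optional[str] = None
    age_min: Optional[int] = None
    age_max: Optional[int] = None

    def __post_init__(self):
        if self.status not in _STATUSES:
            raise ValueError(
                f"status must be one of {_STATUSES}, got {self.status!r}"
            )
        if (
            self.age_min is not None
            and self.age_max is not None
            and self.age_min > self.age_max
        ):
            raise ValueError(
                f"{self.victim_id}: age_min {self.age_min} > age_max {self.age_max}"
            )
        for bound in (self.age_min, self.age_max):
            if bound is not None and bound < 0:
                raise ValueError(f"{self.victim_id}: negative age bound")


@dataclass(frozen=True)
class Roster:
    """Candidate set V and solved set D for one event.

    ``candidates`` holds the *effective* set of possible victims: records
    with status ``candidate`` whose kidnap date precedes the event date.
    Candidate records dated on or after the event date are kept in
    ``excluded`` for reporting but take no part in any computation.
    Identified records are never members of V: per-victim scores divide
    the cell probability by the number of *unidentified* candidates.
    """

    event: EventSpec
    candidates: tuple[VictimRecord, ...]
    identified: tuple[VictimRecord, ...]
    excluded: tuple[VictimRecord, ...] = field(default=())

    @property
    def n_candidates(self) -> int:
        """Size N of the effective candidate set V."""
        return len(self.candidates)

    @property
    def n_solved(self) -> int:
        """Number n_s of already-identified cases."""
        return len(self.identified)

    def __post_init__(self):
        ids = [r.victim_id for r in self.all_records()]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise RosterIntegrityError(f"duplicate victim_id values: {dup}")
        if self.n_solved > self.event.n_e:
            raise RosterIntegrityError(
                f"n_s={self.n_solved} identified cases exceed the event "
                f"death toll n_e={self.event.n_e}"
            )
        for rec in self.candidates:
            if rec.kidnap_date >= self.event.event_date:
                raise RosterIntegrityError(
                    f"{rec.victim_id}: candidate dated on/after the event "
                    "date must be excluded from V"
                )
        for rec in self.identified:
            if rec.kidnap_date >= self.event.event_date:
                raise RosterIntegrityError(
                    f"{rec.victim_id}: identified case dated on/after the "
                    "event date is inconsistent with the event delimitation"
                )

    def all_records(self) -> tuple[VictimRecord, ...]:
        return self.candidates + self.identified + self.excluded

    @classmethod
    def from_records(
        cls, event: EventSpec, records: Iterable[VictimRecord]
    ) -> "Roster":
        """Split records into V / D, excluding candidates dated >= T_e."""
        candidates, identified, excluded = [], [], []
        for rec in records:
            if rec.status == "identified":
                identified.append(rec)
            elif rec.kidnap_date < event.event_date:
                candidates.append(rec)
            else:
                excluded.append(rec)
        if excluded:
            warnings.warn(
                f"{len(excluded)} candidate record(s) dated on/after the "
                f"event date {event.event_date} were excluded from the "
                "candidate set V: "
                + ", ".join(r.victim_id for r in excluded[:10]),
                stacklevel=2,
            )
        return cls(
            event=event,
            candidates=tuple(candidates),
            identified=tuple(identified),
            excluded=tuple(excluded),
        )


def _parse_date(value: str, row: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value)
    except ValueError as exc:
        raise RosterParseError(row, f"unparseable date {value!r}") from exc


def _parse_age(value: str, row: int) -> Optional[int]:
    if value == "":
        return None
    try:
        return int(value)
    except ValueError as exc:
        raise RosterParseError(row, f"unparseable age bound {value!r}") from exc


def read_roster(path: str | Path, event: EventSpec) -> Roster:
    """Read a roster file and build the candidate / solved sets.

    Raises
    ------
    RosterSchemaError
        if a required column is missing.
    RosterParseError
        on an unparseable date or age, naming the (1-based) data row.
    RosterIntegrityError
        on duplicate ``victim_id`` values.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ROSTER_COLUMNS:
        if col not in frame.columns:
            raise RosterSchemaError(col)
    records = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        status = row.status
        if status not in _STATUSES:
            raise RosterParseError(idx, f"unknown status {row.status!r}")
        records.append(
            VictimRecord(
                victim_id=row.victim_id,
                kidnap_date=_parse_date(row.kidnap_date, idx),
                geo_area=row.geo_area or UNKNOWN,
                political_group=row.political_group or UNKNOWN,
                status=status,
                sex=row.sex or None,
                age_min=_parse_age(row.age_min, idx),
                age_max=_parse_age(row.age_max, idx),
            )
        )
    return Roster.from_records(event, records)


def write_roster(roster: Roster, path: str | Path) -> None:
    """Write all records (candidates, identified, excluded) back to CSV.

    Round-trips bit-exactly with :func:`read_roster` for the same event.
    """
    rows = []
    for rec in roster.all_records():
        rows.append(
            {
                "victim_id": rec.victim_id,
                "kidnap_date": rec.kidnap_date.isoformat(),
                "geo_area": "" if rec.geo_area == UNKNOWN else rec.geo_area,
                "political_group": ""
                if rec.political_group == UNKNOWN
                else rec.political_group,
                "status": rec.status,
                "sex": rec.sex or "",
                "age_min": "" if rec.age_min is None else rec.age_min,
                "age_max": "" if rec.age_max is None else rec.age_max,
            }
        )
    pd.DataFrame(rows, columns=list(ROSTER_COLUMNS)).to_csv(path, index=False)


def filter_candidates(
    roster: Roster,
    sex: Optional[str] = None,
    age_range: Optional[tuple[int, int]] = None,
) -> Roster:
    """Restrict V to candidates compatible with a biological profile.

    Used when something is known about the remains themselves (for
    instance their sex).  Records with a missing sex or age are retained:
    an unknown value is compatible with any profile.  The solved set D is
    never filtered.  Idempotent; never enlarges V.

    Parameters
    ----------
    sex
        Required sex label; must occur in the roster.
    age_range
        Inclusive ``(low, high)`` age interval in years; a candidate is
        kept when their recorded age interval overlaps it (or is absent).
    """
    if sex is None and age_range is None:
        return roster
    if sex is not None:
        known = {r.sex for r in roster.all_records() if r.sex is not None}
        if sex not in known:
            raise ProfileError(
                f"sex label {sex!r} does not occur in the roster "
                f"(known labels: {sorted(known)})"
            )
    if age_range is not None:
        lo, hi = age_range
        if lo < 0 or lo > hi:
            raise ProfileError(f"invalid age range {age_range}")

    def compatible(rec: VictimRecord) -> bool:
        if sex is not None and rec.sex is not None and rec.sex != sex:
            return False
        if age_range is not None and not (
            rec.age_min is None and rec.age_max is None
        ):
            rec_lo = rec.age_min if rec.age_min is not None else 0
            rec_hi = rec.age_max if rec.age_max is not None else 10**4
            if rec_hi < age_range[0] or rec_lo > age_range[1]:
                return False
        return True

    kept = tuple(r for r in roster.candidates if compatible(r))
    return replace(roster, candidates=kept)
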