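"""Problem events: the dated, sited (code, diagnosis-text) records under audit.

A problem event is one database record pairing a free-text diagnosis
with an ICPC code at a primary-care site. The study window opens on
1992-01-02 (ICPC coding compulsory in Norway from 1992) and closes at
the end of 2008; within it, events before 2000-01-01 belong to the
*transition* phase (a code was optional) and later events to the
*regular* phase (a code was mandatory).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from datetime import date, datetime
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Sequence

__all__ = [
    "DEFAULT_PHASE_BOUNDARY",
    "DEFAULT_WINDOW_END",
    "DEFAULT_WINDOW_START",
    "EventFormat",
    "EventParseResult",
    "EventReject",
    "Phase",
    "ProblemEvent",
    "filter_window",
    "load_events",
    "phase_of",
    "read_events",
    "write_events",
]

DEFAULT_WINDOW_START = date(1992, 1, 2)
DEFAULT_WINDOW_END = date(2008, 12, 31)
DEFAULT_PHASE_BOUNDARY = date(2000, 1, 1)

REQUIRED_COLUMNS = ("site", "date", "code", "text")


class Phase(str, Enum):
    """Study phase: code-optional transition years vs code-mandatory regular years."""

    TRANSITION = "TRANSITION"
    REGULAR = "REGULAR"


@dataclass(frozen=True)
class ProblemEvent:
    """One dated, sited (code, text) record. Code/text are kept verbatim."""

    site: str
    date: date
    code: str
    text: str
    problem_id: str | None = None  # problem-history membership, uninterpreted

    @property
    def year(self) -> int:
        return self.date.year


@dataclass(frozen=True)
class EventReject:
    line_no: int
    raw: dict
    reason: str


@dataclass
class EventFormat:
    """Dialect of the delimited event export.

    ``date_format`` is ``"iso"`` (ISO-8601) or a ``strptime`` pattern;
    the printed per-site tables use day-first dates, so ``"%d/%m/%Y"``
    is the usual alternative.
    """

    delimiter: str = "\t"
    date_format: str = "iso"
    encoding: str = "utf-8"

    def parse_date(self, value: str) -> date:
        value = value.strip()
        if self.date_format == "iso":
            return date.fromisoformat(value)
        return datetime.strptime(value, self.date_format).date()


@dataclass
class EventParseResult:
    """Events in file order plus reject-listed rows with reasons."""

    events: list[ProblemEvent]
    rejects: list[EventReject]

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


class EventFormatError(ValueError):
    """Structural problem with the event file (e.g. a missing column)."""


def read_events(
    stream: Iterable[str] | IO[str] | str,
    fmt: EventFormat | None = None,
) -> EventParseResult:
    """Parse a delimited event export with a header row.

    Required columns: site, date, code, text (``problem_id`` optional).
    Rows with unparseable dates or an empty site are reject-listed;
    empty *code* fields are accepted verbatim — emptiness is an audit
    outcome, not a parse error.
    """
    fmt = fmt or EventFormat()
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream, delimiter=fmt.delimiter)
    fieldnames = reader.fieldnames or []
    for col in REQUIRED_COLUMNS:
        if col not in fieldnames:
            raise EventFormatError(f"missing required column: {col!r}")

    events: list[ProblemEvent] = []
    rejects: list[EventReject] = []
    for line_no, row in enumerate(reader, start=2):  # line 1 is the header
        site = (row.get("site") or "").strip()
        if not site:
            rejects.append(EventReject(line_no, row, "empty site"))
            continue
        raw_date = row.get("date") or ""
        try:
            event_date = fmt.parse_date(raw_date)
        except (ValueError, TypeError):
            rejects.append(EventReject(line_no, row, f"unparseable date {raw_date!r}"))
            continue
        events.append(
            ProblemEvent(
                site=site,
                date=event_date,
                code=row.get("code") or "",
                text=row.get("text") or "",
                problem_id=(row.get("problem_id") or None),
            )
        )
    return EventParseResult(events, rejects)


def load_events(path: str | Path, fmt: EventFormat | None = None) -> EventParseResult:
    fmt = fmt or EventFormat()
    with open(path, "r", encoding=fmt.encoding, newline="") as fh:
        return read_events(fh, fmt)


def write_events(events: Iterable[ProblemEvent], stream: IO[str]) -> None:
    """Write events as TSV with ISO dates (the dialect ``read_events`` accepts)."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["site", "date", "code", "text", "problem_id"])
    for e in events:
        writer.writerow([e.site, e.date.isoformat(), e.code, e.text, e.problem_id or ""])


def filter_window(
    events: Sequence[ProblemEvent],
    start: date = DEFAULT_WINDOW_START,
    end: date = DEFAULT_WINDOW_END,
) -> list[ProblemEvent]:
    """Keep events with ``start <= date <= end`` (both bounds closed)."""
    if start > end:
        raise ValueError("window start must not exceed end")
    return [e for e in events if start <= e.date <= end]


def phase_of(d: date, boundary: date = DEFAULT_PHASE_BOUNDARY) -> Phase:
    """TRANSITION strictly before ``boundary``, REGULAR from it onwards."""
    return Phase.TRANSITION if d < boundary else Phase.REGULAR
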