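"""The 3-step conformance audit of problem events against the register.

Every event receives exactly one of four labels, decided strictly
sequentially:

1. **MISSING_CODE** — the code field is empty or whitespace-only;
2. **CODE_MISMATCH** — the code is non-empty but absent from the register;
3. **TEXT_MISMATCH** — the code is valid but the normalized diagnosis
   text is not one of that code's registered options;
4. **VALID** — all three steps passed.

Step 3 matches against the options *of the event's own code* by default;
``match_scope="register"`` widens it to any register text for
sensitivity analysis. Matching is exact after normalization — no fuzzy
matching, so misspellings count as mismatches.

Summaries report counts and percentages of the four labels within a
grouping (site, calendar year, phase, or pooled); percentages are kept
unrounded internally and rounded only on output.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import IO, Iterable, Literal, Sequence

import pandas as pd

from .events import DEFAULT_PHASE_BOUNDARY, Phase, ProblemEvent, phase_of
from .normalize import normalize_text
from .register import Register

__all__ = [
    "AuditLabel",
    "AuditResult",
    "AuditSummary",
    "audit_events",
    "classify_event",
    "correct_code_pct_from_step_rates",
    "normalize_text",
    "pool_summaries",
    "summaries_to_frame",
    "summarize",
    "valid_pct_from_step_rates",
    "write_summaries_tsv",
    "year_series",
]

GroupBy = Literal["site", "year", "phase", "ALL"]
MatchScope = Literal["code", "register"]


class AuditLabel(str, Enum):
    MISSING_CODE = "MISSING_CODE"
    CODE_MISMATCH = "CODE_MISMATCH"
    TEXT_MISMATCH = "TEXT_MISMATCH"
    VALID = "VALID"


#: Fixed label order used by summaries and confusion matrices.
LABEL_ORDER = (
    AuditLabel.MISSING_CODE,
    AuditLabel.CODE_MISMATCH,
    AuditLabel.TEXT_MISMATCH,
    AuditLabel.VALID,
)


@dataclass(frozen=True)
class AuditResult:
    """Per-event classification with the year and phase it falls in."""

    event: ProblemEvent
    label: AuditLabel
    year: int
    phase: Phase


def classify_event(
    event: ProblemEvent,
    register: Register,
    match_scope: MatchScope = "code",
) -> AuditLabel:
    """Classify one event through the sequential 3-step funnel."""
    if not event.code.strip():
        return AuditLabel.MISSING_CODE
    code = event.code.strip().upper()
    if code not in register.index:
        return AuditLabel.CODE_MISMATCH
    text = normalize_text(event.text)
    if match_scope == "register":
        matched = text in register.all_texts
    else:
        matched = text in register.option_set(code)
    return AuditLabel.VALID if matched else AuditLabel.TEXT_MISMATCH


def audit_events(
    events: Iterable[ProblemEvent],
    register: Register,
    match_scope: MatchScope = "code",
    phase_boundary: date = DEFAULT_PHASE_BOUNDARY,
) -> list[AuditResult]:
    """Classify every event, order-preserving, attaching year and phase."""
    return [
        AuditResult(
            event=e,
            label=classify_event(e, register, match_scope),
            year=e.date.year,
            phase=phase_of(e.date, phase_boundary),
        )
        for e in events
    ]


@dataclass(frozen=True)
class AuditSummary:
    """Label counts and percentages within one group.

    Percentages are exact (unrounded) fractions of ``n_total``;
    ``pct_valid`` is the complement of the three failure rates, so the
    four always sum to exactly 100.
    """

    group_key: str | int
    n_total: int
    n_missing: int
    n_code_mismatch: int
    n_text_mismatch: int
    n_valid: int
    pct_missing: float
    pct_code_mismatch: float
    pct_text_mismatch: float
    pct_valid: float

    @classmethod
    def from_counts(
        cls,
        group_key: str | int,
        n_missing: int,
        n_code_mismatch: int,
        n_text_mismatch: int,
        n_valid: int,
    ) -> "AuditSummary":
        n_total = n_missing + n_code_mismatch + n_text_mismatch + n_valid
        if n_total == 0:
            raise ValueError("cannot summarize an empty group")
        pct_missing = 100.0 * n_missing / n_total
        pct_code = 100.0 * n_code_mismatch / n_total
        pct_text = 100.0 * n_text_mismatch / n_total
        return cls(
            group_key=group_key,
            n_total=n_total,
            n_missing=n_missing,
            n_code_mismatch=n_code_mismatch,
            n_text_mismatch=n_text_mismatch,
            n_valid=n_valid,
            pct_missing=pct_missing,
            pct_code_mismatch=pct_code,
            pct_text_mismatch=pct_text,
            pct_valid=100.0 - pct_missing - pct_code - pct_text,
        )

    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_missing, self.n_code_mismatch, self.n_text_mismatch, self.n_valid)


def summarize(results: Sequence[AuditResult], group_by: GroupBy = "ALL") -> list[AuditSummary]:
    """One :class:`AuditSummary` per group with at least one event.

    ``group_by`` is ``"site"``, ``"year"``, ``"phase"`` or ``"ALL"``
    (pooled). Groups are returned in sorted key order; empty groups are
    omitted rather than emitted as 0/0.
    """
    keyers = {
        "site": lambda r: r.event.site,
        "year": lambda r: r.year,
        "phase": lambda r: r.phase.value,
        "ALL": lambda r: "ALL",
    }
    try:
        keyer = keyers[group_by]
    except KeyError:
        raise ValueError(f"unknown group_by: {group_by!r}") from None

    counts: dict[str | int, dict[AuditLabel, int]] = {}
    for r in results:
        key = keyer(r)
        group = counts.setdefault(key, {label: 0 for label in LABEL_ORDER})
        group[r.label] += 1
    return [
        AuditSummary.from_counts(
            key,
            group[AuditLabel.MISSING_CODE],
            group[AuditLabel.CODE_MISMATCH],
            group[AuditLabel.TEXT_MISMATCH],
            group[AuditLabel.VALID],
        )
        for key, group in sorted(counts.items(), key=lambda kv: str(kv[0]))
    ]


def pool_summaries(summaries: Sequence[AuditSummary], group_key: str = "ALL") -> AuditSummary:
    """Event-count-weighted pooling: sum the counts, recompute the rates."""
    if not summaries:
        raise ValueError("nothing to pool")
    return AuditSummary.from_counts(
        group_key,
        sum(s.n_missing for s in summaries),
        sum(s.n_code_mismatch for s in summaries),
        sum(s.n_text_mismatch for s in summaries),
        sum(s.n_valid for s in summaries),
    )


def valid_pct_from_step_rates(
    pct_missing: float, pct_code_mismatch: float, pct_text_mismatch: float
) -> float:
    """Share of events passing all three steps, from the three failure rates."""
    return 100.0 - pct_missing - pct_code_mismatch - pct_text_mismatch


def correct_code_pct_from_step_rates(pct_missing: float, pct_code_mismatch: float) -> float:
    """Share of events holding a register-valid code (steps 1-2 passed)."""
    return 100.0 - pct_missing - pct_code_mismatch


def summaries_to_frame(
    summaries: Sequence[AuditSummary], precision: int | None = 1
) -> pd.DataFrame:
    """Tabulate summaries; percentages rounded to ``precision`` decimals."""
    rows = []
    for s in summaries:
        row = {
            "group_key": s.group_key,
            "n_total": s.n_total,
            "n_missing": s.n_missing,
            "n_code_mismatch": s.n_code_mismatch,
            "n_text_mismatch": s.n_text_mismatch,
            "n_valid": s.n_valid,
            "pct_missing": s.pct_missing,
            "pct_code_mismatch": s.pct_code_mismatch,
            "pct_text_mismatch": s.pct_text_mismatch,
            "pct_valid": s.pct_valid,
        }
        if precision is not None:
            for col in row:
                if col.startswith("pct_"):
                    row[col] = round(row[col], precision)
        rows.append(row)
    return pd.DataFrame(rows)


def write_summaries_tsv(
    summaries: Sequence[AuditSummary], stream: IO[str], precision: int = 1
) -> None:
    summaries_to_frame(summaries, precision).to_csv(stream, sep="\t", index=False)


def year_series(results: Sequence[AuditResult], precision: int | None = None) -> pd.DataFrame:
    """Per-calendar-year failure rates, ascending, for plotting the trend.

    Columns: year, n_total, pct_missing, pct_code_mismatch,
    pct_text_mismatch. Years with no events are absent.
    """
    summaries = sorted(summarize(results, "year"), key=lambda s: int(s.group_key))
    frame = pd.DataFrame(
        {
            "year": [int(s.group_key) for s in summaries],
            "n_total": [s.n_total for s in summaries],
            "pct_missing": [s.pct_missing for s in summaries],
            "pct_code_mismatch": [s.pct_code_mismatch for s in summaries],
            "pct_text_mismatch": [s.pct_text_mismatch for s in summaries],
        }
    )
    if precision is not None:
        for col in ("pct_missing", "pct_code_mismatch", "pct_text_mismatch"):
            frame[col] = frame[col].round(precision)
    return frame
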