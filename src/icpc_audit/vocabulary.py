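"""Clinician-added ('new') diagnoses and problem-area code appropriateness.

When the official register lacks a needed diagnosis, physicians attach
their own text to a still-valid code; this module surfaces those novel
texts with usage counts, buckets their reuse (once / 2-10 / >10), and —
for configurable clinical problem areas selected by SQL-LIKE wildcard
patterns — tabulates per-phase counts of events carrying appropriate vs
inappropriate codes, with dispersion statistics across sites.

Novel-diagnosis detection is deliberately register-wide: a text attached
to the wrong code but present elsewhere in the register is a text
mismatch, not a 'new' diagnosis. No clinical adjudication (synonym vs
specification vs error) is attempted — the report only surfaces
candidates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import IO, NamedTuple, Sequence

import numpy as np

from .events import DEFAULT_PHASE_BOUNDARY, Phase, ProblemEvent, phase_of
from .normalize import normalize_text
from .register import ICPC_CHAPTERS, is_valid_code_syntax, Register

__all__ = [
    "AreaPhaseStats",
    "CategoryStats",
    "NovelDiagnosisReport",
    "NovelEntry",
    "ProblemAreaDefinition",
    "UsageBuckets",
    "area_phase_summary",
    "find_novel_diagnoses",
    "like_match",
    "load_area_definitions",
    "match_area",
    "usage_buckets",
    "wildcard_to_regex",
]


# ---------------------------------------------------------------------------
# Novel diagnoses
# ---------------------------------------------------------------------------


@dataclass
class NovelEntry:
    """One normalized text absent from the register, with usage evidence."""

    text: str
    count: int
    codes: set[str]
    first_date: date
    last_date: date


@dataclass
class NovelDiagnosisReport:
    entries: dict[str, NovelEntry] = field(default_factory=dict)

    @property
    def n_novel_texts(self) -> int:
        return len(self.entries)

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("text\tcount\tcodes\tfirst_date\tlast_date\n")
        for text in sorted(self.entries, key=lambda t: (-self.entries[t].count, t)):
            e = self.entries[text]
            codes = ",".join(sorted(e.codes))
            stream.write(f"{e.text}\t{e.count}\t{codes}\t{e.first_date}\t{e.last_date}\n")


def find_novel_diagnoses(
    events: Sequence[ProblemEvent],
    register: Register,
    per_site: bool = False,
) -> NovelDiagnosisReport | dict[str, NovelDiagnosisReport]:
    """Collect texts absent from the register's full normalized text set.

    Events whose text normalizes to the empty string are skipped. With
    ``per_site=True`` a separate report is returned per site.
    """
    if per_site:
        by_site: dict[str, list[ProblemEvent]] = {}
        for e in events:
            by_site.setdefault(e.site, []).append(e)
        return {site: find_novel_diagnoses(evs, register) for site, evs in sorted(by_site.items())}

    report = NovelDiagnosisReport()
    known = register.all_texts
    for e in events:
        text = normalize_text(e.text)
        if not text or text in known:
            continue
        entry = report.entries.get(text)
        code = e.code.strip().upper()
        if entry is None:
            report.entries[text] = NovelEntry(
                text=text,
                count=1,
                codes={code} if code else set(),
                first_date=e.date,
                last_date=e.date,
            )
        else:
            entry.count += 1
            if code:
                entry.codes.add(code)
            entry.first_date = min(entry.first_date, e.date)
            entry.last_date = max(entry.last_date, e.date)
    return report


class UsageBuckets(NamedTuple):
    """Novel-text reuse: used once, a few times (2-10), or many (>10)."""

    once: int
    few: int
    many: int


def usage_buckets(report: NovelDiagnosisReport) -> UsageBuckets:
    once = few = many = 0
    for entry in report.entries.values():
        if entry.count == 1:
            once += 1
        elif entry.count <= 10:
            few += 1
        else:
            many += 1
    return UsageBuckets(once, few, many)


# ---------------------------------------------------------------------------
# SQL-LIKE wildcard matching
# ---------------------------------------------------------------------------


def like_match(pattern: str, text: str) -> bool:
    """SQL ``LIKE`` semantics: ``%`` any run (incl. empty), ``_`` one char.

    Anchored over the whole text, case-insensitive (both sides
    casefolded). Implemented as the classic two-pointer scan with
    backtracking over the most recent ``%``.
    """
    p = pattern.casefold()
    s = text.casefold()
    pi = si = 0
    star = -1
    mark = 0
    while si < len(s):
        if pi < len(p) and (p[pi] == "_" or p[pi] == s[si]):
            pi += 1
            si += 1
        elif pi < len(p) and p[pi] == "%":
            star = pi
            mark = si
            pi += 1
        elif star != -1:
            pi = star + 1
            mark += 1
            si = mark
        else:
            return False
    while pi < len(p) and p[pi] == "%":
        pi += 1
    return pi == len(p)


def wildcard_to_regex(pattern: str) -> str:
    """Translate a LIKE pattern to an anchored regex (``%``→``.*``, ``_``→``.``)."""
    import re

    out = []
    for ch in pattern:
        if ch == "%":
            out.append(".*")
        elif ch == "_":
            out.append(".")
        else:
            out.append(re.escape(ch))
    return "".join(out)


# ---------------------------------------------------------------------------
# Problem areas
# ---------------------------------------------------------------------------


@dataclass
class ProblemAreaDefinition:
    """A clinical problem area: wildcard text patterns + expected code set."""

    name: str
    patterns: list[str] = field(default_factory=list)
    appropriate_codes: set[str] = field(default_factory=set)
    include_codes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.patterns and not self.include_codes:
            raise ValueError(f"area {self.name!r}: needs at least one pattern or include_code")
        for p in self.patterns:
            if not any(ch not in "%_" for ch in p):
                raise ValueError(
                    f"area {self.name!r}: pattern {p!r} has no literal characters"
                )
        for code_set in (self.appropriate_codes, self.include_codes):
            for c in code_set:
                if not is_valid_code_syntax(c.strip().upper(), ICPC_CHAPTERS):
                    raise ValueError(f"area {self.name!r}: invalid code {c!r}")
        self.appropriate_codes = {c.strip().upper() for c in self.appropriate_codes}
        self.include_codes = {c.strip().upper() for c in self.include_codes}


def load_area_definitions(source: str | Path | IO[str]) -> list[ProblemAreaDefinition]:
    """Load area definitions from a JSON list of objects.

    Each object: ``{"name": ..., "patterns": [...], "appropriate_codes":
    [...], "include_codes": [...]}`` (the last key optional).
    """
    if hasattr(source, "read"):
        data = json.load(source)  # type: ignore[arg-type]
    else:
        data = json.loads(Path(source).read_text(encoding="utf-8"))
    return [
        ProblemAreaDefinition(
            name=obj["name"],
            patterns=list(obj.get("patterns", [])),
            appropriate_codes=set(obj.get("appropriate_codes", [])),
            include_codes=set(obj.get("include_codes", [])),
        )
        for obj in data
    ]


def match_area(
    events: Sequence[ProblemEvent], area: ProblemAreaDefinition
) -> list[ProblemEvent]:
    """Events whose normalized text matches any pattern, or code is included."""
    selected = []
    for e in events:
        code = e.code.strip().upper()
        if code and code in area.include_codes:
            selected.append(e)
            continue
        text = normalize_text(e.text)
        if any(like_match(p, text) for p in area.patterns):
            selected.append(e)
    return selected


class CategoryStats(NamedTuple):
    """Across-site dispersion of per-site event counts for one category."""

    median: float
    sd: float
    mean: float
    se: float
    range_lo: int
    range_hi: int


@dataclass(frozen=True)
class AreaPhaseStats:
    """Appropriate vs inappropriate coding for one area in one phase.

    ``n_appropriate + n_inappropriate`` can fall short of ``n_total``:
    events with missing or register-invalid codes count in the phase
    total but in neither category, which is why the two percentages need
    not sum to 100.
    """

    area: str
    phase: Phase
    n_total: int
    n_appropriate: int
    n_inappropriate: int
    pct_appropriate: float
    pct_inappropriate: float
    appropriate: CategoryStats
    inappropriate: CategoryStats
    n_sites: int


def _category_stats(per_site_counts: Sequence[int]) -> CategoryStats:
    arr = np.asarray(per_site_counts, dtype=float)
    n = len(arr)
    sd = float(np.std(arr, ddof=1)) if n > 1 else float("nan")
    se = sd / math.sqrt(n) if n > 1 else float("nan")
    return CategoryStats(
        median=float(np.median(arr)),
        sd=sd,
        mean=float(np.mean(arr)),
        se=se,
        range_lo=int(arr.min()),
        range_hi=int(arr.max()),
    )


def area_phase_summary(
    area_events: Sequence[ProblemEvent],
    area: ProblemAreaDefinition,
    register: Register,
    boundary: date = DEFAULT_PHASE_BOUNDARY,
) -> dict[Phase, AreaPhaseStats]:
    """Per-phase appropriate/inappropriate tabulation for one problem area.

    *Appropriate*: code in the area's configured code set.
    *Inappropriate*: a non-empty, register-valid code outside that set.
    Missing/invalid codes join the phase total only. Dispersion
    statistics use per-site counts over the sites with area events in
    the phase, with sample (n-1) standard deviation and
    ``se = sd / sqrt(n_sites)``. Phases with zero area events are
    omitted.
    """
    per_phase: dict[Phase, dict[str, list[ProblemEvent]]] = {}
    for e in area_events:
        phase = phase_of(e.date, boundary)
        per_phase.setdefault(phase, {}).setdefault(e.site, []).append(e)

    out: dict[Phase, AreaPhaseStats] = {}
    for phase, by_site in per_phase.items():
        app_counts: list[int] = []
        inapp_counts: list[int] = []
        n_total = 0
        for site in sorted(by_site):
            site_app = site_inapp = 0
            for e in by_site[site]:
                n_total += 1
                code = e.code.strip().upper()
                if not code:
                    continue
                if code in area.appropriate_codes:
                    site_app += 1
                elif register.is_valid_code(code):
                    site_inapp += 1
            app_counts.append(site_app)
            inapp_counts.append(site_inapp)
        n_app, n_inapp = sum(app_counts), sum(inapp_counts)
        out[phase] = AreaPhaseStats(
            area=area.name,
            phase=phase,
            n_total=n_total,
            n_appropriate=n_app,
            n_inappropriate=n_inapp,
            pct_appropriate=100.0 * n_app / n_total,
            pct_inappropriate=100.0 * n_inapp / n_total,
            appropriate=_category_stats(app_counts),
            inappropriate=_category_stats(inapp_counts),
            n_sites=len(by_site),
        )
    return out
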