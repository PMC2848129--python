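"""Code-system conversion: rewrite old codes to new ones, texts untouched.

Models the 2004-style ICPC-1 -> ICPC-2 update: a flat ``old<TAB>new``
conversion table is applied once to an event stream. Diagnosis texts are
never rewritten, empty codes are left empty, and codes absent from the
table pass through unchanged but are counted — conversion is
deliberately non-destructive.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from .events import ProblemEvent
from .register import ICPC_CHAPTERS, RegisterReject, is_valid_code_syntax

logger = logging.getLogger(__name__)

__all__ = [
    "ConversionError",
    "ConversionReport",
    "ConversionTable",
    "convert_events",
    "load_conversion_table",
    "parse_conversion_table",
]


class ConversionError(ValueError):
    """Fatal conversion-table defect (conflicting duplicate mappings)."""


@dataclass
class ConversionTable:
    """A function old code -> new code, plus a provenance note."""

    mapping: dict[str, str]
    provenance: str = ""
    rejects: list[RegisterReject] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, code: str) -> str | None:
        return self.mapping.get(code.strip().upper())


@dataclass
class ConversionReport:
    n_converted: int = 0
    n_unmapped: int = 0
    n_empty: int = 0

    def to_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def parse_conversion_table(
    stream: Iterable[str] | IO[str] | str,
    provenance: str = "",
    chapters: str = ICPC_CHAPTERS,
) -> ConversionTable:
    """Parse ``old<TAB>new`` lines; the mapping must be a function.

    Duplicate keys mapping to conflicting values raise
    :class:`ConversionError`; repeated identical lines are harmless.
    Lines with malformed codes are reject-listed. An empty file yields
    an empty mapping with a logged warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    mapping: dict[str, str] = {}
    rejects: list[RegisterReject] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" not in line:
            rejects.append(RegisterReject(line_no, line, "missing tab separator"))
            continue
        old_raw, new_raw = line.split("\t", 1)
        old, new = old_raw.strip().upper(), new_raw.strip().upper()
        if not is_valid_code_syntax(old, chapters):
            rejects.append(RegisterReject(line_no, line, f"invalid old code {old_raw.strip()!r}"))
            continue
        if not is_valid_code_syntax(new, chapters):
            rejects.append(RegisterReject(line_no, line, f"invalid new code {new_raw.strip()!r}"))
            continue
        if old in mapping and mapping[old] != new:
            raise ConversionError(
                f"conflicting mapping for {old}: {mapping[old]} vs {new} (line {line_no})"
            )
        mapping[old] = new
    if not mapping:
        logger.warning("conversion table is empty")
    return ConversionTable(mapping, provenance, rejects)


def load_conversion_table(path: str | Path, provenance: str = "") -> ConversionTable:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_conversion_table(fh, provenance or str(path))


def convert_events(
    events: Sequence[ProblemEvent], table: ConversionTable
) -> tuple[list[ProblemEvent], ConversionReport]:
    """Apply the table once to every event code; texts are byte-identical.

    Mapped codes are replaced (chains are *not* followed transitively),
    unmapped non-empty codes pass through and are counted, empty codes
    stay empty.
    """
    out: list[ProblemEvent] = []
    report = ConversionReport()
    for e in events:
        code = e.code.strip().upper()
        if not code:
            report.n_empty += 1
            out.append(e)
            continue
        new = table.mapping.get(code)
        if new is None:
            report.n_unmapped += 1
            out.append(e)
        else:
            report.n_converted += 1
            out.append(dataclasses.replace(e, code=new))
    return out, report
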