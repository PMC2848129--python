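"""The ICPC classification register: code -> ordered diagnosis-text options.

The Norwegian ICPC-2 extends each three-character code (chapter letter +
two digits, e.g. ``D01``) with synonyms, specifications and local
extensions, so one code maps to an *ordered list* of text options rather
than a single label. This register is the conformance ground truth the
audit classifies against.
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from .normalize import normalize_text

logger = logging.getLogger(__name__)

#: The 17 ICPC chapter letters (I, J, M, O, Q, V and friends are unused).
ICPC_CHAPTERS = "ABDFHKLNPRSTUWXYZ"

__all__ = [
    "ICPC_CHAPTERS",
    "Register",
    "RegisterDialect",
    "RegisterEntry",
    "RegisterError",
    "RegisterReject",
    "is_valid_code_syntax",
    "load_register",
    "parse_register",
]


class RegisterError(ValueError):
    """Unrecoverable register parsing problem (e.g. an empty file)."""


def is_valid_code_syntax(code: str, chapters: str = ICPC_CHAPTERS) -> bool:
    """True iff ``code`` is a chapter letter from ``chapters`` + two digits."""
    return (
        len(code) == 3
        and code[0] in chapters
        and code[1].isdigit()
        and code[2].isdigit()
    )


@dataclass(frozen=True)
class RegisterEntry:
    """One (code, diagnosis text) row of the register."""

    code: str
    text: str


@dataclass(frozen=True)
class RegisterReject:
    """A register line that failed validation, with its reason."""

    line_no: int
    raw_line: str
    reason: str


@dataclass
class RegisterDialect:
    """File-format knobs for the 2-column register TSV."""

    encoding: str = "utf-8"
    comment_prefix: str = "#"
    strip_footnotes: bool = True  # trailing '*' markers are not label content
    chapters: str = ICPC_CHAPTERS


class Register:
    """Code-indexed terminology with ordered, deduplicated text options.

    ``index`` maps each code to its normalized text options in file
    order; every indexed code has at least one option.
    """

    def __init__(
        self,
        entries: Iterable[RegisterEntry],
        rejects: Iterable[RegisterReject] = (),
        chapters: str = ICPC_CHAPTERS,
    ) -> None:
        self.entries: list[RegisterEntry] = list(entries)
        self.rejects: list[RegisterReject] = list(rejects)
        self.chapters = chapters
        self.index: dict[str, list[str]] = {}
        for entry in self.entries:
            options = self.index.setdefault(entry.code, [])
            if entry.text not in options:
                options.append(entry.text)
        self._option_sets: dict[str, frozenset[str]] = {
            code: frozenset(opts) for code, opts in self.index.items()
        }
        self._all_texts: frozenset[str] = frozenset(
            t for opts in self.index.values() for t in opts
        )

    # -- queries ---------------------------------------------------------

    def is_valid_code(self, code: str) -> bool:
        """True iff ``code`` (trimmed, uppercased) is in the register."""
        return code.strip().upper() in self.index

    def option_count(self, code: str) -> int:
        """Number of distinct normalized options for ``code`` (0 if absent)."""
        return len(self.index.get(code.strip().upper(), ()))

    def options(self, code: str) -> list[str]:
        return list(self.index.get(code.strip().upper(), ()))

    def option_set(self, code: str) -> frozenset[str]:
        return self._option_sets.get(code.strip().upper(), frozenset())

    @property
    def all_texts(self) -> frozenset[str]:
        """Every normalized diagnosis text anywhere in the register."""
        return self._all_texts

    def option_count_histogram(self) -> dict[int, int]:
        """Map option-list length -> number of codes with that many options."""
        return dict(Counter(len(opts) for opts in self.index.values()))

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, code: str) -> bool:
        return self.is_valid_code(code)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Register({len(self.index)} codes, {sum(map(len, self.index.values()))} options)"

    # -- serialization ---------------------------------------------------

    def to_tsv(self, stream: IO[str]) -> None:
        """Write the normalized register as ``code<TAB>text`` lines."""
        for code, options in self.index.items():
            for text in options:
                stream.write(f"{code}\t{text}\n")

    def to_tsv_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()

    def write_rejects(self, stream: IO[str]) -> None:
        stream.write("line_no\traw_line\treason\n")
        for r in self.rejects:
            stream.write(f"{r.line_no}\t{r.raw_line}\t{r.reason}\n")


def parse_register(
    stream: Iterable[str] | IO[str], dialect: RegisterDialect | None = None
) -> Register:
    """Parse ``code<TAB>text`` lines into a :class:`Register`.

    Malformed lines (missing tab, bad code syntax, empty text after
    normalization) are collected on ``result.rejects`` rather than
    silently dropped. Duplicate (code, normalized text) pairs are
    deduplicated with a logged warning. A file with no data lines at all
    raises :class:`RegisterError`.
    """
    dialect = dialect or RegisterDialect()
    entries: list[RegisterEntry] = []
    rejects: list[RegisterReject] = []
    seen: set[tuple[str, str]] = set()
    n_data_lines = 0

    for line_no, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if dialect.comment_prefix and line.lstrip().startswith(dialect.comment_prefix):
            continue
        n_data_lines += 1
        if "\t" not in line:
            rejects.append(RegisterReject(line_no, line, "missing tab separator"))
            continue
        code_raw, text_raw = line.split("\t", 1)
        code = code_raw.strip().upper()
        if not is_valid_code_syntax(code, dialect.chapters):
            rejects.append(RegisterReject(line_no, line, f"invalid code {code_raw.strip()!r}"))
            continue
        if dialect.strip_footnotes:
            text = normalize_text(text_raw)
        else:
            text = " ".join(text_raw.split()).casefold()
        if not text:
            rejects.append(RegisterReject(line_no, line, "empty text after normalization"))
            continue
        if (code, text) in seen:
            logger.warning("duplicate register entry %s -> %r (line %d)", code, text, line_no)
            continue
        seen.add((code, text))
        entries.append(RegisterEntry(code, text))

    if n_data_lines == 0:
        raise RegisterError("empty register")
    return Register(entries, rejects, chapters=dialect.chapters)


def load_register(path: str | Path, dialect: RegisterDialect | None = None) -> Register:
    """Read a register TSV file from disk."""
    dialect = dialect or RegisterDialect()
    with open(path, "r", encoding=dialect.encoding) as fh:
        return parse_register(fh, dialect)


def _iter_lines(stream: Iterable[str] | IO[str]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from io.StringIO(stream)
    else:
        yield from stream
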