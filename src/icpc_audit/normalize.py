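"""Diagnosis-text normalization shared by the register and the audit.

The Norwegian ICPC-2 register and the problem-event exports disagree on
case and incidental whitespace, and register labels may carry trailing
footnote markers (``*``). Conformance matching is exact *after* this
normalization; no fuzzy matching is performed anywhere (misspellings are
mismatches by design).
"""

from __future__ import annotations

__all__ = ["normalize_text"]


def normalize_text(text: str) -> str:
    """Canonicalize a diagnosis text for exact matching.

    Rules: strip surrounding whitespace, drop trailing ``*`` footnote
    markers, collapse internal whitespace runs to a single space, and
    casefold. Norwegian letters (æ/ø/å) are preserved by casefolding.

    >>> normalize_text("  Akutt   abdomen ")
    'akutt abdomen'
    >>> normalize_text("Abdominalsmerte INA*")
    'abdominalsmerte ina'
    """
    s = text.strip()
    while s.endswith("*"):
        s = s[:-1].rstrip()
    s = " ".join(s.split())
    return s.casefold()
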