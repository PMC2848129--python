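"""Synthetic registers, conversion tables and problem-event streams.

The audited 16-year export is not publicly available, so every pipeline
stage is exercised against generated data with *known* error structure:
each event is planted as exactly one of the four audit outcomes, and a
truth log records the intended label so recovery can be checked both
exactly (label-for-label under a shared register) and statistically
(rate estimates vs generating probabilities).

Generation conditions mirror the study: missing codes occur in the
transition phase only (a code was mandatory from 2000), the default
category rates are the pooled rates of the real material (6.2% missing,
4.0% invalid code, 53.8% text mismatch), the register is long-tailed in
options per code (a few codes with >80 options, a large mass with one),
and novel-text reuse follows a truncated Zipf law so that single-use
texts dominate.

Within a phase the three probabilities are *marginal* category
probabilities (a categorical mixture per event), so each audited rate
is a direct binomial estimate of its generating parameter. All
randomness flows through one integer-seeded NumPy PCG64 generator;
identical config + seed reproduces the stream byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .audit import LABEL_ORDER, AuditLabel, AuditResult
from .events import (
    DEFAULT_PHASE_BOUNDARY,
    DEFAULT_WINDOW_END,
    DEFAULT_WINDOW_START,
    Phase,
    ProblemEvent,
)
from .register import ICPC_CHAPTERS, Register, RegisterEntry

__all__ = [
    "SynthConfig",
    "SynthConfigError",
    "TruthLog",
    "generate_conversion_table",
    "generate_events",
    "generate_register",
    "recovery_report",
]


class SynthConfigError(ValueError):
    """Invalid generation parameters (e.g. probabilities summing past 1)."""


@dataclass(frozen=True)
class SynthConfig:
    """Generation conditions for register and event-stream synthesis.

    Probabilities are per-event category probabilities within a phase;
    whatever remains after missing/invalid/text-mismatch is emitted as a
    fully valid event. ``p_missing_regular`` defaults to 0 because a
    code was mandatory after the phase boundary.
    """

    n_sites: int = 12
    events_per_site: int = 1000
    date_start: date = DEFAULT_WINDOW_START
    date_end: date = DEFAULT_WINDOW_END
    phase_boundary: date = DEFAULT_PHASE_BOUNDARY
    p_missing_transition: float = 0.062
    p_missing_regular: float = 0.0
    p_invalid_code: float = 0.040
    p_text_mismatch: float = 0.538
    novel_vocab_size: int = 4000
    reuse_exponent: float = 1.2
    register_size: int = 200
    option_tail_exponent: float | None = 1.6  # Zipf tail of options-per-code; None = one each
    max_options: int = 200
    forced_option_counts: tuple[tuple[str, int], ...] = ()
    site_rate_jitter: float = 0.0  # sd of per-site log-normal rate factors
    transition_weight: float | None = None  # None = uniform over the window
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_missing_transition": self.p_missing_transition,
            "p_missing_regular": self.p_missing_regular,
            "p_invalid_code": self.p_invalid_code,
            "p_text_mismatch": self.p_text_mismatch,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SynthConfigError(f"{name}={p} outside [0, 1]")
        for p_missing in (self.p_missing_transition, self.p_missing_regular):
            if p_missing + self.p_invalid_code + self.p_text_mismatch > 1.0 + 1e-12:
                raise SynthConfigError("per-phase probabilities sum past 1")
        if self.register_size < 1:
            raise SynthConfigError("register_size must be >= 1")
        if self.register_size > len(ICPC_CHAPTERS) * 100:
            raise SynthConfigError(
                f"register_size exceeds the {len(ICPC_CHAPTERS) * 100}-code grid"
            )
        if self.n_sites < 1:
            raise SynthConfigError("n_sites must be >= 1")
        if self.events_per_site < 0:
            raise SynthConfigError("events_per_site must be >= 0")
        if self.date_start > self.date_end:
            raise SynthConfigError("date_start after date_end")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("date_start", "date_end", "phase_boundary"):
            d[key] = d[key].isoformat()
        d["forced_option_counts"] = [list(pair) for pair in self.forced_option_counts]
        return d


def _code_grid(chapters: str = ICPC_CHAPTERS) -> list[str]:
    return [f"{ch}{i:02d}" for ch in chapters for i in range(100)]


def generate_register(config: SynthConfig, seed: int | None = None) -> Register:
    """Draw a register from the valid code grid with long-tailed options.

    Option counts per code are Zipf(``option_tail_exponent``) draws
    clipped at ``max_options``; ``forced_option_counts`` pins chosen
    codes to exact counts (e.g. a 167-option catch-all code). Texts are
    synthetic tokens, unique per (code, option).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = _code_grid()
    forced = {c.strip().upper(): k for c, k in config.forced_option_counts}
    free = [c for c in grid if c not in forced]
    n_free = config.register_size - len(forced)
    if n_free < 0:
        raise SynthConfigError("more forced codes than register_size")
    free_idx = sorted(rng.choice(len(free), size=n_free, replace=False).tolist())
    chosen = sorted(forced) + [free[i] for i in free_idx]
    entries: list[RegisterEntry] = []
    for code in chosen:
        if code in forced:
            k = forced[code]
        elif config.option_tail_exponent is None:
            k = 1
        else:
            k = int(min(rng.zipf(config.option_tail_exponent), config.max_options))
        for j in range(k):
            entries.append(RegisterEntry(code, f"diagnose {code.lower()} variant {j + 1}"))
    return Register(entries)


@dataclass
class TruthLog:
    """Intended label per generated event, in event order."""

    labels: list[AuditLabel]
    novel_terms: list[str | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)

    def write_tsv(self, stream) -> None:
        stream.write("index\tlabel\tnovel_term\n")
        for i, label in enumerate(self.labels):
            term = self.novel_terms[i] if i < len(self.novel_terms) else None
            stream.write(f"{i}\t{label.value}\t{term or ''}\n")


def _zipf_weights(size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def generate_events(
    register: Register,
    config: SynthConfig,
    seed: int | None = None,
) -> tuple[list[ProblemEvent], TruthLog]:
    """Emit a sited, dated event stream with planted audit outcomes.

    Per event: a date (uniform over the window, or phase-weighted via
    ``transition_weight``), then a category draw with the phase's
    probabilities — empty code / syntactically-valid-but-unregistered
    code / valid code with a Zipf-reused novel text / valid code with
    one of its own options. The truth log records every intended label.
    """
    config.validate()
    if len(register) == 0:
        raise SynthConfigError("register is empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    codes = sorted(register.index)
    options = [register.index[c] for c in codes]
    grid = _code_grid()
    invalid_pool = sorted(set(grid) - set(codes))
    if not invalid_pool:
        raise SynthConfigError("no syntactically valid codes left outside the register")
    novel_vocab = [f"lokal diagnose {i + 1}" for i in range(config.novel_vocab_size)]
    novel_weights = _zipf_weights(config.novel_vocab_size, config.reuse_exponent)
    novel_cum = np.cumsum(novel_weights)

    n_days = (config.date_end - config.date_start).days + 1
    boundary_offset = (config.phase_boundary - config.date_start).days
    n_total = config.n_sites * config.events_per_site

    # per-site multiplicative rate perturbation (off by default)
    if config.site_rate_jitter > 0:
        factors = np.exp(rng.normal(0.0, config.site_rate_jitter, size=config.n_sites))
    else:
        factors = np.ones(config.n_sites)

    # dates
    if config.transition_weight is None or boundary_offset <= 0 or boundary_offset >= n_days:
        day_offsets = rng.integers(0, n_days, size=n_total)
    else:
        in_transition = rng.random(n_total) < config.transition_weight
        day_offsets = np.where(
            in_transition,
            rng.integers(0, boundary_offset, size=n_total),
            rng.integers(boundary_offset, n_days, size=n_total),
        )

    u_label = rng.random(n_total)
    code_idx = rng.integers(0, len(codes), size=n_total)
    option_u = rng.random(n_total)
    invalid_idx = rng.integers(0, len(invalid_pool), size=n_total)
    novel_idx = np.searchsorted(novel_cum, rng.random(n_total), side="left")

    events: list[ProblemEvent] = []
    labels: list[AuditLabel] = []
    novel_terms: list[str | None] = []
    for i in range(n_total):
        site_no = i // config.events_per_site if config.events_per_site else 0
        site = f"site{site_no + 1:02d}"
        event_date = config.date_start + timedelta(days=int(day_offsets[i]))
        transition = event_date < config.phase_boundary
        f = factors[site_no]
        p_missing = min(
            1.0,
            (config.p_missing_transition if transition else config.p_missing_regular) * f,
        )
        p_invalid = config.p_invalid_code * f
        p_text = config.p_text_mismatch * f
        total = p_missing + p_invalid + p_text
        if total > 1.0:  # jitter pushed the mixture past 1: rescale failures
            p_missing, p_invalid, p_text = (
                p_missing / total,
                p_invalid / total,
                p_text / total,
            )
        u = u_label[i]
        valid_code = codes[code_idx[i]]
        opts = options[code_idx[i]]
        novel_term: str | None = None
        if u < p_missing:
            label = AuditLabel.MISSING_CODE
            code, text = "", opts[int(option_u[i] * len(opts))]
        elif u < p_missing + p_invalid:
            label = AuditLabel.CODE_MISMATCH
            code, text = invalid_pool[invalid_idx[i]], opts[int(option_u[i] * len(opts))]
        elif u < p_missing + p_invalid + p_text:
            label = AuditLabel.TEXT_MISMATCH
            novel_term = novel_vocab[int(novel_idx[i])]
            code, text = valid_code, novel_term
        else:
            label = AuditLabel.VALID
            code, text = valid_code, opts[int(option_u[i] * len(opts))]
        events.append(ProblemEvent(site=site, date=event_date, code=code, text=text))
        labels.append(label)
        novel_terms.append(novel_term)
    return events, TruthLog(labels, novel_terms)


def generate_conversion_table(
    register: Register, n_mappings: int, seed: int = 0
) -> dict[str, str]:
    """Map codes from outside the register onto register codes.

    Emulates an old-version-to-new-version table: keys are syntactically
    valid codes absent from the register (old codes), values are
    register codes, so re-applying the table is a no-op on converted
    streams.
    """
    rng = np.random.default_rng(seed)
    codes = sorted(register.index)
    old_pool = sorted(set(_code_grid()) - set(codes))
    if n_mappings > len(old_pool):
        raise SynthConfigError("not enough out-of-register codes for the mapping")
    old = [old_pool[i] for i in sorted(rng.choice(len(old_pool), size=n_mappings, replace=False))]
    new = [codes[int(i)] for i in rng.integers(0, len(codes), size=n_mappings)]
    return dict(zip(old, new))


def recovery_report(
    truth: TruthLog, results: Sequence[AuditResult]
) -> pd.DataFrame:
    """4x4 confusion matrix of intended (rows) vs assigned (columns) labels.

    With generator and auditor sharing one register and normalization,
    all mass must sit on the diagonal. Raises on length mismatch.
    """
    if len(truth) != len(results):
        raise ValueError(
            f"truth log has {len(truth)} entries but audit produced {len(results)}"
        )
    names = [label.value for label in LABEL_ORDER]
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for intended, result in zip(truth.labels, results):
        mat.loc[intended.value, result.label.value] += 1
    return mat
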