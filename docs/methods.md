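# Methods

## The problem

Primary-care electronic records in Norway code each consultation's
clinical problems with ICPC (International Classification for Primary
Care): a chapter letter plus two digits, e.g. `D01`. The Norwegian
ICPC-2 register extends every code with multiple diagnosis-text options
(synonyms, specifications, local extensions), so one code such as `D01`
carries 11 registered texts, and catch-all codes like `L99` carry over
160. A *problem event* is one dated record pairing a free-text
diagnosis with a code at a site. This package audits such event streams
for conformance with the register, following a long-running 12-site
material in which coding was optional during a transition phase
(1992–1999) and mandatory in the regular phase (2000–2008).

## The audit model

Each event receives exactly one of four labels through a strictly
sequential funnel:

1. `MISSING_CODE` — the code field is empty or whitespace-only;
2. `CODE_MISMATCH` — a non-empty code absent from the register;
3. `TEXT_MISMATCH` — a register-valid code whose normalized diagnosis
   text is not among that code's registered options;
4. `VALID` — all checks passed.

The labels partition the stream, so for any grouping (site, calendar
year, phase, pooled) the four counts sum to the group total and the
unrounded percentages sum to exactly 100; the share of fully
conformant events is the complement
`pct_valid = 100 − pct_missing − pct_code_mismatch − pct_text_mismatch`,
and the share of events holding a register-valid code is
`100 − pct_missing − pct_code_mismatch`. Pooled summaries are the
event-count-weighted combination of per-group summaries, computed on
counts, never on rounded rates.

### Text matching

Matching is exact after normalization: surrounding whitespace stripped,
trailing `*` footnote markers dropped, internal whitespace collapsed,
casefolded (Norwegian æ/ø/å preserved). No fuzzy or edit-distance
matching is attempted — a misspelled diagnosis is a mismatch by design,
since the audit measures adherence to the register as distributed.

Two genuinely open choices are exposed as configuration:

* **Step-3 scope** (`match_scope`): by default the event text must
  match an option *of its own code*. The register is code-indexed and
  locally added texts were attached to valid codes, so per-code
  matching is the natural reading; `match_scope="register"` (any
  register text) is available for sensitivity analysis.
* **Case/whitespace sensitivity** is fixed by the normalization above;
  the raw fields are preserved verbatim on read, so stricter variants
  can be layered on without re-parsing.

### Phases and window

The phase boundary is 2000-01-01: dates strictly before it are
TRANSITION, later dates REGULAR (the source material gives phases only
as year ranges, 1992–1999 vs 2000–2008). The default study window is
closed on both sides, 1992-01-02 through 2008-12-31; both bounds and
the boundary are parameters.

## Code-system conversion

A version update (old → new code) is modelled as a flat table applied
exactly once: mapped codes are rewritten, diagnosis texts are never
touched, empty codes stay empty, and unmapped non-empty codes pass
through unchanged but counted. Chains are not followed transitively.
Conversion is non-destructive by contract: event count, text bytes and
the number of missing codes are invariant. Conflicting duplicate keys
(one old code, two new codes) are a fatal table error; identical
repeats are ignored.

## Novel diagnoses and problem areas

A *novel* ('new') diagnosis is a normalized event text absent from the
register's **entire** text set — deliberately broader than step-3
matching, so a text filed under the wrong code but registered elsewhere
is a text mismatch, not a novel diagnosis. The report keys entries by
normalized text with usage count, the codes it appeared under, and
first/last dates; reuse is bucketed as used once / 2–10 times
(inclusive) / more than 10. No clinical adjudication (synonym vs
specification vs error) is attempted.

Problem areas (shipped defaults: pneumonia/lower-respiratory infection,
diabetes, tonsillitis, anaemia) are defined in editable JSON as SQL-LIKE
wildcard patterns over the normalized text (`%` any run including
empty, `_` exactly one character, anchored, case-insensitive) plus a
configured set of appropriate codes. The appropriate-code sets are
configuration, not constants — the source material never lists the sets
it used, so the shipped ones are best-effort stand-ins built from the
standard ICPC-2 codes for each area. Patterns consisting only of
wildcards are rejected at load (`%` alone selects everything). The
matcher is a two-pointer LIKE scan with backtracking over the latest
`%`; tests check it against an independent regex translation
(`%`→`.*`, `_`→`.`, fully anchored).

Per phase, an area event is *appropriate* if its code is in the
configured set, *inappropriate* if it carries a register-valid code
outside the set; events with missing or invalid codes count in the
phase total but in neither category, which is why the two percentages
need not sum to 100. Dispersion statistics (median, sample n−1 SD,
mean, SE = SD/√n_sites, range) are computed across the per-site counts
of sites contributing area events in that phase — sites is the most
natural dispersion unit for a 12-site material; the unusual
"median ± SD" pairing is kept as the field reports it.

## Synthetic data

The audited export is not publicly available, so a generator stands in
for it, and its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 12 | sites in the material |
| `p_missing_transition` | 0.062 | pooled missing-code rate; transition only |
| `p_missing_regular` | 0.0 | codes mandatory after the boundary |
| `p_invalid_code` | 0.040 | pooled code-mismatch rate |
| `p_text_mismatch` | 0.538 | pooled text-mismatch rate |
| `register_size` | 200 codes | register scale for fast tests |
| `option_tail_exponent` | 1.6 | Zipf tail of options per code |
| `novel_vocab_size` / `reuse_exponent` | 4000 / 1.2 | truncated-Zipf novel-text reuse |

Within a phase the three probabilities are **marginal category
probabilities**: each event draws one of
missing/invalid/text-mismatch/valid from a categorical distribution
(failing probabilities must sum to ≤ 1 per phase). This makes every
audited group rate a direct binomial estimate of its generating
parameter, which is what the statistical-recovery tests assert (each
rate within 3 binomial SE at n = 2×10⁵). A sequential "else-with-p"
reading would make the marginals products of survivor probabilities and
break that correspondence.

Registers are drawn from the valid 17×100 code grid with Zipf-tailed
option counts (clipped at `max_options`); specific codes can be pinned
to exact option counts to reproduce documented extremes (e.g. a
167-option catch-all). The novel vocabulary is disjoint from register
texts by construction, and its size (4000 terms against the default
stream sizes) with exponent 1.2 makes single-use texts dominate heavy
reuse, matching the reported reuse profile qualitatively. Optional
per-site log-normal rate jitter emulates between-site spread; it is off
by default, and when it pushes a site's mixture past 1 the failure
probabilities are rescaled proportionally.

Every event's intended label is written to a truth log; with generator
and auditor sharing one register the intended-vs-assigned confusion
matrix is exactly diagonal (asserted, not statistical). All randomness
flows through a single integer-seeded NumPy PCG64 generator, so a
config + seed reproduces the stream byte-for-byte across platforms.

What the generator does **not** model: clinical content (texts are
synthetic tokens unless a real register file is supplied), problem-
history chaining, within-year seasonality, and any generative model of
the real between-site heterogeneity (which is descriptive only).
Passing tests therefore demonstrate the pipeline's correctness and
calibration, not claims about real coding behaviour.

## Published reference figures

Two small printed tables ship with the package (`icpc_audit.refdata`):
the 12-site table of collection periods, patient/event counts and
per-site failure rates, and the 11-option `D01` register fragment.
They validate arithmetic only — totals (75,951 patients; 1,500,594
events), funnel closure (pooled 6.2/4.0/53.8 → 89.8% register-valid
codes, 36.0% fully conformant), and event-count-weighted pooling of
per-site rates. Reconstructing per-site counts from 1-decimal printed
rates recovers the pooled missing and code-mismatch rates at one
decimal (6.2, 4.0) and 53.5 vs 53.8 for the text-mismatch rate, the
expected accumulation of per-site rounding error at rates of that
magnitude. The full event-level material is not reproducible from
print, so per-site headline rates guide fixtures and generator
conditions rather than being asserted.

## Problem sizes and numerics

Test and acceptance runs use scaled streams: 10 sites × 10,000–20,000
events for recovery checks (10⁵–2×10⁵ events), 300-code registers,
10,000 random pattern/text pairs for the wildcard oracle — sizes chosen
so the binomial standard errors are small against the rates being
recovered while the whole suite stays fast. Percentages are reported at
1 decimal by default with all internal arithmetic unrounded; groups
with zero events are omitted rather than emitted as 0/0; dispersion
over a single site reports SD/SE as NaN rather than inventing a value.
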