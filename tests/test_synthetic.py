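"""Generator determinism, planted-label recovery and rate calibration."""

import io
from datetime import date

import numpy as np
import pytest

from icpc_audit import (
    AuditLabel,
    Phase,
    SynthConfig,
    audit_events,
    find_novel_diagnoses,
    generate_conversion_table,
    generate_events,
    generate_register,
    phase_of,
    recovery_report,
    summarize,
)
from icpc_audit.register import Register, RegisterEntry
from icpc_audit.synthetic import SynthConfigError, TruthLog


SMALL = SynthConfig(n_sites=3, events_per_site=400, register_size=60, seed=7)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_missing_transition": -0.1},
            {"p_invalid_code": 1.5},
            {"p_missing_transition": 0.5, "p_invalid_code": 0.3, "p_text_mismatch": 0.3},
            {"register_size": 0},
            {"register_size": 1701},  # exceeds the 17x100 code grid
            {"date_start": date(2009, 1, 1), "date_end": date(1992, 1, 1)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SynthConfigError):
            SynthConfig(**kwargs).validate()

    def test_defaults_mirror_study_conditions(self):
        cfg = SynthConfig()
        cfg.validate()
        assert cfg.p_missing_regular == 0.0  # code mandatory after the boundary
        assert (cfg.p_missing_transition, cfg.p_invalid_code, cfg.p_text_mismatch) == (
            0.062, 0.040, 0.538,
        )


class TestGenerateRegister:
    def test_size_and_all_ones_distribution(self):
        cfg = SynthConfig(register_size=10, option_tail_exponent=None)
        reg = generate_register(cfg, seed=1)
        assert len(reg) == 10
        assert reg.option_count_histogram() == {1: 10}

    def test_same_seed_byte_identical_serialization(self):
        a = generate_register(SMALL, seed=3).to_tsv_string()
        b = generate_register(SMALL, seed=3).to_tsv_string()
        assert a == b

    def test_different_seeds_differ(self):
        assert (
            generate_register(SMALL, seed=3).to_tsv_string()
            != generate_register(SMALL, seed=4).to_tsv_string()
        )

    def test_forced_long_tail_code(self):
        cfg = SynthConfig(register_size=50, forced_option_counts=(("L99", 167),))
        reg = generate_register(cfg, seed=1)
        assert reg.option_count("L99") == 167
        assert reg.option_count_histogram()[167] == 1

    def test_codes_drawn_from_valid_grid(self):
        reg = generate_register(SMALL, seed=2)
        from icpc_audit.register import is_valid_code_syntax

        assert all(is_valid_code_syntax(c) for c in reg.index)


class TestGenerateEvents:
    def test_determinism_under_seed(self):
        reg = generate_register(SMALL, seed=5)
        ev1, t1 = generate_events(reg, SMALL, seed=11)
        ev2, t2 = generate_events(reg, SMALL, seed=11)
        assert ev1 == ev2
        assert t1.labels == t2.labels

    def test_site_layout(self):
        reg = generate_register(SMALL, seed=5)
        events, _ = generate_events(reg, SMALL, seed=11)
        assert len(events) == SMALL.n_sites * SMALL.events_per_site
        assert len({e.site for e in events}) == SMALL.n_sites

    def test_no_missing_codes_in_regular_phase(self):
        reg = generate_register(SMALL, seed=5)
        events, truth = generate_events(reg, SMALL, seed=11)
        for e, label in zip(events, truth.labels):
            if phase_of(e.date) is Phase.REGULAR:
                assert label is not AuditLabel.MISSING_CODE
                assert e.code.strip()

    def test_all_probabilities_zero_gives_all_valid(self):
        cfg = SynthConfig(
            n_sites=2, events_per_site=200, register_size=30,
            p_missing_transition=0, p_invalid_code=0, p_text_mismatch=0, seed=1,
        )
        reg = generate_register(cfg)
        events, truth = generate_events(reg, cfg)
        assert set(truth.labels) == {AuditLabel.VALID}
        results = audit_events(events, reg)
        assert summarize(results, "ALL")[0].pct_valid == 100.0

    def test_novel_text_count_matches_draw_log(self, ):
        cfg = SynthConfig(
            n_sites=2, events_per_site=2000, register_size=40,
            novel_vocab_size=50, reuse_exponent=1.2, seed=9,
        )
        reg = generate_register(cfg)
        events, truth = generate_events(reg, cfg)
        report = find_novel_diagnoses(events, reg)
        drawn = {t for t in truth.novel_terms if t}
        assert report.n_novel_texts == len(drawn)
        # generator ground truth: per-term usage counts agree
        for term in drawn:
            assert report.entries[term].count == sum(
                1 for t in truth.novel_terms if t == term
            )

    def test_zipf_reuse_skews_to_single_use(self):
        cfg = SynthConfig(
            n_sites=2, events_per_site=3000, register_size=40,
            novel_vocab_size=500, reuse_exponent=1.2, seed=9,
        )
        reg = generate_register(cfg)
        events, _ = generate_events(reg, cfg)
        from icpc_audit import usage_buckets

        buckets = usage_buckets(find_novel_diagnoses(events, reg))
        assert buckets.once > buckets.many  # single-use texts dominate heavy reuse


class TestRecoveryReport:
    def test_shared_register_gives_diagonal_matrix(self):
        reg = generate_register(SMALL, seed=5)
        events, truth = generate_events(reg, SMALL, seed=11)
        confusion = recovery_report(truth, audit_events(events, reg))
        off_diag = confusion.values.sum() - np.diag(confusion.values).sum()
        assert off_diag == 0
        assert confusion.values.sum() == len(events)

    def test_register_missing_one_code_shifts_valid_to_code_mismatch(self):
        reg = generate_register(SMALL, seed=5)
        events, truth = generate_events(reg, SMALL, seed=11)
        dropped = sorted(reg.index)[0]
        crippled = Register(
            [RegisterEntry(c, t) for c in reg.index if c != dropped for t in reg.index[c]]
        )
        confusion = recovery_report(truth, audit_events(events, crippled))
        # all events generated on the dropped code now fail step 2; direct enumeration:
        expected = sum(
            1
            for e, label in zip(events, truth.labels)
            if label is AuditLabel.VALID and e.code == dropped
        )
        assert confusion.loc["VALID", "CODE_MISMATCH"] == expected
        assert confusion.values.sum() == len(events)  # everything accounted for

    def test_empty_streams_give_empty_matrix(self):
        confusion = recovery_report(TruthLog([], []), [])
        assert confusion.values.sum() == 0

    def test_length_mismatch_raises(self):
        reg = generate_register(SMALL, seed=5)
        events, truth = generate_events(reg, SMALL, seed=11)
        with pytest.raises(ValueError, match="truth log"):
            recovery_report(truth, audit_events(events[:-1], reg))


class TestConversionTableGeneration:
    def test_keys_outside_register_values_inside(self):
        reg = generate_register(SMALL, seed=5)
        table = generate_conversion_table(reg, 20, seed=1)
        assert len(table) == 20
        assert all(old not in reg.index for old in table)
        assert all(new in reg.index for new in table.values())
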