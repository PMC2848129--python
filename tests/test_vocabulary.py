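"""Novel-diagnosis detection, reuse buckets, wildcard areas and phase stats."""

import math
import re
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icpc_audit import (
    Phase,
    ProblemEvent,
    area_phase_summary,
    find_novel_diagnoses,
    like_match,
    match_area,
    usage_buckets,
)
from icpc_audit.vocabulary import (
    NovelDiagnosisReport,
    NovelEntry,
    ProblemAreaDefinition,
    wildcard_to_regex,
)


def _ev(code, text, site="A", d=date(1995, 6, 15)):
    return ProblemEvent(site, d, code, text)


class TestNovelDiagnoses:
    def test_all_valid_stream_is_empty_report(self, toy_register):
        events = [_ev("D01", "Akutt abdomen"), _ev("R81", "Pneumoni")]
        assert find_novel_diagnoses(events, toy_register).n_novel_texts == 0

    def test_repeated_unseen_text_counted_once_with_count(self, toy_register):
        events = [_ev("D01", "Magesår") for _ in range(3)]
        report = find_novel_diagnoses(events, toy_register)
        assert report.n_novel_texts == 1
        entry = report.entries["magesår"]
        assert entry.count == 3
        assert entry.codes == {"D01"}

    def test_detection_is_register_wide(self, toy_register):
        # 'Pneumoni' exists under R81: attached to D01 it is a text
        # mismatch, not a novel diagnosis
        report = find_novel_diagnoses([_ev("D01", "Pneumoni")], toy_register)
        assert report.n_novel_texts == 0

    def test_novel_set_disjoint_from_register_texts(self, toy_register):
        events = [_ev("D01", t) for t in ["Magesår", "Akutt abdomen", "Nytt begrep"]]
        report = find_novel_diagnoses(events, toy_register)
        assert set(report.entries).isdisjoint(toy_register.all_texts)

    def test_dates_and_per_site_split(self, toy_register):
        events = [
            _ev("D01", "Magesår", site="A", d=date(1994, 1, 1)),
            _ev("D01", "Magesår", site="B", d=date(2001, 5, 5)),
        ]
        pooled = find_novel_diagnoses(events, toy_register)
        assert pooled.entries["magesår"].first_date == date(1994, 1, 1)
        assert pooled.entries["magesår"].last_date == date(2001, 5, 5)
        per_site = find_novel_diagnoses(events, toy_register, per_site=True)
        assert set(per_site) == {"A", "B"}
        assert per_site["A"].entries["magesår"].count == 1


class TestUsageBuckets:
    def _report(self, counts):
        rep = NovelDiagnosisReport()
        for i, c in enumerate(counts):
            rep.entries[f"t{i}"] = NovelEntry(
                f"t{i}", c, set(), date(1995, 1, 1), date(1995, 1, 1)
            )
        return rep

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([1, 1, 5, 12], (2, 1, 1)),
            ([], (0, 0, 0)),
            ([10] * 100, (0, 100, 0)),  # 10 is inclusive in 'few'
            ([11], (0, 0, 1)),
            ([2], (0, 1, 0)),
        ],
    )
    def test_partition(self, counts, expected):
        assert usage_buckets(self._report(counts)) == expected


class TestWildcardMatching:
    @pytest.mark.parametrize(
        "pattern, text, matches",
        [
            ("%pneumoni%", "Bakteriell pneumoni", True),
            ("%pneumoni%", "pneumoni", True),
            ("%anemi%", "Diabetes mellitus", False),
            ("tonsil_itt", "tonsillitt", True),
            ("tonsil_itt", "tonsilitt", False),  # '_' needs exactly one char
            ("%abdomen", "akutt abdomen", True),
            ("abdomen%", "akutt abdomen", False),  # anchored at both ends
            ("d_abet%", "Diabetes type 2", True),
            ("%ØMHET%", "abdominal ømhet", True),  # case-insensitive incl. æøå
        ],
    )
    def test_like_semantics(self, pattern, text, matches):
        assert like_match(pattern, text) is matches

    @given(
        st.text(alphabet="ab%_", max_size=8),
        st.text(alphabet="ab", max_size=8),
    )
    @settings(max_examples=500, deadline=None)
    def test_agrees_with_regex_translation_oracle(self, pattern, text):
        oracle = re.fullmatch(wildcard_to_regex(pattern), text) is not None
        assert like_match(pattern, text) is oracle


class TestProblemAreaDefinition:
    def test_pattern_without_literals_rejected(self):
        with pytest.raises(ValueError, match="no literal characters"):
            ProblemAreaDefinition("bad", patterns=["%"])

    def test_needs_pattern_or_include_code(self):
        with pytest.raises(ValueError, match="at least one pattern"):
            ProblemAreaDefinition("empty")

    def test_invalid_appropriate_code_rejected(self):
        with pytest.raises(ValueError, match="invalid code"):
            ProblemAreaDefinition("bad", patterns=["%x%"], appropriate_codes={"Q1"})

    def test_shipped_defaults_load(self):
        from icpc_audit.refdata import default_problem_areas

        areas = default_problem_areas()
        assert {a.name for a in areas} == {
            "pneumonia_lower_respiratory", "diabetes", "tonsillitis", "anaemia",
        }


class TestMatchArea:
    def test_selects_by_pattern_or_included_code(self, toy_register):
        area = ProblemAreaDefinition(
            "pneumonia", patterns=["%pneumoni%"], include_codes={"R81"}
        )
        events = [
            _ev("R81", "Lungebetennelse"),      # selected via include_codes
            _ev("D01", "Bakteriell pneumoni"),  # selected via pattern
            _ev("D01", "Akutt abdomen"),        # neither
        ]
        assert match_area(events, area) == events[:2]


class TestAreaPhaseSummary:
    AREA = ProblemAreaDefinition(
        "pneumonia", patterns=["%pneumoni%"], appropriate_codes={"R81"}
    )

    def test_forced_arithmetic_across_sites(self, toy_register):
        # per-site appropriate counts [2, 4, 9] in one phase
        events = []
        for site, k in [("s1", 2), ("s2", 4), ("s3", 9)]:
            events += [_ev("R81", "Pneumoni", site=site) for _ in range(k)]
        stats = area_phase_summary(events, self.AREA, toy_register)[Phase.TRANSITION]
        assert stats.appropriate.median == 4
        assert stats.appropriate.mean == 5
        assert (stats.appropriate.range_lo, stats.appropriate.range_hi) == (2, 9)
        assert stats.appropriate.sd == pytest.approx(math.sqrt(13), abs=1e-9)
        assert stats.appropriate.se == pytest.approx(math.sqrt(13) / math.sqrt(3), abs=1e-9)

    def test_all_appropriate_gives_zero_inappropriate_pct(self, toy_register):
        events = [_ev("R81", "Pneumoni") for _ in range(5)]
        stats = area_phase_summary(events, self.AREA, toy_register)[Phase.TRANSITION]
        assert stats.pct_inappropriate == 0.0
        assert stats.pct_appropriate == 100.0

    def test_missing_and_invalid_codes_join_total_only(self, toy_register):
        events = [
            _ev("R81", "Pneumoni"),       # appropriate
            _ev("D01", "Pneumoni"),       # valid register code, wrong area -> inappropriate
            _ev("", "Pneumoni"),          # missing -> neither
            _ev("Z99", "Pneumoni"),       # invalid -> neither
        ]
        stats = area_phase_summary(events, self.AREA, toy_register)[Phase.TRANSITION]
        assert stats.n_total == 4
        assert stats.n_appropriate == 1
        assert stats.n_inappropriate == 1
        assert stats.n_appropriate + stats.n_inappropriate < stats.n_total
        assert stats.pct_appropriate + stats.pct_inappropriate < 100.0

    def test_phase_split_and_empty_phase_omitted(self, toy_register):
        events = [_ev("R81", "Pneumoni", d=date(2003, 1, 1))]
        stats = area_phase_summary(events, self.AREA, toy_register)
        assert set(stats) == {Phase.REGULAR}
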