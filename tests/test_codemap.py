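"""Code normalization, prefix matching and backward coding."""

import math

import pytest

from promsagree import (
    CodeMap,
    LookbackSpec,
    backward_code,
    evaluate_four_char,
    find_unexplained_reporters,
    match_code,
    normalize_code,
    screen_three_char,
)
from promsagree.codemap import PROVENANCE_BACKWARD, audit_to_frame
from promsagree.exceptions import (
    CodeValidationError,
    ConfigurationError,
    EvaluationError,
    UnknownConditionError,
)
from .conftest import make_admissions, make_cohort


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("e11.9", "E119"),
        ("I10", "I10"),
        (" j45 ", "J45"),
        ("E11.90", "E119"),  # truncated to the 4-character subcategory
    ],
)
def test_normalize(raw, expected):
    assert normalize_code(raw) == expected


@pytest.mark.parametrize("raw", ["10X", "", "EE1", "1", "E1"])
def test_normalize_rejects_malformed(raw):
    with pytest.raises(CodeValidationError):
        normalize_code(raw)


class TestMatching:
    @pytest.fixture
    def toy(self):
        cmap = CodeMap()
        cmap.add_code("diabetes", "E11")
        cmap.add_code("diabetes", "E139")
        return cmap

    def test_three_char_covers_children(self, toy):
        assert match_code(toy, "diabetes", "E119")
        assert match_code(toy, "diabetes", "E11")

    def test_four_char_does_not_cover_siblings(self, toy):
        assert match_code(toy, "diabetes", "E139")
        assert not match_code(toy, "diabetes", "E130")
        assert not match_code(toy, "diabetes", "E13")

    def test_unknown_condition(self, toy):
        with pytest.raises(UnknownConditionError):
            match_code(toy, "stroke", "I60")

    def test_matches_brute_force_child_enumeration(self):
        """Prefix semantics equal full enumeration of every four-character
        child over a mixed-length toy map."""
        cmap = CodeMap()
        members = ["I20", "I25", "J45", "E10", "E119", "N18", "C50", "K70", "G35", "F32"]
        for m in members:
            cmap.add_code("x", m)
        expanded = set(members)
        for m in members:
            if len(m) == 3:
                expanded.update(f"{m}{ch}" for ch in "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        for letter in "IJENCKGF":
            for num in range(100):
                for suffix in ["", "0", "1", "9", "X"]:
                    code = f"{letter}{num:02d}{suffix}"
                    assert match_code(cmap, "x", code) == (code in expanded or code in members)


def _bc_fixture(n_reporters=100, n_nonreporters=100, planted=()):
    """Cohort + admissions where condition 'diabetes' has the given planted
    (code, reporter_fraction, nonreporter_fraction) prevalences on the index
    admission. Carrier sets of different planted codes are staggered so they
    only partially overlap; fractions should be exactly representable at the
    chosen group sizes."""
    rows_c, rows_a = [], []
    k = 0
    for group, n, reports in (("r", n_reporters, True), ("n", n_nonreporters, False)):
        for i in range(n):
            pid = f"{group}{i:04d}"
            link = f"A{k:05d}"
            codes = []
            for j, (code, frac_rep, frac_non) in enumerate(planted):
                frac = frac_rep if reports else frac_non
                if (i + 37 * j) % n < round(frac * n):
                    codes.append(code)
            rows_c.append((pid, link, 1000, {"diabetes"} if reports else set()))
            rows_a.append((link, pid, 1000, 1, codes))
            k += 1
    return make_cohort(rows_c), make_admissions(rows_a)


class TestUnexplainedReporters:
    def test_mapped_code_explains(self):
        cmap = CodeMap()
        cmap.add_code("diabetes", "E11")
        cohort = make_cohort(
            [("p1", "A1", 100, {"diabetes"}), ("p2", "A2", 100, {"diabetes"}), ("p3", "A3", 100, set())]
        )
        admissions = make_admissions(
            [("A1", "p1", 100, 1, ["E119"]), ("A2", "p2", 100, 1, ["I10"]), ("A3", "p3", 100, 1, ["E119"])]
        )
        out = find_unexplained_reporters(cohort, admissions, cmap, "diabetes", LookbackSpec())
        assert out == {"p2"}

    def test_matches_rowwise_brute_force(self, small_fixture, default_codemap):
        from promsagree import build_cohort
        from promsagree.flags import window_code_table

        _, q, a, _ = small_fixture
        cohort, adm, _ = build_cohort(q, a)
        spec = LookbackSpec(365)
        out = find_unexplained_reporters(cohort, adm, default_codemap, "diabetes", spec)
        codes = window_code_table(cohort, adm, spec)
        expected = set()
        for _, row in cohort.iterrows():
            if not row["diabetes"]:
                continue
            mine = codes.loc[codes["patient_id"] == row["patient_id"], "code"]
            if not any(default_codemap.match("diabetes", c) for c in mine):
                expected.add(row["patient_id"])
        assert out == expected


class TestScreening:
    def test_planted_frequencies(self):
        """Categories at 0.5%, 1.5% and 3% of 200 reporters: only the latter
        two pass the strictly-greater-than-1% screen."""
        cohort, admissions = _bc_fixture(
            n_reporters=200,
            n_nonreporters=50,
            planted=[("E650", 0.005, 0.0), ("E700", 0.015, 0.0), ("E750", 0.03, 0.0)],
        )
        cmap = CodeMap()
        cmap.add_condition("diabetes", chapters={"E"})
        out = screen_three_char(cohort, admissions, cmap, "diabetes")
        assert out == ["E70", "E75"]

    def test_exactly_one_percent_not_returned(self):
        cohort, admissions = _bc_fixture(n_reporters=200, planted=[("E700", 0.01, 0.0)])
        cmap = CodeMap()
        cmap.add_condition("diabetes", chapters={"E"})
        assert screen_three_char(cohort, admissions, cmap, "diabetes") == []

    def test_chapter_allowlist_and_mapped_categories_excluded(self):
        cohort, admissions = _bc_fixture(
            planted=[("J450", 0.5, 0.0), ("E700", 0.5, 0.0), ("E100", 0.5, 0.0)]
        )
        cmap = CodeMap()
        cmap.add_condition("diabetes", chapters={"E"})
        cmap.add_code("diabetes", "E10")  # already fully mapped at 3-char level
        assert screen_three_char(cohort, admissions, cmap, "diabetes") == ["E70"]

    def test_empty_chapter_set_rejected(self):
        cohort, admissions = _bc_fixture(planted=[("E700", 0.5, 0.0)])
        cmap = CodeMap()
        cmap.add_condition("diabetes", chapters=set())
        with pytest.raises(ConfigurationError):
            screen_three_char(cohort, admissions, cmap, "diabetes")


class TestFourChar:
    def _eval(self, planted, **kwargs):
        cohort, admissions = _bc_fixture(planted=planted)
        cmap = CodeMap()
        cmap.add_condition("diabetes", chapters={"E"})
        return evaluate_four_char(cohort, admissions, cmap, "diabetes", "E70", **kwargs)

    def test_ratio_four_accepted(self):
        (cand,) = self._eval([("E700", 0.04, 0.01)])
        assert cand.prevalence_ratio == pytest.approx(4.0)
        assert cand.accepted

    def test_ratio_one_rejected(self):
        (cand,) = self._eval([("E700", 0.02, 0.02)])
        assert cand.prevalence_ratio == pytest.approx(1.0)
        assert not cand.accepted

    def test_ratio_exactly_two_accepted(self):
        (cand,) = self._eval([("E700", 0.02, 0.01)])
        assert cand.prevalence_ratio == pytest.approx(2.0)
        assert cand.accepted

    def test_zero_nonreporter_prevalence_is_infinite_and_accepted(self):
        (cand,) = self._eval([("E700", 0.04, 0.0)])
        assert cand.prevalence_ratio == math.inf
        assert cand.accepted

    def test_threshold_sharpness(self):
        """Perturbing counts across the ratio-2 boundary flips acceptance."""
        (just_below,) = self._eval([("E700", 0.19, 0.10)])
        (just_above,) = self._eval([("E700", 0.21, 0.10)])
        assert not just_below.accepted and just_above.accepted

    def test_zero_reporters_is_an_error(self):
        cohort, admissions = _bc_fixture(planted=[("E700", 0.1, 0.1)])
        cohort["diabetes"] = False
        cmap = CodeMap()
        cmap.add_condition("diabetes", chapters={"E"})
        with pytest.raises(EvaluationError):
            evaluate_four_char(cohort, admissions, cmap, "diabetes", "E70")


class TestBackwardCode:
    def test_no_unexplained_reporters_is_a_no_op(self):
        cmap = CodeMap()
        cmap.add_condition("diabetes", chapters={"E"})
        cmap.add_code("diabetes", "E11")
        cohort = make_cohort([("p1", "A1", 100, {"diabetes"}), ("p2", "A2", 100, set())])
        admissions = make_admissions(
            [("A1", "p1", 100, 1, ["E119"]), ("A2", "p2", 100, 1, [])]
        )
        out, audit = backward_code(cohort, admissions, cmap, "diabetes")
        assert out.code_set("diabetes") == cmap.code_set("diabetes")
        assert audit == []

    def test_planted_overrepresented_code_added(self):
        """A code at 6% reporter vs 1% non-reporter prevalence is added with
        backward-coded provenance; a balanced code is not."""
        cohort, admissions = _bc_fixture(
            planted=[("E700", 0.06, 0.01), ("E705", 0.05, 0.05)]
        )
        cmap = CodeMap()
        cmap.add_condition("diabetes", chapters={"E"})
        out, audit = backward_code(cohort, admissions, cmap, "diabetes")
        assert "E700" in out.code_set("diabetes")
        assert "E705" not in out.code_set("diabetes")
        assert out.codes("diabetes")["E700"].provenance == PROVENANCE_BACKWARD

    def test_monotone_and_audit_complete(self):
        cohort, admissions = _bc_fixture(
            planted=[("E700", 0.06, 0.01), ("E701", 0.02, 0.02), ("E702", 0.03, 0.0)]
        )
        cmap = CodeMap()
        cmap.add_condition("diabetes", chapters={"E"})
        cmap.add_code("diabetes", "E11")
        out, audit = backward_code(cohort, admissions, cmap, "diabetes")
        assert out.code_set("diabetes") >= cmap.code_set("diabetes")
        codes = [c.code for c in audit]
        assert codes == sorted(codes) and len(set(codes)) == len(codes)
        assert {"E700", "E701", "E702"} == set(codes)
        frame = audit_to_frame(audit)
        assert list(frame["accepted"]) == [True, False, True]

    def test_other_conditions_untouched(self):
        cohort, admissions = _bc_fixture(planted=[("E700", 0.06, 0.01)])
        cohort["stroke"] = False
        cmap = CodeMap()
        cmap.add_condition("diabetes", chapters={"E"})
        cmap.add_code("stroke", "I60")
        out, _ = backward_code(cohort, admissions, cmap, "diabetes")
        assert out.code_set("stroke") == frozenset({"I60"})


def test_json_round_trip(tmp_path, default_codemap):
    path = tmp_path / "map.json"
    default_codemap.to_json(path)
    loaded = CodeMap.from_json(path)
    assert loaded.to_dict() == default_codemap.to_dict()
    assert loaded.checksum() == default_codemap.checksum()
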