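"""Censoring rules, detection summaries and group comparisons."""

import math

import numpy as np
import pytest
from scipy import stats

from bmrisk.data import (
    CYA,
    MEL,
    AnalyteSpec,
    CensoringRule,
    ConcentrationRecord,
    InfantRecord,
    ValidationError,
    FormatError,
    age_group_of,
    apply_censoring_rule,
    compare_groups,
    detection_ci,
    load_cohort,
    load_concentrations,
    summarize,
    tdi_exceedance_test,
    write_cohort,
    write_concentrations,
)

from .conftest import make_records


class TestTypes:
    def test_analyte_spec_invariants(self):
        with pytest.raises(ValidationError):
            AnalyteSpec("X", tdi=-1, lod=90, loq=270)
        with pytest.raises(ValidationError):
            AnalyteSpec("X", tdi=100, lod=300, loq=270)

    def test_record_rejects_negative_and_uncensored_absent(self):
        with pytest.raises(ValidationError):
            ConcentrationRecord("S1", "MEL", -5.0, False)
        with pytest.raises(ValidationError):
            ConcentrationRecord("S1", "MEL", None, False)

    @pytest.mark.parametrize(
        "days,group",
        [(15, "0-2m"), (60, "0-2m"), (61, "2-4m"), (120, "2-4m"), (121, "4-6m"), (180, "4-6m")],
    )
    def test_age_group_cutoffs(self, days, group):
        assert age_group_of(days) == group

    def test_infant_rejects_inconsistent_group(self):
        with pytest.raises(ValidationError):
            InfantRecord("I1", age_days=30, body_weight=4.0, fir=150.0, age_group="4-6m")


class TestLoading:
    def test_round_trip_preserves_censoring(self, tmp_path):
        records = make_records([670.0, None, 1610.0, 50.0])
        path = tmp_path / "conc.csv"
        write_concentrations(records, path)
        loaded = load_concentrations(path, {"MEL": MEL})
        assert [r.censored for r in loaded] == [False, True, False, True]
        assert loaded[0].value == 670.0
        assert loaded[1].value is None
        # a reported value below the LOD is censored but keeps its value
        assert loaded[3].value == 50.0 and loaded[3].censored

    def test_unknown_analyte_and_negative_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,analyte,value\nS1,ZZZ,5\n")
        with pytest.raises(ValidationError):
            load_concentrations(p, {"MEL": MEL})
        p.write_text("sample_id,analyte,value\nS1,MEL,-5\n")
        with pytest.raises(ValidationError):
            load_concentrations(p, {"MEL": MEL})

    def test_missing_columns_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,conc\nS1,5\n")
        with pytest.raises(FormatError):
            load_concentrations(p, {"MEL": MEL})

    def test_cohort_round_trip_and_default_fir(self, tmp_path):
        infants = [
            InfantRecord("I1", 30, 4.2, 150.0, sample_id="S001"),
            InfantRecord("I2", 100, 6.1, 120.0),
        ]
        p = tmp_path / "cohort.csv"
        write_cohort(infants, p)
        loaded = load_cohort(p)
        assert loaded[0].sample_id == "S001" and loaded[1].sample_id is None
        assert loaded[0].age_group == "0-2m" and loaded[1].age_group == "2-4m"
        p.write_text("infant_id,age_days,body_weight_kg\nI1,30,4.2\n")
        assert load_cohort(p, default_fir=99.0)[0].fir == 99.0


class TestCensoringRules:
    RECORDS = make_records([670.0, None, 1610.0])

    @pytest.mark.parametrize(
        "rule,expected",
        [
            ("exclude", [670.0, 1610.0]),
            ("half_lod", [670.0, 45.0, 1610.0]),
            ("zero", [670.0, 0.0, 1610.0]),
            ("lod", [670.0, 90.0, 1610.0]),
        ],
    )
    def test_rules(self, rule, expected):
        assert apply_censoring_rule(self.RECORDS, rule, MEL).tolist() == expected

    def test_mixed_analytes_rejected(self):
        mixed = make_records([670.0]) + [
            ConcentrationRecord("S9", "CYA", 500.0, False)
        ]
        with pytest.raises(ValidationError):
            apply_censoring_rule(mixed, "exclude", MEL)

    def test_rule_mean_monotonicity(self, fixture_bundle):
        """exclude >= lod >= half_lod >= zero for any censored dataset."""
        for analyte, spec in (("MEL", MEL), ("CYA", CYA)):
            records = fixture_bundle.concentrations[analyte].records
            means = {
                r: apply_censoring_rule(records, r, spec).mean()
                for r in CensoringRule
            }
            assert (
                means[CensoringRule.EXCLUDE]
                >= means[CensoringRule.LOD]
                >= means[CensoringRule.HALF_LOD]
                >= means[CensoringRule.ZERO]
            )


class TestSummarize:
    def test_detection_pct_100_minus_23(self):
        records = make_records([None] * 23 + [500.0] * 77)
        s = summarize(records)
        assert s.detection_pct == 77.0
        assert s.n_below_lod == 23
        lo, hi = s.detection_ci
        assert lo < 77.0 < hi

    def test_detection_ci_matches_clopper_pearson(self):
        lo, hi = detection_ci(84, 100)
        ref = stats.binomtest(84, 100).proportion_ci(method="exact")
        assert lo == pytest.approx(100 * ref.low)
        assert hi == pytest.approx(100 * ref.high)

    def test_single_record_degenerate(self):
        s = summarize(make_records([500.0]))
        assert s.mean == s.min == s.max == 500.0
        assert s.sd == 0.0

    def test_sd_is_sample_sd(self):
        s = summarize(make_records([100.0, 200.0, 300.0]))
        assert s.sd == pytest.approx(np.std([100, 200, 300], ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize([])


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        c = compare_groups([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert c.test_name == "mann-whitney-u"
        assert c.p_value >= 0.99

    def test_complete_separation_exact_p(self):
        # all C(6,3)=20 rank splits: the observed extreme split has
        # one-sided probability 1/20, two-sided p = 0.1
        c = compare_groups([1, 2, 3, 100, 101, 102], ["a"] * 3 + ["b"] * 3)
        assert c.p_value == pytest.approx(0.1)

    def test_three_groups_dispatches_kruskal(self):
        c = compare_groups([1, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"])
        assert c.test_name == "kruskal-wallis"

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1.0, 2.0], ["a", "a"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=12)
        labels = ["a"] * 6 + ["b"] * 6
        p1 = compare_groups(x, labels).p_value
        p2 = compare_groups(np.exp(3 * x), labels).p_value
        assert p1 == pytest.approx(p2)


class TestTdiExceedance:
    def test_counts(self):
        c = tdi_exceedance_test([4000.0, 1000.0], MEL)
        assert c.counts == {"exceeding": 1, "not_exceeding": 1, "n": 2}
        assert math.isnan(c.p_value)  # degenerate reference -> count only

    def test_all_below(self):
        c = tdi_exceedance_test([10.0, 20.0, 30.0], MEL)
        assert c.counts["exceeding"] == 0

    def test_reference_proportion_chi_square(self):
        c = tdi_exceedance_test([4000.0] * 5 + [100.0] * 5, MEL, reference_pct=50.0)
        ref = stats.chisquare([5, 5], f_exp=[5, 5])
        assert c.statistic == pytest.approx(ref.statistic)
        assert c.p_value == pytest.approx(ref.pvalue)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            tdi_exceedance_test([], MEL)
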