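"""Reference-standard classification, risk factors, and eligibility."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipscreen import (
    Ethnicity,
    GlucoseTriplet,
    GlycemicStatus,
    HistoryStatus,
    MissingGlucoseError,
    RiskProfile,
    RiskStatusUnknownError,
    check_eligibility,
    classify_reference,
    risk_profile,
    round_reported,
)

from conftest import make_record
from _oracles import reference_status_oracle


class TestClassifyReference:
    @pytest.mark.parametrize(
        "triplet, expected",
        [
            # cohort-mean triplet, all sub-threshold
            ((4.38, 6.76, 5.96), GlycemicStatus.NORMAL),
            # lower FPG bound of the GDM band
            ((5.1, 6.0, 6.0), GlycemicStatus.GDM),
            # overt-diabetes fasting threshold
            ((7.0, 9.0, 10.0), GlycemicStatus.DIP),
            # 1 h criterion alone
            ((4.5, 10.0, 6.0), GlycemicStatus.GDM),
            # 2 h overt-diabetes threshold
            ((4.5, 9.0, 11.1), GlycemicStatus.DIP),
            # 1 h glucose has no overt-diabetes criterion
            ((4.5, 15.0, 6.0), GlycemicStatus.GDM),
            # 2 h GDM band lower edge
            ((4.5, 6.0, 8.5), GlycemicStatus.GDM),
            # bands abut: 2 h 11.0 is GDM-range, 11.1 is DIP-range
            ((4.5, 6.0, 11.0), GlycemicStatus.GDM),
        ],
    )
    def test_threshold_examples(self, triplet, expected):
        assert classify_reference(GlucoseTriplet(*triplet)) is expected

    @pytest.mark.parametrize(
        "fpg, expected",
        [
            (5.06, GlycemicStatus.GDM),  # rounds up to 5.1
            (5.04, GlycemicStatus.NORMAL),  # rounds down to 5.0
            (6.95, GlycemicStatus.DIP),  # rounds to 7.0: band edges tile
        ],
    )
    def test_one_decimal_rounding_convention(self, fpg, expected):
        assert classify_reference(GlucoseTriplet(fpg, 6.0, 6.0)) is expected

    @pytest.mark.parametrize("missing", ["fpg", "pg1h", "pg2h"])
    def test_missing_value_rejected(self, missing):
        values = {"fpg": 4.5, "pg1h": 6.0, "pg2h": 6.0, missing: None}
        with pytest.raises(MissingGlucoseError):
            classify_reference(GlucoseTriplet(**values))

    def test_grid_against_independent_truth_table(self):
        """Exhaustive grid straddling every threshold edge: the
        classification agrees with a hand-coded truth table and assigns
        exactly one status per triplet."""
        fpgs = [4.0, 4.4, 4.6, 4.7, 5.0, 5.1, 6.9, 7.0, 8.0]
        pg1hs = [6.0, 9.9, 10.0, 12.0]
        pg2hs = [6.0, 8.4, 8.5, 11.0, 11.1]
        for f, o, t in itertools.product(fpgs, pg1hs, pg2hs):
            got = classify_reference(GlucoseTriplet(f, o, t))
            assert got.value == reference_status_oracle(f, o, t), (f, o, t)

    @given(
        fpg=st.floats(1.1, 12.0),
        pg1h=st.floats(1.1, 20.0),
        pg2h=st.floats(1.1, 20.0),
        bumps=st.tuples(st.floats(0, 5), st.floats(0, 5), st.floats(0, 5)),
    )
    @settings(max_examples=300, derandomize=True)
    def test_monotone_in_each_glucose_value(self, fpg, pg1h, pg2h, bumps):
        """Raising glucose can only move the status toward more severe."""
        severity = {GlycemicStatus.NORMAL: 0, GlycemicStatus.GDM: 1, GlycemicStatus.DIP: 2}
        base = severity[classify_reference(GlucoseTriplet(fpg, pg1h, pg2h))]
        raised = classify_reference(
            GlucoseTriplet(fpg + bumps[0], pg1h + bumps[1], pg2h + bumps[2])
        )
        assert severity[raised] >= base


class TestRoundReported:
    @pytest.mark.parametrize(
        "raw, expected", [(4.65, 4.7), (4.649, 4.6), (5.05, 5.1), (4.0, 4.0)]
    )
    def test_half_up_at_one_decimal(self, raw, expected):
        assert round_reported(raw) == pytest.approx(expected)


class TestRiskProfile:
    def test_age_forty_alone_is_high_risk(self):
        assert risk_profile(make_record(age=40.0)).high_risk

    def test_no_factor_present(self):
        r = risk_profile(make_record(age=30, bmi=24, ethnicity=Ethnicity.EUROPEAN))
        assert not r.high_risk

    @pytest.mark.parametrize(
        "ethnicity, high",
        [
            (Ethnicity.NORTH_AFRICAN, True),
            (Ethnicity.INDIAN_PAKISTANI_SRILANKAN, True),
            (Ethnicity.ASIAN, True),
            (Ethnicity.EUROPEAN, False),
            (Ethnicity.SUBSAHARAN_AFRICAN, False),
            (Ethnicity.CARIBBEAN, False),
            (Ethnicity.OTHER, False),
        ],
    )
    def test_high_risk_ethnicities(self, ethnicity, high):
        assert risk_profile(make_record(ethnicity=ethnicity)).high_risk is high

    def test_obesity_is_strictly_above_thirty(self):
        assert not risk_profile(make_record(bmi=30.0)).obesity
        assert risk_profile(make_record(bmi=30.1)).obesity

    def test_first_child_counts_as_no_history(self):
        r = risk_profile(make_record(history_hip=HistoryStatus.FIRST_CHILD))
        assert not r.previous_hip

    def test_missing_attribute_means_risk_unknown(self):
        record = make_record(family_history=None)
        with pytest.raises(RiskStatusUnknownError, match="family_history"):
            risk_profile(record)

    def test_fetal_death_mapping_configurable(self):
        record = make_record(history_fetal_death=HistoryStatus.YES)
        assert risk_profile(record).high_risk
        off = risk_profile(record, fetal_death_as_neonatal_death=False)
        assert not off.high_risk

    def test_high_risk_monotone_in_flags(self):
        """high_risk is the OR of its components: false with none set, true
        whenever any single flag is set."""
        names = [
            "previous_hip",
            "previous_neonatal_death",
            "age_ge_40",
            "family_history",
            "obesity",
            "previous_macrosomia",
            "high_risk_ethnicity",
        ]
        base = {n: False for n in names}
        assert not RiskProfile(**base).high_risk
        for n in names:
            assert RiskProfile(**{**base, n: True}).high_risk
        assert RiskProfile(**base, extra_flags=(True,)).high_risk


class TestEligibility:
    def test_conforming_record_is_eligible(self):
        verdict = check_eligibility(make_record())
        assert verdict.eligible and verdict.reasons == ()

    def test_early_hip_excludes(self):
        verdict = check_eligibility(make_record(early_fpg=5.1))
        assert not verdict.eligible
        assert any("early HIP" in r for r in verdict.reasons)

    def test_twin_pregnancy_excludes(self):
        verdict = check_eligibility(make_record(singleton=False))
        assert not verdict.eligible
        assert any("singleton" in r for r in verdict.reasons)

    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            ({"ga": 31.0}, "gestational age"),
            ({"ga": 21.9}, "gestational age"),
            ({"age": 17.0}, "age"),
            ({"age": 51.0}, "age"),
            ({"prior_diabetes": True}, "diabetes"),
            ({"prior_bariatric_surgery": True}, "bariatric"),
            ({"ethnicity": None}, "risk-factor status"),
        ],
    )
    def test_each_exclusion_reason_is_reported(self, kwargs, fragment):
        verdict = check_eligibility(make_record(**kwargs))
        assert not verdict.eligible
        assert any(fragment in r for r in verdict.reasons)

    def test_multiple_failures_all_listed(self):
        verdict = check_eligibility(make_record(ga=31.0, singleton=False, early_fpg=5.2))
        assert len(verdict.reasons) == 3
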