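"""The seven screening options: decision rules, information discipline,
case classification, and brute-force oracle equivalence."""

from __future__ import annotations

import itertools

import pytest

from hipscreen import (
    ALL_OPTIONS,
    CaseClass,
    GlycemicStatus,
    HistoryStatus,
    MissingGlucoseError,
    OptionId,
    ScreeningDecision,
    apply_option,
    classify_case,
    classify_reference,
    ogtt_required,
    risk_profile,
)
from hipscreen.options import (
    FPG_DIRECT,
    HISTORY_SHORTCUT,
    LOW_RISK_UNSCREENED,
    OGTT_RESULT,
    RULE_OUT_LOW_FPG,
)

from conftest import make_record
from _oracles import option_oracle


def decide(option, record):
    return apply_option(option, record, risk_profile(record))


class TestDecisionExamples:
    def test_history_shortcut_fires_before_glucose(self):
        record = make_record(history_hip=HistoryStatus.YES, fpg=4.2)
        d = decide(OptionId.OPT2, record)
        assert d.positive and d.label is GlycemicStatus.GDM
        assert not d.ogtt_performed
        assert d.rationale == HISTORY_SHORTCUT
        assert d.glucose_reads == frozenset()  # no glucose looked at

    def test_opt2_low_fpg_rules_out(self):
        d = decide(OptionId.OPT2, make_record(fpg=4.5))
        assert not d.positive and not d.ogtt_performed
        assert d.rationale == RULE_OUT_LOW_FPG

    def test_opt2_band_triggers_ogtt_and_1h_criterion_diagnoses(self):
        d = decide(OptionId.OPT2, make_record(fpg=4.8, pg1h=10.5, pg2h=7.0))
        assert d.ogtt_performed and d.positive and d.label is GlycemicStatus.GDM
        assert d.rationale == OGTT_RESULT

    def test_opt3_never_reads_post_load_values(self):
        d = decide(OptionId.OPT3, make_record(fpg=5.3, pg1h=12.0, pg2h=12.0))
        assert d.positive and not d.ogtt_performed
        assert d.glucose_reads == {"fpg"}

    def test_opt3_works_on_fasting_only_record(self):
        d = decide(OptionId.OPT3, make_record(fpg=5.3, pg1h=None, pg2h=None))
        assert d.positive and d.label is GlycemicStatus.GDM

    def test_selective_low_risk_is_unscreened_negative(self):
        d = decide(OptionId.OPT1_SEL, make_record(fpg=5.5))
        assert not d.positive and not d.ogtt_performed
        assert d.rationale == LOW_RISK_UNSCREENED

    def test_fpg_only_diagnosis_in_overt_range_is_dip(self):
        for option in (OptionId.OPT1, OptionId.OPT3):
            d = decide(option, make_record(fpg=7.2))
            assert d.positive and d.label is GlycemicStatus.DIP
            assert d.rationale == FPG_DIRECT and not d.ogtt_performed

    def test_sel_performs_full_ogtt_on_high_risk(self):
        record = make_record(age=41.0, fpg=4.2, pg1h=6.0, pg2h=6.0)
        d = decide(OptionId.SEL, record)
        assert d.ogtt_performed and not d.positive
        assert d.glucose_reads == {"fpg", "pg1h", "pg2h"}

    def test_band_edges_after_rounding(self):
        # 4.65 rounds to 4.7 (in band); 5.04 rounds to 5.0 (in band);
        # 5.06 rounds to 5.1 (direct rule-in)
        assert decide(OptionId.OPT1, make_record(fpg=4.65)).ogtt_performed
        assert decide(OptionId.OPT1, make_record(fpg=5.04)).ogtt_performed
        d = decide(OptionId.OPT1, make_record(fpg=5.06))
        assert d.positive and not d.ogtt_performed


class TestErrors:
    def test_missing_fpg_names_the_option(self):
        record = make_record(fpg=None)
        with pytest.raises(MissingGlucoseError, match="option 1"):
            decide(OptionId.OPT1, record)

    def test_missing_post_load_value_when_ogtt_needed(self):
        record = make_record(fpg=4.8, pg1h=None, pg2h=7.0)
        with pytest.raises(MissingGlucoseError, match="option 2"):
            decide(OptionId.OPT2, record)

    def test_positive_decision_requires_label(self):
        with pytest.raises(ValueError):
            ScreeningDecision(
                option=OptionId.OPT1,
                ogtt_performed=False,
                positive=True,
                label=None,
                rationale=FPG_DIRECT,
            )


def _grid_records():
    """Exhaustive decision grid: FPG straddling every band edge x OGTT
    outcome x history x risk."""
    fpgs = [4.0, 4.6, 4.65, 4.7, 4.9, 5.0, 5.04, 5.06, 5.1, 6.9, 7.0, 7.5]
    pg1hs = [6.0, 10.0]
    pg2hs = [6.0, 8.5, 11.1]
    history = [HistoryStatus.FIRST_CHILD, HistoryStatus.NO, HistoryStatus.YES]
    risk_age = [30.0, 41.0]  # low / high risk via the age factor
    for f, o, t, h, a in itertools.product(fpgs, pg1hs, pg2hs, history, risk_age):
        yield make_record(fpg=f, pg1h=o, pg2h=t, history_hip=h, age=a)


class TestOracleEquivalence:
    def test_all_options_match_bruteforce_decision_tree(self):
        """Every option agrees with an independently transcribed nested-
        conditional version of the flow diagram on the exhaustive grid."""
        for record in _grid_records():
            risk = risk_profile(record)
            for option in ALL_OPTIONS:
                d = apply_option(option, record, risk)
                expected = option_oracle(
                    option.value,
                    record.ogtt.fpg,
                    record.ogtt.pg1h,
                    record.ogtt.pg2h,
                    record.history_hip is HistoryStatus.YES,
                    risk.high_risk,
                )
                got = (d.ogtt_performed, d.positive, d.label.value if d.label else None)
                assert got == expected, (option, record.ogtt, record.history_hip)

    def test_ogtt_required_matches_apply_option(self):
        for record in _grid_records():
            risk = risk_profile(record)
            for option in ALL_OPTIONS:
                assert ogtt_required(option, record, risk) == apply_option(
                    option, record, risk
                ).ogtt_performed

    def test_information_discipline_on_grid(self):
        """Post-load values are read iff an OGTT is performed."""
        for record in _grid_records():
            risk = risk_profile(record)
            for option in ALL_OPTIONS:
                d = apply_option(option, record, risk)
                touched_post_load = bool(d.glucose_reads & {"pg1h", "pg2h"})
                assert touched_post_load == d.ogtt_performed


class TestClassifyCase:
    @pytest.mark.parametrize(
        "positive, reference, expected",
        [
            (True, GlycemicStatus.GDM, CaseClass.TP),
            (True, GlycemicStatus.DIP, CaseClass.TP),
            (True, GlycemicStatus.NORMAL, CaseClass.FP),
            (False, GlycemicStatus.DIP, CaseClass.FN),
            (False, GlycemicStatus.GDM, CaseClass.FN),
            (False, GlycemicStatus.NORMAL, CaseClass.TN),
        ],
    )
    def test_four_way_definition(self, positive, reference, expected):
        d = ScreeningDecision(
            option=OptionId.OPT2,
            ogtt_performed=False,
            positive=positive,
            label=GlycemicStatus.GDM if positive else None,
            rationale=HISTORY_SHORTCUT if positive else RULE_OUT_LOW_FPG,
        )
        assert classify_case(d, reference) is expected

    def test_history_shortcut_in_normal_woman_is_false_positive(self):
        record = make_record(history_hip=HistoryStatus.YES, fpg=4.2)
        d = decide(OptionId.OPT2, record)
        assert classify_case(d, classify_reference(record.ogtt)) is CaseClass.FP


class TestCohortInvariants:
    """Structural guarantees that must hold on any cohort."""

    def _positives(self, option, cohort):
        return {
            r.id
            for r in cohort
            if apply_option(option, r, risk_profile(r)).positive
        }

    def test_positive_set_containment(self, cohort5000):
        pos = {o: self._positives(o, cohort5000) for o in ALL_OPTIONS}
        assert pos[OptionId.OPT3] <= pos[OptionId.OPT1] <= pos[OptionId.OPT2]
        for sel, uni in [
            (OptionId.OPT1_SEL, OptionId.OPT1),
            (OptionId.OPT2_SEL, OptionId.OPT2),
            (OptionId.OPT3_SEL, OptionId.OPT3),
        ]:
            assert pos[sel] <= pos[uni]

    def test_case_classes_partition_cohort(self, cohort5000):
        from hipscreen import evaluate_option

        ev = evaluate_option(OptionId.OPT2, cohort5000)
        c = ev.performance.counts
        assert c.tn + c.fp + c.tp + c.fn == len(cohort5000)

    def test_false_positives_only_from_history_shortcut(self, cohort5000):
        """Options without the history shortcut can never produce a false
        positive; under Option 2 every false positive has a history of HIP."""
        for record in cohort5000[:2000]:
            risk = risk_profile(record)
            reference = classify_reference(record.ogtt)
            for option in ALL_OPTIONS:
                d = apply_option(option, record, risk)
                if classify_case(d, reference) is CaseClass.FP:
                    assert option in (OptionId.OPT2, OptionId.OPT2_SEL)
                    assert record.history_hip is HistoryStatus.YES
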