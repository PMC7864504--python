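"""Shared fixtures: a record factory, a small CSV cohort, and one
session-scoped synthetic cohort reused by the heavier end-to-end tests."""

from __future__ import annotations

import pytest

from hipscreen import (
    Ethnicity,
    GlucoseTriplet,
    HistoryStatus,
    OutcomeRecord,
    WomanRecord,
    default_config,
    generate_cohort,
)


def make_record(
    rid: str = "w1",
    fpg: float = 4.4,
    pg1h: float | None = 6.5,
    pg2h: float | None = 6.0,
    ga: float = 26.0,
    age: float = 30.0,
    bmi: float = 24.0,
    early_fpg: float = 4.3,
    history_hip: HistoryStatus = HistoryStatus.NO,
    history_macrosomia: HistoryStatus = HistoryStatus.NO,
    history_fetal_death: HistoryStatus = HistoryStatus.NO,
    family_history: bool = False,
    ethnicity: Ethnicity = Ethnicity.EUROPEAN,
    singleton: bool = True,
    outcomes: OutcomeRecord | None = None,
    **kwargs,
) -> WomanRecord:
    """A fully-specified eligible low-risk woman, overridable per test."""
    return WomanRecord(
        id=rid,
        age_years=age,
        bmi_pre=bmi,
        early_fpg=early_fpg,
        ogtt=GlucoseTriplet(fpg=fpg, pg1h=pg1h, pg2h=pg2h, ga_weeks=ga),
        history_hip=history_hip,
        history_macrosomia=history_macrosomia,
        history_fetal_death=history_fetal_death,
        family_history_diabetes=family_history,
        ethnicity=ethnicity,
        singleton=singleton,
        outcomes=outcomes or OutcomeRecord(),
        **kwargs,
    )


@pytest.fixture(scope="session")
def cohort5000():
    """Default-configuration synthetic cohort, n=5000, fixed seed."""
    return list(generate_cohort(default_config(n=5000, seed=20210121)).records)


@pytest.fixture
def cohort_csv(tmp_path):
    """A well-formed 4-row cohort CSV on disk."""
    from hipscreen import write_cohort

    records = [
        make_record("a", fpg=4.4),
        make_record("b", fpg=5.5, pg1h=9.0, pg2h=8.0),
        make_record("c", fpg=4.8, pg1h=10.5, pg2h=7.0, history_hip=HistoryStatus.YES),
        make_record("d", fpg=4.2, ethnicity=Ethnicity.ASIAN),
    ]
    path = tmp_path / "cohort.csv"
    write_cohort(records, path)
    return path
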