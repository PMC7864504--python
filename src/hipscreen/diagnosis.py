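"""Reference-standard glycemic classification, risk factors, and eligibility.

The reference standard is the 75 g OGTT read with the IADPSG/WHO thresholds:
GDM when FPG is 5.1-6.9 mmol/L and/or 1 h plasma glucose >= 10.0 and/or 2 h
plasma glucose 8.5-11.0; DIP (diabetes in pregnancy) when FPG >= 7.0 and/or
2 h >= 11.1.  DIP takes precedence.  There is no 1 h criterion for DIP.

All threshold comparisons are made on values rounded to one decimal, the
precision at which plasma glucose is clinically reported.  After rounding the
GDM and DIP fasting bands tile the line with no gap: [5.1, 7.0) is GDM-range,
>= 7.0 is DIP-range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .model import (
    Ethnicity,
    GlucoseTriplet,
    GlycemicStatus,
    HistoryStatus,
    MissingGlucoseError,
    RiskProfile,
    RiskStatusUnknownError,
    WomanRecord,
)


@dataclass(frozen=True, slots=True)
class Thresholds:
    """Diagnostic and risk-factor thresholds (mmol/L, kg/m2, years)."""

    fpg_gdm: float = 5.1
    fpg_dip: float = 7.0
    pg1h_gdm: float = 10.0
    pg2h_gdm: float = 8.5
    pg2h_dip: float = 11.1
    bmi_obesity: float = 30.0
    age_risk: float = 40.0
    #: lower edge of the FPG triage band that triggers an OGTT
    fpg_band_low: float = 4.7
    #: eligibility: gestational-age window for the OGTT, maternal age window,
    #: and the early-pregnancy FPG cutoff below which no early HIP was found
    ga_min: float = 22.0
    ga_max: float = 30.0
    age_min: float = 18.0
    age_max: float = 50.0
    early_fpg_cutoff: float = 5.1


DEFAULT_THRESHOLDS = Thresholds()

#: Ethnic groups at high risk of hyperglycemia in pregnancy under the
#: Australian-New Zealand risk-factor rule as applied to this cohort.
HIGH_RISK_ETHNICITIES = frozenset(
    {
        Ethnicity.NORTH_AFRICAN,
        Ethnicity.INDIAN_PAKISTANI_SRILANKAN,
        Ethnicity.ASIAN,
    }
)


def round_reported(value: float) -> float:
    """Round a glucose value to one decimal, half away from zero.

    Clinical reports carry plasma glucose to 0.1 mmol/L; every threshold
    comparison in this package happens after this rounding, so e.g. a raw
    5.06 mmol/L fasting value meets the 5.1 criterion while 5.04 does not.
    """
    return math.floor(value * 10.0 + 0.5) / 10.0


def classify_reference(
    ogtt: GlucoseTriplet, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> GlycemicStatus:
    """Classify a complete OGTT triplet as NORMAL, GDM or DIP.

    Raises
    ------
    MissingGlucoseError
        If any of the three glucose values is absent; the reference standard
        requires a full OGTT.
    """
    if ogtt.fpg is None or ogtt.pg1h is None or ogtt.pg2h is None:
        raise MissingGlucoseError(
            "reference-standard classification requires fasting, 1 h and 2 h values"
        )
    fpg = round_reported(ogtt.fpg)
    pg1h = round_reported(ogtt.pg1h)
    pg2h = round_reported(ogtt.pg2h)
    if fpg >= thresholds.fpg_dip or pg2h >= thresholds.pg2h_dip:
        return GlycemicStatus.DIP
    if fpg >= thresholds.fpg_gdm or pg1h >= thresholds.pg1h_gdm or pg2h >= thresholds.pg2h_gdm:
        return GlycemicStatus.GDM
    return GlycemicStatus.NORMAL


def is_hip(status: GlycemicStatus) -> bool:
    """Hyperglycemia in pregnancy means any non-normal reference status."""
    return status is not GlycemicStatus.NORMAL


def _history_yes(status: Optional[HistoryStatus]) -> bool:
    # FIRST_CHILD counts as "no history" for risk purposes.
    return status is HistoryStatus.YES


def risk_profile(
    record: WomanRecord,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    *,
    fetal_death_as_neonatal_death: bool = True,
    extra_flags: tuple[bool, ...] = (),
) -> RiskProfile:
    """Compute the Australian-New Zealand risk-factor profile for one woman.

    The factors are: previous hyperglycemia in pregnancy, previous
    neonatal death, maternal age >= 40 years, family history of diabetes,
    pre-pregnancy obesity (BMI strictly > 30 kg/m2), a previous macrosomic
    baby, and high-risk ethnicity.  ``fetal_death_as_neonatal_death``
    controls whether the dataset's history-of-fetal-death variable stands in
    for the previous-neonatal-death factor (the closest field this schema
    carries); ``extra_flags`` lets callers add factors the default rule does
    not cover (e.g. PCOS) without changing the rule itself.

    Raises
    ------
    RiskStatusUnknownError
        If any required attribute is missing — women whose risk status could
        not be determined were excluded from the study population.
    """
    required = {
        "age_years": record.age_years,
        "bmi_pre": record.bmi_pre,
        "ethnicity": record.ethnicity,
        "family_history_diabetes": record.family_history_diabetes,
        "history_hip": record.history_hip,
        "history_macrosomia": record.history_macrosomia,
        "history_fetal_death": record.history_fetal_death,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise RiskStatusUnknownError(
            f"risk status unknown for record {record.id!r}: missing {', '.join(missing)}"
        )
    return RiskProfile(
        previous_hip=_history_yes(record.history_hip),
        previous_neonatal_death=(
            fetal_death_as_neonatal_death and _history_yes(record.history_fetal_death)
        ),
        age_ge_40=record.age_years >= thresholds.age_risk,
        family_history=bool(record.family_history_diabetes),
        obesity=record.bmi_pre > thresholds.bmi_obesity,
        previous_macrosomia=_history_yes(record.history_macrosomia),
        high_risk_ethnicity=record.ethnicity in HIGH_RISK_ETHNICITIES,
        extra_flags=extra_flags,
    )


@dataclass(frozen=True, slots=True)
class EligibilityResult:
    eligible: bool
    reasons: tuple[str, ...]


def check_eligibility(
    record: WomanRecord, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> EligibilityResult:
    """Apply the study inclusion criteria to one record.

    Eligible women had an OGTT between 22 and 30 weeks of gestation, were
    18-50 years old with a singleton pregnancy, had no personal history of
    diabetes or bariatric surgery, a determinable risk-factor status, and no
    hyperglycemia detected in early pregnancy (early FPG < 5.1 mmol/L).
    Always returns a verdict; ``reasons`` lists every failed criterion.
    """
    reasons: list[str] = []
    ga = record.ogtt.ga_weeks
    if ga is None or not (thresholds.ga_min <= ga <= thresholds.ga_max):
        reasons.append(
            f"OGTT gestational age outside {thresholds.ga_min:g}-{thresholds.ga_max:g} WG"
        )
    if record.age_years is None or not (
        thresholds.age_min <= record.age_years <= thresholds.age_max
    ):
        reasons.append(f"age outside {thresholds.age_min:g}-{thresholds.age_max:g} years")
    if not record.singleton:
        reasons.append("not a singleton pregnancy")
    if record.prior_diabetes:
        reasons.append("personal history of diabetes")
    if record.prior_bariatric_surgery:
        reasons.append("history of bariatric surgery")
    try:
        risk_profile(record, thresholds)
    except RiskStatusUnknownError:
        reasons.append("risk-factor status unknown")
    if record.early_fpg is None or round_reported(record.early_fpg) >= thresholds.early_fpg_cutoff:
        reasons.append("early HIP (first-trimester FPG >= 5.1 mmol/L or not measured)")
    return EligibilityResult(eligible=not reasons, reasons=tuple(reasons))


def thresholds_from_dict(d: dict) -> Thresholds:
    """Build a ``Thresholds`` from a (possibly partial) mapping, e.g. a
    parsed YAML config section; unknown keys are rejected."""
    valid = {f for f in Thresholds.__dataclass_fields__}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return replace(DEFAULT_THRESHOLDS, **d)
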