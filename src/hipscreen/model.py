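"""Core domain types for the screening-strategy evaluation pipeline.

One ``WomanRecord`` holds everything the pipeline knows about a single
pregnancy: the 75 g OGTT glucose triplet (fasting, 1 h, 2 h plasma glucose in
mmol/L), maternal characteristics, obstetric-history variables, and binary
pregnancy outcomes.  All types are immutable dataclasses so that records can
be shared freely between pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Optional


class HistoryStatus(str, Enum):
    """Three-level obstetric history variable.

    ``FIRST_CHILD`` means the woman has no previous pregnancy, so the history
    question does not apply; for risk-factor purposes it counts as "no
    history".
    """

    FIRST_CHILD = "first_child"
    NO = "no"
    YES = "yes"


class Ethnicity(str, Enum):
    NORTH_AFRICAN = "north_african"
    EUROPEAN = "european"
    SUBSAHARAN_AFRICAN = "subsaharan_african"
    INDIAN_PAKISTANI_SRILANKAN = "indian_pakistani_srilankan"
    CARIBBEAN = "caribbean"
    ASIAN = "asian"
    OTHER = "other"


class GlycemicStatus(str, Enum):
    """Reference-standard glycemic classification on the 75 g OGTT.

    GDM is moderate hyperglycemia first recognized in pregnancy; DIP is
    overt-diabetes-range hyperglycemia (presumed unrecognized pregravid
    diabetes) and takes precedence when criteria for both are met.
    HIP (hyperglycemia in pregnancy) means status is not NORMAL.
    """

    NORMAL = "normal"
    GDM = "gdm"
    DIP = "dip"


class OptionId(str, Enum):
    """The seven OGTT-sparing screening strategies.

    * ``SEL`` — full OGTT, but only in women with a risk factor.
    * ``OPT1`` — fasting-glucose triage: FPG >= 5.1 diagnoses directly,
      4.7-5.0 mmol/L triggers an OGTT, < 4.7 rules out.
    * ``OPT2`` — as OPT1, plus women with a personal history of
      hyperglycemia in pregnancy are labelled GDM without any test.
    * ``OPT3`` — fasting glucose alone; no OGTT ever.
    * ``*_SEL`` — the same rule restricted to high-risk women; low-risk
      women are unscreened and count as negatives.
    """

    SEL = "sel"
    OPT1 = "1"
    OPT1_SEL = "1-sel"
    OPT2 = "2"
    OPT2_SEL = "2-sel"
    OPT3 = "3"
    OPT3_SEL = "3-sel"

    @property
    def selective(self) -> bool:
        return self in _SELECTIVE

    @property
    def universal_counterpart(self) -> "OptionId":
        """The universal rule a selective option restricts (SEL maps to itself)."""
        return _UNIVERSAL_OF.get(self, self)


_SELECTIVE = {OptionId.SEL, OptionId.OPT1_SEL, OptionId.OPT2_SEL, OptionId.OPT3_SEL}
_UNIVERSAL_OF = {
    OptionId.OPT1_SEL: OptionId.OPT1,
    OptionId.OPT2_SEL: OptionId.OPT2,
    OptionId.OPT3_SEL: OptionId.OPT3,
}

ALL_OPTIONS: tuple[OptionId, ...] = tuple(OptionId)


class CaseClass(str, Enum):
    """A woman's classification by a screening option against the reference
    standard: true/false positive/negative."""

    TN = "tn"
    FP = "fp"
    TP = "tp"
    FN = "fn"


@dataclass(frozen=True, slots=True)
class GlucoseTriplet:
    """OGTT plasma glucose values in mmol/L and gestational age at the test.

    Any glucose value may be ``None`` (not measured); decision rules that do
    not need the post-load values never touch them, so a fasting-only record
    can still be screened by the FPG-based options.
    """

    fpg: Optional[float]
    pg1h: Optional[float]
    pg2h: Optional[float]
    ga_weeks: Optional[float] = None


@dataclass(frozen=True, slots=True)
class OutcomeRecord:
    """Binary pregnancy outcomes; ``None`` encodes missing.

    The composite adverse outcome is derived from preeclampsia, LGA,
    shoulder dystocia and neonatal hypoglycemia only.
    """

    preeclampsia: Optional[bool] = None
    lga: Optional[bool] = None
    sga: Optional[bool] = None
    shoulder_dystocia: Optional[bool] = None
    neonatal_hypoglycemia: Optional[bool] = None
    cesarean: Optional[bool] = None
    preterm_delivery: Optional[bool] = None
    nicu_admission: Optional[bool] = None
    respiratory_distress: Optional[bool] = None
    perinatal_death: Optional[bool] = None
    insulin_therapy: Optional[bool] = None


OUTCOME_FIELDS: tuple[str, ...] = tuple(f.name for f in fields(OutcomeRecord))

#: Components of the composite adverse outcome.
COMPOSITE_COMPONENTS: tuple[str, ...] = (
    "preeclampsia",
    "lga",
    "shoulder_dystocia",
    "neonatal_hypoglycemia",
)


@dataclass(frozen=True, slots=True)
class WomanRecord:
    """One pregnancy: identifiers, eligibility fields, OGTT, history, outcomes."""

    id: str
    age_years: Optional[float]
    bmi_pre: Optional[float]
    early_fpg: Optional[float]
    ogtt: GlucoseTriplet
    history_hip: Optional[HistoryStatus]
    history_macrosomia: Optional[HistoryStatus]
    history_fetal_death: Optional[HistoryStatus]
    family_history_diabetes: Optional[bool]
    ethnicity: Optional[Ethnicity]
    singleton: Optional[bool] = True
    prior_diabetes: Optional[bool] = False
    prior_bariatric_surgery: Optional[bool] = False
    outcomes: OutcomeRecord = field(default_factory=OutcomeRecord)


@dataclass(frozen=True, slots=True)
class RiskProfile:
    """Australian-New Zealand risk-factor flags for selective screening.

    ``high_risk`` is the disjunction of all component flags (plus any
    caller-supplied extension flags).
    """

    previous_hip: bool
    previous_neonatal_death: bool
    age_ge_40: bool
    family_history: bool
    obesity: bool
    previous_macrosomia: bool
    high_risk_ethnicity: bool
    extra_flags: tuple[bool, ...] = ()

    @property
    def high_risk(self) -> bool:
        return (
            self.previous_hip
            or self.previous_neonatal_death
            or self.age_ge_40
            or self.family_history
            or self.obesity
            or self.previous_macrosomia
            or self.high_risk_ethnicity
            or any(self.extra_flags)
        )


@dataclass(frozen=True, slots=True)
class ScreeningDecision:
    """What one screening option decides for one woman.

    ``label`` is ``None`` for a negative decision.  ``rationale`` is a short
    machine-readable code recording which branch of the rule fired.
    ``glucose_reads`` audits which glucose fields the rule actually read;
    post-load values appear there only when an OGTT was performed.
    """

    option: OptionId
    ogtt_performed: bool
    positive: bool
    label: Optional[GlycemicStatus]
    rationale: str
    glucose_reads: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.positive and self.label in (None, GlycemicStatus.NORMAL):
            raise ValueError("positive decision requires a GDM or DIP label")


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    """TN/FP/TP/FN tallies of a screening option against the reference standard."""

    tn: int
    fp: int
    tp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "tp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.tp + self.fn


class CohortError(Exception):
    """Base class for cohort-level errors."""


class SchemaError(CohortError):
    """The input file does not match the documented cohort schema."""


class RowError(CohortError):
    """A row violates an invariant (strict-mode reading)."""


class MissingGlucoseError(CohortError):
    """A decision rule needed a glucose value that is absent."""


class RiskStatusUnknownError(CohortError):
    """Risk-factor status cannot be determined (such women are excluded)."""
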