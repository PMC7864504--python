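"""The seven OGTT-sparing screening options as decision rules.

Each option is a deterministic function of the fasting glucose, the personal
history of hyperglycemia in pregnancy (Options 2/2-Sel only), the risk
profile (selective variants only) and — when the rule calls for one — the
full OGTT read with the reference-standard criteria.

Information discipline: the post-load glucose values (1 h, 2 h) are read if
and only if the decision reports ``ogtt_performed``.  Every access goes
through a tracking view of the glucose triplet and a violation raises
``InformationDisciplineError``, so a rule can never silently peek at values
the screening pathway would not have measured.  A consequence exploited by
the tests: fasting-only records can be screened by Option 3 (and by
Options 1/2 outside the triage band) without error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diagnosis import Thresholds, DEFAULT_THRESHOLDS, classify_reference, round_reported
from .model import (
    CaseClass,
    GlucoseTriplet,
    GlycemicStatus,
    HistoryStatus,
    MissingGlucoseError,
    OptionId,
    RiskProfile,
    ScreeningDecision,
    WomanRecord,
)

# rationale codes
RULE_OUT_LOW_FPG = "RULE_OUT_LOW_FPG"
HISTORY_SHORTCUT = "HISTORY_SHORTCUT"
FPG_DIRECT = "FPG_DIRECT"
OGTT_RESULT = "OGTT_RESULT"
LOW_RISK_UNSCREENED = "LOW_RISK_UNSCREENED"


class InformationDisciplineError(RuntimeError):
    """A decision rule read a post-load glucose value without an OGTT."""


class _TrackedTriplet:
    """View of a ``GlucoseTriplet`` that records which fields are read.

    Reading an absent value raises ``MissingGlucoseError`` at access time, so
    a rule only ever fails on values it genuinely needs.
    """

    __slots__ = ("_ogtt", "reads")

    def __init__(self, ogtt: GlucoseTriplet) -> None:
        self._ogtt = ogtt
        self.reads: set[str] = set()

    def _get(self, name: str) -> float:
        self.reads.add(name)
        value = getattr(self._ogtt, name)
        if value is None:
            raise MissingGlucoseError(f"glucose value {name!r} is missing")
        return value

    @property
    def fpg(self) -> float:
        return self._get("fpg")

    @property
    def pg1h(self) -> float:
        return self._get("pg1h")

    @property
    def pg2h(self) -> float:
        return self._get("pg2h")

    @property
    def ga_weeks(self):
        return self._ogtt.ga_weeks


@dataclass(frozen=True, slots=True)
class _Outcome:
    ogtt: bool
    positive: bool
    label: GlycemicStatus | None
    rationale: str


def _fpg_label(fpg_rounded: float, thresholds: Thresholds) -> GlycemicStatus:
    # FPG-only diagnosis: >= 7.0 is diabetes-in-pregnancy range, below is GDM.
    if fpg_rounded >= thresholds.fpg_dip:
        return GlycemicStatus.DIP
    return GlycemicStatus.GDM


def _full_ogtt(tracked: _TrackedTriplet, thresholds: Thresholds) -> _Outcome:
    status = classify_reference(
        GlucoseTriplet(tracked.fpg, tracked.pg1h, tracked.pg2h, tracked.ga_weeks),
        thresholds,
    )
    positive = status is not GlycemicStatus.NORMAL
    return _Outcome(True, positive, status if positive else None, OGTT_RESULT)


def _fpg_triage(tracked: _TrackedTriplet, thresholds: Thresholds) -> _Outcome:
    """Shared core of Options 1 and 2: rule in at FPG >= 5.1, OGTT in the
    4.7-5.0 mmol/L band, rule out below 4.7."""
    fpg = round_reported(tracked.fpg)
    if fpg >= thresholds.fpg_gdm:
        return _Outcome(False, True, _fpg_label(fpg, thresholds), FPG_DIRECT)
    if fpg >= thresholds.fpg_band_low:
        return _full_ogtt(tracked, thresholds)
    return _Outcome(False, False, None, RULE_OUT_LOW_FPG)


def _decide(
    option: OptionId,
    tracked: _TrackedTriplet,
    history_hip: HistoryStatus | None,
    risk: RiskProfile,
    thresholds: Thresholds,
) -> _Outcome:
    if option.selective and not risk.high_risk:
        return _Outcome(False, False, None, LOW_RISK_UNSCREENED)
    base = option.universal_counterpart
    if option is OptionId.SEL:
        return _full_ogtt(tracked, thresholds)
    if base is OptionId.OPT2 and history_hip is HistoryStatus.YES:
        # The history shortcut fires before any glucose is looked at.
        return _Outcome(False, True, GlycemicStatus.GDM, HISTORY_SHORTCUT)
    if base in (OptionId.OPT1, OptionId.OPT2):
        return _fpg_triage(tracked, thresholds)
    if base is OptionId.OPT3:
        fpg = round_reported(tracked.fpg)
        if fpg >= thresholds.fpg_gdm:
            return _Outcome(False, True, _fpg_label(fpg, thresholds), FPG_DIRECT)
        return _Outcome(False, False, None, RULE_OUT_LOW_FPG)
    raise ValueError(f"unknown option {option!r}")  # pragma: no cover


def apply_option(
    option: OptionId,
    record: WomanRecord,
    risk: RiskProfile,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ScreeningDecision:
    """Run one screening option on one woman.

    Raises
    ------
    MissingGlucoseError
        If the rule needed a glucose value the record does not carry; the
        message names the option.
    """
    tracked = _TrackedTriplet(record.ogtt)
    try:
        out = _decide(option, tracked, record.history_hip, risk, thresholds)
    except MissingGlucoseError as e:
        raise MissingGlucoseError(f"option {option.value}: {e}") from None
    if not out.ogtt and tracked.reads & {"pg1h", "pg2h"}:
        raise InformationDisciplineError(
            f"option {option.value} read post-load glucose without performing an OGTT"
        )
    return ScreeningDecision(
        option=option,
        ogtt_performed=out.ogtt,
        positive=out.positive,
        label=out.label,
        rationale=out.rationale,
        glucose_reads=frozenset(tracked.reads),
    )


def ogtt_required(
    option: OptionId,
    record: WomanRecord,
    risk: RiskProfile,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Would this option send this woman for an OGTT?

    Options 3 and 3-Sel never do; the answer otherwise depends only on the
    risk profile, the history shortcut and the fasting value, so only
    ``fpg`` is read.
    """
    if option.selective and not risk.high_risk:
        return False
    base = option.universal_counterpart
    if option is OptionId.SEL:
        return True
    if base is OptionId.OPT3:
        return False
    if base is OptionId.OPT2 and record.history_hip is HistoryStatus.YES:
        return False
    if record.ogtt.fpg is None:
        raise MissingGlucoseError(f"option {option.value}: glucose value 'fpg' is missing")
    fpg = round_reported(record.ogtt.fpg)
    return thresholds.fpg_band_low <= fpg < thresholds.fpg_gdm


def classify_case(decision: ScreeningDecision, reference: GlycemicStatus) -> CaseClass:
    """Place one decision in the TN/FP/TP/FN taxonomy against the reference
    standard (universal-screening OGTT, IADPSG/WHO criteria)."""
    hip = reference is not GlycemicStatus.NORMAL
    if decision.positive:
        return CaseClass.TP if hip else CaseClass.FP
    return CaseClass.FN if hip else CaseClass.TN
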