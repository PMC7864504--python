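"""Aggregate per-woman screening decisions into diagnostic performance.

Point estimates follow the usual definitions — sensitivity TP/(TP+FN),
specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN) — with two-sided 95%
binomial confidence intervals (Clopper-Pearson exact by default, Wilson on
request).  Predictive values are computed at the cohort's own prevalence; no
external-prevalence adjustment is applied.  A metric with a zero denominator
is reported as undefined, never as 0.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .diagnosis import Thresholds, DEFAULT_THRESHOLDS, classify_reference, risk_profile
from .model import (
    CaseClass,
    COMPOSITE_COMPONENTS,
    ConfusionCounts,
    OUTCOME_FIELDS,
    OptionId,
    OutcomeRecord,
    ScreeningDecision,
    WomanRecord,
)
from .options import apply_option, classify_case, ogtt_required

CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson"}


@dataclass(frozen=True, slots=True)
class Metric:
    """A proportion with its 95% CI and the counts behind it."""

    value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True, slots=True)
class DiagnosticPerformance:
    option: Optional[OptionId]
    counts: ConfusionCounts
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric
    ogtt_count: int
    ogtt_fraction: float
    ci_method: str


def confusion_counts(cases: Iterable[CaseClass]) -> ConfusionCounts:
    """Tally case classes; every woman falls in exactly one cell."""
    tally = Counter(cases)
    total = sum(tally.values())
    if total == 0:
        raise ValueError("cannot tally an empty case collection")
    return ConfusionCounts(
        tn=tally.get(CaseClass.TN, 0),
        fp=tally.get(CaseClass.FP, 0),
        tp=tally.get(CaseClass.TP, 0),
        fn=tally.get(CaseClass.FN, 0),
    )


def _metric(k: int, n: int, method: str) -> Metric:
    if n == 0:
        return Metric(None, None, None, 0, 0)
    lo, hi = proportion_confint(k, n, alpha=0.05, method=method)
    # statsmodels returns numpy scalars (and nan at the k=0 / k=n boundary
    # for the exact method's empty tail); clamp to [0, 1].
    lo = 0.0 if math.isnan(lo) else float(lo)
    hi = 1.0 if math.isnan(hi) else float(hi)
    return Metric(k / n, lo, hi, k, n)


def diagnostic_performance(
    counts: ConfusionCounts,
    ogtt_count: int,
    n: Optional[int] = None,
    ci_method: str = "clopper_pearson",
    option: Optional[OptionId] = None,
) -> DiagnosticPerformance:
    """Compute sensitivity/specificity/PPV/NPV with CIs plus OGTT burden.

    ``n`` defaults to the confusion total and must match it when given;
    ``ogtt_count`` is the number of women the option sends for an OGTT.
    """
    if ci_method not in CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(CI_METHODS)}")
    if n is None:
        n = counts.n
    elif n != counts.n:
        raise ValueError(f"n={n} does not match confusion total {counts.n}")
    if not 0 <= ogtt_count <= n:
        raise ValueError("ogtt_count must be between 0 and n")
    m = CI_METHODS[ci_method]
    return DiagnosticPerformance(
        option=option,
        counts=counts,
        sensitivity=_metric(counts.tp, counts.tp + counts.fn, m),
        specificity=_metric(counts.tn, counts.tn + counts.fp, m),
        ppv=_metric(counts.tp, counts.tp + counts.fp, m),
        npv=_metric(counts.tn, counts.tn + counts.fn, m),
        ogtt_count=ogtt_count,
        ogtt_fraction=ogtt_count / n if n else 0.0,
        ci_method=ci_method,
    )


def ogtt_burden(
    option: OptionId,
    cohort: Sequence[WomanRecord],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[int, float]:
    """Number and fraction of women the option sends for an OGTT."""
    if not cohort:
        return 0, 0.0
    count = sum(
        ogtt_required(option, r, risk_profile(r, thresholds), thresholds) for r in cohort
    )
    return count, count / len(cohort)


def composite_outcome(o: OutcomeRecord) -> Optional[bool]:
    """Composite adverse outcome: preeclampsia, LGA infant, shoulder dystocia
    or neonatal hypoglycemia.  Missing if any component is missing
    (complete-case rule)."""
    values = [getattr(o, name) for name in COMPOSITE_COMPONENTS]
    if any(v is None for v in values):
        return None
    return any(values)


def outcome_rates(
    cohort: Sequence[WomanRecord], cases: Sequence[CaseClass]
) -> pd.DataFrame:
    """Per-case-class rates of the composite and each individual outcome.

    Returns a tidy frame with columns ``group, outcome, numerator,
    denominator, rate, rate_pct``; denominators are complete-case (women with
    the outcome missing are dropped from that outcome's denominator).  A
    group with an empty denominator gets NaN rates.
    """
    if len(cohort) != len(cases):
        raise ValueError("cases must align one-to-one with the cohort")
    if not cohort:
        raise ValueError("empty cohort")
    rows = []
    outcomes = ("composite",) + OUTCOME_FIELDS
    for group in CaseClass:
        members = [r for r, c in zip(cohort, cases) if c is group]
        for name in outcomes:
            if name == "composite":
                vals = [composite_outcome(r.outcomes) for r in members]
            else:
                vals = [getattr(r.outcomes, name) for r in members]
            known = [v for v in vals if v is not None]
            num = sum(known)
            den = len(known)
            rate = num / den if den else float("nan")
            rows.append(
                {
                    "group": group.value,
                    "outcome": name,
                    "numerator": num,
                    "denominator": den,
                    "rate": rate,
                    "rate_pct": 100.0 * rate,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True, slots=True)
class OptionEvaluation:
    """Everything one option produces on one cohort."""

    option: OptionId
    decisions: tuple[ScreeningDecision, ...]
    cases: tuple[CaseClass, ...]
    performance: DiagnosticPerformance


def evaluate_option(
    option: OptionId,
    cohort: Sequence[WomanRecord],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    ci_method: str = "clopper_pearson",
) -> OptionEvaluation:
    """Run one option over a cohort and aggregate its performance."""
    if not cohort:
        raise ValueError("empty cohort")
    decisions = []
    cases = []
    for record in cohort:
        risk = risk_profile(record, thresholds)
        decision = apply_option(option, record, risk, thresholds)
        reference = classify_reference(record.ogtt, thresholds)
        decisions.append(decision)
        cases.append(classify_case(decision, reference))
    counts = confusion_counts(cases)
    ogtt_count = sum(d.ogtt_performed for d in decisions)
    perf = diagnostic_performance(
        counts, ogtt_count, len(cohort), ci_method=ci_method, option=option
    )
    return OptionEvaluation(option, tuple(decisions), tuple(cases), perf)


def performance_table(evaluations: Sequence[OptionEvaluation]) -> pd.DataFrame:
    """Shape a set of option evaluations as one row per option, in the layout
    of a published performance table (OGTT burden then the four metrics with
    CI bounds)."""
    rows = []
    for ev in evaluations:
        p = ev.performance
        row = {
            "option": ev.option.value,
            "ogtt_n": p.ogtt_count,
            "ogtt_pct": 100.0 * p.ogtt_fraction,
        }
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m: Metric = getattr(p, name)
            row[name] = m.value
            row[f"{name}_lo"] = m.ci_low
            row[f"{name}_hi"] = m.ci_high
        rows.append(row)
    return pd.DataFrame(rows)
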