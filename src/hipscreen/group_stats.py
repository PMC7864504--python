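"""Comparisons of the TN/FP/TP/FN case-class groups.

Continuous variables are compared by one-way ANOVA with Welch t tests for
the pairwise post-hoc comparisons; categorical variables by the chi-squared
test, replaced by Fisher's exact test whenever any expected cell count falls
below 5 (2x2 tables by full hypergeometric enumeration, larger tables by a
seeded Monte-Carlo permutation over tables with the observed margins).  All
tests are two-sided; pairwise p-values are Bonferroni-adjusted, i.e.
multiplied by the number of tests and capped at 1, with significance called
at 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CaseClass

#: minimum expected cell count below which the chi-squared approximation is
#: abandoned in favour of Fisher's exact test
EXPECTED_COUNT_RULE = 5.0

ALPHA = 0.05

#: canonical ordering of the six pairwise comparisons among the four groups,
#: matching the a-f superscript scheme of the published group table
PAIR_CODES: tuple[tuple[str, tuple[CaseClass, CaseClass]], ...] = (
    ("a", (CaseClass.TN, CaseClass.FP)),
    ("b", (CaseClass.TN, CaseClass.TP)),
    ("c", (CaseClass.TN, CaseClass.FN)),
    ("d", (CaseClass.FP, CaseClass.TP)),
    ("e", (CaseClass.FP, CaseClass.FN)),
    ("f", (CaseClass.TP, CaseClass.FN)),
)


@dataclass(frozen=True, slots=True)
class PairwiseTest:
    pair: tuple[str, str]
    test: str
    statistic: Optional[float]
    p_raw: float
    p_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


@dataclass(frozen=True, slots=True)
class GroupComparisonResult:
    variable: str
    #: per-group summary: {"mean": .., "sd": .., "n": ..} for continuous,
    #: {"count": .., "percent": .., "n": ..} (per level) for categorical
    summaries: dict
    test: str
    statistic: Optional[float]
    p_value: float
    pairwise: tuple[PairwiseTest, ...]
    degenerate: bool = False
    notes: tuple[str, ...] = ()


def bonferroni_adjust(p_values: Sequence[float], m: int) -> list[float]:
    """Multiply each p by m and cap at 1 (order preserved).

    ``m`` is the number of tests in the family and may exceed the number of
    p-values supplied, but never be smaller.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < len(p_values):
        raise ValueError(f"m={m} smaller than the {len(p_values)} tests supplied")
    out = []
    for p in p_values:
        if not (0.0 <= p <= 1.0 or math.isnan(p)):
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, p * m) if not math.isnan(p) else p)
    return out


def compare_continuous(
    values_by_group: Mapping[str, Sequence[float]],
    variable: str = "",
    pairwise: bool = True,
) -> GroupComparisonResult:
    """One-way ANOVA across groups plus Welch-t pairwise post-hocs.

    Groups with fewer than two observations are excluded with a warning.
    If the within-group variance is exactly zero the ANOVA F statistic is
    undefined and the result is flagged degenerate.
    """
    notes: list[str] = []
    usable: dict[str, np.ndarray] = {}
    for g, vals in values_by_group.items():
        arr = np.asarray([v for v in vals if v is not None and not math.isnan(v)], float)
        if arr.size < 2:
            notes.append(f"group {g!r} excluded: fewer than 2 observations")
            warnings.warn(notes[-1], stacklevel=2)
        else:
            usable[g] = arr
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 observations")
    summaries = {
        g: {"mean": float(a.mean()), "sd": float(a.std(ddof=1)), "n": int(a.size)}
        for g, a in usable.items()
    }
    arrays = list(usable.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        grand = np.concatenate(arrays).mean()
        ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
        # all within-group spread is zero: F is 0/0 or infinite
        stat, p, degenerate = (0.0 if ssb == 0 else math.inf), float("nan"), True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.f_oneway(*arrays)
        stat, p, degenerate = float(stat), float(p), False
    pw: list[PairwiseTest] = []
    if pairwise and len(usable) >= 2:
        pairs = list(combinations(usable, 2))
        raws = []
        stats_list = []
        for g1, g2 in pairs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, pr = stats.ttest_ind(usable[g1], usable[g2], equal_var=False)
            raws.append(float(pr))
            stats_list.append(float(t))
        adj = bonferroni_adjust(raws, max(len(pairs), 6) if len(usable) == 4 else len(pairs))
        pw = [
            PairwiseTest((g1, g2), "welch_t", s, pr, pa)
            for (g1, g2), s, pr, pa in zip(pairs, stats_list, raws, adj)
        ]
    return GroupComparisonResult(
        variable=variable,
        summaries=summaries,
        test="anova",
        statistic=stat,
        p_value=p,
        pairwise=tuple(pw),
        degenerate=degenerate,
        notes=tuple(notes),
    )


def _table_logprob(table: np.ndarray) -> float:
    """Log-probability of an r x c table under fixed margins (multivariate
    hypergeometric null)."""
    from scipy.special import gammaln

    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_exact_rxc(
    table: np.ndarray, n_draws: int = 100_000, seed: int = 20210121
) -> float:
    """Two-sided Fisher-type exact test for an r x c table.

    2x2 tables use full hypergeometric enumeration (the conventional
    "sum of all tables at most as probable" definition).  Larger tables use
    a seeded Monte-Carlo sample of tables with the observed margins; the
    observed table is included in the tally so the p-value is never 0.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    draws = dist.rvs(n_draws, random_state=rng)
    # margins are fixed, so tables order by -sum(log(n_ij!)) alone
    from scipy.special import gammaln

    stat = -gammaln(draws + 1.0).sum(axis=(1, 2))
    obs = -float(gammaln(table + 1.0).sum())
    # tolerance absorbs float noise in log-probability ties
    count = int(np.sum(stat <= obs + 1e-9))
    return (count + 1) / (n_draws + 1)


def compare_categorical(
    contingency: np.ndarray | Sequence[Sequence[int]],
    variable: str = "",
    group_labels: Optional[Sequence[str]] = None,
    pairwise: bool = False,
    fisher_doubling: bool = False,
    seed: int = 20210121,
) -> GroupComparisonResult:
    """Compare groups (rows) over the levels of a categorical variable
    (columns).

    The chi-squared test is used when every expected cell count is at least
    5, otherwise Fisher's exact test.  ``fisher_doubling`` switches the
    two-sided 2x2 Fisher p-value from the sum-of-less-probable-tables rule to
    doubling the smaller one-sided tail.  With ``pairwise`` each pair of
    groups is tested on its own 2-row sub-table under the same rule, with
    Bonferroni adjustment over the pairs.
    """
    table = np.asarray(contingency, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("all-zero row or column in contingency table")
    labels = list(group_labels) if group_labels is not None else [
        f"g{i}" for i in range(table.shape[0])
    ]
    if len(labels) != table.shape[0]:
        raise ValueError("group_labels must match the number of rows")

    def one_test(sub: np.ndarray) -> tuple[str, Optional[float], float]:
        expected = stats.contingency.expected_freq(sub)
        if expected.min() >= EXPECTED_COUNT_RULE:
            chi2, p, _, _ = stats.chi2_contingency(sub, correction=False)
            return "chi2", float(chi2), float(p)
        if sub.shape == (2, 2) and fisher_doubling:
            p_less = stats.fisher_exact(sub, alternative="less")[1]
            p_greater = stats.fisher_exact(sub, alternative="greater")[1]
            return "fisher_doubling", None, min(1.0, 2.0 * min(p_less, p_greater))
        name = "fisher" if sub.shape == (2, 2) else "fisher_mc"
        return name, None, fisher_exact_rxc(sub, seed=seed)

    test_name, statistic, p = one_test(table)
    row_n = table.sum(axis=1)
    summaries = {
        lab: {
            "count": table[i].tolist(),
            "percent": (100.0 * table[i] / row_n[i]).tolist() if row_n[i] else None,
            "n": int(row_n[i]),
        }
        for i, lab in enumerate(labels)
    }
    pw: list[PairwiseTest] = []
    if pairwise:
        pairs = list(combinations(range(table.shape[0]), 2))
        results = []
        for i, j in pairs:
            sub = table[[i, j], :]
            keep = sub.sum(axis=0) > 0  # drop levels absent from both groups
            sub = sub[:, keep]
            if sub.shape[1] < 2:
                results.append(("undefined", None, float("nan")))
            else:
                results.append(one_test(sub))
        adj = bonferroni_adjust([r[2] for r in results], len(pairs))
        pw = [
            PairwiseTest((labels[i], labels[j]), name, s, pr, pa)
            for (i, j), (name, s, pr), pa in zip(pairs, results, adj)
        ]
    return GroupComparisonResult(
        variable=variable,
        summaries=summaries,
        test=test_name,
        statistic=statistic,
        p_value=p,
        pairwise=tuple(pw),
    )


# ---------------------------------------------------------------------------
# cohort-level report

_CONTINUOUS_VARS: tuple[tuple[str, str], ...] = (
    ("fpg_mmol_l", "Fasting plasma glucose (mmol/L)"),
    ("pg1h_mmol_l", "1-h plasma glucose (mmol/L)"),
    ("pg2h_mmol_l", "2-h plasma glucose (mmol/L)"),
    ("ga_ogtt_weeks", "Gestational age at OGTT (WG)"),
    ("age_years", "Age (years)"),
    ("bmi_pre", "Preconception BMI (kg/m2)"),
)

_CATEGORICAL_VARS: tuple[tuple[str, str], ...] = (
    ("history_hip", "History of hyperglycemia in pregnancy"),
    ("history_macrosomia", "History of macrosomia"),
    ("history_fetal_death", "History of fetal death"),
    ("family_history_diabetes", "Family history of diabetes"),
    ("ethnicity", "Ethnicity"),
)

_OUTCOME_VARS: tuple[str, ...] = (
    "composite",
    "preeclampsia",
    "lga",
    "sga",
    "shoulder_dystocia",
    "neonatal_hypoglycemia",
    "cesarean",
    "preterm_delivery",
    "nicu_admission",
    "respiratory_distress",
    "perinatal_death",
    "insulin_therapy",
)


def _sig_codes(pairwise: Sequence[PairwiseTest]) -> str:
    """Render significant pairwise comparisons as the a-f superscript codes."""
    by_pair = {tuple(sorted(p.pair)): p for p in pairwise}
    codes = []
    for code, (g1, g2) in PAIR_CODES:
        p = by_pair.get(tuple(sorted((g1.value, g2.value))))
        if p is not None and p.significant:
            codes.append(code)
    return "".join(codes)


def compare_groups(cohort, cases, seed: int = 20210121) -> pd.DataFrame:
    """Full group-comparison report over a cohort and its case classes.

    One row per variable: group summaries, the global test and p-value, and
    the significant Bonferroni-adjusted pairwise comparisons as a-f codes.
    Only groups actually present in ``cases`` are compared.
    """
    from .performance import composite_outcome

    groups = [g for g in CaseClass if any(c is g for c in cases)]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty case-class groups")
    members = {g: [r for r, c in zip(cohort, cases) if c is g] for g in groups}
    rows = []

    def continuous_value(record, key):
        if key == "fpg_mmol_l":
            return record.ogtt.fpg
        if key == "pg1h_mmol_l":
            return record.ogtt.pg1h
        if key == "pg2h_mmol_l":
            return record.ogtt.pg2h
        if key == "ga_ogtt_weeks":
            return record.ogtt.ga_weeks
        return getattr(record, {"age_years": "age_years", "bmi_pre": "bmi_pre"}[key])

    for key, label in _CONTINUOUS_VARS:
        data = {
            g.value: [continuous_value(r, key) for r in members[g]] for g in groups
        }
        try:
            res = compare_continuous(data, variable=key)
        except ValueError:
            continue
        summary = {
            g: f"{s['mean']:.2f} ({s['sd']:.2f})" for g, s in res.summaries.items()
        }
        rows.append(
            {
                "variable": label,
                "test": res.test,
                "p_value": res.p_value,
                "pairwise_significant": _sig_codes(res.pairwise),
                **{f"group_{g}": v for g, v in summary.items()},
            }
        )

    def categorical_levels(key, record):
        v = getattr(record, key)
        if v is None:
            return None
        if isinstance(v, bool):
            return "yes" if v else "no"
        return v.value

    for key, label in _CATEGORICAL_VARS:
        level_names = sorted(
            {
                lv
                for g in groups
                for r in members[g]
                if (lv := categorical_levels(key, r)) is not None
            }
        )
        if len(level_names) < 2:
            continue
        table = np.array(
            [
                [
                    sum(categorical_levels(key, r) == lv for r in members[g])
                    for lv in level_names
                ]
                for g in groups
            ]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        res = compare_categorical(
            table,
            variable=key,
            group_labels=[g.value for g in groups],
            pairwise=True,
            seed=seed,
        )
        summary = {
            g: "; ".join(
                f"{lv}: {c} ({p:.1f})"
                for lv, c, p in zip(level_names, s["count"], s["percent"])
            )
            for g, s in res.summaries.items()
        }
        rows.append(
            {
                "variable": label,
                "test": res.test,
                "p_value": res.p_value,
                "pairwise_significant": _sig_codes(res.pairwise),
                **{f"group_{g}": v for g, v in summary.items()},
            }
        )

    for name in _OUTCOME_VARS:
        def outcome_value(record):
            if name == "composite":
                return composite_outcome(record.outcomes)
            return getattr(record.outcomes, name)

        counts = []
        ok = True
        for g in groups:
            vals = [outcome_value(r) for r in members[g]]
            known = [v for v in vals if v is not None]
            yes = sum(known)
            no = len(known) - yes
            counts.append([no, yes])
        table = np.array(counts, dtype=np.int64)
        if (table.sum(axis=1) == 0).any():
            ok = False
        if not ok or (table.sum(axis=0) == 0).any():
            continue
        res = compare_categorical(
            table,
            variable=name,
            group_labels=[g.value for g in groups],
            pairwise=True,
            seed=seed,
        )
        summary = {
            g.value: f"{table[i, 1]} ({100.0 * table[i, 1] / table[i].sum():.1f})"
            for i, g in enumerate(groups)
        }
        rows.append(
            {
                "variable": name,
                "test": res.test,
                "p_value": res.p_value,
                "pairwise_significant": _sig_codes(res.pairwise),
                **{f"group_{g}": v for g, v in summary.items()},
            }
        )
    return pd.DataFrame(rows)
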