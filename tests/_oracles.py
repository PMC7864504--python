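"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the plain-language description
of each procedure, without importing the implementation's helpers, so a bug
cannot cancel itself out across both routes.
"""

from __future__ import annotations

import math


def round1(x: float) -> float:
    return math.floor(x * 10 + 0.5) / 10


def reference_status_oracle(fpg: float, pg1h: float, pg2h: float) -> str:
    """IADPSG/WHO truth table, nested conditionals, one-decimal rounding."""
    f, o, t = round1(fpg), round1(pg1h), round1(pg2h)
    if f >= 7.0:
        return "dip"
    if t >= 11.1:
        return "dip"
    if 5.1 <= f <= 6.9:
        return "gdm"
    if o >= 10.0:
        return "gdm"
    if 8.5 <= t <= 11.0:
        return "gdm"
    return "normal"


def option_oracle(
    option: str,
    fpg: float,
    pg1h: float,
    pg2h: float,
    history_hip: bool,
    high_risk: bool,
) -> tuple[bool, bool, str | None]:
    """Decision-tree transcription of the seven screening options.

    Returns (ogtt_performed, positive, label).  Written as literal nested
    conditionals following the published flow diagram.
    """
    f = round1(fpg)

    def ogtt_result():
        status = reference_status_oracle(fpg, pg1h, pg2h)
        return (True, status != "normal", None if status == "normal" else status)

    def fpg_only_label():
        return "dip" if f >= 7.0 else "gdm"

    if option == "sel":
        if not high_risk:
            return (False, False, None)
        return ogtt_result()
    if option in ("1", "1-sel"):
        if option == "1-sel" and not high_risk:
            return (False, False, None)
        if f >= 5.1:
            return (False, True, fpg_only_label())
        if 4.7 <= f <= 5.0:
            return ogtt_result()
        return (False, False, None)
    if option in ("2", "2-sel"):
        if option == "2-sel" and not high_risk:
            return (False, False, None)
        if history_hip:
            return (False, True, "gdm")
        if f >= 5.1:
            return (False, True, fpg_only_label())
        if 4.7 <= f <= 5.0:
            return ogtt_result()
        return (False, False, None)
    if option in ("3", "3-sel"):
        if option == "3-sel" and not high_risk:
            return (False, False, None)
        if f >= 5.1:
            return (False, True, fpg_only_label())
        return (False, False, None)
    raise ValueError(option)


def clopper_pearson_oracle(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI by bisection on the binomial tail sums."""

    def pmf(i: int, p: float) -> float:
        # log-space to survive large n
        log_comb = (
            math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1)
        )
        if p in (0.0, 1.0):
            return float((p == 0.0 and i == 0) or (p == 1.0 and i == n))
        return math.exp(log_comb + i * math.log(p) + (n - i) * math.log1p(-p))

    def tail_ge(p: float) -> float:  # P(X >= k | p)
        return sum(pmf(i, p) for i in range(k, n + 1))

    def tail_le(p: float) -> float:  # P(X <= k | p)
        return sum(pmf(i, p) for i in range(0, k + 1))

    def bisect(f, target, lo, hi, increasing):
        for _ in range(200):
            mid = (lo + hi) / 2
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else bisect(tail_ge, alpha / 2, 0.0, 1.0, True)
    upper = 1.0 if k == n else bisect(tail_le, alpha / 2, 0.0, 1.0, False)
    return lower, upper


def anova_f_oracle(groups) -> tuple[float, int, int]:
    """Textbook one-way ANOVA F from between/within sums of squares."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    k = len(groups)
    n = len(all_vals)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return f, k - 1, n - k


def fisher_2xc_exact_oracle(table) -> float:
    """Two-sided Fisher p for a 2-row table by full enumeration of all
    tables with the observed margins (sum of probabilities <= observed)."""
    import itertools

    import numpy as np
    from scipy.special import gammaln

    table = np.asarray(table, dtype=int)
    r = table.sum(axis=1)
    c = table.sum(axis=0)

    def logprob(t):
        t = np.asarray(t)
        return float(
            gammaln(r + 1).sum()
            + gammaln(c + 1).sum()
            - gammaln(table.sum() + 1)
            - gammaln(t + 1).sum()
        )

    obs = logprob(table)
    total = 0.0
    extreme = 0.0
    ranges = [range(min(r[0], cj) + 1) for cj in c]
    for first_row in itertools.product(*ranges):
        if sum(first_row) != r[0]:
            continue
        second = c - np.asarray(first_row)
        if (second < 0).any():
            continue
        lp = logprob(np.vstack([first_row, second]))
        p = math.exp(lp)
        total += p
        if lp <= obs + 1e-9:
            extreme += p
    return extreme / total
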