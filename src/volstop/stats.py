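"""Behavioral endpoints and two-group statistics.

Success rates per trial type, response times (trial onset to threshold
crossing; NO-GO response times exist only on error trials), lick counts,
the 85%-over-three-consecutive-days training criterion, per-mouse session
averaging (one independent data point per mouse), and the two tests used
for group contrasts: unpaired two-tailed Student's t (pooled variance) and
the Mann-Whitney U test (exact for small untied samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "success_rate",
    "response_times",
    "training_criterion",
    "unpaired_t_test",
    "mann_whitney_u",
    "significance_stars",
    "TestResult",
    "GroupComparison",
    "compare_groups",
]


class StatsError(ValueError):
    pass


class UndefinedRateError(StatsError):
    pass


class InsufficientDataError(StatsError):
    pass


def success_rate(log, trial_type: str) -> float:
    """Successes / presented for one trial type, in [0, 1]."""
    presented = log.presented(trial_type)
    if presented == 0:
        raise UndefinedRateError(
            f"no {trial_type} trials presented in this session")
    return log.successes(trial_type) / presented


def response_times(log, trial_type: str,
                   outcome_filter: str | None = None) -> list[float]:
    """Response times (s) of trials with a threshold crossing.

    ``outcome_filter`` restricts to "success" or "failure" trials.  NO-GO
    response times are defined on error trials only (a successful NO-GO has
    no crossing), so ``response_times(log, "NOGO", "failure")`` is the
    error-trial response-time sample.
    """
    if outcome_filter not in (None, "success", "failure"):
        raise StatsError(f"invalid outcome filter {outcome_filter!r}")
    out = []
    for t in log.trials:
        if t.trial_type != trial_type:
            continue
        if outcome_filter is not None and t.outcome != outcome_filter:
            continue
        if t.response_time is not None:
            out.append(t.response_time)
    return out


def training_criterion(daily_rates) -> bool:
    """True iff some run of 3 consecutive days all reach a rate >= 0.85."""
    rates = list(daily_rates)
    if len(rates) < 3:
        raise InsufficientDataError("need at least 3 daily rates")
    return any(all(r >= 0.85 for r in rates[i:i + 3])
               for i in range(len(rates) - 2))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str
    degenerate: bool = False


def unpaired_t_test(a, b) -> TestResult:
    """Unpaired two-tailed Student's t with pooled variance.

    Degenerate inputs: zero pooled variance with equal means gives
    (t=0, p=1); zero variance with unequal means is flagged degenerate with
    p=0.  Welch's correction is available via ``equal_var=False`` on
    :func:`scipy.stats.ttest_ind` directly; the paradigm's reported test is
    Student's.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise StatsError("non-finite values in input")
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, "student_t")
        sign = math.copysign(1.0, a.mean() - b.mean())
        return TestResult(sign * math.inf, 0.0, "student_t", degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(res.statistic), float(res.pvalue), "student_t")


def mann_whitney_u(a, b) -> TestResult:
    """Two-tailed Mann-Whitney U; U is the smaller of U_a, U_b.

    The p-value is exact (full null distribution) when the combined sample
    size is at most 16 and there are no ties, and a tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 1 or b.size < 1:
        raise InsufficientDataError("each group needs n >= 1")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 16 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return TestResult(u, float(res.pvalue), "mann_whitney_u")


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """A two-group contrast on per-mouse summary values."""

    endpoint: str
    group_a: str
    group_b: str
    values_a: list[float]
    values_b: list[float]
    test: str
    statistic: float
    p_value: float
    stars: str
    flags: dict = field(default_factory=dict)

    @property
    def mean_a(self) -> float:
        return float(np.mean(self.values_a))

    @property
    def mean_b(self) -> float:
        return float(np.mean(self.values_b))


def compare_groups(endpoint: str, group_a: str, values_a, group_b, values_b,
                   test: str = "student_t") -> GroupComparison:
    """Run the requested two-group test and attach the star convention."""
    va = [float(v) for v in values_a if np.isfinite(v)]
    vb = [float(v) for v in values_b if np.isfinite(v)]
    if len(va) < 2 or len(vb) < 2:
        raise InsufficientDataError(
            f"endpoint {endpoint!r}: need >= 2 mice per group")
    if test == "student_t":
        res = unpaired_t_test(va, vb)
    elif test == "mann_whitney_u":
        res = mann_whitney_u(va, vb)
    else:
        raise StatsError(f"unknown test {test!r}")
    flags = {}
    if res.degenerate:
        flags["degenerate"] = True
    if len(va) < len(list(values_a)) or len(vb) < len(list(values_b)):
        flags["dropped_nan"] = True
    return GroupComparison(
        endpoint=endpoint, group_a=group_a, group_b=group_b,
        values_a=va, values_b=vb, test=res.test, statistic=res.statistic,
        p_value=res.p_value, stars=significance_stars(res.p_value),
        flags=flags)
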