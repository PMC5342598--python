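"""Cohort statistics: incidence, profile distributions, Fisher exact, paired t.

The two-sided Fisher exact test is computed from first principles by
enumerating the full hypergeometric support of the 2x2 table with fixed
margins and summing the point probabilities not exceeding the observed
table's (with a small relative tie tolerance, the usual two-sided
convention).  Library implementations serve only as cross-checks in tests.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from scipy import stats as _scipy_stats

from .classify import ProfileCall, ProfileLabel
from .errors import DegenerateVarianceError

#: Relative tolerance for "point probability <= observed" ties.
FISHER_TIE_RTOL = 1e-7


class TestMethod(str, enum.Enum):
    FISHER_EXACT_TWO_SIDED = "FISHER_EXACT_TWO_SIDED"
    PAIRED_T_TWO_TAIL = "PAIRED_T_TWO_TAIL"


@dataclass(frozen=True)
class TestResult:
    method: TestMethod
    p_value: float
    statistic: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = group and columns = category."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError(f"counts must be non-negative integers: {self}")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class IncidenceSummary:
    group: str
    n_positive: int
    n_total: int

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_total


@dataclass(frozen=True)
class ProfileDistribution:
    """Per-label counts among positive cases; percents over positives only."""

    group: str
    counts: dict[ProfileLabel, int] = field(default_factory=dict)

    @property
    def n_positive(self) -> int:
        return sum(
            n for label, n in self.counts.items() if label is not ProfileLabel.NEGATIVE
        )

    @property
    def percents(self) -> dict[ProfileLabel, float]:
        n = self.n_positive
        return {
            label: 100.0 * c / n
            for label, c in self.counts.items()
            if label is not ProfileLabel.NEGATIVE
        }


def incidence(calls: list[ProfileCall], group: str) -> IncidenceSummary:
    """Positive vs negative case counts for one group."""
    if not calls:
        raise ValueError(f"group {group!r} is empty")
    n_pos = sum(1 for c in calls if c.label is not ProfileLabel.NEGATIVE)
    return IncidenceSummary(group=group, n_positive=n_pos, n_total=len(calls))


def profile_distribution(calls: list[ProfileCall], group: str) -> ProfileDistribution:
    """Label counts among the group's positive cases."""
    if not calls:
        raise ValueError(f"group {group!r} is empty")
    counts: dict[ProfileLabel, int] = {}
    for call in calls:
        counts[call.label] = counts.get(call.label, 0) + 1
    dist = ProfileDistribution(group=group, counts=counts)
    if dist.n_positive == 0:
        raise ValueError(f"group {group!r} has no positive cases")
    return dist


# ---------------------------------------------------------------------------
# Fisher exact


def _log_hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(A = a) under the hypergeometric with margins (row1,row2)x(col1,.)."""
    n = row1 + row2
    lg = math.lgamma
    return (
        lg(row1 + 1)
        - lg(a + 1)
        - lg(row1 - a + 1)
        + lg(row2 + 1)
        - lg(col1 - a + 1)
        - lg(row2 - col1 + a + 1)
        - (lg(n + 1) - lg(col1 + 1) - lg(n - col1 + 1))
    )


def fisher_exact_two_sided(
    table: ContingencyTable2x2, tie_rtol: float = FISHER_TIE_RTOL
) -> TestResult:
    """Two-sided Fisher exact p by enumeration over the support.

    p sums the hypergeometric point probabilities of every table with the
    observed margins whose probability is <= the observed table's, within a
    relative tie tolerance.  A zero margin yields p = 1 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2 = a + b, c + d
    col1 = a + c
    if 0 in (row1, row2, col1, table.b + table.d):
        return TestResult(TestMethod.FISHER_EXACT_TWO_SIDED, 1.0, statistic=None)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    log_obs = _log_hypergeom_pmf(a, row1, row2, col1)
    cutoff = log_obs + math.log1p(tie_rtol)
    p = 0.0
    excluded = False
    for k in range(lo, hi + 1):
        log_pk = _log_hypergeom_pmf(k, row1, row2, col1)
        if log_pk <= cutoff:
            p += math.exp(log_pk)
        else:
            excluded = True
    if not excluded:
        p = 1.0  # whole support included: the sum is exactly one
    # odds ratio as the conventional accompanying statistic
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(TestMethod.FISHER_EXACT_TWO_SIDED, min(p, 1.0), statistic=odds)


def paired_t_two_tail(pairs: list[tuple[float, float]]) -> TestResult:
    """Two-tailed paired t-test on (x, y) pairs; d = x - y.

    t = mean(d) / (sd(d)/sqrt(n)) with the n-1 sd denominator; p from the
    Student t distribution with n-1 degrees of freedom.
    """
    if len(pairs) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diffs = [x - y for x, y in pairs]
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    if var == 0.0:
        raise DegenerateVarianceError("paired differences have zero variance")
    t = mean / math.sqrt(var / n)
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), n - 1))
    return TestResult(TestMethod.PAIRED_T_TWO_TAIL, min(max(p, 5e-324), 1.0), statistic=t)


def compare_groups(
    dist_a: ProfileDistribution | IncidenceSummary,
    dist_b: ProfileDistribution | IncidenceSummary,
) -> tuple[ContingencyTable2x2, TestResult]:
    """2x2 (group x category) table and its two-sided Fisher exact test.

    For incidence summaries the categories are positive/negative; for
    profile distributions the two non-negative labels present (more than
    two defined categories must be collapsed upstream).
    """
    if isinstance(dist_a, IncidenceSummary) != isinstance(dist_b, IncidenceSummary):
        raise TypeError("cannot compare an incidence summary with a distribution")
    if isinstance(dist_a, IncidenceSummary):
        table = ContingencyTable2x2(
            dist_a.n_positive,
            dist_a.n_total - dist_a.n_positive,
            dist_b.n_positive,
            dist_b.n_total - dist_b.n_positive,
        )
    else:
        labels = sorted(
            {
                label
                for dist in (dist_a, dist_b)
                for label in dist.counts
                if label is not ProfileLabel.NEGATIVE
            },
            key=lambda l: l.value,
        )
        if len(labels) > 2:
            raise ValueError(f"more than two categories: {[l.value for l in labels]}")
        if len(labels) < 2:
            raise ValueError("need two categories to form a 2x2 table")
        table = ContingencyTable2x2(
            dist_a.counts.get(labels[0], 0),
            dist_a.counts.get(labels[1], 0),
            dist_b.counts.get(labels[0], 0),
            dist_b.counts.get(labels[1], 0),
        )
    return table, fisher_exact_two_sided(table)
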