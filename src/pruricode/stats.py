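"""Inferential statistics on responder counts and paired/unpaired samples.

Pearson's chi-squared on 2x2 tables (uncorrected -- no Yates continuity
correction, matching the convention the reproduced responder statistics
were computed with), Fisher's exact test (two-sided, probability-mass
rule), the Wilcoxon matched-pairs signed-rank test (zero differences
dropped) and the Mann-Whitney U test (mid-ranks for ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from pruricode.psychophysics import ContingencyTable2x2
from pruricode.types import ValidationError


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: Optional[int] = None
    n: Optional[int] = None
    table: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def _check_margins(t: ContingencyTable2x2) -> None:
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if min(margins) == 0:
        raise ValidationError(
            "a margin of the 2x2 table is zero; the chi-squared statistic is "
            "undefined -- use fisher_exact_2x2 instead"
        )


def pearson_chi2_2x2(table: ContingencyTable2x2) -> TestResult:
    """Pearson chi-squared for a 2x2 table, df = 1, no continuity correction.

    statistic = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]
    """
    _check_margins(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    statistic = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(sps.chi2.sf(statistic, df=1))
    return TestResult(
        test_name="pearson_chi2",
        statistic=float(statistic),
        p_value=p,
        df=1,
        n=n,
        table=(a, b, c, d),
    )


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Fisher's exact test, two-sided by the probability-mass rule
    (summing hypergeometric probabilities <= that of the observed table)."""
    arr = table.as_array()
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        test_name="fisher_exact",
        statistic=float(odds) if np.isfinite(odds) else float("inf"),
        p_value=float(p),
        n=int(arr.sum()),
        table=(table.a, table.b, table.c, table.d),
    )


def wilcoxon_matched_pairs(
    x: Sequence[float], y: Sequence[float], *, min_n: int = 5
) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (classical treatment); tied absolute
    differences receive mid-ranks.  The exact null distribution is used
    for small samples without ties, the normal approximation otherwise.
    An all-zero difference vector is degenerate and reported as p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    d = x - y
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; test is degenerate", stacklevel=2)
        return TestResult("wilcoxon_matched_pairs", statistic=0.0, p_value=1.0, n=0)
    if len(nonzero) < min_n:
        raise ValidationError(
            f"only {len(nonzero)} non-zero differences; need at least {min_n}"
        )
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method="auto")
    return TestResult(
        "wilcoxon_matched_pairs",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=int(len(nonzero)),
    )


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U test for two independent samples (mid-ranks for ties;
    exact null when feasible, otherwise normal approximation with tie
    correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    if np.all(np.concatenate([x, y]) == x.flat[0]):
        # one big tie group: rank variance is zero, the test is degenerate
        return TestResult(
            "mann_whitney_u",
            statistic=float(len(x) * len(y) / 2.0),
            p_value=1.0,
            n=int(len(x) + len(y)),
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult(
        "mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=int(len(x) + len(y)),
    )


def format_statistic(value: float, decimals: int = 2) -> float:
    """Round to the reporting precision used for printed statistics."""
    return round(value, decimals)
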