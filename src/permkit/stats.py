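"""Paired and two-sample comparisons with the significance-star convention.

Replicate-level metrics (Papp, recovery) are compared with Student's t-test
between groups (directions, doses) and a paired t-test within groups
(before vs after deconjugation on matched wells).  Stars encode p < 0.05 /
0.01 / 0.001 as * / ** / ***.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult", "DeconjugationComparison",
    "group_compare", "compare_deconjugation", "significance_stars",
]

ALPHA_LEVELS = (0.05, 0.01, 0.001)


def significance_stars(p: "float | None",
                       alphas: Sequence[float] = ALPHA_LEVELS) -> str:
    """Map a p-value to the star annotation: * / ** / *** at 0.05/0.01/0.001."""
    if p is None or not np.isfinite(p):
        return ""
    stars = sum(p < a for a in alphas)
    return "*" * stars


@dataclass(frozen=True)
class TestResult:
    statistic: "float | None"
    p_value: "float | None"
    evaluable: bool
    note: str = ""

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value) if self.evaluable else ""


@dataclass(frozen=True)
class DeconjugationComparison:
    """Matched before/after summary for one metric (papp or recovery)."""

    metric: str
    before_mean: float
    after_mean: float
    fold: "float | None"          # after / before
    test: TestResult

    @property
    def paired_t_p(self) -> "float | None":
        return self.test.p_value


def group_compare(x: Sequence[float], y: Sequence[float],
                  welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test between independent groups.

    Equal-variance Student form by default; Welch via *welch*.  Fewer than
    two values in either group → not evaluable.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        return TestResult(None, None, False, "need >= 2 replicates per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, 1.0, True, "identical constant groups")
        return TestResult(None, None, False, "zero variance, different means")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(float(t), float(p), True)


def paired_compare(before: Sequence[float],
                   after: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on matched replicates."""
    b = np.asarray(list(before), dtype=float)
    a = np.asarray(list(after), dtype=float)
    if len(b) != len(a):
        raise ValueError("paired comparison needs equal-length lists")
    if len(b) < 2:
        return TestResult(None, None, False, "need >= 2 matched replicates")
    d = a - b
    if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
        # all differences exactly zero: no variance, t undefined
        return TestResult(None, None, False, "zero-variance differences")
    t, p = sps.ttest_rel(a, b)
    if not np.isfinite(t):
        return TestResult(None, None, False, "degenerate differences")
    return TestResult(float(t), float(p), True)


def compare_deconjugation(before: Sequence[float], after: Sequence[float],
                          metric: str = "papp") -> DeconjugationComparison:
    """Matched before/after-deconjugation comparison.

    Fold change is the ratio of means (after/before, not available when the
    before-mean is ≤ 0); significance from the paired two-sided t-test.
    """
    b = np.asarray(list(before), dtype=float)
    a = np.asarray(list(after), dtype=float)
    if len(b) != len(a):
        raise ValueError("before/after must be matched, equal-length lists")
    if len(b) == 0:
        return DeconjugationComparison(
            metric=metric, before_mean=float("nan"), after_mean=float("nan"),
            fold=None, test=TestResult(None, None, False, "no matched pairs"))
    mb, ma = float(np.mean(b)), float(np.mean(a))
    fold = ma / mb if mb > 0 else None
    return DeconjugationComparison(
        metric=metric, before_mean=mb, after_mean=ma, fold=fold,
        test=paired_compare(b, a),
    )
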