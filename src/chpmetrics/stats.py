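"""The statistical battery: one-way ANOVA and t-tests at alpha = 0.05.

Sequence comparisons are run as one-way ANOVA followed by uncorrected post
hoc pairwise t-tests; signed volume errors are tested against zero with
one-sample t-tests, and the two non-contrast sequences are compared with a
two-sample t-test.  Two-sample tests default to the pooled (equal-variance)
form, the classical post hoc companion of one-way ANOVA; Welch and paired
modes are available for sensitivity analysis, as is an optional Bonferroni
correction (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "one_way_anova", "t_test", "posthoc_pairwise_t"]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    groups: tuple[str, ...]
    alpha: float = ALPHA_DEFAULT

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value out of [0,1]: {self.p_value}")


def one_way_anova(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> TestResult:
    """F test of equal group means; df = (k−1, N−k)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # identical constant groups: no variance anywhere, F = 0 by convention
        stat, p = 0.0, 1.0
    else:
        res = sps.f_oneway(*arrays)
        stat, p = float(res.statistic), float(res.pvalue)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    labels = tuple(labels) if labels else tuple(f"group{i}" for i in range(k))
    return TestResult(
        name="one-way ANOVA",
        statistic=stat,
        df=(float(k - 1), float(n_total - k)),
        p_value=p,
        groups=labels,
        alpha=alpha,
    )


def t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float] | None = None,
    mode: str = "one-sample",
    mu0: float = 0.0,
    equal_var: bool = True,
    alpha: float = ALPHA_DEFAULT,
    labels: tuple[str, ...] | None = None,
) -> TestResult:
    """Two-tailed t-test in one of three modes.

    ``one-sample`` tests mean(sample_a) against ``mu0``; ``two-sample``
    compares independent samples (pooled by default, Welch if
    ``equal_var=False``); ``paired`` tests the element-wise differences.
    Zero-variance inputs raise rather than returning a silent p value.
    """
    a = np.asarray(sample_a, dtype=float)
    if mode == "one-sample":
        if a.size < 2:
            raise ValueError("one-sample t-test needs >= 2 values")
        if np.ptp(a) == 0:
            raise ValueError("zero variance in sample")
        res = sps.ttest_1samp(a, popmean=mu0)
        df = float(a.size - 1)
        groups = labels or ("sample", f"mu0={mu0:g}")
    elif mode in ("two-sample", "paired"):
        if sample_b is None:
            raise ValueError(f"{mode} t-test needs a second sample")
        b = np.asarray(sample_b, dtype=float)
        if mode == "paired":
            if a.size != b.size:
                raise ValueError("paired t-test needs equal lengths")
            if np.ptp(a - b) == 0:
                raise ValueError("zero variance in paired differences")
            res = sps.ttest_rel(a, b)
            df = float(a.size - 1)
        else:
            if a.size < 2 or b.size < 2:
                raise ValueError("two-sample t-test needs >= 2 values per group")
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                raise ValueError("zero variance in both samples")
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            df = float(res.df)
        groups = labels or ("A", "B")
    else:
        raise ValueError(f"unknown t-test mode {mode!r}")
    return TestResult(
        name=f"{mode} t-test",
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        groups=tuple(groups),
        alpha=alpha,
    )


def posthoc_pairwise_t(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str],
    paired: bool = False,
    equal_var: bool = True,
    bonferroni: bool = False,
    alpha: float = ALPHA_DEFAULT,
) -> list[TestResult]:
    """All pairwise t-tests following an ANOVA; uncorrected by default."""
    if len(groups) != len(labels):
        raise ValueError("labels must match groups")
    results = []
    n_pairs = len(list(combinations(range(len(groups)), 2)))
    for i, j in combinations(range(len(groups)), 2):
        r = t_test(
            groups[i],
            groups[j],
            mode="paired" if paired else "two-sample",
            equal_var=equal_var,
            alpha=alpha,
            labels=(str(labels[i]), str(labels[j])),
        )
        if bonferroni:
            r = TestResult(
                name=r.name + " (Bonferroni)",
                statistic=r.statistic,
                df=r.df,
                p_value=min(1.0, r.p_value * n_pairs),
                groups=r.groups,
                alpha=alpha,
            )
        results.append(r)
    return results
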