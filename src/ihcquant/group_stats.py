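"""Two-group comparison of per-sample H-scores.

Implements the statistics conventionally reported for small IHC cohorts:
per-group mean and standard error of the mean (SEM, n-1 denominator), a
two-sided unpaired t-test (pooled-variance Student test by default,
Welch optional), and the fold-change between group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: str
    h_score: float


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    fold_change: float | None  # mean_a / mean_b; None when mean_b == 0
    equal_var: bool = True


def summarize_group(
    samples: Iterable[SampleRecord], group: str
) -> tuple[int, float, float | None]:
    """Return (n, mean, SEM) of the H-scores in one group.

    SEM is the sample standard deviation (n-1 denominator) over sqrt(n);
    it is undefined (None) for a single-sample group.

    Raises
    ------
    ValueError
        If the group is empty.
    """
    values = np.array([s.h_score for s in samples if s.group == group], dtype=float)
    if values.size == 0:
        raise ValueError(f"group {group!r} has no samples")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else None
    return int(values.size), mean, sem


def compare_groups(
    samples: Sequence[SampleRecord],
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided unpaired t-test plus fold-change between two groups.

    Parameters
    ----------
    samples : sequence of SampleRecord; records in other groups are ignored.
    group_a, group_b : the two labels to compare. Fold-change is
        mean(group_a) / mean(group_b), i.e. group_a is the reference.
    equal_var : pooled-variance Student test when True (default), Welch
        when False.

    Raises
    ------
    ValueError
        If either group has fewer than 2 samples or any score is not finite.
    """
    a = np.array([s.h_score for s in samples if s.group == group_a], dtype=float)
    b = np.array([s.h_score for s in samples if s.group == group_b], dtype=float)
    for label, arr in ((group_a, a), (group_b, b)):
        if arr.size < 2:
            raise ValueError(f"group {label!r} has {arr.size} sample(s); need at least 2")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {label!r} contains non-finite H-scores")

    n_a, mean_a, sem_a = summarize_group(
        [SampleRecord("", group_a, v) for v in a], group_a
    )
    n_b, mean_b, sem_b = summarize_group(
        [SampleRecord("", group_b, v) for v in b], group_b
    )

    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate zero-variance case (e.g. noiseless synthetic cohorts)
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, mean_a - mean_b), 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)

    fold = mean_a / mean_b if mean_b != 0.0 else None
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=n_a,
        n_b=n_b,
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=sem_a,
        sem_b=sem_b,
        t_statistic=t,
        p_value=p,
        fold_change=fold,
        equal_var=equal_var,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values for a family of comparisons.

    Only relevant when several group comparisons are run together; a
    single comparison is reported unadjusted.
    """
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return []
    return list(multipletests(p_values, method="holm")[1])


def format_comparison(c: GroupComparison) -> str:
    """Human-readable report with conventional rounding.

    Means and SEM to 2 decimals, fold-change to 1 decimal, p to 4
    significant figures.
    """
    fold = (
        f"{c.fold_change:.1f}-fold ({c.group_a}/{c.group_b})"
        if c.fold_change is not None
        else f"undefined (mean of {c.group_b} is 0)"
    )
    flavor = "pooled Student" if c.equal_var else "Welch"
    lines = [
        f"Group {c.group_a}: n = {c.n_a}, mean H-score = {c.mean_a:.2f} "
        f"(SEM {c.sem_a:.2f})",
        f"Group {c.group_b}: n = {c.n_b}, mean H-score = {c.mean_b:.2f} "
        f"(SEM {c.sem_b:.2f})",
        f"Fold-change: {fold}",
        f"Two-sided unpaired t-test ({flavor}): t = {c.t_statistic:.4g}, "
        f"p = {c.p_value:.4g}",
    ]
    return "\n".join(lines)
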