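"""Editing-activity distribution statistics and positional composition tests.

Summarizes per-sgRNA genome-editing activities (box plots with Tukey
outlier fences) and tests, position by position along the protospacer,
whether constructs with A/T versus C/G at that position differ in mean
activity. The two-sample comparison is a two-tailed unpaired t-test; an
F test on the group variances (alpha = 0.05) decides between the
classical Student test and Welch's correction. Per-position p-values are
reported raw, without multiple-testing correction, and compared against
the 0.05 line.

Quartiles use linear interpolation (type 7), so fences are reproducible
bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ActivityRecord:
    """One construct's measured editing activity with its protospacer."""

    sgrna_id: str
    protospacer: str
    activity: float  # fraction in [0, 1]

    def __post_init__(self):
        if not 0.0 <= self.activity <= 1.0:
            raise ValueError("activity must lie in [0, 1]")


@dataclass(frozen=True)
class PositionalTest:
    position: int
    mean_at: float
    mean_cg: float
    n_at: int
    n_cg: int
    variance_p: float
    test_type: str      # 'student' or 'welch'
    p_value: float
    applicable: bool = True


def tukey_fences(values: Sequence[float]) -> tuple[float, float]:
    """(lower, upper) Tukey fences: Q1 - 1.5 IQR, Q3 + 1.5 IQR (type-7 quartiles)."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation = type 7
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def tukey_outliers(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, outliers) by the Tukey fences.

    With fewer than 4 values the quartiles are too unstable to fence on:
    nothing is filtered and a warning is issued.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn("n < 4: Tukey filter not applied", stacklevel=2)
        return v, np.array([], dtype=float)
    lo, hi = tukey_fences(v)
    mask = (v >= lo) & (v <= hi)
    return v[mask], v[~mask]


def f_test_variances(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed F test p-value for equality of two sample variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == vb == 0:
        return 1.0
    # convention: larger variance in the numerator
    if va >= vb:
        f, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = 2.0 * stats.f.sf(f, dfn, dfd)
    return min(p, 1.0)


def positional_test(
    records: Iterable[ActivityRecord], position: int, alpha: float = 0.05
) -> PositionalTest:
    """Compare activities of A/T- vs C/G-bearing constructs at one position.

    ``position`` is 1-based along the protospacer. The F test on the group
    variances (at ``alpha``) gates the choice between Student's and
    Welch's two-tailed t-test. With an empty group (or n < 2 in either)
    the test is not applicable and recorded as such.
    """
    at, cg = [], []
    for r in records:
        base = r.protospacer[position - 1]
        (at if base in "AT" else cg).append(r.activity)
    if len(at) < 2 or len(cg) < 2:
        return PositionalTest(
            position=position,
            mean_at=float(np.mean(at)) if at else float("nan"),
            mean_cg=float(np.mean(cg)) if cg else float("nan"),
            n_at=len(at), n_cg=len(cg), variance_p=float("nan"),
            test_type="none", p_value=float("nan"), applicable=False,
        )
    var_p = f_test_variances(at, cg)
    welch = var_p < alpha
    t = stats.ttest_ind(at, cg, equal_var=not welch)
    return PositionalTest(
        position=position,
        mean_at=float(np.mean(at)), mean_cg=float(np.mean(cg)),
        n_at=len(at), n_cg=len(cg), variance_p=var_p,
        test_type="welch" if welch else "student",
        p_value=float(t.pvalue),
    )


def positional_scan(
    records: Sequence[ActivityRecord], positions: Iterable[int] = range(1, 21)
) -> list[PositionalTest]:
    """Run the positional A/T-vs-C/G test across protospacer positions."""
    return [positional_test(records, p) for p in positions]


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Five-number box-plot summary with Tukey fences.

    Whiskers extend to the most extreme data points inside the fences;
    points beyond the fences are outliers. A single value collapses the
    whole summary onto it.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    lo, hi = tukey_fences(v)
    inside = v[(v >= lo) & (v <= hi)]
    out = v[(v < lo) | (v > hi)]
    return BoxplotSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=tuple(sorted(out.tolist())),
    )


def threshold_fraction(
    activities: Iterable[float], threshold: float = 0.20
) -> tuple[int, float]:
    """Number and fraction of activities strictly above the threshold."""
    v = list(activities)
    n_above = sum(a > threshold for a in v)
    return n_above, (n_above / len(v) if v else 0.0)
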