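"""Welch two-sample comparison of population fractions across conditions.

Replicate closed-fraction (peak-area) estimates from separate experiments
are compared with the unpaired two-tailed t-test with Welch's correction:
t = (m1-m2)/sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite degrees of
freedom. p-values map onto the conventional significance ladder
n.s. (p >= 0.05), * (p < 0.05), ** (p < 0.005), *** (p < 0.0005); a p
exactly at a threshold takes the less significant label. No
multiple-testing correction is applied: comparisons are reported per pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientReplicatesError

SIGNIFICANCE_THRESHOLDS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


@dataclass
class ComparisonResult:
    """Welch test outcome for one condition pair."""

    t: float
    df: float
    p: float
    label: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def significance_label(p: float) -> str:
    """Significance code for a two-tailed p-value (strict '<' at thresholds)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    for thresh, label in SIGNIFICANCE_THRESHOLDS:
        if p < thresh:
            return label
    return "n.s."


def welch_t_test(group_a, group_b) -> ComparisonResult:
    """Unpaired two-tailed t-test with Welch's correction.

    Raises
    ------
    InsufficientReplicatesError
        Fewer than two values in either group.

    Notes
    -----
    Two zero-variance groups with equal means return t=0, p=1 by
    convention; with unequal means, p is reported as the smallest positive
    float.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 replicates per group, got {n1} and {n2}"
        )
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if m1 == m2:
            t, df, p = 0.0, float(n1 + n2 - 2), 1.0
        else:
            t = float("inf") if m1 > m2 else float("-inf")
            df = float(n1 + n2 - 2)
            p = float(np.finfo(float).tiny)
    else:
        t = float((m1 - m2) / np.sqrt(se2))
        df = float(se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)))
        p = float(2.0 * stats.t.sf(abs(t), df))
        p = max(p, float(np.finfo(float).tiny))
    return ComparisonResult(
        t=t, df=df, p=p, label=significance_label(p),
        mean_a=float(m1), mean_b=float(m2), n_a=n1, n_b=n2,
    )
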