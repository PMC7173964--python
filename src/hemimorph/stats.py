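"""Hemilineage-level statistics.

For the seven dual-hemilineage lineages, the Notch-off (B) side is compared
against the Notch-on (A) side on three readouts of the main-trajectory
length statistic:

* per-lineage mean length: one-tailed two-sample test (B > A), Welch's form
  by default, at alpha = 0.01;
* coefficient of variation of length across each hemilineage's types:
  one-tailed paired t-test over lineages (B > A);
* number of topology classes per hemilineage: the same paired t-test.

No multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .skeleton import coefficient_of_variation

__all__ = [
    "LineagePair",
    "TestResult",
    "lineage_length_test",
    "paired_one_tailed_t",
    "cv_paired_test",
    "class_count_paired_test",
]

logger = logging.getLogger(__name__)


@dataclass
class LineagePair:
    """A/B measurements for one dual-hemilineage lineage."""

    lineage: str
    A_lengths: list[float]
    B_lengths: list[float]
    A_classes: Optional[int] = None  # distinct topology classes on the A side
    B_classes: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.A_lengths or not self.B_lengths:
            raise ValueError(f"{self.lineage}: both hemilineages need measurements")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    tail: str  # alternative hypothesis, e.g. "B > A"
    n: tuple[int, ...]
    significant: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def lineage_length_test(
    pair: LineagePair,
    alpha: float = 0.01,
    method: str = "welch",
) -> TestResult:
    """One-tailed two-sample test of mean main-trajectory length, B > A.

    ``method``: ``welch`` (unequal-variance t, default), ``pooled``
    (equal-variance t), or ``mannwhitney``.  Significant iff p < alpha.
    """
    a = np.asarray(pair.A_lengths, dtype=float)
    b = np.asarray(pair.B_lengths, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"{pair.lineage}: need >= 2 lengths per side")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        logger.info("%s: degenerate variance with equal means; p = 0.5", pair.lineage)
        return TestResult(0.0, 0.5, "B > A", (len(a), len(b)), significant=False)
    if method == "welch":
        stat, p = sps.ttest_ind(b, a, equal_var=False, alternative="greater")
    elif method == "pooled":
        stat, p = sps.ttest_ind(b, a, equal_var=True, alternative="greater")
    elif method == "mannwhitney":
        stat, p = sps.mannwhitneyu(b, a, alternative="greater")
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        float(stat), float(p), "B > A", (len(a), len(b)), significant=bool(p < alpha)
    )


def paired_one_tailed_t(
    values_A: Sequence[float],
    values_B: Sequence[float],
) -> TestResult:
    """Paired one-tailed t-test on differences d = B - A, alternative mean d > 0.

    t = mean(d) / (sd(d) / sqrt(n)) with n - 1 degrees of freedom.  Zero
    variance of differences is handled exactly: p = 0.5 when all differences
    are zero, otherwise 0 or 1 by the sign of the common difference.
    """
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired samples must have equal length, {a.shape} vs {b.shape}")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult(0.0, 0.5, "B > A", (n,))
        p = 0.0 if d.mean() > 0 else 1.0
        logger.info("degenerate paired t: zero variance, non-zero mean; p = %g", p)
        return TestResult(math.inf if d.mean() > 0 else -math.inf, p, "B > A", (n,))
    t = d.mean() / (sd / math.sqrt(n))
    p = float(sps.t.sf(t, df=n - 1))
    return TestResult(float(t), p, "B > A", (n,))


def cv_paired_test(pairs: Sequence[LineagePair]) -> TestResult:
    """Paired one-tailed t on length coefficients of variation, B > A.

    The CV (sample-sd over mean) of the main-trajectory lengths is computed
    per hemilineage, then the A/B CVs are compared pairwise across lineages.
    """
    cv_a = [coefficient_of_variation(p.A_lengths) for p in pairs]
    cv_b = [coefficient_of_variation(p.B_lengths) for p in pairs]
    return paired_one_tailed_t(cv_a, cv_b)


def class_count_paired_test(pairs: Sequence[LineagePair]) -> TestResult:
    """Paired one-tailed t on topology-class counts per hemilineage, B > A."""
    missing = [p.lineage for p in pairs if p.A_classes is None or p.B_classes is None]
    if missing:
        raise ValueError(f"class counts missing for lineages: {missing}")
    return paired_one_tailed_t(
        [p.A_classes for p in pairs], [p.B_classes for p in pairs]
    )
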