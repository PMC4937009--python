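"""Group-comparison and summary statistics used for model validation.

The Mann-Whitney comparison reports the tie-corrected normal
approximation Z without continuity correction; confidence intervals on
group means use the normal 1.96 multiplier with each group's own n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    """Mean, dispersion and 95% normal confidence bounds of one group."""

    m: float
    sd: float
    se: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class RankTestResult:
    u: float           # Mann-Whitney U of the first sample
    zc: float          # |Z| under the tie-corrected normal approximation
    p_two_sided: float


def mann_whitney_z(x, y) -> RankTestResult:
    """Two-sample Mann-Whitney test with tie-corrected normal approximation.

    Midranks are used for ties; the variance carries the standard tie
    correction and no continuity correction is applied. ``zc`` is |Z|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u1 = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic)
    combined = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return RankTestResult(u=u1, zc=0.0, p_two_sided=1.0)
    z = (u1 - n1 * n2 / 2.0) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return RankTestResult(u=u1, zc=abs(z), p_two_sided=min(p, 1.0))


def summary(values) -> GroupSummary:
    """Mean, sample SD (n-1), SE = SD/sqrt(n) and normal 95% CI for the mean.

    A single observation yields NaN dispersion and bounds; an empty input
    is an error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("summary of an empty sample")
    m = float(arr.mean())
    if arr.size == 1:
        return GroupSummary(m=m, sd=math.nan, se=math.nan,
                            ci_low=math.nan, ci_high=math.nan, n=1)
    sd = float(arr.std(ddof=1))
    se = sd / math.sqrt(arr.size)
    return GroupSummary(
        m=m, sd=sd, se=se,
        ci_low=m - 1.96 * se, ci_high=m + 1.96 * se, n=int(arr.size),
    )


def toplis_check(n_training: int, n_descriptors: int) -> tuple[float, bool]:
    """Training-set-size to descriptor-count ratio; passes iff strictly > 5."""
    if n_descriptors < 1:
        raise ValueError("descriptor count must be positive")
    ratio = n_training / n_descriptors
    return ratio, ratio > 5
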