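"""Demographic comparison statistics for two-group cohort tables.

Chi-square with Yates continuity correction for 2×2 category tables
(gender, handedness) and a pooled-variance two-sample t computed from
published summary statistics (mean ± SD per group) for age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ContingencyTable2x2", "chi_square_yates", "summary_t"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) for group 1 and (c, d) for group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi_square_yates(
    table: ContingencyTable2x2, correction: bool = True
) -> tuple[float, float]:
    """Pearson chi-square on a 2×2 table, Yates-corrected by default, df=1.

    The continuity correction shrinks each |observed − expected| by 0.5
    (floored at 0), so the corrected statistic never exceeds the
    uncorrected one.  A zero row or column marginal makes the expected
    counts degenerate and raises.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal: expected counts undefined")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


def summary_t(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> tuple[float, float]:
    """Pooled-variance two-sample t from summary statistics.

    df = n_a + n_b − 2, two-sided p.  Used when only published group
    means and SDs are available (raw values undeposited); results are
    approximate to the rounding of the printed summaries.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    return float(res.statistic), float(res.pvalue)
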