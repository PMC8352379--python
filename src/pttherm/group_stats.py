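"""Group comparisons and small study utilities.

Endpoints (Tmax, thermal time constant) are compared between nanorod-injected
and saline-injected arms with the classical two-tailed Student t-test (pooled
variance, n1 + n2 - 2 degrees of freedom); Welch's unequal-variance variant
is available behind a flag. No multiple-testing correction is applied.
Significance defaults to alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    significant: bool
    alpha: float = 0.05


@dataclass
class TumorMeasurement:
    """Caliper measurement of an ellipsoid-approximated tumor.

    L (mm) is the longest dimension, W (mm) perpendicular to it; the volume
    follows the modified-ellipsoid formula V = L * W^2 / 2 (mm^3).
    """

    length_l: float
    width_w: float

    def __post_init__(self) -> None:
        tumor_volume(self.length_l, self.width_w)  # validates ordering/positivity

    @property
    def volume(self) -> float:
        return tumor_volume(self.length_l, self.width_w)


def students_t_test(group_a, group_b, alpha: float = 0.05, welch: bool = False) -> TTestResult:
    """Two-tailed two-sample t-test (pooled variance unless welch=True).

    Degenerate case: zero pooled variance with equal means gives t = 0,
    p = 1; zero variance with unequal means raises (the statistic is
    undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_var = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return TTestResult(t_stat=0.0, df=len(a) + len(b) - 2, p_value=1.0,
                               significant=False, alpha=alpha)
        raise ValueError("zero pooled variance with unequal means: t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if welch else float(len(a) + len(b) - 2)
    p = float(res.pvalue)
    return TTestResult(t_stat=float(res.statistic), df=df, p_value=p,
                       significant=p < alpha, alpha=alpha)


def tumor_volume(length_l: float, width_w: float) -> float:
    """Tumor volume V = L * W^2 / 2 in mm^3 from caliper length and width (mm)."""
    if width_w <= 0:
        raise ValueError("width must be positive")
    if width_w > length_l:
        raise ValueError(
            f"W ({width_w} mm) exceeds L ({length_l} mm); L is defined as the longest "
            "dimension — swap the arguments"
        )
    return length_l * width_w ** 2 / 2.0
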