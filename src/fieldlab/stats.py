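"""Group-comparison statistics: Welch's unequal-variance two-sample t-test,
single-outlier Grubbs screening, mean ± SE summaries, and power of the
two-sided two-sample t-test.

Welch's test is computed from summary statistics
``t = (m_a − m_b) / sqrt(se_a² + se_b²)`` with Welch–Satterthwaite fractional
degrees of freedom, so it accepts either raw samples or published
(n, mean, se) summaries.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import GroupComparison, GroupSummary
from .errors import DegenerateStatisticsError, ValidationError


def _summarize(values: Sequence[float], units: str = "") -> GroupSummary:
    return GroupSummary.from_values(values, units=units)


def welch_t_from_summary(a: GroupSummary, b: GroupSummary,
                         label_a: str = "a", label_b: str = "b",
                         values_a=None, values_b=None) -> GroupComparison:
    """Welch's t-test from (n, mean, se) group summaries."""
    if a.n < 2 or b.n < 2:
        raise DegenerateStatisticsError("each group needs n >= 2")
    va, vb = a.se ** 2, b.se ** 2  # variances of the means
    if va + vb == 0:
        if a.mean == b.mean:
            t, df, p = 0.0, float(a.n + b.n - 2), 1.0
            return GroupComparison(label_a, label_b, a.mean, a.se, a.n,
                                   b.mean, b.se, b.n, t, df, p,
                                   values_a=values_a, values_b=values_b)
        raise DegenerateStatisticsError(
            "zero variance in both groups with unequal means")
    t = (a.mean - b.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return GroupComparison(label_a, label_b, a.mean, a.se, a.n,
                           b.mean, b.se, b.n, t, df, p,
                           values_a=values_a, values_b=values_b)


def welch_t(values_a: Sequence[float], values_b: Sequence[float],
            label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-tailed unpaired t-test assuming unequal variance (Welch)."""
    va = [float(x) for x in values_a]
    vb = [float(x) for x in values_b]
    return welch_t_from_summary(_summarize(va), _summarize(vb),
                                label_a, label_b, values_a=va, values_b=vb)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t-quantile formula."""
    if n < 3:
        raise ValidationError("Grubbs test requires n >= 3")
    t2 = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / math.sqrt(n) * math.sqrt(t2 / (n - 2 + t2))


def grubbs_test(values: Sequence[float], alpha: float = 0.05):
    """Single-pass two-sided Grubbs outlier test.

    Returns ``(outlier_index | None, G, G_crit)``; at most one value is
    flagged per call. With zero spread nothing is flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValidationError("Grubbs test requires n >= 3")
    sd = float(v.std(ddof=1))
    g_crit = grubbs_critical(v.size, alpha)
    if sd == 0:
        return None, 0.0, g_crit
    dev = np.abs(v - v.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    return (idx if g > g_crit else None), g, g_crit


def power_two_sample_t(effect_size: float, n_per_group: int,
                       alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test via the noncentral t.

    ``effect_size`` is the standardized mean difference d; equal group sizes.
    """
    if effect_size < 0:
        raise ValidationError("effect_size must be >= 0")
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    df = 2 * n_per_group - 2
    ncp = effect_size * math.sqrt(n_per_group / 2.0)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   label_a: str = "a", label_b: str = "b",
                   alpha: float = 0.05,
                   grubbs_screen: bool = True,
                   grubbs_alpha: float = 0.05) -> GroupComparison:
    """Full group-comparison procedure: optional per-group Grubbs screen
    (one outlier maximum per group), then Welch's test.

    Removed indices refer to the original input ordering and are recorded on
    the result.
    """
    va = list(map(float, values_a))
    vb = list(map(float, values_b))
    removed_a: list[int] = []
    removed_b: list[int] = []
    if grubbs_screen:
        if len(va) >= 3:
            idx, _, _ = grubbs_test(va, alpha=grubbs_alpha)
            if idx is not None:
                removed_a.append(idx)
                va = [x for i, x in enumerate(va) if i != idx]
        if len(vb) >= 3:
            idx, _, _ = grubbs_test(vb, alpha=grubbs_alpha)
            if idx is not None:
                removed_b.append(idx)
                vb = [x for i, x in enumerate(vb) if i != idx]
    if len(va) < 2 or len(vb) < 2:
        raise DegenerateStatisticsError("a group has n < 2 after outlier removal")
    cmp = welch_t(va, vb, label_a, label_b)
    cmp.removed_a = removed_a
    cmp.removed_b = removed_b
    return cmp
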