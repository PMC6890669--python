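"""Group comparisons of monolayer mechanics metrics.

The comparison layer mirrors how stiffness/treatment effects on
traction metrics are usually reported: samples (strain energies pooled
over time points and fields of view) are normalized to the mean of a
vehicle-control group for display, medians of two conditions are
compared with the Wilcoxon rank-sum (Mann-Whitney) test, and effect
sizes are summarized as fold changes of medians with bootstrap
confidence intervals.

The test is exact (full enumeration of rank assignments) when the
pooled sample is small (n_a + n_b <= 16) and tie-free, and otherwise
uses the normal approximation with tie correction and continuity
correction.  Normalization is a display convention: tests run on the
raw values, and the rank-sum test is in any case invariant under the
common positive scaling that normalization applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "normalize_to_control",
    "rank_sum_test",
    "fold_change_summary",
    "compare_groups",
]

EXACT_MAX_TOTAL_N = 16


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group metric comparison."""

    group_labels: tuple[str, str]
    n: tuple[int, int]
    normalization_baseline: float
    statistic: float
    p_value: float
    fold_change: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def normalize_to_control(
    samples_by_group: Mapping[str, Sequence[float]], control_group: str
) -> dict[str, np.ndarray]:
    """Divide every value by the mean of the control group.

    After normalization the control group's mean is exactly 1; the
    transformation is invariant to a common rescaling of all raw values.
    """
    if control_group not in samples_by_group:
        raise KeyError(f"control group {control_group!r} not present")
    control = np.asarray(samples_by_group[control_group], dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    baseline = control.mean()
    if baseline == 0:
        raise ZeroDivisionError("control group mean is zero; cannot normalize")
    return {
        k: np.asarray(v, dtype=float) / baseline for k, v in samples_by_group.items()
    }


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test of two samples.

    Returns (U statistic of sample ``a``, p-value).  Exact null
    enumeration when the pooled size is at most 16 with no ties;
    normal approximation with tie and continuity corrections otherwise.
    Each sample must contain at least 3 values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("rank_sum_test requires at least 3 values per group")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}.get(
        alternative, alternative
    )
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and pooled.size <= EXACT_MAX_TOTAL_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alt, method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fold_change_summary(
    samples_by_group: Mapping[str, Sequence[float]],
    baseline_group: str,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> "pd.DataFrame":
    """Median fold change of every group against a baseline group.

    Per group: median / baseline-median, with a seeded bootstrap
    percentile confidence interval (independent resampling of both
    groups, ``n_boot`` replicates).
    """
    import pandas as pd

    if baseline_group not in samples_by_group:
        raise KeyError(f"baseline group {baseline_group!r} not present")
    base = np.asarray(samples_by_group[baseline_group], dtype=float)
    base_med = np.median(base)
    if base_med == 0:
        raise ZeroDivisionError("baseline median is zero; fold change undefined")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    rows = []
    for name, vals in samples_by_group.items():
        vals = np.asarray(vals, dtype=float)
        fc = np.median(vals) / base_med
        boot_g = np.median(
            rng.choice(vals, size=(n_boot, vals.size), replace=True), axis=1
        )
        boot_b = np.median(
            rng.choice(base, size=(n_boot, base.size), replace=True), axis=1
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            boot_fc = boot_g / boot_b
        lo, hi = np.quantile(boot_fc, [alpha, 1.0 - alpha])
        rows.append(
            {
                "group": name,
                "n": vals.size,
                "median": float(np.median(vals)),
                "fold_change": float(fc),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    samples_by_group: Mapping[str, Sequence[float]],
    group_a: str,
    group_b: str,
    control_group: str | None = None,
    alternative: str = "two_sided",
) -> GroupComparison:
    """Full two-group comparison: rank-sum test plus median fold change.

    ``control_group`` (default: ``group_a``) sets the normalization
    baseline recorded in the result; the test itself runs on raw values.
    """
    control = control_group if control_group is not None else group_a
    a = np.asarray(samples_by_group[group_a], dtype=float)
    b = np.asarray(samples_by_group[group_b], dtype=float)
    baseline = float(np.mean(np.asarray(samples_by_group[control], dtype=float)))
    stat, p = rank_sum_test(a, b, alternative=alternative)
    med_a = np.median(a)
    if med_a == 0:
        raise ZeroDivisionError("group_a median is zero; fold change undefined")
    return GroupComparison(
        group_labels=(group_a, group_b),
        n=(a.size, b.size),
        normalization_baseline=baseline,
        statistic=stat,
        p_value=p,
        fold_change=float(np.median(b) / med_a),
    )
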