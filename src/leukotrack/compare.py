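"""Group comparisons: unpaired t-tests between cohorts of per-track metrics
and paired t-tests on before/after region intensities.

Defaults mirror common practice in intravital imaging papers: two-sided
tests, Student's unpaired variant (Welch available behind a flag), and
significance stars at 0.05 / 0.01 / 0.001 / 0.0001. No multiple-testing
correction is applied; all comparisons are reported so users can adjust
externally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    MetricNotFoundError,
)
from .io import ClusterIntensityRecord

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Star convention: * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001."""
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass
class ComparisonResult:
    """Outcome of a two-group comparison."""

    group_names: tuple[str, str]
    n_per_group: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    test_name: str
    statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str
    mean_difference: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def _as_array(values: Sequence[float], name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < min_n:
        raise InsufficientDataError(f"group {name!r} needs >= {min_n} values, has {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InsufficientDataError(f"group {name!r} contains non-finite values")
    return arr


def compare_unpaired(values_a: Sequence[float], values_b: Sequence[float],
                     variant: str = "student",
                     names: tuple[str, str] = ("A", "B")) -> ComparisonResult:
    """Two-sided unpaired t-test; ``variant`` is ``student`` (pooled variance,
    the default) or ``welch``."""
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    a = _as_array(values_a, names[0], 2)
    b = _as_array(values_b, names[1], 2)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise DegenerateVarianceError("pooled variance is zero; t undefined")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    p = float(res.pvalue)
    return ComparisonResult(
        group_names=names, n_per_group=(a.size, b.size),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        test_name="unpaired-t" if variant == "student" else "welch-t",
        statistic=float(res.statistic), degrees_of_freedom=float(res.df),
        p_value=p, stars=significance_stars(p))


def compare_paired(records: Sequence[ClusterIntensityRecord] |
                   tuple[Sequence[float], Sequence[float]],
                   names: tuple[str, str] = ("before", "after"),
                   ci_level: float = 0.95) -> ComparisonResult:
    """Two-sided paired t-test on after − before differences.

    Accepts either region-intensity records or a ``(before, after)`` pair of
    sequences. Reports the mean difference and its t-based confidence
    interval. Identical pairs throughout give statistic 0 and p = 1 (a null
    result, not an error); a nonzero but constant difference has no variance
    to test against and raises :class:`DegenerateVarianceError`.
    """
    if isinstance(records, tuple) and len(records) == 2:
        before, after = (np.asarray(list(v), dtype=float) for v in records)
    else:
        recs = list(records)
        before = np.array([r.mfi_before for r in recs], dtype=float)
        after = np.array([r.mfi_after for r in recs], dtype=float)
    if before.size != after.size:
        raise InsufficientDataError("before/after must pair up one-to-one")
    if before.size < 2:
        raise InsufficientDataError("paired test needs >= 2 pairs")
    diffs = after - before
    n = diffs.size
    df = n - 1
    if diffs.std(ddof=1) == 0.0:
        if diffs[0] == 0.0:
            statistic, p, half = 0.0, 1.0, 0.0
        else:
            raise DegenerateVarianceError(
                "all pairwise differences identical and nonzero; t undefined")
    else:
        res = stats.ttest_rel(after, before)
        statistic, p = float(res.statistic), float(res.pvalue)
        half = float(stats.t.ppf(0.5 + ci_level / 2, df) * diffs.std(ddof=1) / np.sqrt(n))
    mean_diff = float(diffs.mean())
    return ComparisonResult(
        group_names=names, n_per_group=(n, n),
        means=(float(before.mean()), float(after.mean())),
        sds=(float(before.std(ddof=1)), float(after.std(ddof=1))),
        test_name="paired-t", statistic=statistic, degrees_of_freedom=float(df),
        p_value=p, stars=significance_stars(p),
        mean_difference=mean_diff, ci_low=mean_diff - half, ci_high=mean_diff + half)


def compare_epochs(stats_pre: pd.DataFrame, stats_post: pd.DataFrame,
                   metric: str = "mean_speed",
                   variant: str = "student") -> ComparisonResult:
    """Unpaired comparison of a per-track metric between epochs.

    Tracks before and after the drug are distinct samplings of the cell
    population (cells mobilize, enter or leave the field), so the epochs are
    compared unpaired.
    """
    for name, table in (("pre", stats_pre), ("post", stats_post)):
        if metric not in table.columns:
            raise MetricNotFoundError(f"metric {metric!r} not in {name} stats table")
    return compare_unpaired(stats_pre[metric].to_numpy(),
                            stats_post[metric].to_numpy(),
                            variant=variant, names=("pre", "post"))
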