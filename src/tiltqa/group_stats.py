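"""Normal-vs-abnormal cohort comparisons with the Wilcoxon rank-sum test.

Each per-patient metric (DSC, sDSC, MDA, absolute and signed mean-dose
difference) is compared between the normal- and abnormal-tilt groups,
per structure and per contour source, with a two-tailed Wilcoxon
rank-sum (Mann-Whitney U) test. P-values are exact (full enumeration of
rank assignments) when the combined sample size is at most 20 and the
pooled data carry no ties; otherwise the normal approximation with
tie-corrected variance and continuity correction is used. No
multiple-testing correction is applied: each (structure, source, metric)
combination is tested at raw p, mirroring per-organ/per-vendor QA
practice, and significance tiers are '*' for p < 0.05 and '**' for
p < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .neck_tilt import CohortStratification

__all__ = [
    "GroupTestResult",
    "rank_sum_test",
    "significance_tier",
    "compare_cohorts",
    "EXACT_MAX_N",
]

#: combined sample size up to which the exact null distribution is used
EXACT_MAX_N = 20


@dataclass(frozen=True)
class GroupTestResult:
    structure: str
    source: str
    metric: str
    n_normal: int
    n_abnormal: int
    median_normal: float
    median_abnormal: float
    median_diff: float  # abnormal - normal
    u_statistic: float
    p_value: float
    tier: str  # "ns" | "*" | "**" | "untestable"
    method: str = ""  # "exact" | "asymptotic" | ""


def rank_sum_test(x: Sequence[float], y: Sequence[float]):
    """Two-tailed Mann-Whitney U test.

    Returns ``(U, p)`` where U counts (x, y) pairs with x > y (ties as
    half), so swapping the samples maps U to ``n_x*n_y - U`` with the
    same p. Exact when ``n_x + n_y <= 20`` with no ties, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # all observations tied: no evidence of a location shift
        return float(x.size * y.size / 2.0), 1.0, "degenerate"
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), method


def significance_tier(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_cohorts(
    records: pd.DataFrame,
    stratification: CohortStratification,
    min_group_size: int = 2,
) -> List[GroupTestResult]:
    """Run one rank-sum test per (structure, source, metric).

    ``records`` is a long-form frame with columns ``patient``,
    ``structure``, ``source``, ``metric``, ``value`` and optionally
    ``usable`` (rows with ``usable == False`` — excluded dose records or
    missing contours — are dropped before testing). Every patient with a
    record must carry a stratification label. Groups smaller than
    ``min_group_size`` yield an 'untestable' result without a p-value.
    """
    required = {"patient", "structure", "source", "metric", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records frame lacks columns: {sorted(missing)}")
    df = records.copy()
    if "usable" in df.columns:
        df = df[df["usable"].astype(bool)]
    unlabelled = set(df["patient"]) - set(stratification.labels)
    if unlabelled:
        raise ValueError(f"patients without a tilt label: {sorted(unlabelled)}")
    df["group"] = df["patient"].map(stratification.labels)

    results: List[GroupTestResult] = []
    for (structure, source, metric), sub in df.groupby(
        ["structure", "source", "metric"], sort=True
    ):
        normal = sub.loc[sub["group"] == "normal", "value"].to_numpy(float)
        abnormal = sub.loc[sub["group"] == "abnormal", "value"].to_numpy(float)
        med_n = float(np.median(normal)) if normal.size else float("nan")
        med_a = float(np.median(abnormal)) if abnormal.size else float("nan")
        if normal.size < min_group_size or abnormal.size < min_group_size:
            results.append(
                GroupTestResult(
                    structure, source, metric,
                    int(normal.size), int(abnormal.size),
                    med_n, med_a, med_a - med_n,
                    float("nan"), float("nan"), "untestable", "",
                )
            )
            continue
        u, p, method = rank_sum_test(abnormal, normal)
        results.append(
            GroupTestResult(
                structure, source, metric,
                int(normal.size), int(abnormal.size),
                med_n, med_a, med_a - med_n,
                u, p, significance_tier(p), method,
            )
        )
    return results
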