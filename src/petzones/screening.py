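"""Univariate screening of radiomic features against response labels.

For every feature, zone, and response labeling (one per traditional PET
parameter) the two groups are compared with an independent-samples test:
Student's t (Welch variant) when both groups pass Shapiro-Wilk normality at
alpha = 0.05, otherwise the Mann-Whitney U test.  Significance is a
two-tailed p < 0.05 with no multiple-testing correction — a deliberate
replication choice, not a statistical endorsement.

A feature is *selected* in a zone when it is significant on at least three
of the four parameters, and *consistent across zones* when it is
significant on at least ``k`` parameters (default 1) in every zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .response import PARAMETERS

ALPHA = 0.05
TestName = Literal["t", "mann_whitney"]

__all__ = [
    "ALPHA",
    "ScreeningRecord",
    "SelectionResult",
    "GroupSummary",
    "select_test",
    "compare_groups",
    "screen_zone",
    "cross_zone",
    "group_summary",
]


@dataclass(frozen=True)
class ScreeningRecord:
    feature: str
    zone: int
    parameter: str
    test: str
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class SelectionResult:
    feature: str
    zone: int
    n_significant_params: int
    consistent_across_zones: bool = False

    @property
    def selected(self) -> bool:
        return self.n_significant_params >= 3


@dataclass(frozen=True)
class GroupSummary:
    feature: str
    zone: int
    median_responders: float
    iqr_responders: float
    median_nonresponders: float
    iqr_nonresponders: float

    @property
    def direction(self) -> str:
        if self.median_responders < self.median_nonresponders:
            return "responders_lower"
        if self.median_responders > self.median_nonresponders:
            return "responders_higher"
        return "tie"


def select_test(
    group_a: Sequence[float], group_b: Sequence[float], force_nonparametric: bool = False
) -> TestName:
    """Shapiro-Wilk gate: t-test iff both groups look normal at alpha 0.05."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if min(a.size, b.size) < 3:
        raise ValueError("each group needs at least 3 observations for the normality gate")
    if force_nonparametric:
        return "mann_whitney"
    for g in (a, b):
        if np.ptp(g) == 0:  # Shapiro-Wilk undefined for constant data
            return "mann_whitney"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(g).pvalue < ALPHA:
                return "mann_whitney"
    return "t"


def _mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    n = a.size + b.size
    has_ties = np.unique(np.concatenate([a, b])).size < n
    if n <= 16 and not has_ties:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    return float(
        stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float], test: TestName
) -> float:
    """Two-tailed p-value for the chosen test.

    Mann-Whitney uses exact enumeration for combined n <= 16 without ties
    and the tie-corrected normal approximation otherwise.  A t-test on two
    zero-variance groups falls back to Mann-Whitney with a warning.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if test == "t":
        if a.size < 2 or b.size < 2:
            raise ValueError("the t-test needs at least 2 observations per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                return 1.0
            warnings.warn("zero variance in both groups; falling back to Mann-Whitney")
            return _mann_whitney_p(a, b)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "mann_whitney":
        if a.size < 1 or b.size < 1:
            raise ValueError("Mann-Whitney needs at least 1 observation per group")
        return _mann_whitney_p(a, b)
    raise ValueError(f"unknown test {test!r}")


def screen_zone(
    feature_table: pd.DataFrame,
    labels: Dict[str, Sequence[bool]],
    zone: int,
    force_nonparametric: bool = False,
) -> Tuple[List[ScreeningRecord], List[SelectionResult]]:
    """Screen every feature column against the four per-parameter labelings.

    ``feature_table`` is patients x features; ``labels[param]`` is a boolean
    responder flag per patient (aligned with the table rows).  A degenerate
    parameter whose patients all share one label contributes non-significant
    results for every feature, with a warning.
    """
    records: List[ScreeningRecord] = []
    results: List[SelectionResult] = []
    masks = {}
    for p in PARAMETERS:
        flags = np.asarray(labels[p], bool)
        if flags.size != len(feature_table):
            raise ValueError(f"labels for {p} do not match the table ({flags.size} vs {len(feature_table)})")
        if flags.all() or not flags.any():
            warnings.warn(f"parameter {p}: all patients share one label; no test possible")
            masks[p] = None
        else:
            masks[p] = flags
    for feature in feature_table.columns:
        values = feature_table[feature].to_numpy(float)
        n_sig = 0
        for p in PARAMETERS:
            flags = masks[p]
            if flags is None:
                records.append(ScreeningRecord(feature, zone, p, "none", 1.0))
                continue
            a, b = values[flags], values[~flags]
            test = select_test(a, b, force_nonparametric=force_nonparametric)
            pval = compare_groups(a, b, test)
            records.append(ScreeningRecord(feature, zone, p, test, pval))
            n_sig += pval < ALPHA
        results.append(SelectionResult(feature, zone, n_sig))
    return records, results


def cross_zone(
    records_by_zone: Dict[int, Sequence[ScreeningRecord]],
    results_by_zone: Dict[int, Sequence[SelectionResult]],
    k: int = 1,
) -> Dict[int, List[SelectionResult]]:
    """Flag features significant on >= k parameters in every zone.

    Returns the per-zone selection results with ``consistent_across_zones``
    filled in.  The default k = 1 asks only that the feature separates the
    groups on some parameter in each of the three zones.
    """
    n_sig = {
        z: {}
        for z in records_by_zone
    }
    for z, recs in records_by_zone.items():
        for r in recs:
            n_sig[z][r.feature] = n_sig[z].get(r.feature, 0) + (r.significant)
    features = set.intersection(*(set(d) for d in n_sig.values()))
    consistent = {f for f in features if all(n_sig[z][f] >= k for z in n_sig)}
    out = {}
    for z, results in results_by_zone.items():
        out[z] = [
            SelectionResult(
                r.feature, r.zone, r.n_significant_params, r.feature in consistent
            )
            for r in results
        ]
    return out


def group_summary(
    feature: str, zone: int, values: Sequence[float], responder: Sequence[bool]
) -> GroupSummary:
    """Median and IQR (75th - 25th percentile, linear interpolation) per group."""
    v = np.asarray(values, float)
    flags = np.asarray(responder, bool)
    if not flags.any() or flags.all():
        raise ValueError("both groups need at least one patient")

    def med_iqr(x):
        q25, q50, q75 = np.percentile(x, [25, 50, 75])
        return float(q50), float(q75 - q25)

    mr, ir = med_iqr(v[flags])
    mn, inr = med_iqr(v[~flags])
    return GroupSummary(feature, zone, mr, ir, mn, inr)
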