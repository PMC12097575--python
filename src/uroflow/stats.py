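"""Cohort-level group comparisons.

Two-level factors (collection time, gender) are compared with a two-sided
Welch t-test; the three age groups with classical one-way ANOVA.  Every
test is reported at α = 0.05 with no multiple-testing correction (an
optional Benjamini–Hochberg switch is provided for users who want
family-wise control).  Replicates must be merged into one value per
sample before testing — they are technical repeats, not independent
observations.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError
from .gating import PRIMARY_CLASSES

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: Manifest columns usable as comparison factors, with their test.
FACTORS = {
    "collection_time": "t_two_sided",
    "gender": "t_two_sided",
    "age_group": "anova_one_way",
}

#: Per-sample quantities compared across groups.
DEFAULT_QUANTITIES = (
    ["total_concentration", "identified_fraction", "overall_mean_area"]
    + [f"conc_{c}" for c in PRIMARY_CLASSES]
    + [f"area_{c}" for c in PRIMARY_CLASSES]
)


@dataclasses.dataclass(frozen=True)
class TestResult:
    test: str  # "t_two_sided" or "anova_one_way"
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    quantity: str = ""
    comparison: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def t_test_two_sided(a: Sequence[float], b: Sequence[float], **meta) -> TestResult:
    """Two-sided Welch (unequal-variance) t-test."""
    a, b = _clean(a), _clean(b)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 finite values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult("t_two_sided", 0.0, 1.0, (len(a), len(b)), **meta)
        raise DegenerateDataError("both groups have zero variance")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("t_two_sided", float(stat), float(p), (len(a), len(b)), **meta)


def anova_one_way(groups: Sequence[Sequence[float]], **meta) -> TestResult:
    """Classical one-way ANOVA across two or more groups."""
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in cleaned):
        raise ValidationError("each group needs at least 2 finite values")
    if all(np.var(g) == 0 for g in cleaned):
        if len({float(np.mean(g)) for g in cleaned}) == 1:
            return TestResult(
                "anova_one_way", 0.0, 1.0, tuple(len(g) for g in cleaned), **meta
            )
        raise DegenerateDataError("zero within-group variance with unequal means")
    stat, p = sps.f_oneway(*cleaned)
    return TestResult(
        "anova_one_way", float(stat), float(p), tuple(len(g) for g in cleaned), **meta
    )


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    factor: str
    level: str
    quantity: str
    n: int
    mean: float
    se: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("group summary needs n >= 1")


def _summarize_groups(
    df: pd.DataFrame, factor: str, quantity: str
) -> list[GroupSummary]:
    out = []
    for level, sub in df.groupby(factor, observed=True):
        vals = _clean(sub[quantity])
        if len(vals) == 0:
            continue
        out.append(
            GroupSummary(
                factor=factor,
                level=str(level),
                quantity=quantity,
                n=len(vals),
                mean=float(np.mean(vals)),
                se=float(sps.sem(vals)) if len(vals) > 1 else 0.0,
                min=float(np.min(vals)),
                max=float(np.max(vals)),
            )
        )
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (step-up false-discovery-rate control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(ranked, 0, 1)
    return out


@dataclasses.dataclass
class CohortAnalysis:
    group_summaries: pd.DataFrame
    test_results: pd.DataFrame
    excluded_outliers: pd.DataFrame


def cohort_analysis(
    summaries: pd.DataFrame,
    manifest: pd.DataFrame,
    factors: Sequence[str] = tuple(FACTORS),
    quantities: Sequence[str] | None = None,
    pair_factors: bool = True,
    fdr: bool = False,
) -> CohortAnalysis:
    """Group summaries and hypothesis tests across cohort factors.

    Parameters
    ----------
    summaries
        Replicate-merged per-sample summary table (one row per sample),
        as produced by :func:`uroflow.quantify.summaries_to_frame`.
    manifest
        Sample manifest frame; joined on ``sample_id``.  Outlier-flagged
        participants are excluded from the baseline tables and returned
        separately.
    factors
        Manifest factors to compare (any of ``collection_time``,
        ``gender``, ``age_group``).
    pair_factors
        Also run each factor within the levels of every other requested
        factor (pair-correlation style subgroup comparisons).
    fdr
        Append Benjamini–Hochberg adjusted p-values.
    """
    for f in factors:
        if f not in FACTORS:
            raise ValidationError(f"unknown factor {f!r}; expected one of {list(FACTORS)}")
        if f not in manifest.columns:
            raise ValidationError(f"factor {f!r} absent from manifest")
    quantities = list(quantities or [q for q in DEFAULT_QUANTITIES if q in summaries.columns])
    merged = summaries.merge(
        manifest.drop_duplicates("sample_id"), on="sample_id", how="left"
    )
    outliers = merged.loc[merged["outlier_flag"].astype(bool)]
    base = merged.loc[~merged["outlier_flag"].astype(bool)]

    group_rows: list[GroupSummary] = []
    test_rows: list[TestResult] = []

    def run_factor(df: pd.DataFrame, factor: str, comparison: str) -> None:
        levels = [lv for lv, sub in df.groupby(factor, observed=True) if len(sub) >= 2]
        for quantity in quantities:
            group_rows.extend(_summarize_groups(df, factor, quantity))
        if len(levels) < 2:
            logger.info("skipping %s for %s: fewer than 2 usable levels",
                        factor, comparison or "cohort")
            return
        for quantity in quantities:
            groups = [
                _clean(df.loc[df[factor] == lv, quantity]) for lv in levels
            ]
            if any(len(g) < 2 for g in groups):
                continue
            try:
                if FACTORS[factor] == "t_two_sided" and len(groups) == 2:
                    res = t_test_two_sided(
                        groups[0], groups[1], quantity=quantity,
                        comparison=comparison or factor,
                    )
                else:
                    res = anova_one_way(
                        groups, quantity=quantity, comparison=comparison or factor
                    )
            except DegenerateDataError:
                continue
            test_rows.append(res)

    for factor in factors:
        run_factor(base, factor, factor)
    if pair_factors:
        for fa, fb in itertools.permutations(factors, 2):
            for level, sub in base.groupby(fa, observed=True):
                run_factor(sub, fb, f"{fb}|{fa}={level}")

    gs = pd.DataFrame([dataclasses.asdict(g) for g in group_rows])
    tr = pd.DataFrame([dataclasses.asdict(t) for t in test_rows])
    if len(tr):
        tr["significant"] = tr["p_value"] < ALPHA
        if fdr:
            tr["p_adjusted"] = benjamini_hochberg(tr["p_value"].to_numpy())
    return CohortAnalysis(group_summaries=gs, test_results=tr, excluded_outliers=outliers)
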