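"""Statistics linking simulated bilayer features to delivery readouts.

Pearson correlation with a least-squares line is the primary
statistic, reported for the overall trend, per amine stratum, and for
rule-defined subsets such as formulations with mean CPP > 1 (the
theoretical transition to negative curvature).  Stable-vs-unstable
formulation groups are compared with rank-based two-sample tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "UndefinedCorrelationError",
    "correlate_feature_delivery",
    "compare_groups",
    "build_report",
    "SUBSET_RULES",
]


class UndefinedCorrelationError(ValueError):
    """Zero variance in one of the correlated columns."""


@dataclass
class CorrelationResult:
    feature_name: str
    stratum: str  # "overall" or the stratum label
    subset_rule: str  # "none" or the rule name
    n: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    spearman_rho: float | None = None


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    test: str  # "rank_sum" | "signed_rank"
    statistic: float
    p_value: float
    two_sided: bool


#: Named subset predicates over the feature column.
SUBSET_RULES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "cpp>1": lambda x: x > 1.0,
}


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError(
            "zero variance in feature or delivery column"
        )
    lr = stats.linregress(x, y)
    return float(lr.rvalue), float(lr.pvalue), float(lr.slope), float(lr.intercept)


def correlate_feature_delivery(
    table: pd.DataFrame,
    feature_col: str = "feature",
    delivery_col: str = "delivery",
    stratum_col: str | None = "stratum",
    subset_rule: str | None = None,
    feature_name: str | None = None,
    min_n: int = 3,
    spearman: bool = False,
) -> list[CorrelationResult]:
    """Pearson r, two-sided p, and least-squares line for the overall
    trend, each stratum, and (optionally) a named subset of rows.

    Strata or subsets with fewer than ``min_n`` finite pairs are
    skipped with a warning row omitted (not an error).  The subset
    rule operates on the per-formulation feature value, e.g.
    ``"cpp>1"`` keeps formulations whose mean CPP exceeds 1.
    """
    name = feature_name or feature_col
    df = table[np.isfinite(table[feature_col]) & np.isfinite(table[delivery_col])]

    def run(sub: pd.DataFrame, stratum: str, rule: str) -> CorrelationResult | None:
        if len(sub) < min_n:
            return None
        x = sub[feature_col].to_numpy(dtype=float)
        y = sub[delivery_col].to_numpy(dtype=float)
        r, p, slope, intercept = _pearson(x, y)
        rho = float(stats.spearmanr(x, y).statistic) if spearman else None
        return CorrelationResult(
            feature_name=name, stratum=stratum, subset_rule=rule, n=len(sub),
            pearson_r=r, p_value=p, slope=slope, intercept=intercept,
            spearman_rho=rho,
        )

    frames: list[tuple[pd.DataFrame, str]] = [(df, "overall")]
    if stratum_col is not None and stratum_col in df.columns:
        for label, grp in df.groupby(stratum_col):
            if str(label):
                frames.append((grp, str(label)))

    results: list[CorrelationResult] = []
    for sub, stratum in frames:
        res = run(sub, stratum, "none")
        if res is not None:
            results.append(res)
    if subset_rule is not None:
        pred = SUBSET_RULES[subset_rule]
        for sub, stratum in frames:
            res = run(sub[pred(sub[feature_col].to_numpy(dtype=float))],
                      stratum, subset_rule)
            if res is not None:
                results.append(res)
    return results


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "rank_sum",
    two_sided: bool = True,
) -> GroupComparison:
    """Two-sample comparison of delivery readouts.

    ``rank_sum`` is the Wilcoxon-Mann-Whitney two-sample test
    (independent groups, the default for stable vs unstable
    formulations); ``signed_rank`` is the paired Wilcoxon test and
    requires equal-length paired samples.  Ties are handled by
    midranks.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    alternative = "two-sided" if two_sided else "greater"
    if test == "rank_sum":
        if len(a) < 3 or len(b) < 3:
            raise ValueError("rank_sum needs at least 3 observations per group")
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    elif test == "signed_rank":
        if len(a) != len(b):
            raise ValueError("signed_rank is a paired test: lengths must match")
        res = stats.wilcoxon(a, b, alternative=alternative)
    else:
        raise ValueError(f"unknown test: {test!r}")
    return GroupComparison(
        n_a=len(a), n_b=len(b), test=test,
        statistic=float(res.statistic), p_value=float(res.pvalue),
        two_sided=two_sided,
    )


def build_report(
    features: pd.DataFrame,
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Join per-formulation simulated features onto standardized
    delivery records.

    ``features`` needs columns (lnp_id, feature, charge_state, mean,
    dispersion, dispersion_kind, stable); ``records`` needs (lnp_id,
    standardized_readout) and may carry stratification columns.  One
    output row per formulation x feature x charge state.  Duplicate
    (lnp_id, feature, charge_state) rows in ``features`` are a join
    error; unmatched ids on either side are listed in the summary.
    """
    key = ["lnp_id", "feature", "charge_state"]
    if features.duplicated(subset=key).any():
        dups = features[features.duplicated(subset=key, keep=False)]
        raise ValueError(
            f"duplicate feature rows for: {dups[key].drop_duplicates().to_dict('records')}"
        )
    merged = features.merge(records, on="lnp_id", how="inner")
    unmatched_features = sorted(set(features["lnp_id"]) - set(records["lnp_id"]))
    unmatched_records = sorted(set(records["lnp_id"]) - set(features["lnp_id"]))
    summary = {
        "n_rows": int(len(merged)),
        "n_formulations": int(merged["lnp_id"].nunique()),
        "unmatched_feature_ids": unmatched_features,
        "unmatched_record_ids": unmatched_records,
    }
    return merged, summary
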