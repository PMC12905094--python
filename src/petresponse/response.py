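"""Metabolic response classification and cohort summaries.

The per-target response statistic is the relative difference of an SUV
metric between baseline and follow-up::

    RD (%) = 100 * (SUV_post - SUV_pre) / SUV_pre

classified under PERCIST-adapted thresholds: an increase of at most 15%
(including any decrease) is a *response*, an increase of at least 30% is
*progression*, and the open interval between is *indeterminate*.  Both
boundaries are inclusive toward their named category.

Cohort summaries count categories per metric over a target subset
(all evaluable targets, or the FDG-avid subset with baseline uncorrected
SUV_max >= 7.5 g/mL) and per image condition (raw or partial-volume
corrected), reporting rates rounded half-to-even at one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

from .quantify import FDG_AVID_SUV_MAX, LesionMetrics

__all__ = [
    "CATEGORIES",
    "METRICS",
    "ResponseThresholds",
    "ResponseRecord",
    "CohortSummary",
    "relative_difference",
    "classify",
    "round_rate",
    "summarize",
    "summarize_all",
    "build_response_table",
    "per_target_table",
    "compare_rosters",
]

CATEGORIES = ("response", "indeterminate", "progression")
METRICS = ("suv_max", "suv_mean", "suv_peak")
SUBSETS = ("all_evaluable", "fdg_avid")
CONDITIONS = ("raw", "pvc")


@dataclass(frozen=True)
class ResponseThresholds:
    """Percent-change cut-points of the three-way classification."""

    response_max_percent: float = 15.0
    progression_min_percent: float = 30.0

    def __post_init__(self):
        if not self.response_max_percent < self.progression_min_percent:
            raise ValueError("response threshold must lie below progression threshold")


@dataclass(frozen=True)
class ResponseRecord:
    """Pre/post SUVs, relative difference and category for one target-metric."""

    lesion_id: int
    metric: str
    condition: str
    suv_pre: float
    suv_post: float
    rd_percent: float
    category: str

    def __post_init__(self):
        rd = relative_difference(self.suv_pre, self.suv_post)
        if abs(rd - self.rd_percent) > 1e-9 * max(1.0, abs(rd)):
            raise ValueError("rd_percent inconsistent with pre/post SUVs")


@dataclass
class CohortSummary:
    """Category counts and rounded rates for one (metric, subset, condition)."""

    metric: str
    subset: str
    condition: str
    n_targets: int
    n_response: int
    n_indeterminate: int
    n_progression: int
    rate_response: float | None
    rate_indeterminate: float | None
    rate_progression: float | None

    @property
    def defined(self) -> bool:
        return self.n_targets > 0


def relative_difference(suv_pre: float, suv_post: float) -> float:
    """Percent change from baseline: ``100 * (post - pre) / pre``."""
    if suv_pre <= 0:
        raise ValueError("relative difference undefined for non-positive baseline SUV")
    if suv_post < 0:
        raise ValueError("follow-up SUV must be non-negative")
    return 100.0 * (suv_post - suv_pre) / suv_pre


def classify(rd_percent: float, thresholds: ResponseThresholds | None = None) -> str:
    """Three-way response category of a finite percent change."""
    if thresholds is None:
        thresholds = ResponseThresholds()
    if not math.isfinite(rd_percent):
        raise ValueError("rd_percent must be finite")
    if rd_percent <= thresholds.response_max_percent:
        return "response"
    if rd_percent >= thresholds.progression_min_percent:
        return "progression"
    return "indeterminate"


def round_rate(count: int, total: int) -> float:
    """Percentage ``100 * count / total`` rounded half-to-even at one decimal.

    Half-to-even is the unique rounding consistent with rates such as
    13/16 -> 81.2, 5/16 -> 31.2, 3/16 -> 18.8 and 1/16 -> 6.2.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    rate = Decimal(100 * count) / Decimal(total)
    return float(rate.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def build_response_table(
    pre_metrics: dict[int, LesionMetrics],
    post_metrics: dict[int, LesionMetrics],
    condition: str = "raw",
    baseline_raw_suv_max: dict[int, float] | None = None,
    thresholds: ResponseThresholds | None = None,
) -> pd.DataFrame:
    """Assemble the per-target response table for one image condition.

    One row per (target, metric).  Targets with an absent SUV_peak
    contribute no ``suv_peak`` row.  ``baseline_raw_suv_max`` supplies the
    uncorrected baseline SUV_max that determines FDG-avid subset
    membership (defaults to the pre metrics, appropriate for the raw
    condition).
    """
    if thresholds is None:
        thresholds = ResponseThresholds()
    if baseline_raw_suv_max is None:
        baseline_raw_suv_max = {lid: m.suv_max for lid, m in pre_metrics.items()}
    rows = []
    for lid, m_pre in sorted(pre_metrics.items()):
        m_post = post_metrics[lid]
        for metric in METRICS:
            pre_val = getattr(m_pre, metric)
            post_val = getattr(m_post, metric)
            if pre_val is None or post_val is None:
                continue  # absent SUV_peak: dropped from suv_peak rows only
            rd = relative_difference(pre_val, post_val)
            rows.append(
                {
                    "lesion_id": lid,
                    "metric": metric,
                    "condition": condition,
                    "suv_pre": pre_val,
                    "suv_post": post_val,
                    "rd_percent": rd,
                    "category": classify(rd, thresholds),
                    "evaluable": m_pre.evaluable,
                    "volume_ml": m_pre.volume_ml,
                    "baseline_suv_max_raw": baseline_raw_suv_max[lid],
                }
            )
    return pd.DataFrame(rows)


def _subset_frame(table: pd.DataFrame, metric: str, subset: str, condition: str) -> pd.DataFrame:
    sel = (
        (table["metric"] == metric)
        & (table["condition"] == condition)
        & table["evaluable"]
    )
    if subset == "fdg_avid":
        sel &= table["baseline_suv_max_raw"] >= FDG_AVID_SUV_MAX
    elif subset != "all_evaluable":
        raise ValueError(f"unknown subset {subset!r}")
    return table[sel]


def summarize(
    table: pd.DataFrame, metric: str, subset: str = "all_evaluable", condition: str = "raw"
) -> CohortSummary:
    """Category counts and rates over one (metric, subset, condition) block.

    Only evaluable targets enter the summary; the FDG-avid subset further
    requires baseline uncorrected SUV_max >= 7.5 g/mL.  An empty subset
    yields n = 0 with undefined (None) rates rather than fabricated values.
    """
    sub = _subset_frame(table, metric, subset, condition)
    n = len(sub)
    counts = {cat: int((sub["category"] == cat).sum()) for cat in CATEGORIES}
    if n == 0:
        rates = {cat: None for cat in CATEGORIES}
    else:
        rates = {cat: round_rate(counts[cat], n) for cat in CATEGORIES}
    return CohortSummary(
        metric=metric,
        subset=subset,
        condition=condition,
        n_targets=n,
        n_response=counts["response"],
        n_indeterminate=counts["indeterminate"],
        n_progression=counts["progression"],
        rate_response=rates["response"],
        rate_indeterminate=rates["indeterminate"],
        rate_progression=rates["progression"],
    )


def summarize_all(table: pd.DataFrame) -> pd.DataFrame:
    """All (metric x subset x condition) summaries present in the table."""
    rows = []
    for condition in sorted(table["condition"].unique()) if len(table) else []:
        for subset in SUBSETS:
            for metric in METRICS:
                s = summarize(table, metric, subset, condition)
                rows.append(
                    {
                        "condition": s.condition,
                        "subset": s.subset,
                        "metric": s.metric,
                        "n_targets": s.n_targets,
                        "n_response": s.n_response,
                        "n_indeterminate": s.n_indeterminate,
                        "n_progression": s.n_progression,
                        "rate_response": s.rate_response,
                        "rate_indeterminate": s.rate_indeterminate,
                        "rate_progression": s.rate_progression,
                    }
                )
    return pd.DataFrame(rows)


def per_target_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-target listing suitable for a pre/post/RD bar chart.

    Non-evaluable targets appear but are flagged ``excluded`` so the chart
    can show them while the statistics omit them.
    """
    out = table.copy()
    out["excluded"] = ~out["evaluable"]
    cols = [
        "lesion_id",
        "metric",
        "condition",
        "suv_pre",
        "suv_post",
        "rd_percent",
        "category",
        "evaluable",
        "excluded",
        "volume_ml",
    ]
    return out[cols].sort_values(["condition", "metric", "lesion_id"]).reset_index(drop=True)


def compare_rosters(baseline_ids, followup_ids) -> dict[str, list[int]]:
    """Manifest-level new/resolved lesion roster comparison.

    A lightweight stand-in for the clinical reading that checks follow-up
    studies for new metastatic lesions: ids present only at follow-up are
    reported as new, ids present only at baseline as resolved.
    """
    base = set(baseline_ids)
    post = set(followup_ids)
    return {
        "new_lesions": sorted(post - base),
        "resolved_lesions": sorted(base - post),
        "persistent_lesions": sorted(base & post),
    }
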