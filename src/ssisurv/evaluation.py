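"""Surveillance performance against the manual reference standard.

Semi-automated surveillance is judged on the usual diagnostic-accuracy
quadruple — sensitivity, specificity, PPV, NPV, each with an exact
(Clopper–Pearson) 95% binomial confidence interval — plus the quantity
the automation exists for, **workload reduction**:

    WR = (n_total − n_flagged) / n_total × 100,

the share of surgeries removed from manual chart review.  WR and the
percentage flagged sum to 100 by construction.

Also here: model-comparison tables (deltas against the structured-only
model 1) and keyword-distribution summaries by post-operative day bin
and deep-SSI group, the tabular form behind the keyword heat map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .classifiers import SurveillanceResult
from .cohort import ReferenceLabel
from .notes import KeywordMatch

#: Default post-operative day bins for keyword distributions.
DEFAULT_DAY_BINS = ((1, 7), (8, 14), (15, 30))


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion as a percentage with its 95% CI, or undefined."""

    value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]

    def rounded(self, ndigits: int = 1):
        if self.value is None:
            return None
        return round(self.value, ndigits)

    def __str__(self) -> str:
        if self.value is None:
            return "undefined"
        return f"{self.value:.1f} ({self.ci_low:.1f}–{self.ci_high:.1f})"


@dataclass(frozen=True)
class PerformanceRow:
    """All performance measures of one surveillance model."""

    model_id: Optional[int]
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    workload_reduction: float
    n_flagged: int
    n_total: int
    cm: ConfusionMatrix


def build_confusion(
    results: Sequence[SurveillanceResult], labels: Sequence[ReferenceLabel]
) -> ConfusionMatrix:
    """Cross the final review flags with the deep-SSI reference labels."""
    if not results:
        raise EvaluationError("no surveillance results to evaluate")
    label_by_id = {l.surgery_id: l.deep_ssi for l in labels}
    missing = sorted(r.surgery_id for r in results if r.surgery_id not in label_by_id)
    if missing:
        raise EvaluationError(f"surgeries without a reference label: {missing}")
    tp = fp = fn = tn = 0
    for r in results:
        truth = label_by_id[r.surgery_id]
        if r.final_review_flag:
            tp, fp = tp + truth, fp + (not truth)
        else:
            fn, tn = fn + truth, tn + (not truth)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def confusion_from_counts(
    n_total: int, n_deep_ssi: int, n_flagged: int, n_deep_ssi_flagged: int
) -> ConfusionMatrix:
    """Reconstruct a confusion matrix from published summary counts."""
    return ConfusionMatrix(
        tp=n_deep_ssi_flagged,
        fp=n_flagged - n_deep_ssi_flagged,
        fn=n_deep_ssi - n_deep_ssi_flagged,
        tn=n_total - n_flagged - (n_deep_ssi - n_deep_ssi_flagged),
    )


def _proportion(num: int, den: int, ci_method: str) -> MetricEstimate:
    if den == 0:
        return MetricEstimate(None, None, None)
    method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(ci_method)
    if method is None:
        raise ValueError(f"unknown CI method {ci_method!r}")
    lo, hi = proportion_confint(num, den, alpha=0.05, method=method)
    return MetricEstimate(100 * num / den, 100 * float(lo), 100 * float(hi))


def compute_metrics(
    cm: ConfusionMatrix,
    model_id: Optional[int] = None,
    ci_method: str = "clopper-pearson",
) -> PerformanceRow:
    """Sensitivity/specificity/PPV/NPV (%, with 95% CI) and WR (%).

    A metric with a zero denominator is reported as undefined, never as
    a silent 0.  Values are kept at full precision; rounding to one
    decimal happens only at reporting time.
    """
    if cm.total == 0:
        raise EvaluationError("empty cohort: nothing under surveillance")
    return PerformanceRow(
        model_id=model_id,
        sensitivity=_proportion(cm.tp, cm.tp + cm.fn, ci_method),
        specificity=_proportion(cm.tn, cm.tn + cm.fp, ci_method),
        ppv=_proportion(cm.tp, cm.tp + cm.fp, ci_method),
        npv=_proportion(cm.tn, cm.tn + cm.fn, ci_method),
        workload_reduction=100 * (cm.total - cm.n_flagged) / cm.total,
        n_flagged=cm.n_flagged,
        n_total=cm.total,
        cm=cm,
    )


def report_frame(reports: Sequence[PerformanceRow], ndigits: int = 1) -> pd.DataFrame:
    """Performance table, one row per model, percentages to one decimal."""
    rows = []
    for r in reports:
        rows.append(
            {
                "model": r.model_id,
                "sensitivity": r.sensitivity.rounded(ndigits),
                "sensitivity_ci": str(r.sensitivity),
                "specificity": r.specificity.rounded(ndigits),
                "specificity_ci": str(r.specificity),
                "ppv": r.ppv.rounded(ndigits),
                "ppv_ci": str(r.ppv),
                "npv": r.npv.rounded(ndigits),
                "npv_ci": str(r.npv),
                "workload_reduction": round(r.workload_reduction, ndigits),
                "n_flagged": r.n_flagged,
                "n_total": r.n_total,
            }
        )
    return pd.DataFrame(rows)


def compare_models(reports: Mapping[int, PerformanceRow], ndigits: int = 1) -> pd.DataFrame:
    """One row per model with all metrics plus deltas against model 1."""
    if len(reports) < 2:
        raise EvaluationError("model comparison needs at least two reports")
    if 1 not in reports:
        raise EvaluationError("model comparison needs model 1 as baseline")
    base = reports[1]
    frame = report_frame(
        [reports[k] for k in sorted(reports)], ndigits=ndigits
    ).set_index("model")
    for metric, attr in (
        ("sensitivity", "sensitivity"),
        ("specificity", "specificity"),
        ("ppv", "ppv"),
        ("npv", "npv"),
    ):
        base_val = getattr(base, attr).value
        deltas = []
        for k in sorted(reports):
            val = getattr(reports[k], attr).value
            deltas.append(
                round(val - base_val, ndigits)
                if val is not None and base_val is not None
                else None
            )
        frame[f"delta_{metric}"] = deltas
    frame["delta_workload_reduction"] = [
        round(reports[k].workload_reduction - base.workload_reduction, ndigits)
        for k in sorted(reports)
    ]
    return frame.reset_index()


# ---------------------------------------------------------------------
# Keyword distributions (heat-map input)
# ---------------------------------------------------------------------

def _bin_label(bin_: tuple[int, int]) -> str:
    return f"{bin_[0]}–{bin_[1]}"


def keyword_distribution(
    matches_by_surgery: Mapping[str, Sequence[KeywordMatch]],
    labels: Sequence[ReferenceLabel],
    day_bins: Sequence[tuple[int, int]] = DEFAULT_DAY_BINS,
) -> pd.DataFrame:
    """Non-negated match counts per (keyword, day bin, deep-SSI group).

    Long-format table with columns ``keyword``, ``day_bin``, ``group``
    (``deep_ssi`` / ``no_deep_ssi``) and ``count``; pivot for a heat
    map.  Matches outside every day bin are dropped.
    """
    label_by_id = {l.surgery_id: l.deep_ssi for l in labels}
    counts: dict[tuple[str, str, str], int] = {}
    for sid, matches in matches_by_surgery.items():
        if sid not in label_by_id:
            raise EvaluationError(f"surgery {sid} has no reference label")
        group = "deep_ssi" if label_by_id[sid] else "no_deep_ssi"
        for m in matches:
            if m.negated:
                continue
            for b in day_bins:
                if b[0] <= m.day_post_surgery <= b[1]:
                    key = (m.canonical_keyword, _bin_label(b), group)
                    counts[key] = counts.get(key, 0) + 1
                    break
    frame = pd.DataFrame(
        [
            {"keyword": k, "day_bin": b, "group": g, "count": c}
            for (k, b, g), c in sorted(counts.items())
        ],
        columns=["keyword", "day_bin", "group", "count"],
    )
    return frame


def heatmap_matrix(distribution: pd.DataFrame, group: str) -> pd.DataFrame:
    """Keyword × day-bin count matrix for one deep-SSI group."""
    sub = distribution[distribution["group"] == group]
    return sub.pivot_table(
        index="keyword", columns="day_bin", values="count", fill_value=0, aggfunc="sum"
    )


def plot_keyword_heatmap(distribution: pd.DataFrame, path) -> None:
    """Render the two-group keyword heat map to an image file (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = ["deep_ssi", "no_deep_ssi"]
    fig, axes = plt.subplots(1, 2, figsize=(8, 6), sharey=True)
    for ax, group in zip(axes, groups):
        mat = heatmap_matrix(distribution, group)
        im = ax.imshow(mat.values, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(mat.columns)), mat.columns)
        ax.set_yticks(range(len(mat.index)), mat.index)
        ax.set_title(group.replace("_", " "))
        fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
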