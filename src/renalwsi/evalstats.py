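"""Detection evaluation and agreement statistics.

Detection metrics follow the PASCAL VOC 2010 protocol: greedy score-ordered
matching at an IoU threshold (default 0.5), 11-point interpolated average
precision with ``P_interp(r) = max over attained recalls >= r`` (0 when no
recall point reaches r), and unweighted class-mean mAP.

Agreement statistics: Spearman rank correlation (mean ranks for ties, t
approximation for the p-value), the two-way absolute-agreement
single-measurement intraclass correlation with its F-based 95% confidence
interval, and one-way ANOVA with Tukey-Kramer post hoc comparisons on the
studentized-range distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fuse import iou
from .slideio import Instance

__all__ = [
    "MatchResult",
    "PRCurve",
    "ICCResult",
    "AnovaResult",
    "match_detections",
    "pr_curve",
    "average_precision_11pt",
    "map_over_classes",
    "confusion_metrics",
    "roc_auc",
    "spearman",
    "icc_absolute_single",
    "anova_tukey",
    "review_triage",
]

RECALL_LEVELS = np.linspace(0.0, 1.0, 11)


@dataclass
class MatchResult:
    """Score-ordered TP/FP flags for detections against one ground truth set."""

    scores: np.ndarray          # detection scores, descending
    is_tp: np.ndarray           # parallel boolean flags
    n_gt: int
    iou_threshold: float
    matched_gt: list[int | None] = field(default_factory=list)

    @property
    def n_tp(self) -> int:
        return int(self.is_tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.is_tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp


@dataclass
class PRCurve:
    """Raw rank-wise precision/recall plus 11-point interpolated precision."""

    recalls: np.ndarray
    precisions: np.ndarray
    interp_levels: np.ndarray
    interp_precisions: np.ndarray


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "two-way, absolute agreement, single measurement"


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    #: rows of (group_i, group_j, mean_difference, adjusted_p)
    pairwise: list[tuple[int, int, float, float]]


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------


def match_detections(
    detections: list[Instance],
    ground_truth: list[Instance],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy VOC matching of scored detections against unscored ground truth.

    Detections are processed in descending score order (ties: input order);
    each claims the still-unmatched ground-truth box of highest IoU if that
    IoU reaches the threshold, otherwise it is a false positive.
    """
    labels = ({d.label for d in detections}
              | {g.label for g in ground_truth})
    if len(labels) > 1:
        raise ValueError(
            f"match_detections expects a single class, got {sorted(labels)}"
        )
    for det in detections:
        if det.score is None:
            raise ValueError("detections must be scored")
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, i))
    taken = [False] * len(ground_truth)
    scores = np.array([detections[i].score for i in order], dtype=float)
    is_tp = np.zeros(len(order), dtype=bool)
    matched: list[int | None] = []
    for rank, i in enumerate(order):
        best_iou, best_j = 0.0, None
        for j, gt in enumerate(ground_truth):
            if taken[j]:
                continue
            value = iou(detections[i].bbox, gt.bbox)
            if value > best_iou:
                best_iou, best_j = value, j
        if best_j is not None and best_iou >= iou_threshold:
            taken[best_j] = True
            is_tp[rank] = True
            matched.append(best_j)
        else:
            matched.append(None)
    return MatchResult(scores=scores, is_tp=is_tp, n_gt=len(ground_truth),
                       iou_threshold=iou_threshold, matched_gt=matched)


def pr_curve(match: MatchResult) -> PRCurve:
    if match.n_gt < 1:
        raise ValueError("average precision is undefined with zero ground truth")
    tp_cum = np.cumsum(match.is_tp)
    ranks = np.arange(1, len(match.is_tp) + 1)
    recalls = tp_cum / match.n_gt
    precisions = tp_cum / ranks
    interp = np.zeros(len(RECALL_LEVELS))
    for k, level in enumerate(RECALL_LEVELS):
        attained = precisions[recalls >= level - 1e-12]
        interp[k] = attained.max() if attained.size else 0.0
    return PRCurve(recalls=recalls, precisions=precisions,
                   interp_levels=RECALL_LEVELS.copy(),
                   interp_precisions=interp)


def average_precision_11pt(match: MatchResult) -> float:
    """VOC 11-point interpolated average precision at the match's threshold."""
    curve = pr_curve(match)
    return float(curve.interp_precisions.mean())


def map_over_classes(per_class_ap: dict[str, float] | list[float]) -> float:
    """Unweighted arithmetic mean of per-class average precisions."""
    values = list(per_class_ap.values()) if isinstance(per_class_ap, dict) \
        else list(per_class_ap)
    if not values:
        raise ValueError("mAP requires at least one class AP")
    return float(np.mean(values))


def confusion_metrics(tp: int, tn: int, fp: int, fn: int
                      ) -> tuple[float, float, float]:
    """(sensitivity, specificity, precision); NaN where the denominator is 0."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    sens = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    prec = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    return (sens, spec, prec)


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC; AUC is the Mann-Whitney pairwise statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both positive and negative labels")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # curve: sweep thresholds from high to low
    order = np.argsort(-scores, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    for k, i in enumerate(order):
        if labels[i]:
            tp += 1
        else:
            fp += 1
        # emit a point after each distinct score block
        if k == len(order) - 1 or scores[order[k + 1]] != scores[i]:
            points.append((fp / n_neg, tp / n_pos))
    return points, float(auc)


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mean ranks for ties; t-based p-value.

    Returns ``(nan, nan)`` when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman requires two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))
    if 1.0 - abs(r) < 1e-12:
        r = math.copysign(1.0, r)
    n = len(x)
    if abs(r) >= 1.0:
        return (r, 0.0)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return (r, float(p))


def icc_absolute_single(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC of a two-way layout, absolute agreement, single measurement.

    ``ratings`` is an ``n subjects x k raters`` table with no missing cells.
    The confidence interval follows the F-based procedure of McGraw & Wong.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters table")
    n, k = table.shape
    if n < 3 or k < 2:
        raise ValueError("ICC requires n >= 3 subjects and k >= 2 raters")
    if np.isnan(table).any():
        raise ValueError("ratings table must be complete (no missing cells)")

    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((table - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    mse = max(mse, 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else math.nan

    # F-based 95% CI (McGraw & Wong, case A-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fj = msc / mse if mse > 0 else math.inf
        a = k * icc / (n * (1.0 - icc)) if icc < 1 else math.inf
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1 else math.inf
    if not math.isfinite(a) or not math.isfinite(fj):
        # degenerate perfect-agreement table
        return ICCResult(icc=float(icc), ci_low=float(icc), ci_high=float(icc))
    v_num = ((k - 1) * (n - 1)
             * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2)
    v_den = ((n - 1) * k ** 2 * icc ** 2 * fj ** 2
             + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
    v = v_num / v_den
    f_upper = stats.f.ppf(1 - alpha / 2.0, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2.0, v, n - 1)
    low = (n * (msr - f_upper * mse)
           / (f_upper * (k * msc + (k * n - k - n) * mse) + n * msr))
    high = (n * (f_lower * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_lower * msr))
    low, high = float(min(low, icc)), float(max(high, icc))
    return ICCResult(icc=float(icc), ci_low=max(low, -1.0),
                     ci_high=min(high, 1.0))


def icc_consistency_single(ratings: np.ndarray) -> float:
    """Consistency-type single-measurement ICC (offset-insensitive variant)."""
    table = np.asarray(ratings, dtype=float)
    n, k = table.shape
    grand = table.mean()
    ssr = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ssc = n * ((table.mean(axis=0) - grand) ** 2).sum()
    sse = ((table - grand) ** 2).sum() - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse))


def anova_tukey(groups: list[np.ndarray]) -> AnovaResult:
    """One-way ANOVA with Tukey-Kramer post hoc pairwise comparisons."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group must contain at least two values")
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    total_n = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_between = k - 1
    df_within = total_n - k
    msb = ssb / df_between
    msw = ssw / df_within
    if msw == 0.0:
        f_stat = 0.0 if msb == 0.0 else math.inf
        p = 1.0 if msb == 0.0 else 0.0
    else:
        f_stat = msb / msw
        p = float(stats.f.sf(f_stat, df_between, df_within))

    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            if msw == 0.0:
                p_adj = 1.0 if diff == 0.0 else 0.0
            else:
                se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_within))
            pairwise.append((i, j, diff, p_adj))
    return AnovaResult(f_statistic=float(f_stat), p_value=p, pairwise=pairwise)


def review_triage(per_image_map: dict[str, float],
                  fraction: float = 0.2) -> list[str]:
    """Image ids with the lowest ``fraction`` of mAP values, ties included.

    Selects the ``ceil(fraction * N)`` lowest-mAP images; images tied with
    the value at the cut are all included, so the selection may be larger.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if not per_image_map:
        raise ValueError("at least one image is required")
    items = sorted(per_image_map.items(), key=lambda kv: (kv[1], kv[0]))
    m = math.ceil(fraction * len(items))
    cutoff = items[m - 1][1]
    return [name for name, value in items if value <= cutoff]
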