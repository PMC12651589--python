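"""Per-image segmentation metrics, fold aggregation, and the statistical
comparison machinery (paired Wilcoxon signed-rank, Benjamini-Hochberg,
bootstrap confidence intervals, rank-biserial effect size).

Conventions worth flagging loudly:

* All four ratios use an epsilon of 1e-8 in the denominator.  Taken
  literally, this means the Dice of two empty masks is ~0, not 1 — several
  other toolkits return 1 for that case.
* FNR with an empty ground truth is epsilon-degenerate and reported as 0.
* The cross-fold SD uses the population convention (divide by K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EPS",
    "ConfusionCounts",
    "MetricsRecord",
    "ComparisonResult",
    "confusion_counts",
    "compute_metrics",
    "aggregate_folds",
    "paired_wilcoxon",
    "bh_adjust",
    "bootstrap_ci",
    "rank_biserial",
    "compare_methods",
]

EPS = 1e-8


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsRecord:
    image_id: str
    dice: float
    iou: float
    fpr: float
    fnr: float


@dataclass(frozen=True)
class ComparisonResult:
    raw_p: float
    adjusted_p: float
    effect_size: float  # rank-biserial r
    ci_low: float
    ci_high: float


def confusion_counts(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Exact pixel-wise TP/FP/FN/TN."""
    pred = np.asarray(pred_mask)
    truth = np.asarray(truth_mask)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for arr, name in ((pred, "pred"), (truth, "truth")):
        if not np.all(np.isin(arr, [0, 1])):
            raise ValueError(f"{name} mask must be binary")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def compute_metrics(counts: ConfusionCounts, image_id: str = "") -> MetricsRecord:
    """Dice, IoU, FPR, FNR with epsilon-stabilized denominators."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    dice = 2.0 * tp / (2.0 * tp + fp + fn + EPS)
    iou = tp / (tp + fp + fn + EPS)
    fnr = 0.0 if (fn + tp) == 0 else fn / (fn + tp + EPS)
    fpr = 0.0 if (fp + tn) == 0 else fp / (fp + tn + EPS)
    return MetricsRecord(image_id=image_id, dice=dice, iou=iou, fpr=fpr, fnr=fnr)


def aggregate_folds(per_image: list[MetricsRecord], fold_ids: list[int]) -> pd.DataFrame:
    """Two-level aggregation: image -> fold mean, then fold -> mean +/- SD.

    Returns a frame with one row per fold plus summary rows ``mean`` and
    ``sd`` (population SD over the K fold means).
    """
    if len(per_image) != len(fold_ids):
        raise ValueError("per_image and fold_ids must align")
    df = pd.DataFrame([{
        "fold": f, "dice": r.dice, "iou": r.iou, "fpr": r.fpr, "fnr": r.fnr,
    } for r, f in zip(per_image, fold_ids)])
    counts = df.groupby("fold").size()
    if (counts == 0).any():
        raise ValueError("empty fold")
    fold_means = df.groupby("fold").mean()
    summary = pd.concat([
        fold_means,
        fold_means.agg(["mean"]),
        fold_means.agg(lambda s: float(np.std(s, ddof=0))).to_frame("sd").T,
    ])
    return summary


def _signed_ranks(a, b):
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("degenerate pairing: all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))  # midranks under ties
    return d, ranks


def paired_wilcoxon(scores_a, scores_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped.  For n <= 12 remaining pairs the p-value is
    computed by exact enumeration of all 2^n sign assignments (midranks, so
    ties are handled); otherwise the normal approximation with tie correction
    is used.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired lists of equal length >= 5")
    d, ranks = _signed_ranks(a, b)
    n = d.size
    w_pos = float(ranks[d > 0].sum())
    if n <= 12:
        # enumerate the null distribution of W+ over all sign assignments
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        stat = min(w_pos, float(ranks.sum()) - w_pos)
        p = np.mean((np.minimum(totals, ranks.sum() - totals) <= stat + 1e-12))
        return float(min(1.0, p))
    mu = n * (n + 1) / 4.0
    # variance with tie correction over groups of tied |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_pos - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def bootstrap_ci(per_image_scores, resamples: int = 10_000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for the mean of image-level scores."""
    scores = np.asarray(list(per_image_scores), dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, scores.size, size=(resamples, scores.size))
    means = scores[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def rank_biserial(scores_a, scores_b) -> float:
    """Rank-biserial correlation: (R+ - R-) / (R+ + R-) over signed ranks."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired lists of equal length >= 5")
    d, ranks = _signed_ranks(a, b)
    r_pos = float(ranks[d > 0].sum())
    r_neg = float(ranks[d < 0].sum())
    return (r_pos - r_neg) / (r_pos + r_neg)


def compare_methods(scores_by_method: dict[str, np.ndarray], reference: str,
                    resamples: int = 10_000, seed: int = 0,
                    ) -> dict[str, ComparisonResult]:
    """Compare a reference method's image-level scores against each other
    method: Wilcoxon p (BH-adjusted across comparisons), rank-biserial effect
    size, and a bootstrap CI of the paired mean difference."""
    ref = np.asarray(scores_by_method[reference], dtype=float)
    names = [m for m in scores_by_method if m != reference]
    raw = [paired_wilcoxon(ref, scores_by_method[m]) for m in names]
    adj = bh_adjust(raw)
    out = {}
    for i, m in enumerate(names):
        diffs = ref - np.asarray(scores_by_method[m], dtype=float)
        lo, hi = bootstrap_ci(diffs, resamples=resamples, seed=seed)
        out[m] = ComparisonResult(raw_p=raw[i], adjusted_p=float(adj[i]),
                                  effect_size=rank_biserial(ref, scores_by_method[m]),
                                  ci_low=lo, ci_high=hi)
    return out
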