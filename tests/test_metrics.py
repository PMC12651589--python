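"""Segmentation metrics and the statistical comparison machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from busseg.metrics import (
    ConfusionCounts,
    aggregate_folds,
    bh_adjust,
    bootstrap_ci,
    compute_metrics,
    confusion_counts,
    paired_wilcoxon,
    rank_biserial,
)

# ---------------------------------------------------------------------------
# confusion counts and ratios
# ---------------------------------------------------------------------------


def test_perfect_prediction_counts():
    truth = np.zeros((4, 4), dtype=np.uint8)
    truth[:2, :5] = 0
    truth.ravel()[:10] = 1
    c = confusion_counts(truth, truth)
    assert (c.tp, c.fp, c.fn, c.tn) == (10, 0, 0, 6)


def test_empty_prediction_counts():
    truth = np.zeros((4, 4), dtype=np.uint8)
    truth.ravel()[:4] = 1
    c = confusion_counts(np.zeros_like(truth), truth)
    assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 4, 12)


def test_confusion_matches_nested_loops_on_random_pairs():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        pred = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        truth = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        c = confusion_counts(pred, truth)
        tp = fp = fn = tn = 0
        for i in range(16):
            for j in range(16):
                if pred[i, j] and truth[i, j]:
                    tp += 1
                elif pred[i, j]:
                    fp += 1
                elif truth[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == 256


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion_counts(np.zeros((4, 4), dtype=np.uint8),
                         np.zeros((4, 5), dtype=np.uint8))


def test_metrics_perfect_overlap():
    m = compute_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=6))
    assert m.dice == pytest.approx(1.0, abs=1e-8)
    assert m.iou == pytest.approx(1.0, abs=1e-8)
    assert m.fpr == 0.0 and m.fnr == 0.0


def test_metrics_hand_counted_case():
    # truth 4 px, pred 4 px, overlap 2, on a 16-px grid
    m = compute_metrics(ConfusionCounts(tp=2, fp=2, fn=2, tn=10))
    assert m.dice == pytest.approx(0.5, abs=1e-8)
    assert m.iou == pytest.approx(1 / 3, abs=1e-8)
    assert m.fnr == pytest.approx(0.5, abs=1e-8)
    assert m.fpr == pytest.approx(2 / 12, abs=1e-8)


def test_empty_empty_convention_dice_zero():
    """Epsilon-in-denominator convention: two empty masks give Dice ~0 (other
    toolkits return 1 here)."""
    m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=16))
    assert m.dice == pytest.approx(0.0, abs=1e-7)
    assert m.fpr == 0.0
    assert m.fnr == 0.0  # flagged degenerate case reported as 0


@settings(max_examples=200, derandomize=True, deadline=None)
@given(tp=st.integers(0, 10_000), fp=st.integers(0, 10_000),
       fn=st.integers(0, 10_000), tn=st.integers(0, 10_000))
def test_metric_ranges_and_identity_property(tp, fp, fn, tn):
    """All four ratios stay in [0, 1], pixels are conserved, and the
    Dice-IoU identity holds whenever any foreground is involved."""
    c = ConfusionCounts(tp, fp, fn, tn)
    assert c.total == tp + fp + fn + tn
    m = compute_metrics(c)
    for v in (m.dice, m.iou, m.fpr, m.fnr):
        assert 0.0 <= v <= 1.0
    if tp + fp + fn > 0:
        assert m.dice == pytest.approx(2 * m.iou / (1 + m.iou), abs=1e-9)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25))
def test_bh_property_bounds(p):
    """Adjusted p-values stay in [raw, 1] and keep the step-up ordering."""
    adj = bh_adjust(p)
    assert np.all(adj <= 1.0 + 1e-12)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_dice_iou_identity_on_random_counts():
    rng = np.random.default_rng(5)
    for _ in range(1000):
        tp, fp, fn, tn = rng.integers(0, 500, size=4)
        if tp + fp + fn == 0:
            continue
        m = compute_metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
        assert m.dice == pytest.approx(2 * m.iou / (1 + m.iou), abs=1e-9)
        assert m.iou <= m.dice + 1e-12


# ---------------------------------------------------------------------------
# fold aggregation
# ---------------------------------------------------------------------------


def _records(values, ids=None):
    from busseg.metrics import MetricsRecord
    return [MetricsRecord(image_id=ids[i] if ids else str(i), dice=v, iou=v,
                          fpr=0.0, fnr=0.0) for i, v in enumerate(values)]


def test_aggregate_constant_records_sd_zero():
    recs = _records([0.8] * 10)
    out = aggregate_folds(recs, [i % 5 for i in range(10)])
    assert out.loc["mean", "dice"] == pytest.approx(0.8)
    assert out.loc["sd", "dice"] == pytest.approx(0.0)


def test_aggregate_fold_means_reproduce_reported_mean():
    """The mean over the five reported fold Dice values matches the printed
    cross-fold mean row to within rounding (0.0002)."""
    fold_dice = [0.8846, 0.8910, 0.8583, 0.8649, 0.8836]
    recs = _records(fold_dice)
    out = aggregate_folds(recs, list(range(5)))
    assert out.loc["mean", "dice"] == pytest.approx(np.mean(fold_dice), abs=1e-12)
    assert abs(out.loc["mean", "dice"] - 0.8766) <= 2e-4


def test_aggregate_single_fold():
    out = aggregate_folds(_records([0.5, 0.7]), [0, 0])
    assert out.loc["mean", "dice"] == pytest.approx(0.6)
    assert out.loc["sd", "dice"] == pytest.approx(0.0)


def test_aggregate_two_level_not_pooled():
    """Fold means first, then mean of means: unbalanced folds must not reduce
    to the pooled per-image mean."""
    recs = _records([1.0, 0.0, 0.0, 0.0])
    out = aggregate_folds(recs, [0, 1, 1, 1])
    assert out.loc["mean", "dice"] == pytest.approx(0.5)  # (1.0 + 0.0)/2


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def test_wilcoxon_constant_shift_smallest_p():
    a = np.arange(8, dtype=float)
    p = paired_wilcoxon(a + 1.0, a)
    assert p == pytest.approx(2 / 2**8, abs=1e-12)


def test_wilcoxon_identical_pairs_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        paired_wilcoxon([1.0] * 6, [1.0] * 6)


def test_wilcoxon_matches_full_enumeration_n10():
    """Exact p equals a brute-force enumeration over all 2^10 sign vectors."""
    rng = np.random.default_rng(9)
    for _ in range(10):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        d = a - b
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        s = ranks.sum()
        w_obs = ranks[d > 0].sum()
        stat_obs = min(w_obs, s - w_obs)
        count = 0
        for signs in itertools.product([0, 1], repeat=len(d)):
            w = sum(r for r, sgn in zip(ranks, signs) if sgn)
            if min(w, s - w) <= stat_obs + 1e-12:
                count += 1
        expected = count / 2 ** len(d)
        assert paired_wilcoxon(a, b) == pytest.approx(expected, abs=1e-12)


def test_wilcoxon_matches_scipy_exact_when_no_ties():
    rng = np.random.default_rng(2)
    a = rng.standard_normal(11)
    b = rng.standard_normal(11)
    expected = stats.wilcoxon(a, b, method="exact").pvalue
    assert paired_wilcoxon(a, b) == pytest.approx(expected, rel=1e-9)


def test_wilcoxon_large_n_close_to_scipy_approx():
    rng = np.random.default_rng(3)
    a = rng.standard_normal(60)
    b = a + rng.standard_normal(60) * 0.7 + 0.2
    mine = paired_wilcoxon(a, b)
    ref = stats.wilcoxon(a, b, method="approx", correction=False).pvalue
    assert mine == pytest.approx(ref, rel=1e-6)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def _bh_by_hand(p):
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = m - rank_from_end
        val = min(prev, p[idx] * m / k)
        adj[idx] = val
        prev = val
    return adj


def test_bh_single_p_unchanged():
    np.testing.assert_allclose(bh_adjust([0.04]), [0.04])


def test_bh_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_all_equal_stay_equal():
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2, 0.2]), [0.2] * 4)


def test_bh_matches_hand_step_up_on_random_vectors():
    rng = np.random.default_rng(4)
    for _ in range(100):
        p = rng.random(rng.integers(1, 20))
        np.testing.assert_allclose(bh_adjust(p), _bh_by_hand(p), atol=1e-12)


def test_bh_monotone_and_dominates_raw():
    rng = np.random.default_rng(6)
    for _ in range(20):
        p = rng.random(15)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)  # adjusted never below raw
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # step-up monotonicity


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# bootstrap CI and effect size
# ---------------------------------------------------------------------------


def test_bootstrap_constant_scores_zero_width():
    lo, hi = bootstrap_ci([0.7] * 10, resamples=200, seed=0)
    assert lo == hi == pytest.approx(0.7)


def test_bootstrap_seeded_reproducible():
    scores = np.random.default_rng(0).random(30)
    assert bootstrap_ci(scores, seed=7) == bootstrap_ci(scores, seed=7)


def test_bootstrap_width_matches_clt():
    rng = np.random.default_rng(8)
    scores = rng.standard_normal(50)
    lo, hi = bootstrap_ci(scores, resamples=10_000, seed=1)
    assert lo < scores.mean() < hi
    expected_width = 2 * 1.96 * scores.std(ddof=1) / np.sqrt(50)
    assert (hi - lo) == pytest.approx(expected_width, rel=0.25)


def test_bootstrap_nominal_coverage():
    """~95% of intervals over repeated normal samples cover the true mean."""
    rng = np.random.default_rng(12)
    covered = 0
    n_rep = 500
    for i in range(n_rep):
        sample = rng.standard_normal(100)
        lo, hi = bootstrap_ci(sample, resamples=1000, seed=i)
        covered += lo <= 0.0 <= hi
    assert covered / n_rep == pytest.approx(0.95, abs=0.02)


def test_rank_biserial_extremes_and_hand_case():
    a = np.arange(6, dtype=float)
    assert rank_biserial(a + 1, a) == 1.0
    assert rank_biserial(a - 1, a) == -1.0
    # hand-computed mixed case: d = [1, -2, 3, -4, 5, 6]
    b = a - np.array([1.0, -2.0, 3.0, -4.0, 5.0, 6.0])
    # ranks of |d| = [1, 2, 3, 4, 5, 6]; R+ = 1+3+5+6 = 15, R- = 2+4 = 6
    assert rank_biserial(a, b) == pytest.approx((15 - 6) / 21)
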