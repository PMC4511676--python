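import numpy as np
import pytest

from salbias.evaluation import (
    evaluate_dataset,
    evaluate_images,
    f_beta,
    hit_rate,
    max_f_score,
    pr_auc,
    roc_auc,
    significance_tests,
    threshold_sweep,
)


def brute_force_metrics(smap, mask, beta=0.3):
    """Enumerate every distinct value as a threshold, loop over pixels."""
    s = np.asarray(smap, float).ravel()
    m = np.asarray(mask, bool).ravel()
    points = []
    for t in sorted(set(s)):
        tp = fp = fn = tn = 0
        for v, is_fg in zip(s, m):
            pred = v >= t
            tp += pred and is_fg
            fp += pred and not is_fg
            fn += (not pred) and is_fg
            tn += (not pred) and not is_fg
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / (tp + fn)
        fpr = fp / (fp + tn) if fp + tn else 0.0
        points.append((prec, rec, fpr))
    f1 = max(
        (2 * p * r / (p + r)) if p + r else 0.0 for p, r, _ in points)
    fb = max(
        ((1 + beta**2) * p * r / (beta**2 * p + r)) if beta**2 * p + r else 0.0
        for p, r, _ in points)
    # interpolated-precision envelope, rectangle integration over recall
    recalls = sorted({r for _, r, _ in points})
    area_pr = 0.0
    prev = 0.0
    for r in recalls:
        env = max(p for p, rr, _ in points if rr >= r)
        area_pr += (r - prev) * env
        prev = r
    # ROC trapezoid with (0,0) and (1,1) appended
    roc = sorted([(0.0, 0.0)] + [(f, r) for _, r, f in points] + [(1.0, 1.0)])
    area_roc = sum(
        (x1 - x0) * (y0 + y1) / 2 for (x0, y0), (x1, y1) in zip(roc, roc[1:]))
    return f1, fb, area_pr, area_roc


class TestThresholdSweep:
    def test_perfect_map_reaches_precision_recall_one(self):
        mask = np.zeros((8, 8), bool)
        mask[2:5, 3:7] = True
        c = threshold_sweep(mask.astype(float), mask, n_levels="exact")
        both_one = (c.precision == 1.0) & (c.recall == 1.0)
        assert both_one.any()

    def test_inverted_map_equals_all_positive_f1(self):
        rng = np.random.default_rng(2)
        mask = rng.random((10, 10)) < 0.3
        smap = 1.0 - mask.astype(float)
        c = threshold_sweep(smap, mask, n_levels="exact")
        f1_all_positive = 2 * mask.mean() / (mask.mean() + 1)
        assert max_f_score(c, 1.0) == pytest.approx(f1_all_positive)

    def test_constant_map_single_operating_point(self):
        mask = np.zeros((6, 6), bool)
        mask[1:3, 1:4] = True
        c = threshold_sweep(np.full((6, 6), 0.5), mask, n_levels="exact")
        assert c.recall == pytest.approx([1.0])
        assert c.precision == pytest.approx([mask.mean()])

    def test_counts_consistent_and_recall_monotone(self, rng):
        smap = rng.random((12, 12))
        mask = rng.random((12, 12)) < 0.4
        c = threshold_sweep(smap, mask)
        assert np.all(c.tp + c.fn == c.n_pos)
        assert np.all(np.diff(c.recall) <= 0)
        assert len(c.thresholds) == 256

    def test_empty_mask_signaled(self):
        with pytest.raises(ValueError, match="no foreground"):
            threshold_sweep(np.ones((4, 4)), np.zeros((4, 4)))


class TestFBeta:
    @pytest.mark.parametrize("beta", [0.3, 1.0, 2.0])
    def test_equal_precision_recall_identity(self, beta):
        assert f_beta(0.7, 0.7, beta) == pytest.approx(0.7)

    def test_direct_evaluation(self):
        assert f_beta(0.8, 0.4, 0.3) == pytest.approx(0.739, abs=5e-4)

    def test_beta_one_is_harmonic_mean(self):
        assert f_beta(0.5, 1.0, 1.0) == pytest.approx(2 / 3)

    def test_zero_zero_convention(self):
        assert f_beta(0.0, 0.0, 0.3) == 0.0


class TestAucs:
    def test_perfect_map_gives_unit_areas(self):
        mask = np.zeros((8, 8), bool)
        mask[1:4, 2:6] = True
        c = threshold_sweep(mask.astype(float), mask, n_levels="exact")
        assert pr_auc(c) == pytest.approx(1.0)
        assert roc_auc(c) == pytest.approx(1.0)

    def test_inverted_perfect_map_gives_zero_roc(self):
        mask = np.zeros((8, 8), bool)
        mask[1:4, 2:6] = True
        c = threshold_sweep(1.0 - mask.astype(float), mask, n_levels="exact")
        assert roc_auc(c) == pytest.approx(0.0)

    def test_random_scores_give_half_roc(self, rng):
        smap = rng.random((100, 100))
        mask = rng.random((100, 100)) < 0.5
        c = threshold_sweep(smap, mask, n_levels="exact")
        assert roc_auc(c) == pytest.approx(0.5, abs=0.02)

    def test_constant_map_roc_half(self):
        mask = np.zeros((6, 6), bool)
        mask[2, 2] = True
        c = threshold_sweep(np.full((6, 6), 0.3), mask, n_levels="exact")
        assert roc_auc(c) == pytest.approx(0.5)


class TestAgainstBruteForce:
    def test_all_sweep_metrics_match_oracle(self, rng):
        for _ in range(8):
            smap = rng.integers(0, 12, (16, 16)) / 11.0  # ties included
            mask = rng.random((16, 16)) < 0.35
            if not mask.any():
                mask[0, 0] = True
            c = threshold_sweep(smap, mask, n_levels="exact")
            f1, fb, apr, aroc = brute_force_metrics(smap, mask)
            assert max_f_score(c, 1.0) == pytest.approx(f1, abs=1e-9)
            assert max_f_score(c, 0.3) == pytest.approx(fb, abs=1e-9)
            assert pr_auc(c) == pytest.approx(apr, abs=1e-9)
            assert roc_auc(c) == pytest.approx(aroc, abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        smap = rng.random((20, 20))
        mask = rng.random((20, 20)) < 0.3
        mask[0, 0] = True
        a = threshold_sweep(smap, mask, n_levels="exact")
        b = threshold_sweep(np.exp(3 * smap), mask, n_levels="exact")
        assert max_f_score(a, 1.0) == pytest.approx(max_f_score(b, 1.0), abs=1e-12)
        assert roc_auc(a) == pytest.approx(roc_auc(b), abs=1e-12)
        assert pr_auc(a) == pytest.approx(pr_auc(b), abs=1e-12)


class TestHitRate:
    def test_perfect_and_inverted_maps(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert hit_rate([mask.astype(float)], [mask]) == 1.0
        assert hit_rate([1.0 - mask.astype(float)], [mask]) == 0.0

    def test_constant_map_optimistic_tie_rule(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = True
        with pytest.warns(UserWarning, match="tie"):
            assert hit_rate([np.full((5, 5), 0.5)], [mask]) == 1.0


class TestEvaluateDataset:
    def test_single_perfect_image_all_metrics_one(self):
        mask = np.zeros((10, 10), bool)
        mask[3:7, 2:8] = True
        scores = evaluate_dataset([mask.astype(float)], [mask])
        assert scores.f1 == pytest.approx(1.0)
        assert scores.fbeta == pytest.approx(1.0)
        assert scores.pr_auc == pytest.approx(1.0, abs=1e-6)
        assert scores.roc_auc == pytest.approx(1.0, abs=1e-6)
        assert scores.hit_rate == 1.0

    def test_invariant_to_image_order(self, rng):
        maps = [rng.random((9, 9)) for _ in range(5)]
        masks = [rng.random((9, 9)) < 0.4 for _ in range(5)]
        for m in masks:
            m[0, 0] = True
        a = evaluate_dataset(maps, masks)
        b = evaluate_dataset(maps[::-1], masks[::-1])
        for field in ("f1", "fbeta", "pr_auc", "roc_auc", "hit_rate"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-12)

    def test_per_image_and_pooled_differ_on_heterogeneous_sets(self):
        # image 1: tiny object found perfectly; image 2: big object missed
        m1 = np.zeros((10, 10), bool)
        m1[0, 0] = True
        m2 = np.zeros((10, 10), bool)
        m2[:, :5] = True
        s1 = m1.astype(float)
        s2 = 1.0 - m2.astype(float)
        per = evaluate_dataset([s1, s2], [m1, m2], aggregation="per_image")
        pooled = evaluate_dataset([s1, s2], [m1, m2], aggregation="pooled")
        assert per.f1 != pytest.approx(pooled.f1)

    def test_empty_mask_skipped_with_warning(self, rng):
        maps = [rng.random((6, 6)), rng.random((6, 6))]
        masks = [np.zeros((6, 6), bool), np.ones((6, 6), bool)]
        with pytest.warns(UserWarning, match="empty"):
            scores = evaluate_dataset(maps, masks)
        assert scores.n_images == 1


class TestSignificance:
    def test_identical_scores_not_rejected(self):
        a = np.linspace(0.5, 0.9, 30)
        res = significance_tests(a, a.copy())
        assert not res.reject_equal_means

    def test_large_shift_rejects_both(self, rng):
        a = 0.5 + 0.02 * rng.standard_normal(100)
        res = significance_tests(a, a + 0.3)
        assert res.reject_equal_means and res.reject_worse

    def test_type_one_error_rate_near_alpha(self, rng):
        n, reps, alpha = 30, 2000, 0.05
        rejections = 0
        for _ in range(reps):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            rejections += significance_tests(a, b, alpha).reject_equal_means
        rate = rejections / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_too_few_observations_signaled(self):
        with pytest.raises(ValueError):
            significance_tests([0.5], [0.6])

    def test_per_image_metrics_feed_the_tests(self, rng):
        maps = [rng.random((8, 8)) for _ in range(6)]
        masks = []
        for _ in range(6):
            m = np.zeros((8, 8), bool)
            m[2:5, 2:5] = True
            masks.append(m)
        frame = evaluate_images(maps, masks)
        assert set(frame.columns) == {"f1", "fbeta", "pr_auc", "roc_auc", "hit"}
        res = significance_tests(frame["f1"], frame["f1"] + 0.0)
        assert not res.reject_equal_means
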