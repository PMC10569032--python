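"""Dice/Hausdorff metrics, the compound Dice+Focal loss, and report assembly."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from swunet.losses_metrics import (
    REPORT_COLUMNS,
    ConfusionCounts,
    LossConfig,
    UndefinedMetricError,
    aggregate_reports,
    boundary_points,
    combined_loss,
    confusion,
    dice_coefficient,
    dice_loss,
    focal_loss,
    full_report,
    hausdorff,
    reports_to_csv,
    segmentation_loss,
)


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self, rng):
        mask = rng.integers(0, 2, (16, 16))
        c = confusion(mask, mask, 1)
        assert c.fp == 0 and c.fn == 0
        assert c.total == 256

    def test_complement_prediction_has_no_hits(self):
        true = np.array([[1, 0], [1, 0]])
        c = confusion(1 - true, true, 1)
        assert c.tp == 0 and c.tn == 0

    def test_four_pixel_hand_count(self):
        pred = np.array([1, 1, 0, 0])
        true = np.array([1, 0, 1, 0])
        c = confusion(pred, true, 1)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes"):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)), 1)


class TestDice:
    @pytest.mark.parametrize("counts,expected", [
        (ConfusionCounts(5, 0, 0, 3), 1.0),
        (ConfusionCounts(0, 4, 4, 0), 0.0),
        (ConfusionCounts(1, 0, 1, 2), 2 / 3),
        (ConfusionCounts(0, 0, 0, 9), 1.0),  # both masks empty: agreement
    ])
    def test_worked_values(self, counts, expected):
        assert dice_coefficient(counts) == pytest.approx(expected)

    def test_hard_dice_complements_soft_dice_loss(self, rng):
        """On binary masks with eps -> 0, Dice == 1 - soft Dice loss."""
        for _ in range(20):
            pred = rng.integers(0, 2, (12, 12))
            true = rng.integers(0, 2, (12, 12))
            if pred.sum() + true.sum() == 0:
                continue
            hard = dice_coefficient(confusion(pred, true, 1))
            soft = dice_loss(pred.astype(float), true, eps=1e-12)
            assert hard == pytest.approx(1.0 - soft, abs=1e-8)


class TestHausdorff:
    def test_identical_sets_have_zero_distance(self):
        pts = [(0, 0), (1, 2), (5, 5)]
        assert hausdorff(pts, pts) == 0.0
        assert hausdorff(pts, pts, percentile=95) == 0.0

    def test_three_four_five_pair(self):
        assert hausdorff([(0, 0)], [(3, 4)]) == pytest.approx(5.0)
        assert hausdorff([(0, 0)], [(3, 4)], percentile=95) == pytest.approx(5.0)

    def test_matches_all_pairs_double_loop_oracle(self, rng):
        for _ in range(10):
            x = rng.integers(0, 30, (20, 2))
            y = rng.integers(0, 30, (20, 2))
            d = cdist(x, y)
            expected = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hausdorff(x, y) == pytest.approx(expected)

    def test_symmetric_and_percentile_ordered(self, rng):
        x = rng.integers(0, 20, (15, 2))
        y = rng.integers(0, 20, (12, 2))
        assert hausdorff(x, y) == pytest.approx(hausdorff(y, x))
        assert hausdorff(x, y, 95) <= hausdorff(x, y, 100) + 1e-12

    def test_translation_invariance(self, rng):
        x = rng.integers(0, 20, (10, 2))
        y = rng.integers(0, 20, (10, 2))
        assert hausdorff(x + 7, y + 7) == pytest.approx(hausdorff(x, y))

    def test_empty_set_raises_undefined(self):
        with pytest.raises(UndefinedMetricError):
            hausdorff([], [(1, 1)])


class TestDiceLoss:
    def test_perfect_overlap_is_near_zero(self, rng):
        mask = rng.integers(0, 2, (8, 8)).astype(float)
        mask[0, 0] = 1.0
        assert dice_loss(mask, mask) < 1e-5

    def test_empty_vs_empty_is_exactly_zero(self):
        z = np.zeros((4, 4))
        assert dice_loss(z, z) == 0.0

    def test_total_miss_approaches_one_as_eps_vanishes(self):
        true = np.ones(100)
        pred = np.zeros(100)
        assert dice_loss(pred, true, eps=1e-12) == pytest.approx(1.0, abs=1e-10)

    def test_probabilities_outside_unit_interval_raise(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            dice_loss(np.array([1.5]), np.array([1.0]))


class TestFocalLoss:
    def test_gamma_zero_is_binary_cross_entropy(self, rng):
        p = rng.uniform(0.05, 0.95, (6, 6))
        t = rng.integers(0, 2, (6, 6)).astype(float)
        bce = -(t * np.log(p) + (1 - t) * np.log(1 - p)).sum()
        assert focal_loss(p, t, gamma=0.0) == pytest.approx(bce, rel=1e-10)

    def test_confident_correct_prediction_is_near_zero(self):
        t = np.array([1.0, 0.0])
        p = np.array([1.0, 0.0])
        assert focal_loss(p, t, gamma=2.0) < 1e-5

    def test_single_pixel_worked_value(self):
        # y=1, y'=0.5, gamma=2: -(0.5)^2 * log(0.5) = 0.1733
        val = focal_loss(np.array([0.5]), np.array([1.0]), gamma=2.0)
        assert val == pytest.approx(0.25 * np.log(2.0), rel=1e-6)
        assert val == pytest.approx(0.1733, abs=5e-5)


class TestCombinedLoss:
    def test_weight_collapse_to_dice(self, rng):
        p = rng.uniform(0, 1, (5, 5))
        t = rng.integers(0, 2, (5, 5)).astype(float)
        cfg = LossConfig(alpha=1.0, beta=0.0)
        assert combined_loss(p, t, cfg) == pytest.approx(dice_loss(p, t, cfg.epsilon))

    def test_reference_weighting_is_exact_linear_combination(self, rng):
        p = rng.uniform(0, 1, (5, 5))
        t = rng.integers(0, 2, (5, 5)).astype(float)
        cfg = LossConfig(alpha=0.8, beta=0.2)
        expected = 0.8 * dice_loss(p, t, cfg.epsilon) + 0.2 * focal_loss(
            p, t, cfg.gamma, cfg.clip, cfg.reduction
        )
        assert combined_loss(p, t, cfg) == expected

    def test_homogeneity_in_the_weights(self, rng):
        p = rng.uniform(0, 1, (5, 5))
        t = rng.integers(0, 2, (5, 5)).astype(float)
        one = combined_loss(p, t, LossConfig(alpha=0.8, beta=0.2))
        two = combined_loss(p, t, LossConfig(alpha=1.6, beta=0.4))
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_finite_numeric_gradient_along_probs(self):
        p = np.full((4, 4), 0.3)
        t = np.zeros((4, 4))
        t[1:3, 1:3] = 1.0
        eps = 1e-5
        lo = combined_loss(np.clip(p - eps, 0, 1), t)
        hi = combined_loss(np.clip(p + eps, 0, 1), t)
        g = (hi - lo) / (2 * eps)
        assert np.isfinite(g)


class TestFullReport:
    def test_perfect_prediction_scores(self, rng):
        mask = np.zeros((16, 16), dtype=int)
        mask[4:9, 5:10] = 1
        rep = full_report(mask, mask, classes=[1])
        row = rep.per_class[1]
        assert row["Accuracy"] == 1.0 and row["Dice"] == 1.0
        assert row["Sensitivity"] == 1.0 and row["Specificity"] == 1.0
        assert row["H95"] == 0.0

    def test_toy_counts_give_half_everywhere(self):
        pred = np.array([[1, 1], [0, 0]])
        true = np.array([[1, 0], [1, 0]])
        row = full_report(pred, true, classes=[1]).per_class[1]
        for col in ("Accuracy", "Dice", "Sensitivity", "Specificity"):
            assert row[col] == pytest.approx(0.5)

    def test_report_columns_match_table_header(self):
        assert REPORT_COLUMNS == ("Accuracy", "Dice", "Sensitivity", "Specificity", "H95")
        rep = full_report(np.ones((4, 4), int), np.ones((4, 4), int), classes=[1])
        assert tuple(rep.per_class[1]) == REPORT_COLUMNS

    def test_empty_vs_nonempty_h95_is_undefined_and_counted(self):
        pred = np.zeros((8, 8), int)
        true = np.zeros((8, 8), int)
        true[2:4, 2:4] = 1
        rep = full_report(pred, true, classes=[1])
        assert rep.per_class[1]["H95"] is None
        assert rep.n_undefined >= 1

    def test_aggregate_is_mean_over_cases(self):
        a = full_report(np.ones((4, 4), int), np.ones((4, 4), int), classes=[1])
        pred = np.zeros((4, 4), int)
        pred[0, 0] = 1
        true = np.zeros((4, 4), int)
        true[0, 0] = 1
        true[1, 1] = 1
        b = full_report(pred, true, classes=[1])
        agg = aggregate_reports([a, b])
        assert agg["Dice"] == pytest.approx(
            (a.aggregate()["Dice"] + b.aggregate()["Dice"]) / 2
        )

    def test_csv_has_table_column_order(self):
        rep = full_report(np.ones((4, 4), int), np.ones((4, 4), int), classes=[1])
        csv = reports_to_csv([rep])
        assert csv.splitlines()[0] == "case_id,Accuracy,Dice,Sensitivity,Specificity,H95"

    def test_count_metrics_invariant_under_common_permutation(self, rng):
        pred = rng.integers(0, 2, 64)
        true = rng.integers(0, 2, 64)
        perm = rng.permutation(64)
        c1 = confusion(pred, true, 1)
        c2 = confusion(pred[perm], true[perm], 1)
        assert c1 == c2


class TestSegmentationLoss:
    def test_multiclass_averages_foreground_classes(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(2, 8, 8)).transpose(0, 3, 1, 2)
        labels = rng.integers(0, 3, (2, 8, 8))
        cfg = LossConfig()
        expected = np.mean([
            combined_loss(probs[:, c], (labels == c).astype(float), cfg)
            for c in (1, 2)
        ])
        assert segmentation_loss(probs, labels, cfg) == pytest.approx(expected)


def test_boundary_points_of_a_square_ring():
    mask = np.zeros((8, 8), dtype=bool)
    mask[2:6, 2:6] = True
    pts = {tuple(p) for p in boundary_points(mask)}
    inner = {(3, 3), (3, 4), (4, 3), (4, 4)}
    assert inner.isdisjoint(pts)
    assert (2, 2) in pts and (5, 5) in pts and len(pts) == 12
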