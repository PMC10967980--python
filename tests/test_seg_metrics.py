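import numpy as np
import pytest

from ctenhance.errors import ValidationError
from ctenhance.seg_metrics import (
    METRIC_NAMES,
    ConfusionCounts,
    aggregate,
    compare,
    confusion_counts,
    dice_from_iou,
    metrics_row,
    read_report,
    write_report,
)


def loop_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Independent oracle: explicit double loop over pixels, scalar math."""
    tp = fp = fn = tn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            p, t = int(pred[r, c]), int(truth[r, c])
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1

    def ratio(num, den, agree):
        return num / den if den else (1.0 if agree else 0.0)

    precision = ratio(tp, tp + fp, fn == 0)
    recall = ratio(tp, tp + fn, fp == 0)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "iou": ratio(tp, tp + fp + fn, True),
        "dice": ratio(2 * tp, 2 * tp + fp + fn, True),
        "accuracy": (tp + tn) / (tp + fp + fn + tn),
        "precision": precision,
        "recall": recall,
        "sensitivity": recall,
        "f1": 2 * precision * recall / (precision + recall) if precision + recall else 0.0,
        "specificity": ratio(tn, tn + fp, fn == 0),
    }


def random_mask_pairs(n, shape=(16, 16), seed=50):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        density = rng.uniform(0.0, 1.0)
        yield (
            (rng.random(shape) < density).astype(np.uint8),
            (rng.random(shape) < rng.uniform(0.0, 1.0)).astype(np.uint8),
        )


class TestConfusionCounts:
    def test_all_ones_agreement(self):
        c = confusion_counts(np.ones((10, 10), np.uint8), np.ones((10, 10), np.uint8))
        assert (c.tp, c.fp, c.fn, c.tn) == (100, 0, 0, 0)

    def test_all_false_positive(self):
        c = confusion_counts(np.ones((10, 10), np.uint8), np.zeros((10, 10), np.uint8))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 100, 0, 0)

    def test_enumerable_2x2(self):
        c = confusion_counts(
            np.array([[1, 0], [0, 0]], np.uint8), np.array([[1, 1], [0, 0]], np.uint8)
        )
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 1, 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts(np.zeros((2, 2), np.uint8), np.zeros((3, 3), np.uint8))

    def test_nonbinary_values_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts(np.full((2, 2), 2, np.uint8), np.zeros((2, 2), np.uint8))


class TestMetricsRow:
    def test_perfect_segmentation_scores_all_ones(self):
        row = metrics_row(ConfusionCounts(tp=50, fp=0, fn=0, tn=50))
        assert all(getattr(row, m) == 1.0 for m in METRIC_NAMES)

    def test_disjoint_nonempty_masks(self):
        row = metrics_row(ConfusionCounts(tp=0, fp=10, fn=10, tn=80))
        for m in ("iou", "dice", "precision", "recall", "f1"):
            assert getattr(row, m) == 0.0

    def test_enumerated_2x2_values(self):
        row = metrics_row(ConfusionCounts(tp=1, fp=0, fn=1, tn=2))
        assert row.iou == 0.5
        assert row.dice == pytest.approx(2 / 3)
        assert row.accuracy == 0.75
        assert row.precision == 1.0
        assert row.recall == 0.5
        assert row.specificity == 1.0

    def test_both_masks_empty_is_perfect_agreement(self):
        row = metrics_row(ConfusionCounts(tp=0, fp=0, fn=0, tn=4))
        assert row.iou == row.dice == row.precision == row.recall == row.f1 == 1.0

    def test_identities_and_oracle_on_random_masks(self):
        for pred, truth in random_mask_pairs(200):
            row = metrics_row(confusion_counts(pred, truth))
            ref = loop_metrics(pred, truth)
            for m in METRIC_NAMES:
                if m == "f1":
                    # oracle evaluates 2PR/(P+R); implementation uses the
                    # algebraically identical count form (1-ulp differences)
                    assert getattr(row, m) == pytest.approx(ref[m], abs=1e-12)
                else:
                    assert getattr(row, m) == ref[m], m
            assert row.f1 == row.dice
            assert row.recall == row.sensitivity
            assert row.dice == pytest.approx(dice_from_iou(row.iou), abs=1e-15)

    def test_swap_symmetry(self):
        for pred, truth in random_mask_pairs(50, seed=51):
            a = metrics_row(confusion_counts(pred, truth))
            b = metrics_row(confusion_counts(truth, pred))
            assert a.iou == b.iou and a.dice == b.dice and a.accuracy == b.accuracy
            assert a.precision == b.recall and a.recall == b.precision

    def test_complement_duality_swaps_sensitivity_and_specificity(self):
        for pred, truth in random_mask_pairs(50, seed=52):
            a = metrics_row(confusion_counts(pred, truth))
            b = metrics_row(confusion_counts(1 - pred, 1 - truth))
            assert a.sensitivity == b.specificity
            assert a.specificity == b.sensitivity


class TestDiceFromIoU:
    @pytest.mark.parametrize("j, expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_endpoints(self, j, expected):
        assert dice_from_iou(j) == expected

    @pytest.mark.parametrize("j, printed", [(0.6667, 0.8000), (0.9635, 0.9814)])
    def test_published_benchmark_rows(self, j, printed):
        assert round(dice_from_iou(j), 4) == printed

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            dice_from_iou(1.5)


class TestAggregateAndCompare:
    def _rows(self, values):
        from ctenhance.seg_metrics import MetricsRow

        return [
            MetricsRow(case_id=str(i + 1), **dict(zip(METRIC_NAMES, v)))
            for i, v in enumerate(values)
        ]

    def test_single_row_mean_equals_row(self):
        rows = self._rows([[0.5, 2 / 3, 0.75, 1.0, 0.5, 0.5, 2 / 3, 1.0]])
        report = aggregate(rows)
        assert report.mean_row.values() == rows[0].values()

    def test_identical_rows_mean_equals_common_row(self):
        rows = self._rows([[0.9, 0.95, 0.99, 0.9, 0.92, 0.92, 0.95, 0.99]] * 10)
        report = aggregate(rows)
        for m in METRIC_NAMES:
            assert getattr(report.mean_row, m) == pytest.approx(getattr(rows[0], m))

    def test_mean_within_column_bounds(self):
        rng = np.random.default_rng(53)
        rows = self._rows(rng.random((7, 8)).tolist())
        report = aggregate(rows)
        for m in METRIC_NAMES:
            col = [getattr(r, m) for r in rows]
            assert min(col) <= getattr(report.mean_row, m) <= max(col)

    def test_empty_rows_rejected(self):
        with pytest.raises(ValidationError):
            aggregate([])

    def test_compare_uses_rounded_mean_convention(self):
        a = aggregate(self._rows([[0.90005] * 8]))  # mean rounds to 0.9001 (half-up at 4dp)
        b = aggregate(self._rows([[0.8] * 8]))
        deltas = compare(a, b)
        assert deltas["iou"] == round(round(0.90005, 4) - 0.8, 4)

    @pytest.mark.parametrize("ext", ["csv", "json"])
    def test_report_round_trip(self, tmp_path, ext):
        rng = np.random.default_rng(54)
        rows = self._rows(np.round(rng.random((3, 8)), 4).tolist())
        report = aggregate(rows)
        path = tmp_path / f"report.{ext}"
        write_report(report, path)
        back = read_report(path)
        assert [r.case_id for r in back.rows] == ["1", "2", "3"]
        for orig, rt in zip(report.rows, back.rows):
            for m in METRIC_NAMES:
                assert getattr(rt, m) == pytest.approx(getattr(orig, m), abs=5e-5)
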