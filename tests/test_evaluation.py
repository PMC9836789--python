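"""Metric formulas, macro/micro identities, ROC-AUC and Grad-CAM contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionfusion import evaluation as ev
from lesionfusion import nn
from tests.conftest import TINY_INPUT, tiny_model


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(np.arange(7), 2)
        cm = ev.confusion_matrix(y, y)
        np.testing.assert_array_equal(cm.counts, np.eye(7, dtype=int) * 2)

    def test_single_confusion_cell(self):
        # two melanomas called nevi: the classic Mel-as-Nv error
        cm = ev.confusion_matrix([4, 4], [5, 5])
        assert cm.counts[4, 5] == 2
        assert cm.counts.sum() == 2

    def test_row_sums_equal_supports(self, rng):
        y_true = rng.integers(0, 7, 100)
        y_pred = rng.integers(0, 7, 100)
        cm = ev.confusion_matrix(y_true, y_pred)
        assert cm.total == 100
        for c in range(7):
            assert cm.supports[c] == (y_true == c).sum()
            tp, tn, fp, fn = cm.one_vs_rest(c)
            assert tp + tn + fp + fn == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            ev.confusion_matrix([0, 1], [0])


class TestClassMetrics:
    @pytest.mark.parametrize("precision,recall,f1", [
        # published two-stream comparison table, F1 column to two decimals
        (66.43, 75.09, 70.50),
        (77.85, 85.52, 81.50),
        (80.94, 87.61, 84.14),
        (83.53, 95.04, 88.91),
        (76.47, 83.23, 79.71),
        (82.88, 94.10, 88.13),
    ])
    def test_f1_worked_examples(self, precision, recall, f1):
        assert round(ev.f1_from_precision_recall(precision, recall), 2) == f1

    def test_equal_precision_recall_gives_same_f1(self):
        assert ev.f1_from_precision_recall(64.0, 64.0) == pytest.approx(64.0)

    def test_degenerate_zero_counts_flagged(self):
        counts = np.zeros((7, 7), dtype=int)
        counts[0, 1] = 3  # class 0 never predicted as itself, class 1 never actual
        metrics = ev.class_metrics(ev.ConfusionMatrix(counts))
        row = metrics.per_class.loc["Akiec"]
        assert row["precision"] == 0.0 and row["recall"] == 0.0
        assert any("Akiec" in f for f in metrics.zero_division_flags)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_micro_identity_on_random_label_sets(self, seed):
        """micro-precision = micro-recall = micro-F1 = accuracy for
        single-label multiclass predictions."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        y_true = rng.integers(0, 7, n)
        y_pred = rng.integers(0, 7, n)
        m = ev.class_metrics(ev.confusion_matrix(y_true, y_pred))
        assert m.micro["precision"] == pytest.approx(m.accuracy)
        assert m.micro["recall"] == pytest.approx(m.accuracy)
        assert m.micro["f1"] == pytest.approx(m.accuracy)

    def test_f1_between_precision_and_recall(self, rng):
        y_true = rng.integers(0, 7, 200)
        y_pred = rng.integers(0, 7, 200)
        m = ev.class_metrics(ev.confusion_matrix(y_true, y_pred))
        for _, row in m.per_class.iterrows():
            lo = min(row["precision"], row["recall"])
            hi = max(row["precision"], row["recall"])
            assert lo - 1e-9 <= row["f1"] <= hi + 1e-9

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import precision_recall_fscore_support
        y_true = rng.integers(0, 7, 150)
        y_pred = rng.integers(0, 7, 150)
        m = ev.class_metrics(ev.confusion_matrix(y_true, y_pred))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(7), average="macro", zero_division=0)
        assert m.macro["precision"] == pytest.approx(100 * p)
        assert m.macro["recall"] == pytest.approx(100 * r)


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        scores = np.eye(7)[y] * 0.9 + 0.1 / 7
        res = ev.roc_auc(y, scores / scores.sum(1, keepdims=True))
        for _, (_, _, a) in res.per_class.items():
            assert a == pytest.approx(1.0)

    def test_identical_scores_give_chance_auc(self):
        y = np.array([0, 1] * 5)
        scores = np.full((10, 7), 1 / 7)
        res = ev.roc_auc(y, scores)
        for _, (_, _, a) in res.per_class.items():
            assert a == pytest.approx(0.5)

    def test_binary_toy_matches_mann_whitney(self, rng):
        """AUC equals the Mann-Whitney U statistic / (n1*n0)."""
        from scipy.stats import mannwhitneyu
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        p1 = rng.random(10)
        scores = np.zeros((10, 7))
        scores[:, 1] = p1
        scores[:, 0] = 1 - p1
        res = ev.roc_auc(y, scores)
        u = mannwhitneyu(p1[y == 1], p1[y == 0], alternative="two-sided").statistic
        assert res.per_class["Bcc"][2] == pytest.approx(u / 25)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 3, 40)
        raw = rng.random((40, 7))
        scores = raw / raw.sum(1, keepdims=True)
        warped = np.exp(3 * scores)
        a1 = ev.roc_auc(y, scores)
        with pytest.warns(UserWarning):
            a2 = ev.roc_auc(y, warped)
        for name in a1.per_class:
            assert a1.per_class[name][2] == pytest.approx(a2.per_class[name][2])

    def test_absent_class_excluded_from_macro_with_warning(self):
        y = np.array([0, 0, 1, 1])
        scores = np.full((4, 7), 1 / 7)
        with pytest.warns(UserWarning, match="absent"):
            res = ev.roc_auc(y, scores)
        assert set(res.per_class) == {"Akiec", "Bcc"}
        assert len(res.skipped) == 5

    def test_curves_span_unit_square(self, rng):
        y = rng.integers(0, 7, 60)
        raw = rng.random((60, 7))
        res = ev.roc_auc(y, raw / raw.sum(1, keepdims=True))
        for fpr, tpr, a in res.per_class.values():
            assert fpr[0] == 0 and tpr[0] == 0
            assert fpr[-1] == 1 and tpr[-1] == 1
            assert 0 <= a <= 1


class TestGradCam:
    @pytest.fixture(scope="class")
    def model(self):
        return tiny_model(seed=3)

    def test_output_contract(self, model, rng):
        img = rng.random((3, TINY_INPUT, TINY_INPUT)).astype(np.float32)
        cam = ev.grad_cam(model, img, target_class=2)
        assert cam.shape == (TINY_INPUT, TINY_INPUT)
        assert cam.min() >= 0 and cam.max() <= 1

    def test_accepts_uint8_hwc_images(self, model, rng):
        img = rng.integers(0, 255, (TINY_INPUT, TINY_INPUT, 3), dtype=np.uint8)
        cam = ev.grad_cam(model, img, target_class=0)
        assert cam.shape == (TINY_INPUT, TINY_INPUT)

    def test_zero_head_weights_give_zero_map(self, rng):
        model = tiny_model(seed=4)
        model.head.weight.data[:] = 0
        model.head.bias.data[:] = 0
        img = rng.random((3, TINY_INPUT, TINY_INPUT)).astype(np.float32)
        cam = ev.grad_cam(model, img, target_class=1)
        np.testing.assert_array_equal(cam, 0.0)

    def test_invalid_layer_rejected(self, model, rng):
        img = rng.random((3, TINY_INPUT, TINY_INPUT)).astype(np.float32)
        with pytest.raises(ValueError, match="not a convolutional feature map"):
            ev.grad_cam(model, img, 0, layer="head")


class TestReport:
    def test_perfect_classifier_reports_all_100(self):
        y = np.repeat(np.arange(7), 3)
        scores = np.eye(7)[y]
        rep = ev.evaluate_predictions(y, y, scores)
        s = rep.summary()
        assert s["accuracy"] == 100.0 and s["f1"] == 100.0
        assert s["micro_auc"] == 1.0 and s["macro_auc"] == 1.0

    def test_delta_reproduces_published_gain(self):
        """The residual-augmented stream's precision gain over plain VGG-16."""
        improved = {"precision": 77.85, "recall": 85.52, "f1": 81.50, "accuracy": 87.60}
        plain = {"precision": 66.43, "recall": 75.09, "f1": 70.50, "accuracy": 72.48}
        delta = ev.report_delta(improved, plain)
        assert delta == {"precision": 11.42, "recall": 10.43,
                         "f1": 11.00, "accuracy": 15.12}

    def test_delta_with_self_is_zero(self):
        y = np.repeat(np.arange(7), 2)
        rep = ev.evaluate_predictions(y, y)
        assert all(v == 0 for v in ev.report_delta(rep, rep).values())

    def test_report_writes_tables(self, tmp_path, rng):
        y = rng.integers(0, 7, 40)
        raw = rng.random((40, 7))
        rep = ev.evaluate_predictions(y, y, raw / raw.sum(1, keepdims=True))
        tables = ev.report(rep, out_dir=tmp_path)
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "confusion.csv").exists()
        assert (tmp_path / "roc_points.csv").exists()
        assert {"metrics", "confusion", "roc_points"} <= set(tables)
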