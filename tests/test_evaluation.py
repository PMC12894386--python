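"""Metrics, McNemar's test, noise sweep, feature export, Grad-CAM."""

import numpy as np
import pytest

import lightwavenet._engine as E
from lightwavenet.errors import UsageError
from lightwavenet.evaluation import (
    evaluate,
    evaluate_predictions,
    export_features,
    grad_cam,
    intra_class_variance,
    mcnemar_test,
    noise_sweep,
)

from _oracles import mcnemar_exact_oracle


class TestMetrics:
    def test_perfect_classifier(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = evaluate_predictions(y, y)
        assert rep.accuracy == 1.0
        assert np.all(rep.per_class_precision == 1.0)
        assert np.all(rep.per_class_recall == 1.0)
        assert np.all(rep.per_class_f1 == 1.0)
        assert rep.confusion.trace() == rep.n

    def test_two_class_confusion_example(self):
        # confusion [[8,2],[3,7]]
        y_true = np.array([0] * 10 + [1] * 10)
        y_pred = np.array([0] * 8 + [1] * 2 + [0] * 3 + [1] * 7)
        rep = evaluate_predictions(y_true, y_pred)
        assert rep.confusion.tolist() == [[8, 2], [3, 7]]
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.per_class_precision[0] == pytest.approx(8 / 11)
        assert rep.per_class_recall[0] == pytest.approx(0.8)
        assert rep.per_class_f1[0] == pytest.approx(0.7619, abs=1e-4)
        # macro values are plain means of the per-class vectors
        assert rep.macro_f1 == pytest.approx(rep.per_class_f1.mean())

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 40)
        y_pred = rng.integers(0, 3, 40)
        perm = rng.permutation(40)
        a = evaluate_predictions(y_true, y_pred, 3)
        b = evaluate_predictions(y_true[perm], y_pred[perm], 3)
        assert np.array_equal(a.confusion, b.confusion)
        assert a.accuracy == b.accuracy

    def test_zero_predicted_positives_flagged_not_crashing(self):
        rep = evaluate_predictions(np.array([0, 1, 1]), np.array([0, 0, 0]), 2)
        assert rep.per_class_precision[1] == 0.0
        assert 1 in rep.zero_division_classes

    def test_report_serializes(self, tmp_path):
        rep = evaluate_predictions(np.array([0, 1]), np.array([0, 1]), 2)
        rep.to_json(tmp_path / "r.json")
        rep.confusion_to_csv(tmp_path / "c.csv")
        assert (tmp_path / "r.json").stat().st_size > 0
        assert (tmp_path / "c.csv").read_text().strip().splitlines() == ["1,0", "0,1"]


class TestMcNemar:
    def test_identical_predictions(self):
        y = np.array([0, 1, 0, 1])
        res = mcnemar_test(y, y, y)
        assert res == {"b_count": 0, "c_count": 0, "p_value": 1.0}

    def test_ten_zero_discordance(self):
        labels = np.zeros(10, dtype=int)
        preds_a = np.zeros(10, dtype=int)          # always right
        preds_b = np.ones(10, dtype=int)           # always wrong
        res = mcnemar_test(preds_a, preds_b, labels)
        assert res["b_count"] == 10 and res["c_count"] == 0
        assert res["p_value"] == pytest.approx(2 * 0.5**10, rel=1e-6)
        assert res["p_value"] < 0.05

    def test_symmetric_discordance_is_insignificant(self):
        labels = np.zeros(10, dtype=int)
        preds_a = np.array([0] * 5 + [1] * 5)
        preds_b = np.array([1] * 5 + [0] * 5)
        assert mcnemar_test(preds_a, preds_b, labels)["p_value"] == pytest.approx(1.0)

    def test_exact_pvalues_match_full_enumeration(self):
        for n in range(1, 13):
            for b in range(n + 1):
                c = n - b
                labels = np.zeros(n + 4, dtype=int)
                preds_a = np.array([0] * b + [1] * c + [0, 0, 1, 1])
                preds_b = np.array([1] * b + [0] * c + [0, 0, 1, 1])
                got = mcnemar_test(preds_a, preds_b, labels)
                assert (got["b_count"], got["c_count"]) == (b, c)
                assert got["p_value"] == pytest.approx(
                    mcnemar_exact_oracle(b, c), rel=1e-9
                ), f"b={b} c={c}"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test(np.zeros(3), np.zeros(4), np.zeros(3))


class TestModelEvaluation:
    def test_evaluate_counts_every_record(self, trained_micro, synth_split):
        rep = evaluate(trained_micro, synth_split.test)
        assert rep.n == len(synth_split.test)
        assert rep.confusion.sum() == rep.n
        assert 0.0 <= rep.accuracy <= 1.0

    def test_noise_sweep_level_zero_equals_plain_accuracy(self, trained_micro, synth_split):
        rep = evaluate(trained_micro, synth_split.test)
        sweep = noise_sweep(trained_micro, synth_split.test, levels=(0.0, 0.1), seed=0)
        assert sweep[0.0] == pytest.approx(rep.accuracy)
        again = noise_sweep(trained_micro, synth_split.test, levels=(0.0, 0.1), seed=0)
        assert sweep == again


class TestFeatures:
    def test_export_dimensions_follow_stage_widths(self, trained_micro, synth_split):
        cfg = trained_micro.config
        for stage, dim in zip((1, 2, 3, 4), cfg.stage_channels):
            feats, labels = export_features(trained_micro, synth_split.test[:6], stage)
            assert feats.shape == (6, dim)
            assert labels.shape == (6,)

    def test_intra_class_variance_degenerate_and_duplication(self):
        x = np.random.default_rng(0).normal(size=(12, 5))
        y = np.repeat([0, 1, 2], 4)
        v = intra_class_variance(x, y)
        assert v > 0
        assert intra_class_variance(np.vstack([x, x]), np.concatenate([y, y])) == (
            pytest.approx(v)
        )
        same = np.tile(x[0], (6, 1))
        assert intra_class_variance(same, np.zeros(6, int)) == pytest.approx(0.0)


class TestGradCam:
    def test_heatmap_contract(self, trained_micro, synth_split):
        img = synth_split.test[0].pixels
        cam = grad_cam(trained_micro, img, target_class=synth_split.test[0].label)
        assert cam.shape == img.shape[1:]
        assert cam.min() >= 0.0 and cam.max() <= 1.0
        assert cam.max() > 0  # the predicted class leaves evidence
        again = grad_cam(trained_micro, img, target_class=synth_split.test[0].label)
        assert np.array_equal(cam, again)

    def test_requires_gradient_tracking(self, trained_micro, synth_split):
        with E.no_grad():
            with pytest.raises(UsageError, match="no_grad"):
                grad_cam(trained_micro, synth_split.test[0].pixels, 0)

    def test_rejects_bad_inputs(self, trained_micro, synth_split):
        with pytest.raises(ValueError):
            grad_cam(trained_micro, synth_split.test[0].pixels, target_class=99)
        with pytest.raises(ValueError):
            grad_cam(trained_micro, synth_split.test[0].pixels, 0, stage=7)
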