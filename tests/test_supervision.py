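"""Loss formulas, gradient routing, training loop, and cross-validation."""

import numpy as np
import pytest

import lightwavenet._engine as E
from lightwavenet._engine import autograd as F
from lightwavenet.data import DatasetSplit
from lightwavenet.errors import ConfigError, DataError, UsageError
from lightwavenet.network import LightWaveNet
from lightwavenet.supervision import (
    LossConfig,
    TrainConfig,
    cross_entropy,
    cross_validate,
    multi_stage_loss,
    train,
)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy(np.array([0.0, 1.0, 0.0]), 1) == 0.0

    def test_uniform_ten_way_is_ln10(self):
        assert cross_entropy(np.full(10, 0.1), 4) == pytest.approx(np.log(10.0))

    def test_hand_computed_value(self):
        assert cross_entropy(np.array([0.7, 0.2, 0.1]), 1) == pytest.approx(
            1.609438, abs=1e-6
        )

    def test_zero_probability_is_large_but_finite(self):
        v = cross_entropy(np.array([1.0, 0.0]), 1)
        assert np.isfinite(v) and v > 20

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_one_hot_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(6))
        label = int(rng.integers(6))
        onehot = np.zeros(6)
        onehot[label] = 1.0
        oracle = -float(np.sum(onehot * np.log(np.maximum(p, 1e-12))))
        assert cross_entropy(p, label) == pytest.approx(oracle)

    def test_rejects_non_probability_input(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([0.5, 0.1]), 0)


class TestMultiStageLoss:
    def test_lambda_zero_keeps_only_the_main_loss(self):
        assert multi_stage_loss(2.5, [9.0, 9.0, 9.0], 0.0) == 2.5

    def test_lambda_one_keeps_only_the_aux_sum(self):
        assert multi_stage_loss(2.5, [1.0, 2.0, 3.0], 1.0) == 6.0

    def test_default_weighting_arithmetic(self):
        assert multi_stage_loss(1.0, [1.0, 1.0, 1.0], 0.1) == pytest.approx(1.2)

    def test_missing_aux_terms_rejected(self):
        with pytest.raises(UsageError):
            multi_stage_loss(1.0, [1.0, 1.0], 0.1)
        with pytest.raises(ConfigError):
            multi_stage_loss(1.0, [1.0] * 3, 1.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_linear_in_each_argument(self, seed):
        rng = np.random.default_rng(seed)
        lam = float(rng.uniform(0, 1))
        m, aux = float(rng.normal()), list(rng.normal(size=3))
        a = multi_stage_loss(2 * m, aux, lam)
        b = multi_stage_loss(0.0, aux, lam)
        assert a - b == pytest.approx((1 - lam) * 2 * m, abs=1e-9)


def test_aux_loss_routes_gradient_into_stage_one(micro_config):
    model = LightWaveNet(micro_config, seed=0)
    model.train(True)
    # give the (zero-initialized) aux head nonzero weights so its loss can
    # propagate into the features, as it does after the first optimizer step
    rng = np.random.default_rng(0)
    w = model.aux_heads[0].fc.weight
    w.data = rng.normal(0, 0.1, size=w.data.shape).astype(np.float32)
    x = np.random.default_rng(0).random((4, 3, 64, 64), dtype=np.float32)
    out = model.forward(x)
    loss = F.cross_entropy_logits(out.aux_logits[0], np.array([0, 1, 2, 3]))
    loss.backward()
    stage1_grads = [
        p.grad for name, p in model.named_parameters() if name.startswith("stages.0.")
    ]
    assert any(g is not None and np.abs(g).max() > 0 for g in stage1_grads)
    assert model.head.weight.grad is None  # main head untouched by the aux loss


class TestTrainLoop:
    def test_loss_decreases_and_log_is_complete(self, micro_config, synth_split, tmp_path):
        model = LightWaveNet(micro_config, seed=0)
        log = train(
            model,
            synth_split,
            TrainConfig(epochs=3, batch_size=16),
            LossConfig(),
            seed=0,
            log_path=tmp_path / "log.jsonl",
        )
        assert len(log.epochs) == 3
        assert log.epochs[-1].train_loss < log.epochs[0].train_loss
        lines = (tmp_path / "log.jsonl").read_text().strip().splitlines()
        assert len(lines) == 3

    def test_same_seed_reproduces_loss_trajectory(self, micro_config, synth_split):
        runs = []
        for _ in range(2):
            model = LightWaveNet(micro_config, seed=5)
            log = train(model, synth_split, TrainConfig(epochs=2, batch_size=16),
                        LossConfig(), seed=5)
            runs.append([r.train_loss for r in log.epochs])
        assert runs[0] == runs[1]

    def test_lambda_changes_total_but_not_main_loss_of_first_epoch(
        self, micro_config, synth_split
    ):
        logs = []
        for lam in (0.0, 0.1):
            model = LightWaveNet(micro_config, seed=5)
            logs.append(
                train(model, synth_split, TrainConfig(epochs=1, batch_size=16),
                      LossConfig(lambda_aux=lam), seed=5)
            )
        assert logs[0].epochs[0].train_loss != logs[1].epochs[0].train_loss
        # identical batches and weights before the first update -> aux losses logged
        assert logs[0].epochs[0].train_aux_loss > 0

    def test_empty_split_rejected(self, micro_config):
        model = LightWaveNet(micro_config, seed=0)
        with pytest.raises(DataError):
            train(model, DatasetSplit([], [], []), TrainConfig(epochs=1), LossConfig())


class TestCrossValidate:
    def test_each_sample_held_out_exactly_once(self, micro_config, synth_records):
        result = cross_validate(
            synth_records,
            lambda s: LightWaveNet(micro_config, seed=s),
            k=3,
            tcfg=TrainConfig(epochs=1, batch_size=16),
            lcfg=LossConfig(),
            seed=0,
        )
        assert len(result.fold_accuracies) == 3
        counts = np.bincount(result.fold_assignments, minlength=3)
        assert counts.sum() == len(synth_records)
        assert counts.min() >= len(synth_records) // 3 - 2
        assert result.mean_accuracy == pytest.approx(
            float(np.mean(result.fold_accuracies))
        )

    def test_fold_assignment_is_seed_deterministic(self, synth_records):
        from lightwavenet.supervision import _fold_assignments

        labels = np.array([r.label for r in synth_records])
        a = _fold_assignments(labels, 4, seed=9)
        b = _fold_assignments(labels, 4, seed=9)
        assert np.array_equal(a, b)
        # stratified: each fold carries a balanced share of every class
        for f in range(4):
            per_class = np.bincount(labels[a == f], minlength=4)
            assert per_class.max() - per_class.min() <= 1

    def test_k_below_two_rejected(self, micro_config, synth_records):
        with pytest.raises(ConfigError):
            cross_validate(synth_records, lambda s: LightWaveNet(micro_config, seed=s), k=1)
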