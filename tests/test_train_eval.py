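"""Learning-rate schedule, fold construction and the training loop."""

import numpy as np
import pytest

from eegemotion import (
    LabelScheme,
    ModelConfig,
    TrainConfig,
    ValidationError,
    build_model,
    build_sample_set,
    cosine_lr,
    make_folds,
    run_ablation,
    run_cross_validation,
    train_one_fold,
)
from eegemotion.train_eval import evaluate, train_model


class TestCosineSchedule:
    def test_endpoints_exact(self):
        tc = TrainConfig(lr_init=1e-3, lr_final_fraction=0.1, epochs=150)
        assert cosine_lr(0, tc) == pytest.approx(1e-3, abs=1e-12)
        assert cosine_lr(149, tc) == pytest.approx(1e-4, abs=1e-12)

    def test_midpoint_is_average_of_extremes(self):
        tc = TrainConfig(lr_init=1e-3, lr_final_fraction=0.1, epochs=151)
        assert cosine_lr(75, tc) == pytest.approx(0.00055, abs=1e-12)

    def test_monotone_decrease(self):
        tc = TrainConfig(epochs=50)
        lrs = [cosine_lr(e, tc) for e in range(50)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_out_of_range_epoch_rejected(self):
        tc = TrainConfig(epochs=10)
        with pytest.raises(ValidationError):
            cosine_lr(10, tc)
        with pytest.raises(ValidationError):
            cosine_lr(-1, tc)

    def test_single_epoch_returns_initial(self):
        assert cosine_lr(0, TrainConfig(epochs=1)) == 1e-3


class TestFolds:
    def test_equal_sizes_when_divisible(self):
        folds = make_folds(12_800, 10, seed=0)
        assert [len(f) for f in folds] == [1280] * 10

    def test_partition_exhaustive_and_disjoint(self):
        for k in (3, 7, 10):
            folds = make_folds(101, k, seed=1)
            sizes = sorted(len(f) for f in folds)
            assert max(sizes) - min(sizes) <= 1
            joined = np.concatenate(folds)
            assert len(joined) == 101
            assert len(np.unique(joined)) == 101

    def test_deterministic_under_seed(self):
        a = make_folds(500, 10, seed=7)
        b = make_folds(500, 10, seed=7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)
        c = make_folds(500, 10, seed=8)
        assert any(not np.array_equal(fa, fc) for fa, fc in zip(a, c))

    def test_group_folding_keeps_groups_whole(self):
        groups = np.repeat(np.arange(20), 5)
        folds = make_folds(100, 4, seed=0, groups=groups)
        for fold in folds:
            fold_groups = groups[fold]
            for g in np.unique(fold_groups):
                assert (groups == g).sum() == (fold_groups == g).sum()

    def test_bad_k_rejected(self):
        with pytest.raises(ValidationError):
            make_folds(5, 6, seed=0)


def _toy_samples(rng, n=96, shape=(2, 9, 9)):
    """Linearly separable toy set: class mean shift on one channel."""
    y = rng.integers(0, 2, size=n)
    x = rng.normal(size=(n, *shape)).astype(np.float32) * 0.1
    x[y == 1, 0] += 0.8
    return x, y


class TestTraining:
    def test_constant_predictor_is_exactly_chance(self):
        """Zeroed head predicts one class; accuracy is exactly 50 / 25."""
        rng = np.random.default_rng(0)
        for n_classes, expected in [(2, 50.0), (4, 25.0)]:
            cfg = ModelConfig(block_channels=(2,), n_classes=n_classes, input_shape=(9, 9, 2))
            net = build_model(cfg, seed=0)
            net.head.weight.value[...] = 0.0
            net.head.bias.value[...] = 0.0
            x = rng.normal(size=(4 * n_classes, 2, 9, 9)).astype(np.float32)
            y = np.tile(np.arange(n_classes), 4)
            acc, confusion = evaluate(net, x, y)
            assert acc == expected
            assert confusion.sum() == 4 * n_classes
            assert confusion[:, 0].sum() == 4 * n_classes  # all predicted class 0

    def test_loss_decreases_on_separable_data(self, rng):
        x, y = _toy_samples(rng)
        cfg = ModelConfig(block_channels=(2, 4), n_classes=2, input_shape=(9, 9, 2))
        net = build_model(cfg, seed=0)
        tc = TrainConfig(epochs=4, batch_size=32, seed=0)
        losses = train_model(net, x, y, tc)
        assert losses[-1] < losses[0]

    def test_train_one_fold_learns_toy_problem(self, rng):
        x, y = _toy_samples(rng, n=160)
        cfg = ModelConfig(block_channels=(2, 4), n_classes=2, input_shape=(9, 9, 2))
        tc = TrainConfig(epochs=8, batch_size=32, seed=0)
        result = train_one_fold(x[:128], y[:128], x[128:], y[128:], cfg, tc)
        assert result.accuracy >= 90.0
        assert result.confusion.sum() == 32

    def test_sigmoid_head_equivalent_task(self, rng):
        x, y = _toy_samples(rng, n=128)
        cfg = ModelConfig(block_channels=(2, 4), n_classes=2, input_shape=(9, 9, 2))
        tc = TrainConfig(epochs=8, batch_size=32, seed=0, head="sigmoid")
        result = train_one_fold(x[:96], y[:96], x[96:], y[96:], cfg, tc)
        assert result.accuracy >= 90.0

    def test_nonfinite_batch_aborts_training(self, rng):
        x, y = _toy_samples(rng, n=32)
        x[5, 0, 0, 0] = np.inf
        cfg = ModelConfig(block_channels=(2,), n_classes=2, input_shape=(9, 9, 2))
        net = build_model(cfg, seed=0)
        tc = TrainConfig(epochs=1, batch_size=32, seed=0)
        with pytest.raises(ValidationError, match="non-finite|NaN"):
            train_model(net, x, y, tc)

    def test_cross_validation_reports_all_folds(self, rng):
        x, y = _toy_samples(rng, n=90)
        cfg = ModelConfig(block_channels=(2,), n_classes=2, input_shape=(9, 9, 2))
        tc = TrainConfig(epochs=2, batch_size=32, folds=3, seed=0)
        cv = run_cross_validation((x, y), cfg, tc)
        assert len(cv.fold_accuracies) == 3
        assert cv.mean_accuracy == pytest.approx(cv.fold_accuracies.mean())


class TestAblation:
    @pytest.fixture()
    def tiny_trials(self, small_trials):
        return small_trials

    def _tc(self):
        return TrainConfig(epochs=2, batch_size=64, folds=2, seed=0)

    def _mc(self):
        return ModelConfig(block_channels=(2, 4))

    def test_kernel_axis_rows(self, tiny_trials):
        table = run_ablation(
            "kernels", tiny_trials, grid=[(3,), (5, 7)],
            model_config=self._mc(), train_config=self._tc(),
            filter_method="spectral",
        )
        assert list(table["kernels"]) == ["3", "5+7"]
        assert table["mean_accuracy"].between(0, 100).all()

    def test_band_axis_rows_and_shapes(self, tiny_trials):
        table = run_ablation(
            "bands", tiny_trials, grid=[("beta", "gamma"), ("raw",)],
            model_config=self._mc(), train_config=self._tc(),
            filter_method="spectral",
        )
        assert list(table["bands"]) == ["beta+gamma", "raw"]
        assert (table["n_samples"] == 80).all()

    def test_shift_axis_truncates_tail(self, tiny_trials):
        table = run_ablation(
            "shift", tiny_trials, grid=[0.0, 2.0],
            model_config=self._mc(), train_config=self._tc(),
            filter_method="spectral",
        )
        # shift 2 s only fits 9 full segments of the 60 s window
        assert list(table["n_samples"]) == [80, 72]

    def test_unknown_axis_rejected(self, tiny_trials):
        with pytest.raises(ValidationError):
            run_ablation("optimizers", tiny_trials)
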