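"""Architecture contracts of the multi-scale-kernel CNN."""

import numpy as np
import pytest

from eegemotion import ModelConfig, ValidationError, build_block, build_model
from eegemotion.nnet import BatchNorm2d, softmax_cross_entropy

KERNEL_CONFIGS = [(3,), (5,), (7,), (3, 5), (3, 7), (5, 7), (3, 5, 7)]


def _closed_form_count(kernels, channels, depth, h, w, n_classes):
    """Independent hand-expanded parameter count."""
    total = 0
    in_ch = depth
    for out in channels:
        for k in kernels:
            total += k * k * in_ch * out + out  # branch conv
        total += len(kernels) * out * out + out  # 1x1 fusion
        total += 2 * out  # batch norm
        in_ch = out
    total += (h * w * in_ch + 1) * n_classes
    return total


class TestConfig:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(kernel_sizes=(4,))

    def test_default_has_four_blocks(self):
        assert len(ModelConfig().block_channels) == 4

    def test_parameter_count_matches_hand_expansion(self):
        cfg = ModelConfig()
        expected = _closed_form_count((5, 7), (16, 32, 64, 128), 6, 18, 18, 2)
        assert cfg.parameter_count() == expected
        net = build_model(cfg, seed=0)
        assert net.parameter_count() == expected

    @pytest.mark.parametrize("kernels", KERNEL_CONFIGS)
    def test_parameter_count_all_kernel_sets(self, kernels):
        cfg = ModelConfig(kernel_sizes=kernels, block_channels=(4, 8), n_classes=4,
                          input_shape=(18, 18, 6))
        net = build_model(cfg, seed=0)
        assert net.parameter_count() == cfg.parameter_count()
        assert cfg.parameter_count() == _closed_form_count(
            kernels, (4, 8), 6, 18, 18, 4
        )

    def test_capacity_monotone_in_kernels_and_channels(self):
        base = ModelConfig(kernel_sizes=(5,), block_channels=(8, 16))
        more_kernels = ModelConfig(kernel_sizes=(5, 7), block_channels=(8, 16))
        wider = ModelConfig(kernel_sizes=(5,), block_channels=(8, 32))
        assert more_kernels.parameter_count() > base.parameter_count()
        assert wider.parameter_count() > base.parameter_count()


class TestBlock:
    def test_branch_concat_and_fusion_depths(self, rng):
        block = build_block(6, 16, (5, 7), seed=0)
        x = rng.normal(size=(2, 6, 18, 18)).astype(np.float32)
        outs = [b.forward(x, train=False) for b in block.branches]
        assert all(o.shape == (2, 16, 18, 18) for o in outs)
        assert block.fuse.in_channels == 32  # concatenated branch maps
        assert block.forward(x, train=False).shape == (2, 16, 18, 18)

    def test_single_kernel_degenerates_to_one_branch(self, rng):
        block = build_block(6, 8, (3,), seed=0)
        assert len(block.branches) == 1
        x = rng.normal(size=(1, 6, 9, 9)).astype(np.float32)
        assert block.forward(x, train=False).shape == (1, 8, 9, 9)


class TestForward:
    @pytest.mark.parametrize("kernels", KERNEL_CONFIGS)
    def test_all_kernel_sets_build_and_preserve_spatial_size(self, kernels, rng):
        cfg = ModelConfig(kernel_sizes=kernels, block_channels=(4, 8, 8, 8))
        net = build_model(cfg, seed=0)
        x = rng.random((2, 6, 18, 18)).astype(np.float32)
        h = x
        for block in net.blocks:
            h = block.forward(h, train=False)
            assert h.shape[2:] == (18, 18)
        assert net.forward(x, train=False).shape == (2, 2)

    @pytest.mark.parametrize("n_classes", [2, 4])
    def test_head_matches_task(self, n_classes, rng):
        cfg = ModelConfig(block_channels=(4, 8), n_classes=n_classes)
        net = build_model(cfg, seed=0)
        x = rng.random((3, 6, 18, 18)).astype(np.float32)
        assert net.forward(x, train=False).shape == (3, n_classes)

    def test_raw_arm_input_shape(self, rng):
        cfg = ModelConfig(block_channels=(4, 8), input_shape=(9, 9, 6))
        net = build_model(cfg, seed=0)
        assert net.forward(rng.random((2, 6, 9, 9)).astype(np.float32), train=False).shape == (2, 2)

    def test_zero_input_zero_head_gives_zero_logits(self):
        cfg = ModelConfig(block_channels=(4, 4))
        net = build_model(cfg, seed=0)
        net.head.weight.value[...] = 0.0
        net.head.bias.value[...] = 0.0
        logits = net.forward(np.zeros((2, 6, 18, 18), dtype=np.float32), train=False)
        np.testing.assert_array_equal(logits, 0.0)

    def test_duplicate_samples_identical_logits_in_eval(self, rng):
        cfg = ModelConfig(block_channels=(4, 4))
        net = build_model(cfg, seed=0)
        x = rng.random((1, 6, 18, 18)).astype(np.float32)
        batch = np.concatenate([x, x], axis=0)
        logits = net.forward(batch, train=False)
        np.testing.assert_array_equal(logits[0], logits[1])

    def test_repeated_forward_bitwise_reproducible(self, rng):
        cfg = ModelConfig(block_channels=(4, 4))
        x = rng.random((2, 6, 18, 18)).astype(np.float32)
        a = build_model(cfg, seed=3).forward(x, train=False)
        b = build_model(cfg, seed=3).forward(x, train=False)
        np.testing.assert_array_equal(a, b)

    def test_wrong_shape_rejected(self, rng):
        net = build_model(ModelConfig(block_channels=(4,)), seed=0)
        with pytest.raises(ValidationError):
            net.forward(rng.random((2, 6, 9, 9)).astype(np.float32), train=False)

    def test_nonfinite_activations_rejected(self):
        net = build_model(ModelConfig(block_channels=(4,)), seed=0)
        x = np.zeros((1, 6, 18, 18), dtype=np.float32)
        x[0, 0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            net.forward(x)


class TestGradients:
    def test_network_gradient_matches_finite_differences(self, rng):
        """End-to-end gradient check through block, BN and head."""
        cfg = ModelConfig(kernel_sizes=(3, 5), block_channels=(2, 3),
                          n_classes=2, input_shape=(5, 5, 2))
        net = build_model(cfg, seed=1)
        for p in net.parameters():  # float64 for clean finite differences
            p.value = p.value.astype(np.float64)
        x = rng.normal(size=(4, 2, 5, 5)).astype(np.float32)
        y = np.array([0, 1, 1, 0])

        def loss_value():
            logits = net.forward(x, train=True)
            loss, _ = softmax_cross_entropy(logits, y)
            return loss

        logits = net.forward(x, train=True)
        _, dlogits = softmax_cross_entropy(logits, y)
        net.backward(dlogits.astype(np.float64))
        params = net.parameters()
        checked = 0
        for p in params[::3]:
            flat = p.value.ravel()
            gflat = p.grad.ravel()
            idx = rng.integers(0, flat.size)
            eps = 1e-5
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss_value()
            flat[idx] = orig - eps
            down = loss_value()
            flat[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert gflat[idx] == pytest.approx(numeric, rel=1e-3, abs=1e-7)
            checked += 1
        assert checked >= 3

    def test_batchnorm_backward_matches_finite_differences(self, rng):
        bn = BatchNorm2d(3)
        x = rng.normal(size=(4, 3, 2, 2)).astype(np.float64)
        w = rng.normal(size=x.shape)

        def loss(v):
            bn2 = BatchNorm2d(3)
            bn2.gamma.value = bn.gamma.value
            bn2.beta.value = bn.beta.value
            return float((bn2.forward(v, train=True) * w).sum())

        out = bn.forward(x, train=True)
        dx = bn.backward(w)
        eps = 1e-5
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            numeric = (loss(xp) - loss(xm)) / (2 * eps)
            assert dx[idx] == pytest.approx(numeric, rel=1e-3, abs=1e-6)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        from eegemotion.model import MSKCNN

        cfg = ModelConfig(block_channels=(4, 4))
        net = build_model(cfg, seed=5)
        x = rng.random((3, 6, 18, 18)).astype(np.float32)
        net.forward(x, train=True)  # populate batch-norm running stats
        before = net.predict_logits(x)
        path = tmp_path / "weights.pkl"
        net.save(path)
        restored = MSKCNN.load(path)
        np.testing.assert_array_equal(before, restored.predict_logits(x))
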