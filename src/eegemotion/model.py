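"""The multi-scale-kernel CNN classifier.

Four convolution blocks (output channels 16, 32, 64, 128 by default), each
holding parallel convolutions of distinct kernel sizes (5x5 and 7x7 by
default) fused by a 1x1 convolution, then batch normalization and ReLU.
There is no pooling: spatial size is preserved through the whole stack
(same padding), and a single fully connected layer maps the flattened
final feature maps to the class logits.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .nnet import Linear, MultiScaleBlock, Parameter

DEFAULT_KERNEL_SIZES: tuple[int, ...] = (5, 7)
DEFAULT_BLOCK_CHANNELS: tuple[int, ...] = (16, 32, 64, 128)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture settings.

    ``input_shape`` is (height, width, depth) of one sample tensor —
    (18, 18, 6) for the four-band configuration.  ``kernel_sizes`` is the
    set of parallel branch sizes in every block.
    """

    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES
    block_channels: tuple[int, ...] = DEFAULT_BLOCK_CHANNELS
    n_classes: int = 2
    input_shape: tuple[int, int, int] = (18, 18, 6)

    def __post_init__(self) -> None:
        if not self.kernel_sizes:
            raise ValidationError("kernel_sizes must be non-empty")
        for k in self.kernel_sizes:
            if k % 2 == 0:
                raise ValidationError(f"kernel sizes must be odd, got {k}")
        if not self.block_channels:
            raise ValidationError("block_channels must be non-empty")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")

    def parameter_count(self) -> int:
        """Closed-form trainable parameter count of the built network."""
        h, w, depth = self.input_shape
        total = 0
        in_ch = depth
        n_branches = len(set(self.kernel_sizes))
        for out in self.block_channels:
            total += sum(k * k * in_ch * out + out for k in set(self.kernel_sizes))
            total += n_branches * out * out + out  # 1x1 fusion
            total += 2 * out  # batch norm scale and shift
            in_ch = out
        total += (h * w * in_ch + 1) * self.n_classes  # fully connected head
        return total


class MSKCNN:
    """The assembled network: blocks, flatten (channel-major), FC head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(77,)))
        h, w, depth = config.input_shape
        self.blocks: list[MultiScaleBlock] = []
        in_ch = depth
        for out in config.block_channels:
            self.blocks.append(MultiScaleBlock(in_ch, out, config.kernel_sizes, rng))
            in_ch = out
        self.head = Linear(h * w * in_ch, config.n_classes, rng)
        self.seed = seed

    # -- forward / backward -------------------------------------------------
    def forward(self, batch: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits for a batch shaped (N, depth, H, W), float32."""
        x = np.asarray(batch, dtype=np.float32)
        if x.ndim != 4:
            raise ValidationError(f"batch must be 4-D (N, C, H, W), got {x.ndim}-D")
        h, w, depth = self.config.input_shape
        if x.shape[1:] != (depth, h, w):
            raise ValidationError(
                f"batch shape {x.shape[1:]} != configured (depth, H, W) = ({depth}, {h}, {w})"
            )
        for i, block in enumerate(self.blocks):
            x = block.forward(x, train)
            if not np.isfinite(x).all():
                raise ValidationError(f"NaN/Inf activations after block {i}")
        self._feat_shape = x.shape
        return self.head.forward(x.reshape(x.shape[0], -1), train)

    def backward(self, dlogits: np.ndarray) -> None:
        grad = self.head.backward(dlogits).reshape(self._feat_shape)
        for block in reversed(self.blocks):
            grad = block.backward(grad)

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for block in self.blocks:
            params.extend(block.parameters())
        params.extend(self.head.parameters())
        return params

    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def predict_logits(self, samples: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode logits (frozen batch-norm statistics)."""
        samples = np.asarray(samples, dtype=np.float32)
        outs = [
            self.forward(samples[i : i + batch_size], train=False)
            for i in range(0, samples.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def predict(self, samples: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Predicted class indices."""
        logits = self.predict_logits(samples, batch_size)
        if logits.shape[1] == 1:  # single-logit sigmoid head
            return (logits.ravel() > 0).astype(int)
        return logits.argmax(axis=1)

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "params": [p.value.copy() for p in self.parameters()],
            "bn_stats": [
                (b.bn.running_mean.copy(), b.bn.running_var.copy()) for b in self.blocks
            ],
        }

    def save(self, path: str | Path) -> None:
        with open(Path(path), "wb") as fh:
            pickle.dump(self.state_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "MSKCNN":
        with open(Path(path), "rb") as fh:
            state = pickle.load(fh)
        net = cls(state["config"], seed=state["seed"])
        for p, v in zip(net.parameters(), state["params"]):
            p.value[...] = v
        for block, (rm, rv) in zip(net.blocks, state["bn_stats"]):
            block.bn.running_mean[...] = rm
            block.bn.running_var[...] = rv
        return net


def build_block(
    in_channels: int,
    out_channels: int,
    kernel_sizes: Sequence[int] = DEFAULT_KERNEL_SIZES,
    seed: int = 0,
) -> MultiScaleBlock:
    """One multi-scale convolution block (see :class:`MultiScaleBlock`)."""
    rng = np.random.default_rng(seed)
    return MultiScaleBlock(in_channels, out_channels, kernel_sizes, rng)


def build_model(config: ModelConfig, seed: int = 0) -> MSKCNN:
    """Construct the network from its configuration."""
    return MSKCNN(config, seed=seed)
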