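"""Training protocol, segment-level k-fold cross-validation and ablations.

The reference protocol: Adam, initial learning rate 1e-3 annealed by a
cosine schedule to one tenth at the final epoch, 150 epochs, batch size
640, cross-entropy loss (binary tasks use a two-logit softmax head, which
is the binary cross-entropy of the equivalent sigmoid; a single-logit
sigmoid head is available), and ten-fold cross-validation with folds
drawn at random over ALL segments pooled across subjects.  Note that
segment-level folding places segments of the same trial in both the
training and validation split; a ``group_by`` option provides
leakage-free folding by trial or subject for honest benchmarking, but the
default replicates the reference protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .filterbank import BandDefinition, default_bands
from .io_dataset import LabelScheme, TrialRecord
from .model import ModelConfig, MSKCNN, build_model
from .nnet import Adam, Linear, sigmoid_binary_cross_entropy, softmax_cross_entropy
from .pipeline import SampleSet, build_sample_set
from .segmentation import SegmentSpec


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are the reference protocol."""

    lr_init: float = 1e-3
    lr_final_fraction: float = 0.1
    epochs: int = 150
    batch_size: int = 640
    folds: int = 10
    seed: int = 0
    head: str = "softmax"  # or "sigmoid" (single-logit, binary only)

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.folds < 1:
            raise ValidationError("epochs, batch_size and folds must be >= 1")
        if self.head not in ("softmax", "sigmoid"):
            raise ValidationError(f"unknown head {self.head!r}")


@dataclass
class FoldResult:
    """Outcome of one cross-validation fold."""

    fold: int
    accuracy: float
    confusion: np.ndarray
    losses: list[float]


@dataclass
class CVResult:
    """All folds of one cross-validation run."""

    fold_results: list[FoldResult]
    model_config: ModelConfig
    train_config: TrainConfig

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.fold_results])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """Cosine-annealed learning rate at an epoch (0-based).

    lr(e) = lr_min + (lr_init - lr_min)/2 * (1 + cos(pi * e / (E - 1)))
    with lr_min = lr_init * lr_final_fraction, so lr(0) = lr_init and
    lr(E-1) = lr_min.
    """
    if not (0 <= epoch < config.epochs):
        raise ValidationError(f"epoch {epoch} outside [0, {config.epochs})")
    if config.epochs == 1:
        return config.lr_init
    lr_min = config.lr_init * config.lr_final_fraction
    return lr_min + 0.5 * (config.lr_init - lr_min) * (
        1.0 + np.cos(np.pi * epoch / (config.epochs - 1))
    )


def make_folds(
    n_samples: int,
    k: int,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Random partition of sample indices into k folds of near-equal size.

    Default is segment-level folding (every sample independent).  If
    ``groups`` is given (e.g. trial or subject ids per sample), whole
    groups are assigned to folds so no group straddles a fold boundary.
    """
    if k < 1 or k > n_samples:
        raise ValidationError(f"need 1 <= k <= n_samples, got k={k}, n={n_samples}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(101,)))
    if groups is None:
        perm = rng.permutation(n_samples)
        return [np.sort(fold) for fold in np.array_split(perm, k)]
    groups = np.asarray(groups)
    unique = np.unique(groups)
    if k > unique.size:
        raise ValidationError(f"k={k} exceeds the {unique.size} distinct groups")
    gperm = rng.permutation(unique)
    folds = []
    for chunk in np.array_split(gperm, k):
        mask = np.isin(groups, chunk)
        folds.append(np.flatnonzero(mask))
    return folds


def _loss_fn(head: str) -> Callable:
    return softmax_cross_entropy if head == "softmax" else sigmoid_binary_cross_entropy


def train_model(
    net: MSKCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    train_config: TrainConfig,
    fold: int = 0,
    log: list | None = None,
) -> list[float]:
    """Train a network in place; returns the per-epoch mean training loss."""
    loss_fn = _loss_fn(train_config.head)
    opt = Adam(net.parameters(), lr=train_config.lr_init)
    epoch_losses = []
    n = x_train.shape[0]
    for epoch in range(train_config.epochs):
        opt.lr = cosine_lr(epoch, train_config)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=train_config.seed, spawn_key=(fold, epoch))
        )
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            logits = net.forward(x_train[idx], train=True)
            loss, dlogits = loss_fn(logits, y_train[idx])
            if not np.isfinite(loss):
                raise ValidationError(
                    f"training diverged: loss={loss} at epoch {epoch}, lr={opt.lr:.3g}, "
                    f"batch of {idx.size}"
                )
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        mean_loss = float(np.mean(losses))
        epoch_losses.append(mean_loss)
        if log is not None:
            log.append({"fold": fold, "epoch": epoch, "lr": opt.lr, "loss": mean_loss})
    return epoch_losses


def evaluate(net: MSKCNN, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Accuracy (percent) and confusion matrix on a validation set."""
    pred = net.predict(x)
    n_classes = max(net.config.n_classes, 2)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (y, pred), 1)
    return float((pred == y).mean() * 100.0), confusion


def train_one_fold(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
    fold: int = 0,
    log: list | None = None,
) -> FoldResult:
    """Train a freshly initialized model on one train/validation split."""
    net = build_model(model_config, seed=train_config.seed + fold)
    if train_config.head == "sigmoid":
        if model_config.n_classes != 2:
            raise ValidationError("sigmoid head requires a binary task")
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=train_config.seed + fold, spawn_key=(78,))
        )
        net.head = Linear(net.head.weight.value.shape[1], 1, rng)
    losses = train_model(net, x_train, y_train, train_config, fold=fold, log=log)
    accuracy, confusion = evaluate(net, x_val, y_val)
    return FoldResult(fold=fold, accuracy=accuracy, confusion=confusion, losses=losses)


def run_cross_validation(
    samples: SampleSet | tuple[np.ndarray, np.ndarray],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    group_by: str | None = None,
    log: list | None = None,
) -> CVResult:
    """k-fold cross-validation with independently initialized models.

    ``group_by`` may be ``"trial"`` or ``"subject"`` for leakage-free
    folding; the default (None) is the segment-level random split.
    """
    train_config = train_config or TrainConfig()
    if isinstance(samples, SampleSet):
        x, y = samples.tensors, samples.labels
        meta = samples.meta
        input_shape = samples.input_shape
    else:
        x, y = samples
        meta = None
        input_shape = (x.shape[2], x.shape[3], x.shape[1])
    if model_config is None:
        model_config = ModelConfig(n_classes=int(y.max()) + 1, input_shape=input_shape)
    groups = None
    if group_by is not None:
        if meta is None:
            raise ValidationError("group_by requires a SampleSet with metadata")
        if group_by == "trial":
            groups = (meta["subject_id"].to_numpy() * 1000 + meta["trial_id"].to_numpy())
        elif group_by == "subject":
            groups = meta["subject_id"].to_numpy()
        else:
            raise ValidationError(f"unknown group_by {group_by!r}")
    folds = make_folds(x.shape[0], train_config.folds, seed=train_config.seed, groups=groups)
    results = []
    all_idx = np.arange(x.shape[0])
    for i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        results.append(
            train_one_fold(
                x[train_idx], y[train_idx], x[val_idx], y[val_idx],
                model_config, train_config, fold=i, log=log,
            )
        )
    return CVResult(fold_results=results, model_config=model_config, train_config=train_config)


# ---------------------------------------------------------------------------
# Ablation grids
# ---------------------------------------------------------------------------

BAND_GRID: tuple[tuple[str, ...], ...] = (
    ("theta",), ("alpha",), ("beta",), ("gamma",),
    ("raw",), ("beta", "gamma"), ("theta", "alpha", "beta", "gamma"),
)
KERNEL_GRID: tuple[tuple[int, ...], ...] = (
    (3,), (5,), (7,), (3, 5), (3, 7), (5, 7), (3, 5, 7),
)
SHIFT_GRID: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)


def run_ablation(
    axis: str,
    trials: Sequence[TrialRecord],
    grid: Sequence | None = None,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    label_scheme: LabelScheme | None = None,
    segment_spec: SegmentSpec | None = None,
    filter_method: str = "filtfilt",
) -> pd.DataFrame:
    """Cross-validate along one ablation axis; returns one row per grid point.

    Axes: ``bands`` (band subsets incl. the raw arm), ``kernels`` (kernel
    size combinations), ``shift`` (segment start offsets in seconds, with
    trailing segments truncated when they no longer fit).
    """
    train_config = train_config or TrainConfig()
    label_scheme = label_scheme or LabelScheme()
    segment_spec = segment_spec or SegmentSpec()
    rows = []
    if axis == "bands":
        grid = grid or BAND_GRID
        for subset in grid:
            subset = tuple(subset)
            if subset == ("raw",):
                bands: Sequence[BandDefinition] | str = "raw"
            else:
                by_name = {b.name: b for b in default_bands()}
                try:
                    bands = [by_name[s] for s in subset]
                except KeyError as exc:
                    raise ValidationError(f"unknown band in grid: {exc}") from exc
            samples = build_sample_set(
                trials, bands=bands, segment_spec=segment_spec,
                label_scheme=label_scheme, filter_method=filter_method,
            )
            cfg = _config_for(model_config, samples, label_scheme)
            cv = run_cross_validation(samples, cfg, train_config)
            rows.append({"bands": "+".join(subset), "mean_accuracy": cv.mean_accuracy,
                         "n_samples": samples.n_samples})
    elif axis == "kernels":
        grid = grid or KERNEL_GRID
        samples = build_sample_set(
            trials, segment_spec=segment_spec, label_scheme=label_scheme,
            filter_method=filter_method,
        )
        for kernels in grid:
            cfg = _config_for(model_config, samples, label_scheme, kernel_sizes=tuple(kernels))
            cv = run_cross_validation(samples, cfg, train_config)
            rows.append({"kernels": "+".join(str(k) for k in kernels),
                         "mean_accuracy": cv.mean_accuracy, "n_samples": samples.n_samples})
    elif axis == "shift":
        grid = grid if grid is not None else SHIFT_GRID
        for shift in grid:
            spec = replace(segment_spec, start_offset_s=float(shift), truncate_tail=True)
            samples = build_sample_set(
                trials, segment_spec=spec, label_scheme=label_scheme,
                filter_method=filter_method,
            )
            cfg = _config_for(model_config, samples, label_scheme)
            cv = run_cross_validation(samples, cfg, train_config)
            rows.append({"shift_s": float(shift), "mean_accuracy": cv.mean_accuracy,
                         "n_samples": samples.n_samples})
    else:
        raise ValidationError(f"unknown ablation axis {axis!r}")
    return pd.DataFrame(rows)


def _config_for(
    base: ModelConfig | None,
    samples: SampleSet,
    label_scheme: LabelScheme,
    kernel_sizes: tuple[int, ...] | None = None,
) -> ModelConfig:
    cfg = base or ModelConfig()
    return replace(
        cfg,
        input_shape=samples.input_shape,
        n_classes=label_scheme.n_classes,
        kernel_sizes=kernel_sizes or cfg.kernel_sizes,
    )
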