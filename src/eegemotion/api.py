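"""High-level modelling interface in the Model / Results idiom.

:class:`EmotionRecognitionModel` is built from data (trial records or an
assembled sample set); ``fit()`` runs the cross-validated training
protocol and returns an :class:`EmotionRecognitionResults` carrying fold
accuracies, confusion tables and a ``summary()`` report.

Example
-------
>>> from eegemotion import SynthConfig, generate_dataset, EmotionRecognitionModel
>>> trials = generate_dataset(SynthConfig(n_subjects=1, effect_size=1.5, seed=7))
>>> model = EmotionRecognitionModel.from_trials(trials, task="arousal_binary")
>>> res = model.fit()
>>> print(res.summary())              # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .io_dataset import LabelScheme, TrialRecord
from .model import ModelConfig
from .pipeline import SampleSet, build_sample_set
from .segmentation import SegmentSpec
from .train_eval import CVResult, TrainConfig, run_cross_validation


class EmotionRecognitionModel:
    """A multi-scale-kernel CNN emotion classifier bound to a dataset."""

    def __init__(
        self,
        samples: SampleSet,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        task: str = "arousal_binary",
    ):
        self.samples = samples
        if model_config is None:
            n_classes = max(int(samples.labels.max()) + 1, 2) if samples.labels.size else 2
            self.model_config = ModelConfig(
                input_shape=samples.input_shape, n_classes=n_classes
            )
        else:
            self.model_config = replace(model_config, input_shape=samples.input_shape)
        self.train_config = train_config or TrainConfig()
        self.task = task

    @classmethod
    def from_trials(
        cls,
        trials: Sequence[TrialRecord],
        task: str = "arousal_binary",
        bands=None,
        segment_spec: SegmentSpec | None = None,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        filter_method: str = "filtfilt",
        threshold: float = 5.0,
    ) -> "EmotionRecognitionModel":
        """Run the feature pipeline on trial records and bind the model."""
        scheme = LabelScheme(task=task, threshold=threshold)
        samples = build_sample_set(
            trials,
            bands=bands,
            segment_spec=segment_spec,
            label_scheme=scheme,
            filter_method=filter_method,
        )
        return cls(samples, model_config, train_config, task=task)

    def fit(self, group_by: str | None = None, log: list | None = None) -> "EmotionRecognitionResults":
        """Cross-validated training; returns the results object."""
        cv = run_cross_validation(
            self.samples, self.model_config, self.train_config, group_by=group_by, log=log
        )
        return EmotionRecognitionResults(self, cv)


class EmotionRecognitionResults:
    """Cross-validation outcome with accessors and a summary table."""

    def __init__(self, model: EmotionRecognitionModel, cv: CVResult):
        self.model = model
        self.cv = cv

    @property
    def fold_accuracies(self) -> np.ndarray:
        return self.cv.fold_accuracies

    @property
    def mean_accuracy(self) -> float:
        return self.cv.mean_accuracy

    @property
    def std_accuracy(self) -> float:
        return float(self.cv.fold_accuracies.std())

    @property
    def confusion(self) -> np.ndarray:
        """Summed confusion matrix over all validation folds."""
        return np.sum([f.confusion for f in self.cv.fold_results], axis=0)

    def summary(self) -> str:
        mc, tc = self.cv.model_config, self.cv.train_config
        lines = [
            "Emotion Recognition (multi-scale-kernel CNN)",
            "=" * 52,
            f"task:             {self.model.task}",
            f"samples:          {self.model.samples.n_samples}",
            f"input shape:      {mc.input_shape} (H, W, depth)",
            f"kernel sizes:     {mc.kernel_sizes}",
            f"block channels:   {mc.block_channels}",
            f"parameters:       {mc.parameter_count():,}",
            f"folds:            {tc.folds}  epochs: {tc.epochs}  batch: {tc.batch_size}",
            f"lr schedule:      cosine {tc.lr_init:g} -> {tc.lr_init * tc.lr_final_fraction:g}",
            "-" * 52,
        ]
        for f in self.cv.fold_results:
            lines.append(f"fold {f.fold:2d} accuracy: {f.accuracy:6.2f} %")
        lines.append("-" * 52)
        lines.append(
            f"mean accuracy:    {self.mean_accuracy:6.2f} %  (+/- {self.std_accuracy:.2f})"
        )
        return "\n".join(lines)

    def plot_fold_accuracies(self, ax=None):
        """Bar chart of per-fold validation accuracies."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        acc = self.fold_accuracies
        ax.bar(np.arange(acc.size), acc)
        ax.axhline(self.mean_accuracy, color="k", linestyle="--", label="mean")
        ax.set_xlabel("fold")
        ax.set_ylabel("accuracy (%)")
        ax.legend()
        return ax
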