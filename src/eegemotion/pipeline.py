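"""End-to-end feature pipeline: trials -> network-ready sample tensors.

For every trial: band-pass decomposition (unless the ``raw`` arm is
requested), baseline stripping and segmentation, the six time-domain
features per (segment, channel, band), per-trial min-max normalization,
topographic 9x9 mapping and band tiling.  The result is a float32 array
(n_samples, depth, H, W) ready for the CNN, the integer labels, and a
metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FEATURE_NAMES, extract_all, normalize_trial
from .filterbank import BandDefinition, default_bands, apply_filterbank
from .io_dataset import LabelScheme, TrialRecord
from .segmentation import SegmentSpec, split_band_signals
from .topomap import DEFAULT_BAND_TILING, ElectrodeLayout, SampleTensor, assemble_sample

RAW_BAND = "raw"


@dataclass
class SampleSet:
    """Assembled dataset: tensors (N, depth, H, W), labels and provenance."""

    tensors: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame
    band_names: tuple[str, ...]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n_samples(self) -> int:
        return self.tensors.shape[0]

    @property
    def input_shape(self) -> tuple[int, int, int]:
        """(H, W, depth) of one sample, as the model config expects."""
        _, d, h, w = self.tensors.shape
        return (h, w, d)


def trial_to_samples(
    trial: TrialRecord,
    bands: Sequence[BandDefinition] | None | str = None,
    segment_spec: SegmentSpec | None = None,
    label_scheme: LabelScheme | None = None,
    layout: ElectrodeLayout | None = None,
    filter_method: str = "filtfilt",
    normalization: str = "per_band_feature",
) -> list[SampleTensor]:
    """Run the full feature pipeline on one trial.

    ``bands`` may be a list of band definitions, the string ``"raw"`` for
    the unfiltered arm (9x9xk tensors), or None for the four standard
    bands.  Band filtering precedes segmentation.
    """
    segment_spec = segment_spec or SegmentSpec()
    label_scheme = label_scheme or LabelScheme()
    layout = layout or ElectrodeLayout.default()
    fs = trial.sampling_rate_hz
    if isinstance(bands, str):
        if bands != RAW_BAND:
            raise ValidationError(f"unknown band specification {bands!r}")
        band_signals = {RAW_BAND: np.asarray(trial.signal, dtype=float)}
    else:
        band_signals = apply_filterbank(
            np.asarray(trial.signal, dtype=float),
            bands=bands or default_bands(),
            fs=fs,
            method=filter_method,
        )
    segments = split_band_signals(band_signals, fs, segment_spec)
    label = label_scheme.label_of(trial.ratings)
    feats = extract_all(
        segments, subject_id=trial.subject_id, trial_id=trial.trial_id, label=label
    )
    feats = normalize_trial(feats, grouping=normalization)
    order = [b for b in DEFAULT_BAND_TILING if b in band_signals] or list(band_signals)
    return [assemble_sample(f, layout, band_order=order) for f in feats]


def build_sample_set(
    trials: Sequence[TrialRecord],
    bands: Sequence[BandDefinition] | None | str = None,
    segment_spec: SegmentSpec | None = None,
    label_scheme: LabelScheme | None = None,
    layout: ElectrodeLayout | None = None,
    filter_method: str = "filtfilt",
    normalization: str = "per_band_feature",
) -> SampleSet:
    """Assemble every trial's segments into one :class:`SampleSet`."""
    layout = layout or ElectrodeLayout.default()
    tensors, labels, meta = [], [], []
    band_names: tuple[str, ...] | None = None
    for trial in trials:
        for s in trial_to_samples(
            trial, bands, segment_spec, label_scheme, layout, filter_method, normalization
        ):
            tensors.append(np.transpose(s.data, (2, 0, 1)))  # depth-major for the CNN
            labels.append(s.label)
            meta.append((s.subject_id, s.trial_id, s.segment_index))
            band_names = s.band_names
    if not tensors:
        raise ValidationError("no samples produced")
    return SampleSet(
        tensors=np.stack(tensors).astype(np.float32),
        labels=np.asarray(labels, dtype=int),
        meta=pd.DataFrame(meta, columns=["subject_id", "trial_id", "segment_index"]),
        band_names=band_names,
    )


def save_sample_set(samples: SampleSet, path) -> None:
    """Persist a sample set as a compressed ``.npz`` container."""
    np.savez_compressed(
        path,
        tensors=samples.tensors,
        labels=samples.labels,
        meta=samples.meta.to_numpy(),
        band_names=np.array(samples.band_names),
        feature_names=np.array(samples.feature_names),
    )


def load_sample_set(path) -> SampleSet:
    with np.load(path, allow_pickle=False) as z:
        return SampleSet(
            tensors=z["tensors"],
            labels=z["labels"],
            meta=pd.DataFrame(
                z["meta"], columns=["subject_id", "trial_id", "segment_index"]
            ),
            band_names=tuple(str(b) for b in z["band_names"]),
            feature_names=tuple(str(f) for f in z["feature_names"]),
        )
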