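"""Time-domain features per (segment, channel, band) and trial normalization.

Six statistics are computed from every band-filtered segment: differential
entropy (DE), mean, mean of the first difference, mean of the second
difference, standard deviation and variance.  DE of a segment is taken
under the Gaussian model, DE = 1/2 ln(2*pi*e*sigma^2) nats with sigma^2
the biased (1/n) sample variance — the standard closed-form estimator for
band-limited EEG; a histogram plug-in estimator is available for
comparison.  The difference means are the literal signed sums, which
telescope ((x_n - x_1)/(n-1) etc.); an ``absolute_differences`` switch
gives the |.| variant common in the first-difference literature.

Features are min-max normalized to [0, 1] *within one trial*, by default
separately per (band, feature-type) group — pooling channels and segments
— so that quantities of different physical units never share a scale while
the spatial topography within a feature map is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: Canonical feature order (the depth order of the sample tensor).
FEATURE_NAMES: tuple[str, ...] = ("de", "mean", "mean_d1", "mean_d2", "std", "var")

#: Floor used for the DE of an (exactly) constant segment, whose Gaussian
#: closed form diverges to -inf: DE at the smallest positive normal double.
DE_FLOOR = 0.5 * float(np.log(2.0 * np.pi * np.e * np.finfo(float).tiny))

_NORM_GROUPINGS = ("per_band_feature", "per_trial", "per_channel")


def differential_entropy(segment: np.ndarray, method: str = "gaussian", bins: int = 64) -> float:
    """Differential entropy of one segment in nats.

    ``gaussian`` (default) evaluates 1/2 ln(2*pi*e*sigma^2) with the biased
    sample variance; ``histogram`` uses a plug-in estimate from a
    ``bins``-bin histogram.  A zero-variance segment returns
    :data:`DE_FLOOR`, with a warning.
    """
    x = np.asarray(segment, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError("differential entropy needs at least 2 samples")
    if method == "gaussian":
        var = x.var()
        if var <= 0.0:
            warnings.warn("zero-variance segment: DE floored", RuntimeWarning, stacklevel=2)
            return DE_FLOOR
        return 0.5 * float(np.log(2.0 * np.pi * np.e * var))
    if method == "histogram":
        counts, edges = np.histogram(x, bins=bins)
        width = edges[1] - edges[0]
        if width == 0.0:
            warnings.warn("zero-variance segment: DE floored", RuntimeWarning, stacklevel=2)
            return DE_FLOOR
        p = counts[counts > 0] / x.size
        return float(-(p * np.log(p)).sum() + np.log(width))
    raise ValidationError(f"unknown DE method {method!r}")


def mean(segment: np.ndarray) -> float:
    """Arithmetic mean of the segment."""
    x = _check_segment(segment)
    return float(x.mean())


def mean_first_diff(segment: np.ndarray, absolute: bool = False) -> float:
    """Mean of consecutive differences, 1/(n-1) * sum(x_{i+1} - x_i).

    The signed sum telescopes to (x_n - x_1)/(n-1); ``absolute`` averages
    |x_{i+1} - x_i| instead.
    """
    x = _check_segment(segment)
    d = np.diff(x)
    return float(np.abs(d).mean() if absolute else d.mean())


def mean_second_diff(segment: np.ndarray, absolute: bool = False) -> float:
    """Mean of lag-2 differences, 1/(n-2) * sum(x_{i+2} - x_i)."""
    x = _check_segment(segment)
    d = x[2:] - x[:-2]
    return float(np.abs(d).mean() if absolute else d.mean())


def variance(segment: np.ndarray) -> float:
    """Biased (1/n) sample variance."""
    x = _check_segment(segment)
    return float(x.var())


def std(segment: np.ndarray) -> float:
    """Square root of the biased sample variance."""
    x = _check_segment(segment)
    return float(x.std())


def _check_segment(segment: np.ndarray) -> np.ndarray:
    x = np.asarray(segment, dtype=float).ravel()
    if x.size < 3:
        raise ValidationError(f"segment needs >= 3 samples, got {x.size}")
    return x


def _feature_block(segments: np.ndarray, absolute_differences: bool) -> np.ndarray:
    """Vectorized features for an array (..., time) -> (..., 6)."""
    x = np.asarray(segments, dtype=float)
    if x.shape[-1] < 3:
        raise ValidationError("segments need >= 3 samples")
    var = x.var(axis=-1)
    mu = x.mean(axis=-1)
    d1 = np.diff(x, axis=-1)
    d2 = x[..., 2:] - x[..., :-2]
    if absolute_differences:
        d1, d2 = np.abs(d1), np.abs(d2)
    with np.errstate(divide="ignore"):
        de = np.where(var > 0.0, 0.5 * np.log(2.0 * np.pi * np.e * np.maximum(var, np.finfo(float).tiny)), DE_FLOOR)
    if np.any(var <= 0.0):
        warnings.warn("zero-variance segment(s): DE floored", RuntimeWarning, stacklevel=2)
    return np.stack(
        [de, mu, d1.mean(axis=-1), d2.mean(axis=-1), np.sqrt(var), var], axis=-1
    )


@dataclass
class SegmentFeatures:
    """Feature values of one segment: array (channels, bands, 6 features).

    ``normalized`` records whether the values have been through the
    per-trial min-max scaling (and therefore lie in [0, 1]).
    """

    values: np.ndarray
    band_names: tuple[str, ...]
    subject_id: int
    trial_id: int
    segment_index: int
    label: int | None = None
    normalized: bool = False
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.values.shape[0], len(self.band_names), len(self.feature_names))
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} != (channels, bands, features) {expected}"
            )
        if np.isnan(self.values).any():
            raise ValidationError("feature values contain NaN")


def extract_all(
    band_segments: Mapping[str, np.ndarray],
    subject_id: int = 0,
    trial_id: int = 0,
    label: int | None = None,
    absolute_differences: bool = False,
) -> list[SegmentFeatures]:
    """Features for every segment of one trial.

    ``band_segments`` maps band name -> array (n_segments, channels, time);
    all bands must agree on the segment and channel counts.  Returns one
    (unnormalized) :class:`SegmentFeatures` per segment with a
    (channels, n_bands, 6) value array.
    """
    names = tuple(band_segments)
    stacks = [np.asarray(band_segments[b]) for b in names]
    shape0 = stacks[0].shape
    for b, s in zip(names, stacks):
        if s.shape != shape0:
            raise ValidationError(f"band {b!r}: shape {s.shape} != {shape0}")
        if s.ndim != 3:
            raise ValidationError(f"band {b!r}: expected (segments, channels, time)")
    # (bands, n_seg, C, T) -> features (bands, n_seg, C, 6) -> (n_seg, C, bands, 6)
    feats = _feature_block(np.stack(stacks, axis=0), absolute_differences)
    feats = np.transpose(feats, (1, 2, 0, 3))
    return [
        SegmentFeatures(
            values=feats[i],
            band_names=names,
            subject_id=subject_id,
            trial_id=trial_id,
            segment_index=i,
            label=label,
        )
        for i in range(feats.shape[0])
    ]


def normalize_trial(
    features: Sequence[SegmentFeatures], grouping: str = "per_band_feature"
) -> list[SegmentFeatures]:
    """Min-max scale the features of one trial into [0, 1].

    All inputs must share (subject_id, trial_id).  ``grouping`` fixes which
    values share a (min, max):

    - ``per_band_feature`` (default): each (band, feature-type) pair,
      pooling channels and segments of the trial;
    - ``per_trial``: one global min/max over everything in the trial;
    - ``per_channel``: each (channel, band, feature-type) triple.

    A degenerate group (max == min) maps to all zeros, with a warning.
    Idempotent: normalizing a second time changes nothing.
    """
    if grouping not in _NORM_GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}; expected one of {_NORM_GROUPINGS}")
    feats = list(features)
    if not feats:
        return []
    key = (feats[0].subject_id, feats[0].trial_id)
    for f in feats:
        if (f.subject_id, f.trial_id) != key:
            raise ValidationError("normalize_trial mixes segments from different trials")
    stack = np.stack([f.values for f in feats], axis=0)  # (n_seg, C, B, F)
    if grouping == "per_band_feature":
        axes = (0, 1)
    elif grouping == "per_trial":
        axes = (0, 1, 2, 3)
    else:  # per_channel
        axes = (0,)
    lo = stack.min(axis=axes, keepdims=True)
    hi = stack.max(axis=axes, keepdims=True)
    span = hi - lo
    degenerate = span <= 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate normalization group(s) set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    scaled = np.where(degenerate, 0.0, (stack - lo) / np.where(degenerate, 1.0, span))
    return [
        SegmentFeatures(
            values=scaled[i],
            band_names=f.band_names,
            subject_id=f.subject_id,
            trial_id=f.trial_id,
            segment_index=f.segment_index,
            label=f.label,
            normalized=True,
            feature_names=f.feature_names,
        )
        for i, f in enumerate(feats)
    ]
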