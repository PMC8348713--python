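"""Cut trials into equal non-overlapping segments after the baseline.

A DEAP trial is 63 s: a 3 s pre-stimulus baseline followed by 60 s of
stimulus.  The baseline is discarded and the active window is cut into
``n_segments`` contiguous, non-overlapping pieces (10 pieces of 6 s by
default); every segment inherits the label of its trial.  An optional
start offset shifts the window to probe robustness to where the signal is
cut; with ``truncate_tail`` enabled, segments that would overrun the
recording are dropped instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SegmentationOverflowError, ValidationError


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


@dataclass(frozen=True)
class SegmentSpec:
    """Where and how to cut one trial.

    All durations in seconds.  Defaults reproduce the standard protocol:
    drop a 3 s baseline, split the following 60 s into 10 segments.
    """

    baseline_s: float = 3.0
    active_s: float = 60.0
    n_segments: int = 10
    start_offset_s: float = 0.0
    truncate_tail: bool = False

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValidationError("n_segments must be >= 1")
        if self.active_s <= 0:
            raise ValidationError("active_s must be positive")
        if self.start_offset_s < 0:
            raise ValidationError("start_offset_s must be >= 0")
        if self.baseline_s < 0:
            raise ValidationError("baseline_s must be >= 0")

    @property
    def segment_s(self) -> float:
        return self.active_s / self.n_segments

    def segment_samples(self, fs: float) -> int:
        return _round_half_even(fs * self.segment_s)

    def start_sample(self, fs: float) -> int:
        return _round_half_even(fs * (self.baseline_s + self.start_offset_s))


def split_trial(signal: np.ndarray, fs: float, spec: SegmentSpec | None = None) -> list[np.ndarray]:
    """Split a (channels, samples) trial into segment matrices.

    Returns ``spec.n_segments`` arrays of shape (channels, segment_samples)
    that are contiguous views of the input (concatenating them reproduces
    the corresponding slice bit-exactly).  If the requested window does not
    fit, raises :class:`SegmentationOverflowError` naming the deficit —
    unless ``spec.truncate_tail`` is set, in which case trailing segments
    are dropped.
    """
    spec = spec or SegmentSpec()
    signal = np.asarray(signal)
    if signal.ndim != 2:
        raise ValidationError(f"signal must be 2-D (channels x samples), got {signal.ndim}-D")
    n_total = signal.shape[1]
    seg_len = spec.segment_samples(fs)
    if seg_len < 1:
        raise ValidationError("segment length is below one sample")
    start = spec.start_sample(fs)
    needed = start + spec.n_segments * seg_len
    n_keep = spec.n_segments
    if needed > n_total:
        if not spec.truncate_tail:
            raise SegmentationOverflowError(
                f"need {needed} samples (start {start} + {spec.n_segments} x {seg_len}) "
                f"but trial has {n_total}; deficit {needed - n_total} samples"
            )
        n_keep = max(0, (n_total - start) // seg_len)
        if n_keep == 0:
            raise SegmentationOverflowError(
                f"no full segment fits: start {start}, segment {seg_len}, trial {n_total}"
            )
    return [signal[:, start + i * seg_len : start + (i + 1) * seg_len] for i in range(n_keep)]


def split_band_signals(
    band_signals: dict[str, np.ndarray], fs: float, spec: SegmentSpec | None = None
) -> dict[str, np.ndarray]:
    """Apply :func:`split_trial` to every band; returns band -> (n_seg, C, T)."""
    return {
        band: np.stack(split_trial(x, fs, spec), axis=0) for band, x in band_signals.items()
    }
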