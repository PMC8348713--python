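"""Synthetic EEG with the statistical structure the pipeline exploits.

The generator emulates, at the level the downstream stages care about:

* band-limited oscillatory content in Theta/Alpha/Beta/Gamma, synthesized
  by FFT masking of white noise (deliberately independent of the
  Butterworth filter bank so the two never test each other circularly);
* a 1/f^alpha background on every electrode;
* spatial structure: each electrode mixes a regionally shared source
  (anchor sources spread over the scalp grid, weights decaying with grid
  distance) with its own private noise, so neighbouring electrodes are
  strongly correlated;
* class-dependent power modulation concentrated in the high bands:
  the arousal class scales Beta power and the valence class scales Gamma
  power on a designated (frontal, by default) electrode group by
  ``1 + effect_size`` for the high class and ``1 - 0.5*effect_size`` for
  the low class.  ``effect_size = 0`` produces label-independent signals.

Ratings are drawn consistently with the injected classes (high class ->
rating in (5, 9], low -> [1, 5)) and per-subject class assignments are
balanced.  Everything derives deterministically from one global seed
through per-subject / per-trial seed sequences, so any subset of the
dataset is reproducible independently of generation order.

This is not physiologically realistic EEG (no ERPs, blinks or drift);
only the statistics listed above are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.fft as sfft

from .errors import ValidationError
from .filterbank import DEFAULT_BAND_EDGES
from .io_dataset import (
    DEAP_CHANNELS,
    RATING_NAMES,
    TrialRecord,
    write_subject_file,
)
from .topomap import ElectrodeLayout

#: Electrodes carrying the class-coded power modulation.
DEFAULT_TARGET_CHANNELS: tuple[str, ...] = ("F3", "F4", "Fz", "FC1", "FC2")

#: Scalp positions of the regional anchor sources (3x3 lattice on the grid).
_ANCHORS = [(r, c) for r in (1, 4, 7) for c in (1, 4, 7)]
_ANCHOR_SCALE = 2.0  # grid cells; spread of the anchor mixing weights


@dataclass
class SynthConfig:
    """Study conditions for the synthetic dataset.

    ``effect_size`` in [0, 2] is the multiplicative power-modulation
    strength on the designated electrodes; ``spatial_smoothness`` in
    [0, 1] is the mixing weight of the shared regional source against
    per-electrode noise; ``noise_exponent`` is the alpha of the 1/f^alpha
    background.  Defaults mirror a DEAP-sized recording: 128 Hz, 63 s
    trials (3 s baseline + 60 s stimulus), 40 trials per subject.
    """

    n_subjects: int = 32
    n_trials_per_subject: int = 40
    sampling_rate_hz: float = 128.0
    trial_duration_s: float = 63.0
    band_powers: dict[str, float] = field(
        default_factory=lambda: {"theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0}
    )
    noise_amplitude: float = 1.0
    effect_size: float = 1.0
    spatial_smoothness: float = 0.8
    noise_exponent: float = 1.0
    amplitude_jitter: float = 0.05
    target_channels: tuple[str, ...] = DEFAULT_TARGET_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.trial_duration_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"trial_duration_s x sampling_rate_hz = {n} is not an integer sample count"
            )
        if not (0.0 <= self.effect_size <= 2.0):
            raise ValidationError("effect_size must lie in [0, 2]")
        if not (0.0 <= self.spatial_smoothness <= 1.0):
            raise ValidationError("spatial_smoothness must lie in [0, 1]")
        unknown = set(self.band_powers) - set(DEFAULT_BAND_EDGES)
        if unknown:
            raise ValidationError(f"unknown bands in band_powers: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration_s * self.sampling_rate_hz))


def _band_noise_rows(
    rng: np.random.Generator, n_rows: int, n_samples: int, fs: float, low_hz: float, high_hz: float
) -> np.ndarray:
    """(n_rows, n_samples) of unit-RMS noise FFT-masked to [low_hz, high_hz].

    An intentionally simple reference synthesis with ideal (brick-wall)
    band edges, independent of the Butterworth filter bank.
    """
    freqs = sfft.rfftfreq(n_samples, 1.0 / fs)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():
        raise ValidationError(f"band [{low_hz}, {high_hz}] Hz contains no FFT bin")
    spec = sfft.rfft(rng.standard_normal((n_rows, n_samples)), axis=-1)
    spec[:, ~keep] = 0.0
    x = sfft.irfft(spec, n=n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def band_limited_noise(
    rng: np.random.Generator, n_samples: int, fs: float, low_hz: float, high_hz: float
) -> np.ndarray:
    """Unit-RMS noise whose spectrum is confined to [low_hz, high_hz]."""
    return _band_noise_rows(rng, 1, n_samples, fs, low_hz, high_hz)[0]


def _pink_noise_rows(
    rng: np.random.Generator, n_rows: int, n_samples: int, fs: float, exponent: float
) -> np.ndarray:
    """(n_rows, n_samples) of unit-RMS 1/f^alpha noise."""
    freqs = sfft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = sfft.rfft(rng.standard_normal((n_rows, n_samples)), axis=-1)
    x = sfft.irfft(spec * shaping, n=n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def pink_noise(
    rng: np.random.Generator, n_samples: int, fs: float, exponent: float
) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise (amplitude spectrum ~ f^(-alpha/2))."""
    return _pink_noise_rows(rng, 1, n_samples, fs, exponent)[0]


def _anchor_weights(layout: ElectrodeLayout, channels: Sequence[str]) -> np.ndarray:
    """(n_channels, n_anchors) mixing weights, unit L2 row norm."""
    rows, cols = layout.index_arrays(channels)
    pos = np.stack([rows, cols], axis=1).astype(float)
    anchors = np.array(_ANCHORS, dtype=float)
    d2 = ((pos[:, None, :] - anchors[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2.0 * _ANCHOR_SCALE**2))
    return w / np.linalg.norm(w, axis=1, keepdims=True)


def _class_assignments(rng: np.random.Generator, n_trials: int) -> np.ndarray:
    """Balanced binary class labels for one subject's trials."""
    labels = np.zeros(n_trials, dtype=int)
    labels[: n_trials // 2] = 1
    rng.shuffle(labels)
    return labels


def _rating(rng: np.random.Generator, high: bool) -> float:
    # high -> (5, 9], low -> [1, 5): strict with respect to the split at 5
    u = rng.random()
    return 9.0 - 4.0 * u if high else 1.0 + 4.0 * u


def generate_trial_signal(
    config: SynthConfig,
    rng: np.random.Generator,
    arousal_high: bool,
    valence_high: bool,
    layout: ElectrodeLayout | None = None,
) -> np.ndarray:
    """One (32, n_samples) trial signal under the generative model."""
    layout = layout or ElectrodeLayout.default()
    n = config.n_samples
    fs = config.sampling_rate_hz
    n_ch = len(DEAP_CHANNELS)
    n_anchor = len(_ANCHORS)
    weights = _anchor_weights(layout, DEAP_CHANNELS).astype(np.float32)
    s = config.spatial_smoothness
    mix_norm = float(np.sqrt(s**2 + (1.0 - s) ** 2)) or 1.0
    target_idx = np.array([DEAP_CHANNELS.index(c) for c in config.target_channels])

    # One white-noise spectrum per source; disjoint frequency masks of the
    # same white noise yield independent band components (float32 for speed).
    freqs = sfft.rfftfreq(n, 1.0 / fs)
    white = rng.standard_normal((n_anchor + n_ch, n), dtype=np.float32)
    spec = sfft.rfft(white, axis=-1)
    signal = np.zeros((n_ch, n), dtype=np.float32)
    for band, amp in config.band_powers.items():
        lo, hi = DEFAULT_BAND_EDGES[band]
        keep = (freqs >= lo) & (freqs <= hi)
        if not keep.any():
            raise ValidationError(f"band {band}: [{lo}, {hi}] Hz contains no FFT bin")
        masked = np.where(keep[None, :], spec, 0.0)
        rows = sfft.irfft(masked, n=n, axis=-1)
        rows /= rows.std(axis=-1, keepdims=True)
        shared = weights @ rows[:n_anchor]
        own = rows[n_anchor:]
        component = (s * shared + (1.0 - s) * own) / mix_norm
        gains = np.full(
            n_ch, amp * (1.0 + config.amplitude_jitter * rng.standard_normal()), dtype=np.float32
        )
        e = config.effect_size
        if e > 0.0 and band in ("beta", "gamma"):
            high = arousal_high if band == "beta" else valence_high
            gains[target_idx] *= (1.0 + e) if high else (1.0 - 0.5 * e)
        signal += gains[:, None] * component
    if config.noise_amplitude > 0.0:
        shaping = np.zeros_like(freqs, dtype=np.float32)
        shaping[1:] = (freqs[1:] ** (-config.noise_exponent / 2.0)).astype(np.float32)
        pink_spec = sfft.rfft(rng.standard_normal((n_ch, n), dtype=np.float32), axis=-1)
        noise = sfft.irfft(pink_spec * shaping, n=n, axis=-1)
        noise /= noise.std(axis=-1, keepdims=True)
        signal += np.float32(config.noise_amplitude) * noise
    return signal.astype(np.float64)


def generate_subject(
    config: SynthConfig, subject_id: int, layout: ElectrodeLayout | None = None
) -> list[TrialRecord]:
    """Generate one subject's trials.

    Seeding is hierarchical (global seed -> per-subject -> per-trial), so
    any subject is reproducible on its own, independent of which other
    subjects are generated.
    """
    layout = layout or ElectrodeLayout.default()
    subj_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(subject_id,))
    )
    arousal = _class_assignments(subj_rng, config.n_trials_per_subject)
    valence = _class_assignments(subj_rng, config.n_trials_per_subject)
    trials: list[TrialRecord] = []
    for t in range(1, config.n_trials_per_subject + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(subject_id, t))
        )
        a_high = bool(arousal[t - 1])
        v_high = bool(valence[t - 1])
        sig = generate_trial_signal(config, rng, a_high, v_high, layout)
        ratings = {
            "valence": _rating(rng, v_high),
            "arousal": _rating(rng, a_high),
            "dominance": 1.0 + 8.0 * rng.random(),
            "liking": 1.0 + 8.0 * rng.random(),
        }
        trials.append(
            TrialRecord(
                subject_id=subject_id,
                trial_id=t,
                signal=sig,
                ratings=ratings,
                sampling_rate_hz=config.sampling_rate_hz,
            )
        )
    return trials


def generate_dataset(config: SynthConfig, layout: ElectrodeLayout | None = None) -> list[TrialRecord]:
    """Generate the full synthetic dataset as trial records with ratings."""
    layout = layout or ElectrodeLayout.default()
    trials: list[TrialRecord] = []
    for subj in range(1, config.n_subjects + 1):
        trials.extend(generate_subject(config, subj, layout))
    return trials


def write_dataset(config: SynthConfig, out_dir: str | Path, fmt: str = "dat") -> list[Path]:
    """Generate and persist the dataset as DEAP-layout subject files.

    Writes ``s01.<fmt>`` ... plus a plain-text ``manifest.txt`` recording
    the configuration and seed.  Files round-trip bit-exactly through
    :func:`eegemotion.io_dataset.load_deap_subject`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = ElectrodeLayout.default()
    paths = []
    for subj in range(1, config.n_subjects + 1):
        subject_trials = generate_subject(config, subj, layout)
        strict = config.n_trials_per_subject == 40
        path = out_dir / f"s{subj:02d}.{fmt}"
        write_subject_file(subject_trials, path, strict_layout=strict)
        paths.append(path)
    lines = ["# eegemotion synthetic dataset manifest"]
    for key, value in asdict(config).items():
        lines.append(f"{key} = {value!r}")
    lines.append(f"files = {[p.name for p in paths]!r}")
    (out_dir / "manifest.txt").write_text("\n".join(lines) + "\n")
    return paths
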