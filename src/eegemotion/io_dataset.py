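"""Trial records, emotion labels and readers for DEAP-style subject files.

The DEAP "preprocessed" release stores one file per subject containing a
``data`` array of shape (40 trials, 40 channels, 8064 samples) recorded at
128 Hz and a ``labels`` array of shape (40, 4) holding the self-assessed
valence, arousal, dominance and liking ratings on a 1-9 scale.  Only the
first 32 channels are EEG; the remainder are peripheral sensors and are
dropped on load.  Two on-disk dialects are supported, chosen by file
extension: the pickled-dictionary dialect (``.dat``/``.pkl``) and the
MATLAB container dialect (``.mat``).
"""

from __future__ import annotations

import pickle
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import DataUnavailableError, FormatError, ValidationError

#: Channel order of the DEAP preprocessed release (Geneva order), EEG only.
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Column order of the ratings array in DEAP subject files.
RATING_NAMES: tuple[str, ...] = ("valence", "arousal", "dominance", "liking")

SAMPLING_RATE_HZ = 128.0
N_EEG_CHANNELS = 32
N_TRIALS_PER_SUBJECT = 40
N_FILE_CHANNELS = 40
N_SAMPLES_PER_TRIAL = 8064  # 63 s at 128 Hz

LOW, HIGH = "low", "high"

#: Four-class labels in the conventional order: the class index is
#: 2*(arousal is low) + (valence is low).
FOUR_CLASS_NAMES: tuple[str, ...] = ("HAHV", "HALV", "LAHV", "LALV")


@dataclass
class TrialRecord:
    """One subject-trial: the EEG signal plus the four self-assessments.

    Parameters
    ----------
    subject_id, trial_id
        One-based identifiers.
    signal
        Array of shape (n_channels, n_samples) in microvolts.
    ratings
        Mapping with keys ``valence``, ``arousal``, ``dominance``,
        ``liking``; values in [1, 9].
    sampling_rate_hz
        Sampling rate of ``signal``.
    """

    subject_id: int
    trial_id: int
    signal: np.ndarray
    ratings: dict[str, float]
    sampling_rate_hz: float = SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValidationError(
                f"signal must be 2-D (channels x samples), got {self.signal.ndim}-D"
            )
        missing = set(RATING_NAMES) - set(self.ratings)
        if missing:
            raise ValidationError(f"missing ratings: {sorted(missing)}")
        for name in RATING_NAMES:
            r = float(self.ratings[name])
            if not (1.0 <= r <= 9.0):
                raise ValidationError(f"rating {name}={r} outside [1, 9]")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class LabelScheme:
    """How ratings are turned into classification targets.

    ``task`` is one of ``arousal_binary``, ``valence_binary`` or
    ``four_class``.  Ratings strictly above ``threshold`` are "high";
    ratings equal to the threshold count as "low" (the dominant convention
    in the DEAP literature, configurable here).
    """

    task: str = "arousal_binary"
    threshold: float = 5.0

    _TASKS = ("arousal_binary", "valence_binary", "four_class")

    def __post_init__(self) -> None:
        if self.task not in self._TASKS:
            raise ValidationError(f"unknown task {self.task!r}; expected one of {self._TASKS}")

    @property
    def n_classes(self) -> int:
        return 4 if self.task == "four_class" else 2

    def label_of(self, ratings: Mapping[str, float]) -> int:
        """Integer class index of a trial given its ratings.

        Binary tasks: 0 = low, 1 = high.  Four-class: index into
        :data:`FOUR_CLASS_NAMES`.
        """
        a = binarize_rating(ratings["arousal"], self.threshold)
        v = binarize_rating(ratings["valence"], self.threshold)
        if self.task == "arousal_binary":
            return int(a == HIGH)
        if self.task == "valence_binary":
            return int(v == HIGH)
        return FOUR_CLASS_NAMES.index(four_class_label(a, v))


def binarize_rating(rating: float, threshold: float = 5.0) -> str:
    """Map a 1-9 self-assessment to ``"low"`` or ``"high"``.

    ``high`` iff ``rating > threshold``; a rating exactly at the split point
    is low.
    """
    rating = float(rating)
    if not (1.0 <= rating <= 9.0):
        raise ValidationError(f"rating {rating} outside [1, 9]")
    return HIGH if rating > threshold else LOW


def four_class_label(arousal_class: str, valence_class: str) -> str:
    """Combine the two binary labels into one of HAHV, HALV, LAHV, LALV."""
    for c in (arousal_class, valence_class):
        if c not in (LOW, HIGH):
            raise ValidationError(f"invalid binary class {c!r}")
    return FOUR_CLASS_NAMES[2 * (arousal_class == LOW) + (valence_class == LOW)]


def _subject_id_from_path(path: Path) -> int:
    m = re.search(r"s(\d+)", path.stem)
    return int(m.group(1)) if m else 0


def _load_arrays(path: Path) -> tuple[np.ndarray, np.ndarray]:
    if path.suffix in (".dat", ".pkl", ".pickle"):
        with open(path, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
    elif path.suffix == ".mat":
        from scipy.io import loadmat

        payload = loadmat(str(path))
    else:
        raise FormatError(
            f"unrecognised extension {path.suffix!r}; expected .dat/.pkl or .mat"
        )
    try:
        return np.asarray(payload["data"]), np.asarray(payload["labels"])
    except (KeyError, TypeError, IndexError) as exc:
        raise FormatError(f"{path}: missing 'data'/'labels' entries") from exc


def load_deap_subject(path: str | Path, subject_id: int | None = None) -> list[TrialRecord]:
    """Read one DEAP-layout subject file into a list of 40 trial records.

    Only the 32 EEG channels are retained, in the file's native order
    (:data:`DEAP_CHANNELS`).  The subject id is parsed from the filename
    (``s01.dat`` style) unless given explicitly.

    Raises
    ------
    DataUnavailableError
        If the file does not exist.  DEAP is licence-gated; the synthetic
        generator (:mod:`eegemotion.synthetic`) writes files in the same
        layout.
    FormatError
        If the arrays inside do not have the documented shapes.
    """
    path = Path(path)
    if not path.exists():
        raise DataUnavailableError(
            f"{path} not found. DEAP is distributed under licence; generate a "
            "synthetic stand-in with eegemotion.synthetic.write_subject_file "
            "or the `eegemotion synth` command."
        )
    data, labels = _load_arrays(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: data array must be 3-D, got {data.ndim}-D")
    n_trials, n_chan, n_samp = data.shape
    if n_trials != N_TRIALS_PER_SUBJECT:
        raise FormatError(
            f"{path}: expected {N_TRIALS_PER_SUBJECT} trials (axis 0), got {n_trials}"
        )
    if n_chan < N_EEG_CHANNELS:
        raise FormatError(
            f"{path}: expected >= {N_EEG_CHANNELS} channels (axis 1), got {n_chan}"
        )
    if labels.shape != (N_TRIALS_PER_SUBJECT, 4):
        raise FormatError(
            f"{path}: labels must be ({N_TRIALS_PER_SUBJECT}, 4), got {labels.shape}"
        )
    sid = subject_id if subject_id is not None else _subject_id_from_path(path)
    records = []
    for t in range(n_trials):
        ratings = {name: float(labels[t, j]) for j, name in enumerate(RATING_NAMES)}
        records.append(
            TrialRecord(
                subject_id=sid,
                trial_id=t + 1,
                signal=data[t, :N_EEG_CHANNELS, :],
                ratings=ratings,
            )
        )
    return records


def write_subject_file(
    trials: Iterable[TrialRecord],
    path: str | Path,
    strict_layout: bool = True,
) -> Path:
    """Write trial records as a DEAP-layout subject file.

    The signal is padded with zero rows up to the 40-channel file layout so
    that :func:`load_deap_subject` is the single ingestion path for both
    real and synthetic data.  ``strict_layout`` enforces the 40-trial DEAP
    count.
    """
    path = Path(path)
    trials = list(trials)
    if strict_layout and len(trials) != N_TRIALS_PER_SUBJECT:
        raise ValidationError(
            f"DEAP layout requires {N_TRIALS_PER_SUBJECT} trials, got {len(trials)}"
        )
    n_samp = trials[0].n_samples
    data = np.zeros((len(trials), N_FILE_CHANNELS, n_samp))
    labels = np.zeros((len(trials), 4))
    for i, tr in enumerate(trials):
        if tr.signal.shape != (N_EEG_CHANNELS, n_samp):
            raise ValidationError(
                f"trial {tr.trial_id}: signal shape {tr.signal.shape} != "
                f"({N_EEG_CHANNELS}, {n_samp})"
            )
        data[i, :N_EEG_CHANNELS, :] = tr.signal
        labels[i] = [tr.ratings[name] for name in RATING_NAMES]
    payload = {"data": data, "labels": labels}
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".dat", ".pkl", ".pickle"):
        with open(path, "wb") as fh:
            pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)
    elif path.suffix == ".mat":
        from scipy.io import savemat

        savemat(str(path), payload)
    else:
        raise FormatError(
            f"unrecognised extension {path.suffix!r}; expected .dat/.pkl or .mat"
        )
    return path
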