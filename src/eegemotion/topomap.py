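"""Topographic assembly: 9x9 scalp grids, band tiling and sample tensors.

Per-channel feature values are placed on a 9x9 grid that mirrors the 10-20
electrode placement (unoccupied cells are exactly zero), one grid per
frequency band; the band grids are tiled into a single larger matrix
(2x2 -> 18x18 for four bands, 1x2 -> 9x18 for two) and the six feature
types are stacked along the depth axis, giving the 18x18x6 network input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .features import FEATURE_NAMES, SegmentFeatures
from .io_dataset import DEAP_CHANNELS

GRID_SIZE = 9
MIDLINE_COL = 4

#: Default tiling of the four bands into 2x2 quadrants (row-major).
DEFAULT_BAND_TILING: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class ElectrodeLayout:
    """Channel-name -> (row, col) map into the 9x9 scalp grid."""

    positions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.positions) != len(DEAP_CHANNELS):
            raise ValidationError(
                f"layout has {len(self.positions)} electrodes, expected {len(DEAP_CHANNELS)}"
            )
        seen: dict[tuple[int, int], str] = {}
        for name, (r, c) in self.positions.items():
            if not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE):
                raise ValidationError(f"{name}: position ({r}, {c}) outside the 9x9 grid")
            if (r, c) in seen:
                raise ValidationError(f"{name} and {seen[(r, c)]} share cell ({r}, {c})")
            seen[(r, c)] = name
        # left/right homologues mirror about the midline column
        for name, (r, c) in self.positions.items():
            if name[-1].isdigit():
                n = int(name[-1])
                partner = name[:-1] + str(n + 1 if n % 2 else n - 1)
                if partner in self.positions:
                    pr, pc = self.positions[partner]
                    if pr != r or pc != 2 * MIDLINE_COL - c:
                        raise ValidationError(
                            f"{name} at ({r},{c}) and {partner} at ({pr},{pc}) "
                            "do not mirror about the midline"
                        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ElectrodeLayout":
        """Load a layout from a ``NAME row col`` text file."""
        positions = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            name, r, c = line.split()
            positions[name] = (int(r), int(c))
        return cls(positions)

    @classmethod
    def default(cls) -> "ElectrodeLayout":
        """The packaged 9x9 layout for DEAP's 32 channels."""
        ref = resources.files("eegemotion").joinpath("layouts/deap_9x9.txt")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def index_arrays(self, channels: Sequence[str] = DEAP_CHANNELS) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) arrays aligned with ``channels`` for vectorized mapping."""
        missing = [c for c in channels if c not in self.positions]
        if missing:
            raise ValidationError(f"channels absent from layout: {missing}")
        rc = np.array([self.positions[c] for c in channels])
        return rc[:, 0], rc[:, 1]


@dataclass
class SampleTensor:
    """One model input: (height, width, depth) array in [0,1] plus its label."""

    data: np.ndarray
    label: int | None
    subject_id: int
    trial_id: int
    segment_index: int
    band_names: tuple[str, ...] = DEFAULT_BAND_TILING
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"sample tensor must be 3-D, got {self.data.ndim}-D")


def map_to_grid(
    channel_values: np.ndarray | Mapping[str, float],
    layout: ElectrodeLayout | None = None,
    channels: Sequence[str] = DEAP_CHANNELS,
) -> np.ndarray:
    """Place 32 per-channel values on the 9x9 grid; empty cells are zero.

    ``channel_values`` is either an array aligned with ``channels`` or a
    name -> value mapping covering exactly the layout's electrodes.
    """
    layout = layout or ElectrodeLayout.default()
    if isinstance(channel_values, Mapping):
        extra = sorted(set(channel_values) - set(layout.positions))
        missing = sorted(set(layout.positions) - set(channel_values))
        if extra or missing:
            raise ValidationError(f"channel mismatch: missing {missing}, extra {extra}")
        channels = tuple(channel_values)
        values = np.array([channel_values[c] for c in channels], dtype=float)
    else:
        values = np.asarray(channel_values, dtype=float)
        if values.shape != (len(channels),):
            raise ValidationError(
                f"expected {len(channels)} values, got shape {values.shape}"
            )
    rows, cols = layout.index_arrays(channels)
    grid = np.zeros((GRID_SIZE, GRID_SIZE))
    grid[rows, cols] = values
    return grid


def read_from_grid(
    grid: np.ndarray,
    layout: ElectrodeLayout | None = None,
    channels: Sequence[str] = DEAP_CHANNELS,
) -> np.ndarray:
    """Inverse of :func:`map_to_grid`: read the 32 electrode cells back."""
    layout = layout or ElectrodeLayout.default()
    rows, cols = layout.index_arrays(channels)
    return np.asarray(grid)[rows, cols]


def tile_bands(
    band_grids: Mapping[str, np.ndarray], order: Sequence[str] | None = None
) -> np.ndarray:
    """Tile per-band 9x9 grids into one matrix.

    Four bands tile 2x2 (row-major in ``order``) into 18x18; two bands tile
    side by side into 9x18; one band passes through unchanged.
    """
    if order is None:
        order = [b for b in DEFAULT_BAND_TILING if b in band_grids] or list(band_grids)
    if set(order) != set(band_grids):
        raise ValidationError(
            f"tiling order {list(order)} does not match bands {sorted(band_grids)}"
        )
    grids = []
    for b in order:
        g = np.asarray(band_grids[b])
        if g.shape != (GRID_SIZE, GRID_SIZE):
            raise ValidationError(f"band {b!r}: grid shape {g.shape} != 9x9")
        grids.append(g)
    if len(grids) == 1:
        return grids[0]
    if len(grids) == 2:
        return np.concatenate(grids, axis=1)
    if len(grids) == 4:
        top = np.concatenate(grids[:2], axis=1)
        bottom = np.concatenate(grids[2:], axis=1)
        return np.concatenate([top, bottom], axis=0)
    raise ValidationError(f"no tiling defined for {len(grids)} bands")


def assemble_sample(
    features: SegmentFeatures,
    layout: ElectrodeLayout | None = None,
    feature_order: Sequence[str] = FEATURE_NAMES,
    band_order: Sequence[str] | None = None,
    channels: Sequence[str] = DEAP_CHANNELS,
) -> SampleTensor:
    """Build the (H, W, 6) sample tensor of one segment.

    Depth indexes the feature types in ``feature_order``; each depth slice
    is the band tiling of that feature's 9x9 grids.  Requires normalized
    features (all values in [0, 1]).
    """
    if not features.normalized or features.values.min() < 0.0 or features.values.max() > 1.0:
        raise ValidationError("assemble_sample requires per-trial normalized features in [0,1]")
    layout = layout or ElectrodeLayout.default()
    unknown = set(feature_order) - set(features.feature_names)
    if unknown:
        raise ValidationError(f"unknown feature types {sorted(unknown)}")
    slices = []
    for fname in feature_order:
        fi = features.feature_names.index(fname)
        grids = {
            b: map_to_grid(features.values[:, bi, fi], layout, channels)
            for bi, b in enumerate(features.band_names)
        }
        slices.append(tile_bands(grids, band_order))
    return SampleTensor(
        data=np.stack(slices, axis=-1),
        label=features.label,
        subject_id=features.subject_id,
        trial_id=features.trial_id,
        segment_index=features.segment_index,
        band_names=tuple(band_order or features.band_names),
        feature_names=tuple(feature_order),
    )


def pearson_correlation_map(
    trial_signal: np.ndarray, reference_channel: str, channels: Sequence[str] = DEAP_CHANNELS
) -> np.ndarray:
    """Pearson r of every channel against one reference channel.

    Returns 32 values in [-1, 1] with r = 1 at the reference itself.  A
    constant channel has no defined correlation and is reported as 0 with
    a warning.
    """
    x = np.asarray(trial_signal, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("trial_signal must be (channels, time) with >= 2 samples")
    if reference_channel not in channels:
        raise ValidationError(f"unknown reference channel {reference_channel!r}")
    ref = x[list(channels).index(reference_channel)]
    sd = x.std(axis=1)
    const = sd == 0.0
    if const.any() or ref.std() == 0.0:
        warnings.warn("constant channel(s): correlation reported as 0", RuntimeWarning, stacklevel=2)
    if ref.std() == 0.0:
        out = np.zeros(x.shape[0])
        out[list(channels).index(reference_channel)] = 1.0
        return out
    xc = x - x.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    denom = np.where(const, 1.0, sd * ref.std()) * x.shape[1]
    r = np.where(const, 0.0, (xc @ rc) / denom)
    return np.clip(r, -1.0, 1.0)


def plot_correlation_topomap(r: np.ndarray, layout: ElectrodeLayout | None = None, ax=None):
    """Show a 32-channel correlation vector on the scalp grid."""
    import matplotlib.pyplot as plt

    layout = layout or ElectrodeLayout.default()
    grid = map_to_grid(r, layout)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(grid, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    return ax
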