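"""Color-frequency histogram features.

Each sample image contributes one row to the regression matrix: the pixels
of the selected grid cells are pooled and, per color channel, counted into
a 256-bin frequency histogram; the per-channel histograms are concatenated
in a declared channel order.  Pooling (one histogram over the union of the
selected subimages) keeps the feature length constant no matter how many
cells a chromosome selects, so a single PLS architecture serves every
candidate subset.

Channels are named ``"R" "G" "B" "H" "S" "V" "gray"``; every channel lives
on the shared 0-255 intensity domain (see :mod:`chromaroi.image_grid` for
the HSV/grayscale quantisation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ShapeError
from .image_grid import RasterImage, ROIGrid, to_grayscale, to_hsv

__all__ = [
    "CHANNELS",
    "DEFAULT_CHANNELS",
    "FeatureVector",
    "FeatureMatrix",
    "channel_plane",
    "channel_histogram",
    "roi_histogram",
    "build_feature_matrix",
]

#: Recognised channel names in canonical concatenation order.
CHANNELS = ("R", "G", "B", "H", "S", "V", "gray")

#: Default channel selection: plain RGB histograms.
DEFAULT_CHANNELS = ("R", "G", "B")

N_BINS = 256


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated per-channel 256-bin histograms plus their layout."""

    values: np.ndarray  # (256 * n_channels,) int64 counts (or float if normalised)
    channels: tuple[str, ...]

    def __len__(self) -> int:
        return self.values.shape[0]

    def channel_slice(self, channel: str) -> slice:
        i = self.channels.index(channel)
        return slice(i * N_BINS, (i + 1) * N_BINS)


@dataclass(frozen=True)
class FeatureMatrix:
    """Sample-by-feature matrix with aligned response vector and ids."""

    X: np.ndarray  # (I, J_feat)
    y: np.ndarray  # (I,)
    sample_ids: tuple[str, ...]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.sample_ids):
            raise ShapeError("X rows, y and sample_ids must align")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def feature_names(self) -> list[str]:
        base = [f"{ch}_{b:03d}" for ch in self.channels for b in range(N_BINS)]
        if self.n_features == len(base):
            return base
        # per-cell layout: repeat the channel/bin names per block
        n_blocks, rem = divmod(self.n_features, len(base))
        if rem:
            raise ShapeError("feature count inconsistent with channel layout")
        return [f"c{blk}_{name}" for blk in range(n_blocks) for name in base]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names())
        df.insert(0, "y", self.y)
        df.insert(0, "sample_id", list(self.sample_ids))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        bins = [c for c in df.columns if c not in ("sample_id", "y")]
        channels = tuple(dict.fromkeys(c.split("_")[0] for c in bins))
        return cls(
            X=df[bins].to_numpy(dtype=np.float64),
            y=df["y"].to_numpy(dtype=np.float64),
            sample_ids=tuple(str(s) for s in df["sample_id"]),
            channels=channels,
        )


def _validate_channels(channels: Sequence[str]) -> tuple[str, ...]:
    channels = tuple(channels)
    if not channels:
        raise DomainError("channel selection must be non-empty")
    unknown = [c for c in channels if c not in CHANNELS]
    if unknown:
        raise DomainError(f"unknown channels {unknown}; valid: {CHANNELS}")
    return channels


def channel_plane(img: RasterImage, channel: str) -> np.ndarray:
    """Return the J x K uint8 intensity plane of a named channel."""
    if channel in ("R", "G", "B"):
        return img.pixels[:, :, ("R", "G", "B").index(channel)]
    if channel in ("H", "S", "V"):
        return to_hsv(img)[:, :, ("H", "S", "V").index(channel)]
    if channel == "gray":
        return to_grayscale(img)
    raise DomainError(f"unknown channel {channel!r}")


def channel_histogram(
    channel_grid: np.ndarray, mask: Iterable[tuple[slice, slice]]
) -> np.ndarray:
    """256-bin frequency histogram of the pixels pooled over the mask blocks.

    ``mask`` is an iterable of half-open ``(row_slice, col_slice)`` pixel
    blocks; bin *b* counts the pooled pixels with intensity *b*, so the bins
    sum to the pooled pixel count.
    """
    blocks = list(mask)
    if not blocks:
        raise DomainError("mask must contain at least one pixel block")
    hist = np.zeros(N_BINS, dtype=np.int64)
    for rs, cs in blocks:
        block = channel_grid[rs, cs]
        hist += np.bincount(block.ravel(), minlength=N_BINS)
    return hist


def roi_histogram(
    img: RasterImage,
    grid: ROIGrid,
    selected: Iterable[int],
    channels: Sequence[str] = DEFAULT_CHANNELS,
    normalize: bool = False,
) -> FeatureVector:
    """Pooled per-channel histograms of the selected grid cells.

    ``selected`` holds 1-based linear cell indices (the unfolded candidate
    vector positions).  The feature length is ``256 * len(channels)``
    regardless of how many cells are selected.  With ``normalize=True`` the
    counts become relative frequencies.
    """
    channels = _validate_channels(channels)
    sel = sorted(set(int(i) for i in selected))
    if not sel:
        raise DomainError("selection must contain at least one subimage")
    for i in sel:
        if not (1 <= i <= grid.n):
            raise DomainError(f"subimage index {i} outside [1, {grid.n}]")
    blocks = [grid.cell_slices(i) for i in sel]
    parts = []
    for ch in channels:
        plane = channel_plane(img, ch)
        hist = channel_histogram(plane, blocks)
        parts.append(hist)
    values = np.concatenate(parts)
    if normalize:
        npix = float(sum((rs.stop - rs.start) * (cs.stop - cs.start) for rs, cs in blocks))
        values = values.astype(np.float64) / npix
    return FeatureVector(values=values, channels=channels)


def build_feature_matrix(
    samples: Sequence[tuple[str, RasterImage, float]],
    grid: ROIGrid,
    selected: Iterable[int],
    channels: Sequence[str] = DEFAULT_CHANNELS,
    normalize: bool = False,
    per_cell: bool = False,
) -> FeatureMatrix:
    """Stack per-sample ROI histograms into the regression matrix X with y.

    ``samples`` is a sequence of ``(sample_id, image, response)``; all
    images must share dimensions (the grid is defined on one geometry).
    With ``per_cell=True`` each selected cell contributes its own
    concatenated channel histograms (in ascending cell order) instead of
    pooling — the feature length then scales with the selection size.
    """
    channels = _validate_channels(channels)
    sel = list(selected)
    rows = []
    ids = []
    ys = []
    shape = None
    for sid, img, y in samples:
        if shape is None:
            shape = (img.height, img.width)
        elif (img.height, img.width) != shape:
            raise ShapeError(
                f"sample {sid!r} has dimensions {(img.height, img.width)}, "
                f"expected {shape}"
            )
        if not np.isfinite(y):
            raise DomainError(f"sample {sid!r} has non-finite response {y}")
        if per_cell:
            parts = [
                roi_histogram(img, grid, [c], channels, normalize=normalize).values
                for c in sorted(set(int(i) for i in sel))
            ]
            values = np.concatenate(parts)
        else:
            values = roi_histogram(
                img, grid, sel, channels, normalize=normalize
            ).values
        rows.append(values.astype(np.float64))
        ids.append(str(sid))
        ys.append(float(y))
    if not rows:
        raise DomainError("no samples given")
    return FeatureMatrix(
        X=np.vstack(rows),
        y=np.asarray(ys, dtype=np.float64),
        sample_ids=tuple(ids),
        channels=channels,
    )
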