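"""Raster images, color-model conversion and the ROI grid.

A 2D chromatogram is handled as an ordinary 24-bit RGB raster of shape
``J x K`` (J rows = second chromatographic dimension, K columns = first
dimension).  The image is partitioned into ``roi2`` rows by ``roi1``
columns of near-equal rectangular subimages; the grid cells are unfolded
row-major into a flat candidate vector that the genetic algorithm indexes.

Conventions, declared once and used everywhere:

* pixel coordinates are 0-based and half-open internally;
* grid cells are labelled 1-based ``(row, col)`` with row 1 at the image
  top in every user-facing report;
* unfolding is row-major: ``index = (row - 1) * roi1 + col``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DomainError, ImageFormatError

__all__ = [
    "RasterImage",
    "ROIGrid",
    "load_image",
    "to_grayscale",
    "to_hsv",
    "partition_image",
    "export_grid_preview",
]

#: ITU-R BT.601 luma weights used for the grayscale channel.
GRAYSCALE_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class RasterImage:
    """A 24-bit RGB raster: ``pixels[j, k] = (R, G, B)`` with values 0-255."""

    pixels: np.ndarray  # (J, K, 3) uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"expected a (J, K, 3) RGB array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ImageFormatError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        """J, the pixel count along the second chromatographic dimension."""
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        """K, the pixel count along the first chromatographic dimension."""
        return self.pixels.shape[1]

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path)


def load_image(path: str | Path) -> RasterImage:
    """Load a 24-bit BMP or PNG as a :class:`RasterImage`.

    The channel order is normalised to RGB regardless of the on-disk byte
    order.  Palette, grayscale or alpha-carrying images are rejected: the
    pipeline's histogram features are defined on true 24-bit color rasters.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode != "RGB":
                raise ImageFormatError(
                    f"{path.name}: expected 24-bit RGB image, got mode {mode!r}"
                )
            arr = np.asarray(im, dtype=np.uint8)
    except ImageFormatError:
        raise
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot decode image {path}: {exc}") from exc
    return RasterImage(arr)


def to_grayscale(img: RasterImage) -> np.ndarray:
    """Map each pixel to ITU-R BT.601 luma, rounded to uint8.

    ``gray = round(0.299 R + 0.587 G + 0.114 B)``
    """
    w = np.asarray(GRAYSCALE_WEIGHTS)
    gray = np.tensordot(img.pixels.astype(np.float64), w, axes=([2], [0]))
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def to_hsv(img: RasterImage) -> np.ndarray:
    """Hexcone RGB -> HSV, each channel rescaled to integer levels 0-255.

    Hue (natively 0-360 deg), saturation and value (natively 0-1) are all
    linearly quantised to [0, 255] so every color channel shares the same
    256-bin histogram domain.
    """
    from matplotlib.colors import rgb_to_hsv

    hsv = rgb_to_hsv(img.pixels.astype(np.float64) / 255.0)
    return np.clip(np.rint(hsv * 255.0), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class ROIGrid:
    """Partition of a J x K image into roi2 rows x roi1 columns of cells.

    ``row_bounds``/``col_bounds`` hold the ``roi2 + 1`` / ``roi1 + 1``
    half-open pixel offsets; cell ``(r, c)`` (1-based) covers
    ``[row_bounds[r-1], row_bounds[r]) x [col_bounds[c-1], col_bounds[c])``.
    """

    roi1: int
    roi2: int
    row_bounds: tuple[int, ...]
    col_bounds: tuple[int, ...]

    @property
    def n(self) -> int:
        """Total number of subimages, roi1 * roi2 (length of the unfolded
        candidate vector)."""
        return self.roi1 * self.roi2

    @property
    def height(self) -> int:
        return self.row_bounds[-1]

    @property
    def width(self) -> int:
        return self.col_bounds[-1]

    def unfold_index(self, row: int, col: int) -> int:
        """1-based (row, col) -> 1-based linear index, row-major."""
        if not (1 <= row <= self.roi2 and 1 <= col <= self.roi1):
            raise DomainError(
                f"(row, col) = ({row}, {col}) outside grid "
                f"{self.roi2} rows x {self.roi1} cols"
            )
        return (row - 1) * self.roi1 + col

    def fold_index(self, index: int) -> tuple[int, int]:
        """1-based linear index -> 1-based (row, col); inverse of
        :meth:`unfold_index`."""
        if not (1 <= index <= self.n):
            raise DomainError(f"linear index {index} outside [1, {self.n}]")
        row, col = divmod(index - 1, self.roi1)
        return row + 1, col + 1

    def cell_slices(self, index: int) -> tuple[slice, slice]:
        """Half-open (row_slice, col_slice) pixel block of a 1-based linear
        cell index."""
        row, col = self.fold_index(index)
        return (
            slice(self.row_bounds[row - 1], self.row_bounds[row]),
            slice(self.col_bounds[col - 1], self.col_bounds[col]),
        )

    def cell_pixel_count(self, index: int) -> int:
        rs, cs = self.cell_slices(index)
        return (rs.stop - rs.start) * (cs.stop - cs.start)


def partition_image(img: RasterImage | tuple[int, int], roi1: int, roi2: int) -> ROIGrid:
    """Partition an image (or a bare ``(J, K)`` shape) into a roi1 x roi2 grid.

    Boundaries are ``floor(i * dim / roi)`` so blocks differ by at most one
    pixel per axis and no pixel is dropped; they depend only on the image
    dimensions, never on pixel content.
    """
    if isinstance(img, RasterImage):
        J, K = img.height, img.width
    else:
        J, K = img
    if not (1 <= roi2 <= J):
        raise DomainError(f"roi2 = {roi2} outside [1, J = {J}]")
    if not (1 <= roi1 <= K):
        raise DomainError(f"roi1 = {roi1} outside [1, K = {K}]")
    row_bounds = tuple(i * J // roi2 for i in range(roi2 + 1))
    col_bounds = tuple(i * K // roi1 for i in range(roi1 + 1))
    return ROIGrid(roi1=roi1, roi2=roi2, row_bounds=row_bounds, col_bounds=col_bounds)


def export_grid_preview(
    img: RasterImage,
    grid: ROIGrid,
    image_path: str | Path,
    bounds_csv_path: str | Path | None = None,
) -> None:
    """Write a preview image with grid lines and (row, col) labels, plus an
    optional CSV of half-open subimage bounds."""
    from PIL import ImageDraw

    pil = Image.fromarray(img.pixels, mode="RGB")
    draw = ImageDraw.Draw(pil)
    for b in grid.row_bounds[1:-1]:
        draw.line([(0, b), (img.width - 1, b)], fill=(0, 0, 0))
    for b in grid.col_bounds[1:-1]:
        draw.line([(b, 0), (b, img.height - 1)], fill=(0, 0, 0))
    for idx in range(1, grid.n + 1):
        row, col = grid.fold_index(idx)
        rs, cs = grid.cell_slices(idx)
        draw.text((cs.start + 2, rs.start + 2), f"{row},{col}", fill=(0, 0, 0))
    pil.save(image_path)

    if bounds_csv_path is not None:
        with open(bounds_csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row", "col", "y0", "y1", "x0", "x1"])
            for idx in range(1, grid.n + 1):
                row, col = grid.fold_index(idx)
                rs, cs = grid.cell_slices(idx)
                writer.writerow([row, col, rs.start, rs.stop, cs.start, cs.stop])
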