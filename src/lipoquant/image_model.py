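"""Core image/mask data types, TIFF I/O and generic preprocessing operators.

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, 0-based, with pixel centers at
  integer coordinates;
* all distances are Euclidean, in pixel units;
* intensities are kept in their original (arbitrary) units — nothing is
  rescaled to ``[0, 1]`` on load, because every downstream statistic is
  either a ratio or scale-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

__all__ = [
    "MultiChannelImage",
    "BinaryMask",
    "CellROI",
    "ChannelCountMismatchError",
    "read_image",
    "write_image",
    "read_mask",
    "rasterize_polygon_csv",
    "subtract_background",
    "otsu_mask",
    "dilate_mask",
    "mask_union",
    "mask_difference",
]


class ChannelCountMismatchError(ValueError):
    """Number of channel names does not match number of image planes."""


@dataclass(frozen=True)
class MultiChannelImage:
    """Named 2D intensity channels on one pixel grid with a physical pixel size.

    Parameters
    ----------
    channels
        Mapping of channel name to 2D float array of nonnegative, finite
        intensities. All channels must share the same shape.
    pixel_size_um
        Physical pixel size in micrometres (must be > 0).
    bit_depth
        Source bit depth, kept as metadata only.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float = 1.0
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel is required")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        shapes = set()
        clean: dict[str, np.ndarray] = {}
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not a 2D plane (ndim={arr.ndim})")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            shapes.add(arr.shape)
            clean[name] = arr
        if len(shapes) != 1:
            raise ValueError(f"channels have inconsistent shapes: {sorted(shapes)}")
        object.__setattr__(self, "channels", clean)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {sorted(self.channels)}"
            ) from None


@dataclass(frozen=True)
class BinaryMask:
    """2D boolean mask on the same pixel grid as the image it derives from."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError(f"mask must be 2D, got ndim={grid.ndim}")
        object.__setattr__(self, "grid", grid.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def area(self) -> int:
        return int(np.count_nonzero(self.grid))

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "BinaryMask":
        return cls(np.zeros(shape, dtype=bool))

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "BinaryMask":
        return cls(np.ones(shape, dtype=bool))


@dataclass(frozen=True)
class CellROI:
    """Binary cell mask plus binary nucleus mask for one outlined cell."""

    cell_mask: BinaryMask
    nucleus_mask: BinaryMask
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise ValueError("cell and nucleus masks have different shapes")
        if self.cell_mask.area() == 0:
            raise ValueError("cell mask is empty")
        if np.any(self.nucleus_mask.grid & ~self.cell_mask.grid):
            raise ValueError("nucleus mask is not contained in cell mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_mask.shape


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(
    path: str | Path,
    channel_names: list[str],
    pixel_size_um: float = 1.0,
) -> MultiChannelImage:
    """Read a single- or multi-page TIFF into a :class:`MultiChannelImage`.

    Each page becomes one channel, keyed by ``channel_names`` in page order.
    Intensities are cast to float64 without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected 2D planes, got array of ndim {data.ndim} from {path}")
    if data.shape[0] != len(channel_names):
        raise ChannelCountMismatchError(
            f"{path} has {data.shape[0]} plane(s) but {len(channel_names)} "
            f"channel name(s) were given"
        )
    bit_depth = data.dtype.itemsize * 8 if np.issubdtype(data.dtype, np.integer) else None
    channels = {name: data[i].astype(np.float64) for i, name in enumerate(channel_names)}
    return MultiChannelImage(channels=channels, pixel_size_um=pixel_size_um, bit_depth=bit_depth)


def write_image(
    image: MultiChannelImage,
    path: str | Path,
    channel_order: list[str] | None = None,
    dtype: np.dtype | str | None = None,
) -> None:
    """Write channels as a multi-page TIFF (one page per channel).

    If ``dtype`` is None, integral-valued images that fit in uint16 are
    written as uint16, otherwise float64 — so integer pixel data round-trips
    bit-exactly through :func:`read_image`.
    """
    names = channel_order if channel_order is not None else list(image.channels)
    stack = np.stack([image.channel(n) for n in names])
    if dtype is None:
        integral = np.all(stack == np.round(stack))
        if integral and stack.min() >= 0 and stack.max() <= np.iinfo(np.uint16).max:
            stack = stack.astype(np.uint16)
    else:
        stack = stack.astype(dtype)
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask from an 8-bit TIFF/PNG (0 = false, nonzero = true)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
        if data.ndim == 3:  # RGB(A) PNG: any nonzero channel counts
            data = data.max(axis=-1)
    if data.ndim != 2:
        raise ValueError(f"mask {path} is not a single 2D plane")
    return BinaryMask(data != 0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    tifffile.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


def rasterize_polygon_csv(path: str | Path, shape: tuple[int, int]) -> dict[str, BinaryMask]:
    """Rasterize polygon outlines from a vertex CSV.

    Expected columns: ``cell_id, vertex_index, row, col``. Returns one filled
    mask per ``cell_id``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"cell_id", "vertex_index", "row", "col"}
    if not required.issubset(df.columns):
        raise ValueError(f"polygon CSV must have columns {sorted(required)}")
    masks: dict[str, BinaryMask] = {}
    for cell_id, grp in df.groupby("cell_id", sort=True):
        verts = grp.sort_values("vertex_index")[["row", "col"]].to_numpy(dtype=float)
        masks[str(cell_id)] = BinaryMask(polygon2mask(shape, verts))
    return masks


# ---------------------------------------------------------------------------
# Preprocessing operators
# ---------------------------------------------------------------------------

def subtract_background(channel: np.ndarray, ball_radius_px: int = 50) -> np.ndarray:
    """Rolling-ball style background subtraction.

    The background is estimated by grayscale opening with a disk structuring
    element of the given radius and subtracted from the input. Flat regions
    map to ~0; features smaller than the ball are preserved.
    """
    if ball_radius_px < 1:
        raise ValueError(f"ball_radius_px must be >= 1, got {ball_radius_px}")
    channel = np.asarray(channel, dtype=np.float64)
    background = opening(channel, disk(int(ball_radius_px)))
    out = channel - background
    # opening is anti-extensive, so out >= 0 up to float error
    np.clip(out, 0.0, None, out=out)
    return out


def otsu_mask(channel: np.ndarray, nbins: int = 256) -> BinaryMask:
    """Threshold a channel by Otsu's method; mask = pixels strictly above it.

    A constant channel cannot be thresholded: an empty mask is returned with
    a warning so degenerate cells still flow through batch runs.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.min() == channel.max():
        warnings.warn("otsu_mask: constant channel, returning empty mask", stacklevel=2)
        return BinaryMask.empty(channel.shape)
    thr = threshold_otsu(channel, nbins=nbins)
    return BinaryMask(channel > thr)


def dilate_mask(mask: BinaryMask, radius_px: float) -> BinaryMask:
    """Dilate by an exact Euclidean disk of the given radius.

    Every pixel within Euclidean distance ``radius_px`` of an input true pixel
    is set; the result is always a superset of the input.
    """
    if radius_px < 0:
        raise ValueError(f"radius_px must be >= 0, got {radius_px}")
    if radius_px == 0 or mask.area() == 0:
        return BinaryMask(mask.grid.copy())
    dist = ndi.distance_transform_edt(~mask.grid)
    return BinaryMask(dist <= radius_px + 1e-9)


def mask_union(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return BinaryMask(a.grid | b.grid)


def mask_difference(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return BinaryMask(a.grid & ~b.grid)
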