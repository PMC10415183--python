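"""Per-cell statistics: enrichment at LDs, masked Pearson colocalization,
LD area fraction and LD density per physical area.

Two enrichment definitions are first-class because they are used for
different figures of merit:

* ``enrichment_sum`` — fraction of the decorator channel's summed intensity
  falling inside the detected LD radii (filled disks);
* ``enrichment_mean`` — mean intensity inside an LD(-surface) mask relative
  to the mean over the whole cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .detection import Blob, BlobSet, blobs_to_mask
from .image_model import BinaryMask, CellROI, dilate_mask, mask_difference, otsu_mask

__all__ = [
    "EnrichmentResult",
    "CorrelationResult",
    "MorphometryResult",
    "enrichment_sum",
    "enrichment_mean",
    "masked_pearson",
    "peripheral_mask",
    "ld_area_fraction",
    "ld_density_per_area",
]


@dataclass(frozen=True)
class EnrichmentResult:
    cell_id: str
    total_intensity: float | None = None
    ld_intensity: float | None = None
    enrichment_sum: float | None = None
    enrichment_mean: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    cell_id: str
    region: str  # ld_localized | peripheral | patch
    channel_pair: tuple[str, str]
    pearson_r: float
    n_pixels: int


@dataclass(frozen=True)
class MorphometryResult:
    cell_id: str
    ld_area_px: int | None = None
    cell_area_px: int | None = None
    area_fraction: float | None = None
    normalized_area_fraction: float | None = None
    ld_count: int | None = None
    density_per_um2: float | None = None


def enrichment_sum(
    decorator_channel: np.ndarray,
    blobs: BlobSet | list[Blob],
    roi: CellROI,
    cell_id: str = "cell",
) -> EnrichmentResult:
    """Sum-based enrichment: LD-localized intensity over total cell intensity.

    Total is the summed decorator intensity over the cell mask; LD-localized
    is the sum over the filled disks of the detected radii, intersected with
    the cell mask. The decorator channel should be background-subtracted.
    """
    decorator_channel = np.asarray(decorator_channel, dtype=np.float64)
    cell = roi.cell_mask.grid
    total = float(decorator_channel[cell].sum())
    ld_mask = blobs_to_mask(blobs, decorator_channel.shape).grid & cell
    ld = float(decorator_channel[ld_mask].sum())
    if total == 0:
        warnings.warn(
            f"enrichment_sum: zero total intensity in cell {cell_id!r}", stacklevel=2
        )
        return EnrichmentResult(cell_id, total_intensity=0.0, ld_intensity=ld)
    return EnrichmentResult(
        cell_id, total_intensity=total, ld_intensity=ld, enrichment_sum=ld / total
    )


def enrichment_mean(
    decorator_channel: np.ndarray,
    ld_mask: BinaryMask,
    roi: CellROI,
    cell_id: str = "cell",
) -> EnrichmentResult:
    """Mean-based enrichment: mean intensity in the LD mask over the cell mean.

    The LD mask is intersected with the cell mask first. Values > 1 indicate
    enrichment at LDs.
    """
    decorator_channel = np.asarray(decorator_channel, dtype=np.float64)
    cell = roi.cell_mask.grid
    inside = ld_mask.grid & cell
    n_in = int(inside.sum())
    if n_in == 0:
        warnings.warn(
            f"enrichment_mean: empty LD mask in cell {cell_id!r}", stacklevel=2
        )
        return EnrichmentResult(cell_id)
    mean_cell = float(decorator_channel[cell].mean())
    if mean_cell == 0:
        warnings.warn(
            f"enrichment_mean: zero mean cell intensity in cell {cell_id!r}",
            stacklevel=2,
        )
        return EnrichmentResult(cell_id)
    mean_ld = float(decorator_channel[inside].mean())
    return EnrichmentResult(cell_id, enrichment_mean=mean_ld / mean_cell)


def masked_pearson(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    mask: BinaryMask,
    cell_id: str = "cell",
    region: str = "peripheral",
    channel_pair: tuple[str, str] = ("a", "b"),
) -> CorrelationResult:
    """Pearson correlation over the pixel pairs selected by ``mask``.

    Computed in double precision via the mean-centered (two-pass) formula.
    A constant channel within the mask yields NaN with a warning.
    """
    channel_a = np.asarray(channel_a, dtype=np.float64)
    channel_b = np.asarray(channel_b, dtype=np.float64)
    if channel_a.shape != channel_b.shape or channel_a.shape != mask.shape:
        raise ValueError("channel/mask shapes differ")
    n = mask.area()
    if n < 2:
        raise ValueError(f"masked_pearson needs >= 2 in-mask pixels, got {n}")
    a = channel_a[mask.grid]
    b = channel_b[mask.grid]
    if a.std() == 0 or b.std() == 0:
        warnings.warn(
            f"masked_pearson: constant channel within mask for cell {cell_id!r}",
            stacklevel=2,
        )
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return CorrelationResult(cell_id, region, channel_pair, r, n)


def peripheral_mask(roi: CellROI, dilation_px: float = 160) -> BinaryMask:
    """Cell-periphery mask: the nuclear mask dilated by ``dilation_px`` and
    subtracted from the whole-cell mask. May be empty."""
    return mask_difference(roi.cell_mask, dilate_mask(roi.nucleus_mask, dilation_px))


def ld_area_fraction(
    ld_channel: np.ndarray,
    roi: CellROI,
    cell_id: str = "cell",
    otsu_scope: str = "cell",
) -> MorphometryResult:
    """Total LD area (Otsu threshold on the LD channel) divided by cell area.

    ``otsu_scope`` selects whether the Otsu threshold is computed from the
    in-cell pixels only (``"cell"``, default) or the whole image (``"image"``).
    """
    ld_channel = np.asarray(ld_channel, dtype=np.float64)
    if ld_channel.shape != roi.shape:
        raise ValueError("channel/ROI shapes differ")
    cell = roi.cell_mask.grid
    cell_area = int(cell.sum())
    if cell_area == 0:
        raise ValueError("empty cell mask")
    if otsu_scope == "cell":
        vals = ld_channel[cell]
        if vals.min() == vals.max():
            warnings.warn("ld_area_fraction: constant channel in cell", stacklevel=2)
            ld_grid = np.zeros_like(cell)
        else:
            from skimage.filters import threshold_otsu

            ld_grid = ld_channel > threshold_otsu(vals, nbins=256)
    elif otsu_scope == "image":
        ld_grid = otsu_mask(ld_channel).grid
    else:
        raise ValueError(f"otsu_scope must be 'cell' or 'image', got {otsu_scope!r}")
    ld_area = int((ld_grid & cell).sum())
    return MorphometryResult(
        cell_id,
        ld_area_px=ld_area,
        cell_area_px=cell_area,
        area_fraction=ld_area / cell_area,
    )


def ld_density_per_area(
    ld_count: int,
    image_shape: tuple[int, int],
    pixel_size_um: float,
) -> float:
    """LD count normalized to the physical image area, in counts per µm²."""
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    h, w = image_shape
    area_um2 = h * w * pixel_size_um**2
    return ld_count / area_um2
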