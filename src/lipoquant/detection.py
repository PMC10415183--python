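"""Lipid-droplet detection and LD-derived masks.

LDs are detected as scale-space blobs (Laplacian of Gaussian); detected
centroids and radii drive the filled LD mask, the surface "donut" mask,
local-maxima counting, and the tissue mature-LD correlation filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import blob_log

from .image_model import BinaryMask, CellROI

__all__ = [
    "Blob",
    "BlobSet",
    "DetectionConfig",
    "detect_lds_log",
    "blobs_to_mask",
    "surface_donut_mask",
    "donut_expansion_px",
    "count_local_maxima",
    "filter_mature_lds",
]


@dataclass(frozen=True)
class Blob:
    """One detected droplet: centroid (row, col) and radius, in pixels."""

    row: float
    col: float
    radius_px: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError(f"radius_px must be > 0, got {self.radius_px}")


@dataclass(frozen=True)
class DetectionConfig:
    """Scale-space blob detection parameters.

    ``log_threshold`` is relative to the channel maximum (the channel is
    normalized by its max before detection, making detection invariant to
    intensity scale). ``radius_factor`` converts the detected Gaussian sigma
    to a blob radius; sqrt(2) is the 2D LoG extremum relation.
    """

    min_sigma_px: float = 1.5
    max_sigma_px: float = 8.0
    num_sigma: int = 10
    log_threshold: float = 0.05
    overlap_max: float = 0.5
    radius_factor: float = math.sqrt(2.0)

    def __post_init__(self) -> None:
        if not 0 < self.min_sigma_px < self.max_sigma_px:
            raise ValueError("need 0 < min_sigma_px < max_sigma_px")
        if self.num_sigma < 2:
            raise ValueError("num_sigma must be >= 2")
        if not 0 <= self.overlap_max <= 1:
            raise ValueError("overlap_max must be in [0, 1]")
        if self.radius_factor <= 0:
            raise ValueError("radius_factor must be > 0")

    def asdict(self) -> dict:
        return {
            "min_sigma_px": self.min_sigma_px,
            "max_sigma_px": self.max_sigma_px,
            "num_sigma": self.num_sigma,
            "log_threshold": self.log_threshold,
            "overlap_max": self.overlap_max,
            "radius_factor": self.radius_factor,
        }


@dataclass(frozen=True)
class BlobSet:
    """Detected blobs plus a record of how they were obtained."""

    blobs: tuple[Blob, ...]
    source_channel: str = ""
    detection_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "blobs", tuple(self.blobs))
        seen = set()
        for b in self.blobs:
            key = (b.row, b.col)
            if key in seen:
                raise ValueError(f"duplicate blob centroid at {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.blobs)

    def __iter__(self):
        return iter(self.blobs)

    def replace_blobs(self, blobs) -> "BlobSet":
        return BlobSet(tuple(blobs), self.source_channel, self.detection_config)


def detect_lds_log(
    channel: np.ndarray,
    roi: CellROI | None = None,
    cfg: DetectionConfig | None = None,
    source_channel: str = "",
) -> BlobSet:
    """Detect LDs at local maxima of the scale-normalized LoG response.

    The channel should be background-subtracted. If ``roi`` is given, only
    blobs whose centroid falls inside the cell mask are kept.
    """
    cfg = cfg or DetectionConfig()
    channel = np.asarray(channel, dtype=np.float64)
    peak = channel.max()
    if peak <= 0:
        return BlobSet((), source_channel, cfg.asdict())
    raw = blob_log(
        channel / peak,
        min_sigma=cfg.min_sigma_px,
        max_sigma=cfg.max_sigma_px,
        num_sigma=cfg.num_sigma,
        threshold=cfg.log_threshold,
        overlap=cfg.overlap_max,
    )
    blobs = []
    for row, col, sigma in raw:
        if roi is not None:
            r, c = int(round(row)), int(round(col))
            h, w = roi.cell_mask.shape
            if not (0 <= r < h and 0 <= c < w and roi.cell_mask.grid[r, c]):
                continue
        blobs.append(Blob(float(row), float(col), float(cfg.radius_factor * sigma)))
    # deterministic ordering: larger radius first, then lexicographic centroid
    blobs.sort(key=lambda b: (-b.radius_px, b.row, b.col))
    return BlobSet(tuple(blobs), source_channel, cfg.asdict())


def _disk_indices(blob: Blob, shape: tuple[int, int], inner: float, outer: float):
    """Index arrays of pixels with inner <= distance(centroid) <= outer."""
    h, w = shape
    r0 = max(int(math.floor(blob.row - outer)), 0)
    r1 = min(int(math.ceil(blob.row + outer)), h - 1)
    c0 = max(int(math.floor(blob.col - outer)), 0)
    c1 = min(int(math.ceil(blob.col + outer)), w - 1)
    if r1 < r0 or c1 < c0:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    d = np.hypot(rr - blob.row, cc - blob.col)
    sel = (d >= inner - 1e-9) & (d <= outer + 1e-9)
    return rr[sel], cc[sel]


def blobs_to_mask(blobs: BlobSet | list[Blob], shape: tuple[int, int]) -> BinaryMask:
    """Union of filled disks (distance <= radius from each centroid)."""
    grid = np.zeros(shape, dtype=bool)
    for b in blobs:
        rr, cc = _disk_indices(b, shape, 0.0, b.radius_px)
        grid[rr, cc] = True
    return BinaryMask(grid)


def donut_expansion_px(radius_px: float, scale: float = 0.3, lo: int = 2, hi: int = 5) -> int:
    """Outward expansion of the surface mask: clip(round(scale * r), lo, hi)."""
    return int(np.clip(math.floor(scale * radius_px + 0.5), lo, hi))


def surface_donut_mask(
    blobs: BlobSet | list[Blob],
    shape: tuple[int, int],
    core_fraction: float = 0.6,
    expansion_scale: float = 0.3,
    expansion_min_px: int = 2,
    expansion_max_px: int = 5,
) -> BinaryMask:
    """Annular LD-surface mask: each radius is expanded outward by 2-5 px
    (proportional to the radius) and the central disk is removed.

    Per blob the annulus is ``core_fraction*r <= d <= r + e(r)`` with
    ``e(r) = clip(round(expansion_scale * r), expansion_min_px, expansion_max_px)``;
    the result is the union over blobs.
    """
    if not 0 < core_fraction < 1:
        raise ValueError(f"core_fraction must be in (0, 1), got {core_fraction}")
    grid = np.zeros(shape, dtype=bool)
    for b in blobs:
        e = donut_expansion_px(b.radius_px, expansion_scale, expansion_min_px, expansion_max_px)
        rr, cc = _disk_indices(b, shape, core_fraction * b.radius_px, b.radius_px + e)
        grid[rr, cc] = True
    return BinaryMask(grid)


def count_local_maxima(
    channel: np.ndarray,
    roi: CellROI | None = None,
    prominence: float = 1.0,
) -> int:
    """Count local maxima whose topographic prominence exceeds a threshold.

    Prominence is the height of a peak above the highest saddle connecting it
    to a larger peak (the global maximum gets max - min). Computed by a
    union-find sweep over pixels in descending intensity (8-connectivity),
    then peaks are filtered to the ROI cell mask if one is given.
    """
    if prominence <= 0:
        raise ValueError(f"prominence must be > 0, got {prominence}")
    channel = np.asarray(channel, dtype=np.float64)
    peaks = _prominent_peaks(channel, prominence)
    if roi is None:
        return len(peaks)
    return sum(1 for r, c in peaks if roi.cell_mask.grid[r, c])


def _prominent_peaks(channel: np.ndarray, prominence: float) -> list[tuple[int, int]]:
    """Peak locations with prominence strictly above the threshold.

    Classic 0-dimensional persistence: sweep pixels from high to low; a new
    connected component is born at each local max, and when two components
    merge the younger one dies with prominence = birth - saddle level.
    """
    h, w = channel.shape
    flat = channel.ravel()
    order = np.argsort(flat, kind="stable")[::-1]

    parent = np.full(h * w, -1, dtype=np.int64)  # -1 = not yet activated
    birth_level: dict[int, float] = {}
    birth_pixel: dict[int, int] = {}
    out: list[tuple[int, int]] = []

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    neighbor_offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for idx in order:
        level = flat[idx]
        r, c = divmod(int(idx), w)
        roots = set()
        for dr, dc in neighbor_offsets:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w:
                nidx = nr * w + nc
                if parent[nidx] >= 0:
                    roots.add(find(nidx))
        if not roots:
            parent[idx] = idx
            birth_level[int(idx)] = level
            birth_pixel[int(idx)] = int(idx)
            continue
        # attach to the oldest (highest-birth) component; others die here
        keep = max(roots, key=lambda rt: (birth_level[rt], -rt))
        parent[idx] = keep
        for rt in roots:
            if rt == keep:
                continue
            if birth_level[rt] - level > prominence:
                pr, pc = divmod(birth_pixel[rt], w)
                out.append((pr, pc))
            parent[rt] = keep

    global_min = flat.min()
    for rt in {find(i) for i in np.flatnonzero(parent >= 0)}:
        if birth_level[rt] - global_min > prominence:
            pr, pc = divmod(birth_pixel[rt], w)
            out.append((pr, pc))
    return out


def filter_mature_lds(
    blobs: BlobSet,
    ld_channel: np.ndarray,
    marker_channel: np.ndarray,
    patch_halfwidth_scale: float = 1.5,
    patch_halfwidth_min: int = 3,
) -> BlobSet:
    """Keep blobs whose local LD-vs-marker patch correlation is negative.

    For each putative LD, the Pearson correlation between the LD and marker
    channels is computed over a square patch centered at the blob with
    halfwidth ``max(ceil(patch_halfwidth_scale * r), patch_halfwidth_min)``.
    Blobs with correlation >= 0 are rejected (surface-decorated mature LDs
    anticorrelate with their core stain); degenerate constant patches are
    dropped with a warning.
    """
    ld_channel = np.asarray(ld_channel, dtype=np.float64)
    marker_channel = np.asarray(marker_channel, dtype=np.float64)
    if ld_channel.shape != marker_channel.shape:
        raise ValueError("LD and marker channels have different shapes")
    h, w = ld_channel.shape
    kept = []
    for b in blobs:
        hw = max(math.ceil(patch_halfwidth_scale * b.radius_px), patch_halfwidth_min)
        r, c = int(round(b.row)), int(round(b.col))
        r0, r1 = max(r - hw, 0), min(r + hw, h - 1)
        c0, c1 = max(c - hw, 0), min(c + hw, w - 1)
        a = ld_channel[r0 : r1 + 1, c0 : c1 + 1].ravel()
        m = marker_channel[r0 : r1 + 1, c0 : c1 + 1].ravel()
        if a.std() == 0 or m.std() == 0:
            warnings.warn(
                f"filter_mature_lds: constant patch at ({r}, {c}), blob dropped",
                stacklevel=2,
            )
            continue
        corr = float(np.corrcoef(a, m)[0, 1])
        if corr < 0:
            kept.append(b)
    return blobs.replace_blobs(kept)
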