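"""Synthetic multi-channel cell scenes with exhaustive ground truth.

Every downstream stage (detection, enrichment, colocalization, Keima
ratiometry, morphometry) is validated against scenes produced here: disk
shaped LDs with a size distribution, surface-ring vs filled decorator
labeling, partially overlapping lysosome fields, two-compartment Keima
excitation ratios, and Poisson-Gaussian camera noise over a smooth
background.

Determinism: one seed fixes the whole scene. The seed is split into
placement / intensity / noise substreams, so toggling or reseeding the noise
never moves the geometry or the recorded ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.ndimage import gaussian_filter

from .detection import Blob, _disk_indices
from .image_model import BinaryMask, CellROI, MultiChannelImage, write_image, write_mask

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "SceneInfeasibleError",
    "simulate_cell",
    "render_decorator",
    "render_keima",
    "write_scene",
]

CHANNEL_ORDER = ["bodipy", "decorator", "lamp1", "keima_ex488", "keima_ex561"]


class SceneInfeasibleError(RuntimeError):
    """LD packing could not be satisfied within the attempt budget."""


class SceneParams(BaseModel):
    """Full parameterization of one synthetic cell scene."""

    model_config = {"frozen": True}

    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = Field(0.107, gt=0)
    cell_radius_px: float = Field(110.0, gt=0)
    nucleus_radius_px: float = Field(30.0, ge=0)
    n_lds: int = Field(12, ge=0)
    ld_radius_range_px: tuple[float, float] = (4.0, 8.0)
    min_ld_separation_px: float = Field(20.0, ge=0)
    n_nonspecific_spots: int = Field(0, ge=0)

    decorator_mode: Literal["surface_ring", "filled", "absent"] = "surface_ring"
    on_ld_intensity_fraction: float = Field(0.4, ge=0, le=1)
    nonspecific_intensity_fraction: float = Field(0.0, ge=0, le=1)
    ring_inner_fraction: float = Field(0.9, gt=0, lt=1)
    ring_outer_pad_px: float = Field(2.0, ge=0)
    decorator_total_intensity: float = Field(1e6, gt=0)

    lysosome_overlap_fraction: float = Field(0.5, ge=0, le=1)
    n_extra_lysosomes: int = Field(5, ge=0)
    lysosome_peak_intensity: float = Field(500.0, gt=0)

    keima_lyso_ratio: float = Field(3.0, gt=0)
    keima_cyto_ratio: float = Field(0.5, gt=0)
    lyso_pixel_fraction: float = Field(0.3, ge=0, le=1)
    keima488_level: float = Field(100.0, gt=0)

    ld_peak_intensity: float = Field(1000.0, gt=0)
    psf_sigma_px: float = Field(1.0, ge=0)
    background_level: float = Field(0.0, ge=0)
    noise_gaussian_sd: float = Field(0.0, ge=0)
    noise_poisson: bool = False
    seed: int = 0
    noise_seed: int | None = None

    @model_validator(mode="after")
    def _check(self) -> "SceneParams":
        rmin, rmax = self.ld_radius_range_px
        if not 0 < rmin <= rmax:
            raise ValueError("ld_radius_range_px must satisfy 0 < min <= max")
        if self.nucleus_radius_px >= self.cell_radius_px:
            raise ValueError("nucleus must be smaller than the cell")
        if self.on_ld_intensity_fraction + self.nonspecific_intensity_fraction > 1 + 1e-12:
            raise ValueError("on-LD plus nonspecific intensity fractions exceed 1")
        return self


@dataclass(frozen=True)
class SyntheticScene:
    """Rendered channels plus the ground truth needed to grade every stage."""

    image: MultiChannelImage
    roi: CellROI
    true_blobs: tuple[tuple[float, float, float], ...]  # (row, col, radius_px)
    labels: tuple[str, ...]  # 'mature' | 'nonspecific', parallel to true_blobs
    intensity_budget: dict
    true_mean_keima_ratio: float
    lyso_mask: BinaryMask
    reporter_mask: BinaryMask
    clean_channels: dict
    params: SceneParams

    @property
    def mature_blobs(self) -> tuple[tuple[float, float, float], ...]:
        return tuple(b for b, l in zip(self.true_blobs, self.labels) if l == "mature")

    @property
    def nonspecific_blobs(self) -> tuple[tuple[float, float, float], ...]:
        return tuple(b for b, l in zip(self.true_blobs, self.labels) if l == "nonspecific")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _disk_grid(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius + 1e-9


def _place_spots(params: SceneParams, rng: np.random.Generator):
    """Rejection-sample spot centroids/radii inside the cytoplasmic annulus."""
    h, w = params.image_size
    center = (h // 2, w // 2)
    rmin, rmax = params.ld_radius_range_px
    n_total = params.n_lds + params.n_nonspecific_spots
    margin = 3.0  # keep rings / donut analysis masks inside the cell
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 400 * max(n_total, 1) + 400
    while len(placed) < n_total and attempts < max_attempts:
        attempts += 1
        r = float(rng.uniform(rmin, rmax))
        # centers on the integer pixel grid, matching the detector's output grid
        row = float(rng.integers(0, h))
        col = float(rng.integers(0, w))
        d_center = np.hypot(row - center[0], col - center[1])
        if d_center + r + margin > params.cell_radius_px:
            continue
        if d_center < params.nucleus_radius_px + r + 1:
            continue
        if any(
            np.hypot(row - pr, col - pc) < params.min_ld_separation_px
            for pr, pc, _ in placed
        ):
            continue
        placed.append((row, col, r))
    if len(placed) < n_total:
        density = n_total * (params.min_ld_separation_px / 2) ** 2 * np.pi
        avail = np.pi * (params.cell_radius_px**2 - params.nucleus_radius_px**2)
        raise SceneInfeasibleError(
            f"placed only {len(placed)}/{n_total} spots after {attempts} attempts "
            f"(requested packing ~{density / avail:.2f} of the cytoplasmic annulus)"
        )
    return center, tuple(placed)


# ---------------------------------------------------------------------------
# channel renderers (noiseless)
# ---------------------------------------------------------------------------

def _render_bodipy(params: SceneParams, blobs, labels) -> np.ndarray:
    img = np.zeros(params.image_size, dtype=np.float64)
    for (row, col, r), label in zip(blobs, labels):
        amp = params.ld_peak_intensity
        rr, cc = _disk_indices(Blob(row, col, r), params.image_size, 0.0, r)
        img[rr, cc] = amp
    if params.psf_sigma_px > 0:
        img = gaussian_filter(img, params.psf_sigma_px)
    return img


def _decorator_regions(params: SceneParams, blobs, labels, mode: str):
    """Pixel index sets for on-LD paint, nonspecific paint and cytoplasm."""
    shape = params.image_size
    on_grid = np.zeros(shape, dtype=bool)
    ns_grid = np.zeros(shape, dtype=bool)
    spots_grid = np.zeros(shape, dtype=bool)
    for (row, col, r), label in zip(blobs, labels):
        b = Blob(row, col, r)
        rr, cc = _disk_indices(b, shape, 0.0, r)
        spots_grid[rr, cc] = True
        if label == "mature":
            if mode == "surface_ring":
                rr, cc = _disk_indices(
                    b, shape, params.ring_inner_fraction * r, r + params.ring_outer_pad_px
                )
            on_grid[rr, cc] = True
            spots_grid[rr, cc] = True
        else:
            ns_grid[rr, cc] = True
    return on_grid, ns_grid, spots_grid


def _render_decorator_channel(
    params: SceneParams, blobs, labels, roi: CellROI, mode: str, on_fraction: float
) -> tuple[np.ndarray, dict]:
    """Paint the decorator channel and return it with its intensity budget.

    The requested fraction of the channel's total intensity goes on mature
    LDs (ring or filled disk); an optional fraction goes on nonspecific
    spots; the remainder is spread uniformly over the cytoplasm (cell minus
    nucleus minus all painted spot regions). Budgets are exact before noise.
    """
    total = params.decorator_total_intensity
    on_grid, ns_grid, spots_grid = _decorator_regions(params, blobs, labels, mode)
    ns_fraction = params.nonspecific_intensity_fraction if ns_grid.any() else 0.0
    cyto_fraction = 1.0 - on_fraction - ns_fraction

    img = np.zeros(params.image_size, dtype=np.float64)
    n_on = int(on_grid.sum())
    if on_fraction > 0:
        if n_on == 0:
            raise ValueError("on_ld_intensity_fraction > 0 but no mature LD region")
        img[on_grid] = on_fraction * total / n_on
    n_ns = int(ns_grid.sum())
    if ns_fraction > 0:
        img[ns_grid] = ns_fraction * total / n_ns
    cyto_grid = roi.cell_mask.grid & ~roi.nucleus_mask.grid & ~spots_grid
    n_cyto = int(cyto_grid.sum())
    if cyto_fraction > 0:
        if n_cyto == 0:
            raise ValueError("no cytoplasmic pixels to carry off-LD intensity")
        img[cyto_grid] = cyto_fraction * total / n_cyto
    budget = {
        "on_ld": float(img[on_grid].sum()),
        "off_ld": float(img[~on_grid].sum()),
        "total": float(img.sum()),
    }
    return img, budget


def _render_lysosomes(
    params: SceneParams, blobs, labels, roi: CellROI, rng: np.random.Generator
) -> np.ndarray:
    """Lysosome field partially overlapping the LDs plus free puncta."""
    img = np.zeros(params.image_size, dtype=np.float64)
    mature = [(row, col, r) for (row, col, r), l in zip(blobs, labels) if l == "mature"]
    k = int(round(params.lysosome_overlap_fraction * len(mature)))
    chosen = list(rng.choice(len(mature), size=k, replace=False)) if k else []
    for i in sorted(chosen):
        row, col, r = mature[i]
        rr, cc = _disk_indices(Blob(row, col, r), params.image_size, 0.0, r)
        img[rr, cc] = params.lysosome_peak_intensity
    cyto = np.argwhere(roi.cell_mask.grid & ~roi.nucleus_mask.grid)
    for _ in range(params.n_extra_lysosomes):
        row, col = cyto[rng.integers(len(cyto))]
        r = float(rng.uniform(3, 6))
        rr, cc = _disk_indices(Blob(float(row), float(col), r), params.image_size, 0.0, r)
        img[rr, cc] = params.lysosome_peak_intensity
    if params.psf_sigma_px > 0:
        img = gaussian_filter(img, params.psf_sigma_px)
    return img


def _build_lyso_mask(
    params: SceneParams, roi: CellROI, rng: np.random.Generator
) -> BinaryMask:
    """Lysosomal compartment for the Keima channels: small puncta (disks of
    radius 3-6 px) inside the reporter support, trimmed to hit the requested
    pixel fraction exactly."""
    reporter = roi.cell_mask.grid & ~roi.nucleus_mask.grid
    n_reporter = int(reporter.sum())
    target = int(round(params.lyso_pixel_fraction * n_reporter))
    grid = np.zeros(params.image_size, dtype=bool)
    if target == 0:
        return BinaryMask(grid)
    coords = np.argwhere(reporter)
    attempts = 0
    while int(grid.sum()) < target and attempts < 10000:
        attempts += 1
        row, col = coords[rng.integers(len(coords))]
        r = float(rng.uniform(3, 6))
        rr, cc = _disk_indices(Blob(float(row), float(col), r), params.image_size, 0.0, r)
        keep = reporter[rr, cc]
        grid[rr[keep], cc[keep]] = True
    excess = int(grid.sum()) - target
    if excess > 0:
        on = np.flatnonzero(grid.ravel())
        grid.ravel()[on[-excess:]] = False
    return BinaryMask(grid)


def _render_keima_channels(
    params: SceneParams, roi: CellROI, lyso_mask: BinaryMask
) -> tuple[np.ndarray, np.ndarray, float]:
    reporter = roi.cell_mask.grid & ~roi.nucleus_mask.grid
    ex488 = np.zeros(params.image_size, dtype=np.float64)
    ex561 = np.zeros(params.image_size, dtype=np.float64)
    ex488[reporter] = params.keima488_level
    ex561[reporter] = params.keima488_level * params.keima_cyto_ratio
    lyso = lyso_mask.grid & reporter
    ex561[lyso] = params.keima488_level * params.keima_lyso_ratio
    n_rep = int(reporter.sum())
    n_lyso = int(lyso.sum())
    true_mean = (
        n_lyso * params.keima_lyso_ratio + (n_rep - n_lyso) * params.keima_cyto_ratio
    ) / n_rep
    return ex488, ex561, float(true_mean)


def _apply_noise(
    clean: dict[str, np.ndarray], params: SceneParams, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Poisson shot noise on (signal + background), then Gaussian read noise,
    clipped at zero. Channel order is fixed so the stream is reproducible."""
    noisy = {}
    for name in CHANNEL_ORDER:
        if name not in clean:
            continue
        img = clean[name] + params.background_level
        if params.noise_poisson:
            img = rng.poisson(img).astype(np.float64)
        if params.noise_gaussian_sd > 0:
            img = img + rng.normal(0, params.noise_gaussian_sd, size=img.shape)
        noisy[name] = np.clip(img, 0, None)
    return noisy


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_cell(params: SceneParams) -> SyntheticScene:
    """Render one synthetic cell; deterministic given ``params.seed``.

    Ground truth (blob geometry, intensity budgets, compartment ratios) is
    recorded from the noiseless model, before Poisson/Gaussian noise.
    """
    ss = np.random.SeedSequence(params.seed)
    s_place, s_intensity, s_noise = ss.spawn(3)
    place_rng = np.random.default_rng(s_place)
    intensity_rng = np.random.default_rng(s_intensity)
    noise_rng = np.random.default_rng(
        params.noise_seed if params.noise_seed is not None else s_noise
    )

    center, blobs = _place_spots(params, place_rng)
    labels = tuple(
        ["mature"] * params.n_lds + ["nonspecific"] * params.n_nonspecific_spots
    )
    cell_mask = BinaryMask(_disk_grid(params.image_size, center, params.cell_radius_px))
    nucleus_mask = BinaryMask(
        _disk_grid(params.image_size, center, params.nucleus_radius_px)
    )
    roi = CellROI(cell_mask, nucleus_mask, cell_id=f"sim-{params.seed}")

    clean: dict[str, np.ndarray] = {}
    budget: dict[str, dict] = {}
    clean["bodipy"] = _render_bodipy(params, blobs, labels)
    budget["bodipy"] = {"total": float(clean["bodipy"].sum())}
    if params.decorator_mode != "absent":
        clean["decorator"], budget["decorator"] = _render_decorator_channel(
            params, blobs, labels, roi, params.decorator_mode,
            params.on_ld_intensity_fraction,
        )
    clean["lamp1"] = _render_lysosomes(params, blobs, labels, roi, intensity_rng)
    lyso_mask = _build_lyso_mask(params, roi, intensity_rng)
    ex488, ex561, true_mean = _render_keima_channels(params, roi, lyso_mask)
    clean["keima_ex488"] = ex488
    clean["keima_ex561"] = ex561

    noisy = _apply_noise(clean, params, noise_rng)
    image = MultiChannelImage(channels=noisy, pixel_size_um=params.pixel_size_um)
    reporter_mask = BinaryMask(cell_mask.grid & ~nucleus_mask.grid)
    return SyntheticScene(
        image=image,
        roi=roi,
        true_blobs=blobs,
        labels=labels,
        intensity_budget=budget,
        true_mean_keima_ratio=true_mean,
        lyso_mask=lyso_mask,
        reporter_mask=reporter_mask,
        clean_channels=clean,
        params=params,
    )


def render_decorator(
    scene: SyntheticScene,
    mode: str | None = None,
    on_fraction: float | None = None,
) -> np.ndarray:
    """Re-render the (noiseless) decorator channel of an existing scene,
    optionally overriding the labeling mode or the on-LD intensity fraction."""
    mode = mode if mode is not None else scene.params.decorator_mode
    if mode not in {"surface_ring", "filled"}:
        raise ValueError(f"invalid decorator mode {mode!r}")
    on_fraction = (
        on_fraction if on_fraction is not None else scene.params.on_ld_intensity_fraction
    )
    if not 0 <= on_fraction <= 1:
        raise ValueError(f"on_fraction must be in [0, 1], got {on_fraction}")
    channel, _ = _render_decorator_channel(
        scene.params, scene.true_blobs, scene.labels, scene.roi, mode, on_fraction
    )
    return channel


def render_keima(scene: SyntheticScene) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless dual-excitation Keima channels of an existing scene."""
    ex488, ex561, _ = _render_keima_channels(scene.params, scene.roi, scene.lyso_mask)
    return ex488, ex561


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

def write_scene(scene: SyntheticScene, outdir: str | Path, scene_id: str) -> dict:
    """Write a scene as plain files: multi-page TIFF, mask TIFFs, ground-truth
    CSVs and the resolved parameters as JSON. Returns the path manifest."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = [n for n in CHANNEL_ORDER if n in scene.image.channels]
    paths = {
        "image": outdir / f"{scene_id}.tif",
        "cell_mask": outdir / f"{scene_id}_cell_mask.tif",
        "nucleus_mask": outdir / f"{scene_id}_nucleus_mask.tif",
        "blobs": outdir / f"{scene_id}_blobs.csv",
        "budget": outdir / f"{scene_id}_budget.csv",
        "keima_truth": outdir / f"{scene_id}_keima_truth.csv",
        "params": outdir / f"{scene_id}_params.json",
    }
    write_image(scene.image, paths["image"], channel_order=names)
    write_mask(scene.roi.cell_mask, paths["cell_mask"])
    write_mask(scene.roi.nucleus_mask, paths["nucleus_mask"])
    pd.DataFrame(
        [
            {"scene_id": scene_id, "row": r, "col": c, "radius_px": rad, "label": lab}
            for (r, c, rad), lab in zip(scene.true_blobs, scene.labels)
        ]
    ).to_csv(paths["blobs"], index=False)
    pd.DataFrame(
        [
            {"scene_id": scene_id, "channel": ch, **vals}
            for ch, vals in scene.intensity_budget.items()
        ]
    ).to_csv(paths["budget"], index=False)
    pd.DataFrame(
        [
            {
                "scene_id": scene_id,
                "true_mean_keima_ratio": scene.true_mean_keima_ratio,
                "lyso_area_px": scene.lyso_mask.area(),
                "reporter_area_px": scene.reporter_mask.area(),
            }
        ]
    ).to_csv(paths["keima_truth"], index=False)
    paths["params"].write_text(json.dumps(scene.params.model_dump(), indent=2))
    return {k: str(v) for k, v in paths.items()}
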