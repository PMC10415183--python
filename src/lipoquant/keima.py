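"""Dual-excitation Keima ratiometry for lipophagy flux.

The reporter mask is the union of per-channel Otsu masks on the two
excitation channels; per-pixel 561/488 ratios are summarized over that mask
and normalized to a control condition's group mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .image_model import BinaryMask, mask_union, otsu_mask

__all__ = [
    "KeimaResult",
    "keima_reporter_mask",
    "keima_ratio",
    "normalize_to_control",
]


@dataclass(frozen=True)
class KeimaResult:
    """Per-cell Keima ratiometry summary.

    ``mean_ratio`` is the mean over the reporter mask of the per-pixel
    ex561/ex488 ratio (the headline value, matching ratio-image
    construction); ``total_ratio`` is the ratio of channel sums over the
    same pixels.
    """

    cell_id: str
    condition: str = ""
    reporter_mask_area_px: int = 0
    n_excluded_pixels: int = 0
    mean_ratio: float = float("nan")
    total_ratio: float = float("nan")
    normalized_ratio: float = float("nan")
    qc_flags: tuple[str, ...] = ()


def keima_reporter_mask(
    ex488: np.ndarray,
    ex561: np.ndarray,
) -> tuple[BinaryMask, tuple[str, ...]]:
    """Union of Otsu masks on the two excitation channels.

    Returns the mask plus QC flags ('empty_mask' when both channels are
    degenerate and nothing is selected).
    """
    ex488 = np.asarray(ex488, dtype=np.float64)
    ex561 = np.asarray(ex561, dtype=np.float64)
    if ex488.shape != ex561.shape:
        raise ValueError("excitation channels have different shapes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = mask_union(otsu_mask(ex488), otsu_mask(ex561))
    flags: tuple[str, ...] = ()
    if mask.area() == 0:
        warnings.warn("keima_reporter_mask: empty reporter mask", stacklevel=2)
        flags = ("empty_mask",)
    return mask, flags


def keima_ratio(
    ex488: np.ndarray,
    ex561: np.ndarray,
    mask: BinaryMask,
    cell_id: str = "cell",
    condition: str = "",
    eps: float = 1e-9,
    cell_mask: BinaryMask | None = None,
    cleaved_mask_fraction_threshold: float = 0.9,
) -> KeimaResult:
    """Per-pixel 561/488 ratio summary over the reporter mask.

    Pixels with ex488 <= ``eps`` are excluded from the per-pixel ratio (a
    pseudocount would bias dim cells) and counted in ``n_excluded_pixels``.
    If a ``cell_mask`` is supplied and the reporter mask covers more of the
    cell than ``cleaved_mask_fraction_threshold``, the
    ``cleaved_reporter_suspected`` QC flag is raised — flagged, never
    silently dropped.
    """
    ex488 = np.asarray(ex488, dtype=np.float64)
    ex561 = np.asarray(ex561, dtype=np.float64)
    if ex488.shape != ex561.shape or ex488.shape != mask.shape:
        raise ValueError("channel/mask shapes differ")
    flags: list[str] = []
    area = mask.area()
    if area == 0:
        warnings.warn(f"keima_ratio: empty mask for cell {cell_id!r}", stacklevel=2)
        return KeimaResult(cell_id, condition, 0, 0, qc_flags=("empty_mask",))

    if cell_mask is not None and cell_mask.area() > 0:
        frac = (mask.grid & cell_mask.grid).sum() / cell_mask.area()
        if frac > cleaved_mask_fraction_threshold:
            flags.append("cleaved_reporter_suspected")

    valid = mask.grid & (ex488 > eps)
    n_excluded = area - int(valid.sum())
    if not valid.any():
        warnings.warn(
            f"keima_ratio: all pixels excluded for cell {cell_id!r}", stacklevel=2
        )
        return KeimaResult(
            cell_id, condition, area, n_excluded, qc_flags=tuple(flags + ["all_excluded"])
        )
    ratios = ex561[valid] / ex488[valid]
    mean_ratio = float(ratios.mean())
    sum488 = float(ex488[valid].sum())
    total_ratio = float(ex561[valid].sum() / sum488) if sum488 > 0 else float("nan")
    return KeimaResult(
        cell_id,
        condition,
        reporter_mask_area_px=area,
        n_excluded_pixels=n_excluded,
        mean_ratio=mean_ratio,
        total_ratio=total_ratio,
        qc_flags=tuple(flags),
    )


def normalize_to_control(
    results: list[KeimaResult],
    control_condition: str,
) -> list[KeimaResult]:
    """Divide every mean_ratio by the control group's mean of mean_ratio.

    By construction the control group's normalized mean equals 1. Raises if
    the control group is empty or its mean is zero/undefined.
    """
    control = [
        r.mean_ratio
        for r in results
        if r.condition == control_condition and math.isfinite(r.mean_ratio)
    ]
    if not control:
        raise ValueError(f"no usable results in control condition {control_condition!r}")
    control_mean = float(np.mean(control))
    if control_mean == 0:
        raise ValueError("control group mean ratio is zero")
    return [replace(r, normalized_ratio=r.mean_ratio / control_mean) for r in results]
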