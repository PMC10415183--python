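"""Batch orchestration: manifest in, per-cell metric tables out.

Stages are toggleable; per-image failures are logged and skipped so one bad
field of view never kills a batch. Identical config + inputs produce
byte-identical CSV outputs, and every output row carries the config hash.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_laplace

from . import keima as keima_mod
from .config import RunConfig
from .detection import BlobSet, detect_lds_log, filter_mature_lds, surface_donut_mask, count_local_maxima
from .image_model import CellROI, read_image, read_mask, subtract_background
from .quantify import (
    enrichment_mean,
    enrichment_sum,
    ld_area_fraction,
    ld_density_per_area,
    masked_pearson,
    peripheral_mask,
)

logger = logging.getLogger("lipoquant")

__all__ = ["PipelineResult", "run_pipeline", "summarize_condition"]


@dataclass
class PipelineResult:
    per_cell: pd.DataFrame
    keima: pd.DataFrame
    blobs: pd.DataFrame
    summary: pd.DataFrame
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _log_response_at(channel: np.ndarray, blobs: BlobSet, radius_factor: float) -> list[float]:
    """Scale-normalized LoG response sampled at each detection, for audit."""
    peak = channel.max()
    if peak <= 0 or not len(blobs):
        return [float("nan")] * len(blobs)
    norm = channel / peak
    out = []
    cache: dict[float, np.ndarray] = {}
    for b in blobs:
        sigma = b.radius_px / radius_factor
        if sigma not in cache:
            cache[sigma] = -(sigma**2) * gaussian_laplace(norm, sigma)
        r = int(round(b.row))
        c = int(round(b.col))
        out.append(float(cache[sigma][r, c]))
    return out


def _process_row(row: pd.Series, config: RunConfig, image_id: str) -> dict:
    image = read_image(
        row["image_path"], config.channels, pixel_size_um=float(row["pixel_size_um"])
    )
    roi = CellROI(
        read_mask(row["cell_roi_path"]),
        read_mask(row["nucleus_roi_path"]),
        cell_id=image_id,
    )
    channels = dict(image.channels)
    if config.background_subtract:
        channels = {
            name: subtract_background(ch, config.ball_radius_px)
            for name, ch in channels.items()
        }

    metrics: dict = {
        "image_id": image_id,
        "cell_id": image_id,
        "condition": row["condition"],
        "pixel_size_um": float(row["pixel_size_um"]),
    }
    blob_rows: list[dict] = []
    keima_result = None

    blobs = BlobSet((), config.ld_channel, {})
    if config.stages.detect:
        ld = channels[config.ld_channel]
        blobs = detect_lds_log(
            ld, roi, config.detection.to_detection_config(), config.ld_channel
        )
        kept = blobs
        if config.marker_channel is not None:
            kept = filter_mature_lds(blobs, ld, channels[config.marker_channel])
        kept_keys = {(b.row, b.col) for b in kept}
        responses = _log_response_at(ld, blobs, config.detection.radius_factor)
        for b, resp in zip(blobs, responses):
            blob_rows.append(
                {
                    "image_id": image_id,
                    "cell_id": image_id,
                    "row": b.row,
                    "col": b.col,
                    "radius_px": b.radius_px,
                    "log_response": resp,
                    "kept_after_filter": (b.row, b.col) in kept_keys,
                }
            )
        blobs = kept
        metrics["ld_count"] = len(blobs)

    if config.stages.enrich and config.decorator_channel is not None:
        deco = channels[config.decorator_channel]
        es = enrichment_sum(deco, blobs, roi, cell_id=image_id)
        metrics["enrichment_sum"] = es.enrichment_sum
        donut = surface_donut_mask(
            blobs,
            image.shape,
            core_fraction=config.core_fraction,
            expansion_scale=config.expansion_scale,
            expansion_min_px=config.expansion_min_px,
            expansion_max_px=config.expansion_max_px,
        )
        em = enrichment_mean(deco, donut, roi, cell_id=image_id)
        metrics["enrichment_mean"] = em.enrichment_mean

    if config.stages.coloc:
        peri = peripheral_mask(roi, config.dilation_px)
        for a, b in config.pearson_pairs:
            if peri.area() < 2:
                metrics[f"pearson_peripheral_{a}_{b}"] = float("nan")
                continue
            res = masked_pearson(
                channels[a], channels[b], peri, cell_id=image_id,
                region="peripheral", channel_pair=(a, b),
            )
            metrics[f"pearson_peripheral_{a}_{b}"] = res.pearson_r

    if (
        config.stages.keima
        and config.keima488_channel is not None
        and config.keima488_channel in channels
        and config.keima561_channel in channels
    ):
        ex488 = channels[config.keima488_channel]
        ex561 = channels[config.keima561_channel]
        mask, flags = keima_mod.keima_reporter_mask(ex488, ex561)
        keima_result = keima_mod.keima_ratio(
            ex488,
            ex561,
            mask,
            cell_id=image_id,
            condition=str(row["condition"]),
            eps=config.keima_eps,
            cell_mask=roi.cell_mask,
        )

    if config.stages.morpho:
        morpho = ld_area_fraction(
            channels[config.ld_channel], roi, cell_id=image_id,
            otsu_scope=config.otsu_scope,
        )
        metrics["ld_area_fraction"] = morpho.area_fraction
        if config.find_maxima_prominence is not None:
            count = count_local_maxima(
                channels[config.ld_channel], roi, config.find_maxima_prominence
            )
            metrics["ld_count"] = count
        if "ld_count" in metrics:
            metrics["density_per_um2"] = ld_density_per_area(
                metrics["ld_count"], image.shape, float(row["pixel_size_um"])
            )

    return {"metrics": metrics, "blob_rows": blob_rows, "keima": keima_result}


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> PipelineResult:
    """Execute the configured stages over every manifest row and write the
    report bundle (CSV tables, run log, resolved config) to the output dir."""
    manifest = config.validate_inputs()  # aborts before processing on bad config
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    per_cell_rows: list[dict] = []
    blob_rows: list[dict] = []
    keima_results: list = []
    failures: list[tuple[str, str]] = []
    log_lines: list[str] = []

    for idx, row in manifest.iterrows():
        image_id = Path(str(row["image_path"])).stem
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = _process_row(row, config, image_id)
            for w in caught:
                log_lines.append(f"WARN {image_id}: {w.message}")
        except Exception as exc:  # pragma: no cover - exercised via bad input tests
            failures.append((image_id, str(exc)))
            log_lines.append(f"FAIL {image_id}: {exc}")
            logger.error("image %s failed: %s", image_id, exc)
            continue
        per_cell_rows.append(result["metrics"])
        blob_rows.extend(result["blob_rows"])
        if result["keima"] is not None:
            keima_results.append(result["keima"])
        log_lines.append(f"OK   {image_id}")

    if keima_results and config.control_condition is not None:
        try:
            keima_results = keima_mod.normalize_to_control(
                keima_results, config.control_condition
            )
        except ValueError as exc:
            log_lines.append(f"WARN keima normalization skipped: {exc}")

    per_cell = pd.DataFrame(per_cell_rows)
    blobs_df = pd.DataFrame(
        blob_rows,
        columns=[
            "image_id", "cell_id", "row", "col", "radius_px",
            "log_response", "kept_after_filter",
        ],
    )
    keima_df = pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "condition": r.condition,
                "mask_area_px": r.reporter_mask_area_px,
                "n_excluded_pixels": r.n_excluded_pixels,
                "mean_ratio": r.mean_ratio,
                "total_ratio": r.total_ratio,
                "normalized_ratio": r.normalized_ratio,
                "qc_flags": ";".join(r.qc_flags),
            }
            for r in keima_results
        ],
        columns=[
            "cell_id", "condition", "mask_area_px", "n_excluded_pixels",
            "mean_ratio", "total_ratio", "normalized_ratio", "qc_flags",
        ],
    )
    summary = summarize_condition(per_cell) if len(per_cell) else pd.DataFrame(
        columns=["condition", "metric", "n", "mean", "sd"]
    )
    for df in (per_cell, blobs_df, keima_df, summary):
        df["config_hash"] = cfg_hash

    per_cell.to_csv(outdir / "per_cell_metrics.csv", index=False)
    keima_df.to_csv(outdir / "keima_metrics.csv", index=False)
    blobs_df.to_csv(outdir / "blobs.csv", index=False)
    summary.to_csv(outdir / "condition_summary.csv", index=False)
    (outdir / "resolved_config.json").write_text(
        json.dumps({"config_hash": cfg_hash, **config.model_dump()}, indent=2, default=str)
    )
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(per_cell, keima_df, blobs_df, summary, failures)


def summarize_condition(
    per_cell: pd.DataFrame,
    group_col: str = "condition",
    metric_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per (condition, metric): n, mean, sample s.d. (n-1 denominator).

    Groups of size one report the s.d. as missing.
    """
    if metric_cols is None:
        skip = {group_col, "image_id", "cell_id", "config_hash", "pixel_size_um"}
        metric_cols = [
            c
            for c in per_cell.columns
            if c not in skip and pd.api.types.is_numeric_dtype(per_cell[c])
        ]
    rows = []
    for cond, grp in per_cell.groupby(group_col, sort=True):
        for metric in metric_cols:
            vals = grp[metric].dropna().to_numpy(dtype=float)
            n = len(vals)
            rows.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "n": n,
                    "mean": float(np.mean(vals)) if n else float("nan"),
                    "sd": float(np.std(vals, ddof=1)) if n > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["condition", "metric", "n", "mean", "sd"])
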