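"""Run configuration: validated, hashable, written verbatim into outputs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .detection import DetectionConfig

__all__ = ["StageToggles", "RunConfig", "load_run_config"]

MANIFEST_COLUMNS = [
    "image_path",
    "cell_roi_path",
    "nucleus_roi_path",
    "condition",
    "pixel_size_um",
]


class StageToggles(BaseModel):
    detect: bool = True
    enrich: bool = True
    coloc: bool = True
    keima: bool = True
    morpho: bool = True


class DetectionSettings(BaseModel):
    min_sigma_px: float = 1.5
    max_sigma_px: float = 8.0
    num_sigma: int = 10
    log_threshold: float = 0.05
    overlap_max: float = 0.5
    radius_factor: float = 2.0**0.5

    def to_detection_config(self) -> DetectionConfig:
        return DetectionConfig(**self.model_dump())


class RunConfig(BaseModel):
    """Everything needed for a reproducible end-to-end run."""

    manifest: str
    channels: list[str]
    output_dir: str = "lipoquant_out"

    ld_channel: str = "bodipy"
    decorator_channel: str | None = "decorator"
    marker_channel: str | None = None  # enables the mature-LD filter
    keima488_channel: str | None = "keima_ex488"
    keima561_channel: str | None = "keima_ex561"
    pearson_pairs: list[tuple[str, str]] = Field(default_factory=list)

    background_subtract: bool = True
    ball_radius_px: int = Field(50, ge=1)
    detection: DetectionSettings = Field(default_factory=DetectionSettings)
    dilation_px: float = Field(160.0, ge=0)
    core_fraction: float = Field(0.6, gt=0, lt=1)
    expansion_scale: float = Field(0.3, gt=0)
    expansion_min_px: int = Field(2, ge=0)
    expansion_max_px: int = Field(5, ge=0)
    otsu_scope: str = "cell"
    find_maxima_prominence: float | None = None  # None: count detected blobs
    keima_eps: float = Field(1e-9, ge=0)
    control_condition: str | None = None
    stages: StageToggles = Field(default_factory=StageToggles)
    seed: int = 0

    def config_hash(self) -> str:
        # analysis parameters only: where outputs land must not change the hash
        payload = self.model_dump()
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def load_manifest(self) -> pd.DataFrame:
        path = Path(self.manifest)
        if not path.exists():
            raise FileNotFoundError(f"manifest not found: {path}")
        df = pd.read_csv(path)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest is missing columns: {missing}")
        return df

    def validate_inputs(self) -> pd.DataFrame:
        """Fail before any processing if a referenced file is missing."""
        df = self.load_manifest()
        for col in ("image_path", "cell_roi_path", "nucleus_roi_path"):
            for p in df[col].dropna():
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")
        if (df["pixel_size_um"] <= 0).any():
            raise ValueError("manifest contains non-positive pixel sizes")
        return df


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML/JSON run config; keyword overrides win over file values."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
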