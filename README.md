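# lipoquant

Quantification pipeline for lipid-droplet (LD) biology in multi-channel
fluorescence microscopy:

- **LD detection** as scale-space blobs (Laplacian of Gaussian), with filled
  LD masks, annular "donut" surface masks, and prominence-based local-maxima
  counting;
- **enrichment at LDs** — sum-based (fraction of a protein channel's total
  intensity inside detected LD radii) and mean-based (mean inside an LD mask
  over the whole-cell mean);
- **masked Pearson colocalization**, including cell-periphery masks (cell
  mask minus the nucleus dilated by a configurable radius);
- **dual-excitation Keima ratiometry** for lipophagy flux (Otsu reporter
  mask union, per-pixel 561/488 ratios, control-condition normalization, QC
  flags);
- **Otsu morphometry** (LD area per cell area) and LD density per physical
  area;
- a **"true mature LD" filter** for tissue images: putative LDs are kept
  only when the LD-core stain anticorrelates with a surface-decorating
  marker in a local patch;
- a **synthetic microscopy generator** producing multi-channel cell scenes
  with exhaustive ground truth (blob geometry, per-region intensity budgets,
  true compartment ratios), which drives the entire test suite — no raw
  imaging data is required.

## CLI

```bash
# render 4 synthetic scenes (TIFFs + masks + ground-truth CSVs + manifest)
lipoquant simulate --out scenes/ --n-scenes 4 --seed 0

# full pipeline: per-cell metrics, Keima table, blobs table, condition summary
lipoquant run --config run.yaml --out results/

# single stages
lipoquant detect  --config run.yaml
lipoquant enrich  --config run.yaml
lipoquant coloc   --config run.yaml
lipoquant keima   --config run.yaml
lipoquant morpho  --config run.yaml

# aggregate an existing per-cell table to mean +/- s.d. per condition
lipoquant summarize --metrics results/per_cell_metrics.csv --out summary.csv
```

A minimal `run.yaml`:

```yaml
manifest: scenes/manifest.csv          # image_path, cell_roi_path,
                                       # nucleus_roi_path, condition, pixel_size_um
channels: [bodipy, decorator, lamp1, keima_ex488, keima_ex561]
output_dir: results
ld_channel: bodipy
decorator_channel: decorator
pearson_pairs: [[lamp1, bodipy]]
control_condition: ctrl
dilation_px: 160
background_subtract: true
```

Every output row carries the hash of the resolved configuration, which is
also written verbatim to `resolved_config.json`; identical config + inputs
produce byte-identical CSVs.

## Package layout

| module | contents |
| --- | --- |
| `lipoquant.image_model` | `MultiChannelImage`, `BinaryMask`, `CellROI`, TIFF/PNG/polygon-CSV I/O, background subtraction, Otsu, mask algebra |
| `lipoquant.synthetic` | `SceneParams`, `simulate_cell`, decorator/Keima renderers, scene fixtures on disk |
| `lipoquant.detection` | LoG blob detection, LD/donut masks, prominence peak counting, mature-LD filter |
| `lipoquant.quantify` | enrichment, masked Pearson, peripheral mask, area fraction, density |
| `lipoquant.keima` | reporter mask, 561/488 ratios, control normalization |
| `lipoquant.config` / `lipoquant.pipeline` / `lipoquant.cli` | validated run config, batch orchestration, CLI |
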