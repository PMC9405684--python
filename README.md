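# vasculomorph

Quantification of vascular angioarchitecture in 2D fluorescence microscopy
images: vessel-network metrics, local fractal dimension (LFD) complexity
analysis, semi-automated artery tracing, topology-preserving skeletonization
with branch/tortuosity measurement, collateral-vessel analysis, and the
group-comparison statistics used to contrast age/sex cohorts — plus synthetic
vascular generators with exact analytic ground truth so every stage is
testable without any external data.

## Modules

| Module | What it does |
| --- | --- |
| `imaging_io` | Raster/ZStack/ROI/mask types; max projection, polygon ROI extraction, auto contrast, sharpening, morphological haze reduction, Otsu/fixed binarization; TIFF/PNG and ImageJ `.roi` readers |
| `network_metrics` | Frangi-based vessel segmentation; vessel density, junction density, total/average vessel length over an ROI |
| `fractal` | Box-counting dimension, sliding-window LFD maps, LFD histograms and their four summary features (skewness, excess kurtosis, peak frequency, max LFD) |
| `tracing` | Live-wire style tracing: Hessian-ridge/intensity cost image, Dijkstra shortest paths between seed points, snapping, smoothing/subsampling, stroke rasterization |
| `skeleton` | Lee thinning, endpoint/junction/slab tagging, branch-graph construction with junction clustering, step-sum branch length, Euclidean distance, tortuosity T = length/chord, summaries, ROI-scoped collateral reports |
| `synthetic` | Bifurcating vessel trees, grid (anastomotic) networks, fractal fixtures and imaging noise — each with exact ground truth (counts, polylines, tortuosity, stroke mask) |
| `stats_report` | One-way ANOVA + Tukey HSD, two-way ANOVA (Type II/III) + Sidak within-group sex comparisons, covariance ellipses, advisory normality tests |
| `pipeline` | End-to-end orchestration from a single YAML config with per-stage intermediates and a checksummed manifest |

## CLI

```bash
# synthesize a calibrated tree image with ground truth
vasculomorph simulate tree --depth 3 --seed 42 -o tree.tif --truth truth.json

# prepare a raw image (projection, ROI, contrast, sharpening, haze removal)
vasculomorph prepare in.tif --roi roi.json --haze-radius 20 -o prepared.tif

# AngioTool-style whole-field metrics
vasculomorph metrics prepared.tif --roi roi.json -o metrics.csv

# local fractal dimension map + histogram + features
vasculomorph fractal mask.tif --window 128 --stride 64 -o lfd.csv

# seed-point batch tracing (JSON {branch_id: [[x, y], ...]})
vasculomorph trace prepared.tif --seeds seeds.json --gamma 0.7 --scale 2 -o tracing.json

# skeletonize a binary mask and quantify branches
vasculomorph skeleton mask.tif --detailed -o summary.csv

# group statistics from a tidy CSV (sample_id, age_bin, sex, metric, value)
vasculomorph compare metrics.csv --metric vessel_density_percent --design two-way -o result.json

# full pipeline from a config
vasculomorph run config.yaml
```

A minimal pipeline config:

```yaml
output_dir: out
seed: 42
simulate: {kind: tree, depth: 2, noise_sigma: 5.0, background_level: 12.0}
segment: {scales: [1.0, 2.0, 3.0], min_object_px: 30}
fractal: {window: 128, stride: 64, min_foreground: 50}
```

## Conventions

- Coordinates are 0-based, x right / y down, pixel centers on integers.
- Foreground connectivity is 8-connected throughout; branch length uses the
  step-sum convention (1 px orthogonal, sqrt(2) px diagonal, scaled by the
  pixel size in um). Note this convention overestimates the Euclidean length
  of oblique straight lines by up to ~8% — the synthetic ground truth
  exposes both the geometric and the step-sum (chamfer) length.
- Tortuosity T = branch path length / Euclidean distance between branch
  extremes; T = 1 for straight vessels, undefined for closed cycles.
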