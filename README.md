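# astromorph

Sholl-based morphometry and median-stratified profiling of GFAP-labeled
astrocytes in 2D micrographs, with a synthetic-phantom module providing
exact ground truth for every stage.

The pipeline covers:

- **Synthetic data** (`astromorph.phantoms`): star-shaped single-astrocyte
  phantoms (disc soma + straight/bifurcating arms) and multi-cell field
  images, drawn directly as rasters with exact-by-construction truth
  (soma area, primary/terminal counts, maximal reach, planted cell counts);
  metric-vector cohorts generated around the six reference profile centers.
- **Segmentation** (`astromorph.segmentation`): Otsu/fixed thresholding,
  optional watershed splitting, center-component cell selection,
  orientation-constrained gap closing (no branches added de novo),
  opening-based soma/process separation, and field-based cell counting with
  per-case cumulative summaries.
- **Sholl engine** (`astromorph.sholl`): topology-preserving
  skeletonization with endpoint/branch-point/soma-attachment
  classification; concentric supercover rings at a fixed radial increment
  (default 10 px); per-ring intersection counts in two modes — `pixel`
  (pixel-level crossings, the default) and `run` (classical crossing
  components).
- **Morphometrics** (`astromorph.morphometrics`): the six descriptors —
  maximum process length (µm, from the soma outline), total intersections,
  terminal-to-primary branch ratio, soma size (µm²), length-to-soma ratio
  (µm⁻¹), estimated circular territory size (µm², from the soma center).
- **Profiling** (`astromorph.profiling`): pooled global medians/IQRs,
  above/below binarization (ties → below), signature-table lookup to
  profiles 1–6 with a rank-based disambiguator for the shared 4/6 pattern;
  unmatched patterns stay `unclassified`.
- **Statistics** (`astromorph.stats`): tie-corrected Kruskal–Wallis
  (exact permutation p for pooled n ≤ 10, chi-square otherwise), two-stage
  adaptive (BKY) FDR step-up, targeted post hoc design against the profile
  whose median is closest to the global median, median/IQR summaries.
- **Pipeline + CLI** (`astromorph.pipeline`, `astromorph.cli`): ROI
  extraction (300×300 → 4× nearest-neighbor upsampling with calibration
  compensation), manifest-driven batch runs with deterministic outputs and
  logged per-cell exclusions.

Coordinates are (row, col), 0-based, origin top-left. Default calibration
is 0.25 µm/px (configurable; required input in practice).

## CLI

```sh
# synthesize a demo study (single-cell + field TIFFs, truth JSONs, manifest)
astromorph simulate --out-dir demo --seed 1 --n-cells 12 --n-field-cases 3

# full pipeline: metrics, profiles, medians, density counts, statistics
astromorph run-all --manifest demo/manifest.csv --out-dir demo_out

# per-stage tools
astromorph segment --image demo/cell_000.tif --out-dir seg_out
astromorph sholl   --image demo/cell_000.tif --out-dir sholl_out --overlay
astromorph metrics --image demo/cell_000.tif
astromorph profile --metrics-csv demo_out/metrics.csv --out-dir prof_out
astromorph stats   --metrics-csv demo_out/metrics.csv
```

`run-all` writes `metrics.csv`, `profiles.csv`, `medians.json`,
`density.csv`, `stats.json`, `exclusions.csv` and `run_log.txt`; identical
config + inputs produce byte-identical CSVs.

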