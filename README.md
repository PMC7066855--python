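# spheroplane

Quantitative evaluation of spheroid microarrays deposited in agar receiver
blocks: 3D segmentation of spheroids from confocal-style z-stacks, planarity
statistics based on the least-squares centroid plane, per-well/row/column
capture-success statistics across plates, and a LOESS trend surface for
non-planar deposition patterns. A synthetic-scene module generates
ground-truth phantoms (ellipsoidal spheroids on an 8×12 grid, tilted/bowed
centroid planes, depth-dependent attenuation, Bernoulli capture failures) so
the entire pipeline is testable without real imaging data.

## What it computes

- **Segmentation** — global Otsu (or fixed) threshold, 26-connected 3D
  labeling, minimum-volume debris filter, 6-connected surface extraction,
  unweighted volume centroids in physical μm, mean radius r̄ (mean
  surface-to-centroid distance), nearest-node well assignment.
- **Planarity** — ordinary least-squares plane `z = p0 + px·x + py·y`
  through all centroids; per-spheroid distance `d` to that plane
  (perpendicular by default, vertical as an option) normalized by r̄;
  mean/median/max summary plus mean ± SD (n−1) aggregation across samples.
- **Capture statistics** — per-well mean success across plates, grand
  mean ± SD of per-plate fractions, and two-sided one-sample t-tests of each
  row/column against the grand mean (default sample unit: per-plate
  row/column means; α = 0.01, strict `p < α`).
- **Trend surface** — locally weighted polynomial regression (tricube
  weights, span 0.5, degree 2 by default) of centroid z on (x, y) with R²
  evaluated at the observed centroids.

## CLI

All stages are subcommands of `spheroplane` (config in YAML; every value in
μm; stacks are multi-page TIFFs in (z, y, x) order; plate maps are CSVs with
row labels A–H and columns 1–12):

```sh
# generate a ground-truth scene, rendered stack, and plate-map series
spheroplane simulate -c config.yaml -o sim/

# full analysis: segment -> planarity -> capture -> trend
spheroplane analyze --stack sim/stack.tif \
    --plates sim/plate_1.csv --plates sim/plate_2.csv \
    -c config.yaml -o results/

# or stage by stage
spheroplane segment --stack sim/stack.tif -c config.yaml -o seg/
spheroplane planarity --spheroids seg/spheroids.csv -o out/
spheroplane capture sim/plate_*.csv -o out/
spheroplane trend --spheroids seg/spheroids.csv -o out/ --plot
```

Example config:

```yaml
scene:
  grid_rows: 8
  grid_cols: 12
  pitch: 3800        # μm center-to-center
  mean_diameter: 500 # μm
  plane_p0: 900
  plane_px: -0.001
  plane_py: -0.005
  z_noise_sd: 30
  capture_prob: 0.8
imaging:
  voxel_xy: 40          # 10 μm matches the tests but needs ~16× the memory
  section_thickness: 30
  field_x: 48000        # large enough to hold the 8×12 grid at 3800 μm pitch
  field_y: 32000
  field_z: 1500
n_plates: 6
seed: 1
```

Exit codes: 0 success, 2 invalid configuration, 3 stage failure. Logs go to
stderr; data only to files (CSV/JSON/TIFF, with units in column headers).

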