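# imcfiber

Quantitative analysis of imaging mass cytometry (IMC) pseudoimages of
skeletal muscle sections.

IMC ablates a stained tissue section spot by spot and reads out, per
~1 µm² pixel, the ion counts of every metal-conjugated antibody in the
panel — up to dozens of markers on a single section. In dystrophic muscle
(e.g. Becker muscular dystrophy) this makes it possible to follow, on one
slide, how fibers are lost and replaced by fibrotic and adipose stroma:
collagens and fibroblast markers expand, capillaries and satellite cells
disappear, M2 macrophages infiltrate, and profibrotic cytokines accumulate.

`imcfiber` turns multi-channel 16-bit pseudoimage stacks plus ROI polygons
into tidy, testable numbers:

- **ROI metrics** per marker: positive fraction
  (100 · |{p ∈ ROI : v(p) ≥ t}| / |ROI|), mean intensity over the ROI, and
  mean intensity of the positive pixels, with per-sample/per-marker raw
  count thresholds (manual or reproducible automatic Otsu/quantile).
- **Fiber segmentation** from the laminin channel (smooth → threshold →
  connected interiors → watershed), the stroma mask as the exact ROI
  complement of the fibers, and per-fiber cross-sectional areas (CSA) with
  per-marker positive-area fractions.
- **Fiber positivity rules**: a fiber is called marker-positive when the
  marker covers ≥ 10% of its area (≥ 5% for CTGF), giving the percentages
  of MYH3+, CD56+, MYH3−CD56+, CTGF+, PDGFA+ and TGFβ+ fibers.
- **Object counting**: nucleus-gated, size-gated cells (CD56 satellite
  cells, CD68/CD206 macrophages with the M2 = CD206+ split), capillaries
  vs larger vessels from CD31, densities per mm², nearest-vessel
  distances.
- **Statistics**: Shapiro–Wilk checks, unpaired t-tests (α = 0.05),
  two-sample Kolmogorov–Smirnov comparison of CSA distributions, and
  Spearman rank correlations over a declared family of sample-level
  quantities with Bonferroni correction (p_adj = min(1, m·p)); at cohort
  scale (n ≤ 12) Spearman p-values are permutation-based rather than the
  t-approximation.
- **A synthetic muscle-section generator** with complete ground truth
  (fiber label map, true stroma fraction, every planted cell/vessel/fat
  vacuole, per-channel true masks) and five stage presets — control, mild,
  moderate, advanced-fibrosis, advanced-fat — so every pipeline stage has
  a recoverable target.

## Worked example

Run the full workflow on a synthetic cohort (two samples per stage,
400 × 400 µm frames):

```python
from imcfiber.pipeline import RunConfig, run_full

cfg = RunConfig(output_dir="results/demo", seed=1, n_per_group=2, frame=(400, 400))
res = run_full(cfg)
order = ["control", "mild", "moderate", "advanced_fibrosis", "advanced_fat"]
print(res["sample_summary"].groupby("group", sort=False)[
    ["stroma_pct", "capillary_density_mm2", "n_satellite_cells", "n_m2"]
].mean().loc[order].round(2))
```

prints

```
                   stroma_pct  capillary_density_mm2  n_satellite_cells  n_m2
group
control                 15.51                 375.00               25.0   2.0
mild                    23.08                 284.38               17.5   6.0
moderate                34.11                 187.50               12.0  12.0
advanced_fibrosis       49.90                 112.50                7.0  20.0
advanced_fat            52.66                  62.50                5.0  26.0
```

i.e. the measured stroma fraction rises and capillary density and
satellite-cell counts fall monotonically with disease stage, while M2
macrophages accumulate — the qualitative structure the generator planted,
recovered by segmentation and counting alone. The same run reports the
CSA distribution contrast (`res["ks"]` → D = 0.194, p = 5.5e-04, control
vs dystrophic fibers) and the corrected correlation family, e.g. stroma %
vs capillary density r = −0.99, p_adj = 0.002 (exact/MC permutation p,
m = 10 pairs). Outputs land in `results/demo/` as CSVs
(`roi_metrics.csv`, `fibers.csv`, `objects.csv`, `sample_summary.csv`,
`csa_summary.csv`, `correlations.csv`, `region_comparison.csv`) plus
`run_log.txt`.

The same workflow is available from a shell:

```bash
imcfiber synth --stage moderate --frame 400 --out synthetic/   # stacks + ground truth
imcfiber run-all --config run.yaml --seed 1                    # full pipeline
imcfiber quantify --config run.yaml                            # ROI metrics only
imcfiber compare-regions --config run.yaml                     # fibrotic vs non-fibrotic
```

For real acquisitions, point the config at exported multi-page OME-TIFF
stacks, a panel CSV (marker_name, metal_tag, channel_index, target_class;
the packaged default transcribes a 17-channel muscle panel), and QuPath
GeoJSON ROI exports (`mode: files`).

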