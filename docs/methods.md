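# Methods

## Data model and conventions

An IMC pseudoimage is an H×W×C stack of non-negative integer ion counts at
1 pixel = 1 µm², one channel per metal-conjugated antibody, exported as a
multi-page 16-bit TIFF. Values pass through unchanged — no rescaling,
spillover compensation or hot-pixel correction — on the assumption that the
export step preserves raw dual counts. A panel CSV binds page indices to
marker names and biological target classes; it must contain exactly one
nuclei entry and unique, contiguous channel indices. The packaged default
panel transcribes a 17-channel muscle panel (ECM: collagens I/III/VI, TE7;
fiber markers: laminin, MYH3; cells: CD56, CD68, CD206; vessels: CD31,
αSMA; cytokines: TGFβ, CTGF, PDGF-AA; PDGFRα; perilipin; iridium nuclei).

ROIs are simple polygons in pixel coordinates (x = column, y = row,
0-based). Rasterization uses pixel-center containment: pixel (r, c) is in
the ROI iff the polygon covers the point (c + 0.5, r + 0.5), **boundary
inclusive**. The convention is arbitrary but fixed and testable: the
rasterizer is property-tested against an independent point-in-polygon
oracle, and the rasterized area of any rectangle of area A differs from A
by at most its perimeter. Holes are supported as interior rings;
multi-part features are split. Edge exclusion is the annotator's
responsibility; `erode_margin` offers an N-µm morphological margin for
synthetic runs.

## ROI metrics

Positivity is inclusive: a pixel is positive when value ≥ threshold, so
t = 0 marks everything — the intuitive degenerate case. Thresholds are raw
counts per (sample, marker), carried with their provenance (`manual` or
`auto`); automatic options are two-class Otsu restricted to ROI pixels
(falling back to max+1 on constant planes) and an upper quantile. Per
(ROI, marker) we report ROI area, positive fraction (percent), mean
intensity over all ROI pixels, and mean intensity over positive pixels —
reported as *missing*, never zero, when nothing is positive. Object
densities are counts per mm² (ROI area / 10⁶).

The stroma compartment is defined geometrically, not by ECM staining:
stroma = ROI ∖ fiber labels, so stroma and fibers partition the ROI
exactly and "stroma %" + "fiber %" = 100 by construction. ECM markers are
then quantified within that stroma mask for the stroma-only analyses.

## Fiber segmentation

The original workflow used an external deep-learning model on the laminin
channel; this package substitutes a deterministic classical pipeline with
the same downstream contract (a label map):

1. Gaussian smooth the laminin channel, `smooth_sigma_um` (default 1 µm).
2. Boundary mask = smoothed laminin ≥ threshold (default: Otsu within the
   ROI).
3. Candidate interiors = 4-connected components of ROI ∖ boundary.
4. Watershed on the smoothed laminin landscape assigns any non-boundary
   pixels left over; the boundary itself stays stroma.
5. Gates: area < `min_fiber_area_um2` (100) or > `max_fiber_area_um2`
   (20 000) dropped; optionally drop fibers touching the ROI border.
   Labels are canonicalized 1..n in raster order, so identical inputs give
   identical label maps.

CSA convention: the reported fiber area is the area *inside* the
basal-lamina ring — the laminin wall is not split between adjacent fibers.
(`assign_boundary=True` restores wall absorption for sensitivity checks.)
On the 16-fiber calibration lattice (40 µm fibers, 3 µm walls, Poisson
noise) this recovers all fibers at IoU > 0.99 with mean CSA within 1% of
the planted 1600 µm².

Laminin alone cannot distinguish a fiber interior from a laminin-free
stroma patch — both are low-signal regions bounded by laminin. Two
defenses: the `max_fiber_area_um2` gate removes implausibly large
candidates, and the pipeline optionally (default on) reclassifies
candidates whose interior is more than 50% ECM-positive
(collagen I/III/VI, TE7) back into stroma. `exclude_border` defaults to
False because in whole-frame analyses every peripheral fiber touches the
ROI edge, and discarding them would corrupt the partition-based stroma %.

## Cells, vessels, fiber positivity

Cells are 4-connected components of a thresholded cell-marker channel with
25 ≤ area ≤ 500 µm² that overlap the thresholded nuclei channel in ≥ 1
pixel; oversized components are logged as diffuse signal. CD31 components
are capillaries in 10–300 µm² and large vessels above; smaller specks are
noise. A CD68 cell is M2 when it overlaps the CD206 mask (the CD206+ count
proper is reported separately). These gates are declared substitutes for
the original semi-automatic, human-reviewed counting — the original
bounds were never published. Nearest-vessel distances are centroid to
centroid (Euclidean, µm).

A fiber is positive for a marker when the marker's thresholded pixels
cover at least 10% of the fiber's area (5% for CTGF, which is read with a
more permissive rule); the comparison is inclusive ("at least"), and the
fraction is a thresholded-pixel area fraction, not an intensity fraction.
The same threshold set serves ROI metrics and fiber scoring. CSA summaries
report the arithmetic mean and the sample (n−1) SD, a relative-frequency
histogram (default 250 µm² bins) and a binning-free ECDF over pooled
per-group CSAs.

## Statistics

- Shapiro–Wilk normality check (n ≥ 3; constant vectors are rejected as
  degenerate).
- Two-sided unpaired t-tests, Welch by default with a pooled-variance
  option; significance at p ≤ 0.05.
- Two-sample KS with the asymptotic p for CSA distribution contrasts.
- Spearman rank correlation (midranks for ties) over a user-declared
  family of quantity pairs; Bonferroni p_adj = min(1, m·p) with m = the
  number of declared pairs, recorded in every row.

Spearman p-values at cohort scale are permutation-based: full enumeration
(exact) for n ≤ 8; for 8 < n ≤ 12 a seeded Monte-Carlo permutation p with
the add-one estimator, p = (1 + #{|r*| ≥ |r|}) / (1 + B), B = 4999. The
add-one estimator satisfies P(p ≤ α) ≤ α for any B, so Bonferroni
family-wise error control is exact by construction. The t-approximation is
used only for n > 12: at n = 10 it is anti-conservative in the far tail
(measured null FWER 0.081 at m = 20 vs the nominal 0.05; the permutation p
brings it to ≈ 0.04–0.05).

## Synthetic sections

The generator emulates a transverse muscle section; it is the ground-truth
supply for every recovery test, not a biophysical simulation.

- **Geometry.** Fiber profiles are Voronoi cells of a jittered hexagonal
  lattice. The pitch is solved in closed form from the target mean CSA: a
  hexagon of area A eroded by half the wall width w/2 has
  √area ≈ √A − 0.93·w, so pitch = √(A_cell / (√3/2)) with
  A_cell = (√A_fiber + 0.93 w)². Fiber-to-fiber size spread comes from the
  lattice jitter (0.5·σ·pitch), approximating the right-skewed CSA spread
  via the lognormal parameters (median, σ); the realized distribution is
  not exactly lognormal, but the interior-fiber mean converges to the
  lognormal target mean (verified within 10% on an 800 µm frame, and
  within 0.5% in practice). Frame-truncated edge fibers are recorded but
  excluded from the CSA target list, as in standard CSA practice.
- **Stroma.** A smoothed-noise field thresholded at the `stroma_fraction`
  quantile yields endomysial/perimysial patches; the realized (recorded)
  true stroma fraction additionally includes the 3 µm laminin wall
  network, so it exceeds the parameter by roughly the wall fraction.
- **Channels.** Laminin paints a shell around every fiber. ECM and
  cytokine stage trends are *coverage* fractions of the stroma at a fixed
  signal amplitude — positive-area trends, matching the %-area readout —
  not intensity ramps, which keeps every painted signal far above the
  Poisson background. Fiber-level positivity plants whole-fiber marker
  fills on stage-dependent fractions of fibers (MYH3+ fibers mostly
  co-express CD56). Capillaries are CD31 disks (r = 3 µm) with ≥ 10 µm
  separation; one large vessel (r = 13 µm, αSMA ring); fat vacuoles are
  perilipin annuli placed perivascularly; cells are 3–4 µm-radius disks
  with 2 µm nucleus dots, placed near capillaries with probability
  `cell_near_vessel_prob` (0.8 in the control preset, 0.3 in dystrophic
  presets) else uniformly in stroma, plus 60 marker-negative nuclei.
- **Noise.** Per-channel expected counts = background (0.2) + signal
  (120–150) × mask; the emitted image is a Poisson draw clipped to 16 bit.
  Ion counts are Poisson by physics; no Gaussian camera noise is added.
- **Presets.** Five stages with monotone trends (patch coverage
  0.03/0.12/0.25/0.42/0.46; capillaries 60/45/30/18/10; satellite cells
  25/18/12/7/4; M2 2/6/12/20/26; fat foci 0/1/2/3/14). Magnitudes are the
  generator's own choices — only the direction of each trend is modelled.
  Cohorts derive per-sample seeds from one base seed.
- **Sub-ROIs.** Fibrotic-focus and non-fibrotic windows are chosen from
  ground truth as the stroma-richest and stroma-poorest non-overlapping
  squares, standing in for the annotator's manual selection.

What the generator does **not** emulate: ablation artifacts (line streaks,
drift), isotope spillover, antibody-specific background, partial-volume
mixing at object borders, nucleus instance shapes, or serial sections.
Passing recovery tests therefore demonstrates the correctness of the
measurement pipeline on well-posed inputs, not robustness to every real
acquisition artifact.

## Problem sizes

Default analyses use 400 × 400 µm frames (≈ 50–70 fibers per section) and
two samples per stage — the cohort shape of a small biopsy study. The
calibration lattice is 4 × 4 fibers of 40 µm with 20 planted cells and 20
capillaries. The null-calibration study uses 1000 replicates of n = 10
samples × 20 independent pairs.

## Known limitations

- The classical fiber segmentation needs a contiguous laminin boundary;
  heavily degraded or gappy laminin merges fibers (no learned shape
  prior).
- Cell counting is projection-based: overlapping same-marker cells within
  10 µm merge into one component.
- The ECM-exclusion step assumes fibers are not collagen-filled; fibrotic
  fiber ghosts would be reclassified as stroma.
- Exact Spearman enumeration is O(n!) and capped at n = 8; the MC regime
  trades a little power (conservative add-one p) for validity.
- The threshold comparator (≥ vs >) is a convention; results shift by the
  mass of pixels exactly at threshold.
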