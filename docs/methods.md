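# Methods

## Scope and data model

`epifluid` analyses segmented, tracked 2D label rasters of an epithelium on
a cartographic map projection: one integer raster per time frame, label 0
for background (including the closing window), identical labels denoting
the same cell across frames, and a physical pixel size in µm.  An optional
per-pixel metric field describes the distortion of the projection; recoil
tracks enter separately as CSV tables.  The package does not segment,
track or register images — those are upstream concerns — and it does not
simulate tissue mechanics; it measures state from geometry.

## Cell geometry from label rasters

Cell outlines are extracted as **crack boundaries**: the polygon follows
the pixel edges between a label and its surroundings, so its shoelace area
equals the pixel count exactly and round-trips are unambiguous (0-based
pixel indices, x = column, y = row, vertices scaled to µm).  The raw crack
boundary overestimates the perimeter of any non-axis-aligned edge (the
staircase effect, up to ~27 % for straight edges and +22 % for the shape
index of rasterized hexagons at 18 px spacing).  Two corrections are
available:

* **Douglas–Peucker simplification** (default, tolerance 1.4 px): collapses
  the 1-px staircase back onto straight segments.  On hexagonal reference
  lattices (side ≈ 10 px) the shape index lands within 0.33 % of the
  closed-form 3.7224, which is why this is the default for Voronoi-like
  (polygonal) cells.  The tolerance must exceed the maximal staircase
  deviation (~0.7 px) and stay below real boundary features; 1.4 px was
  measured once on the hexagonal construction and frozen.
* **Gaussian vertex smoothing** (optional, off by default): appropriate for
  genuinely curved boundaries, but on polygonal cells it rounds corners and
  biases p low (−1.3 % at σ = 1 px, −3.4 % at σ = 2 px on the same
  lattices), so it is not part of the default path.

Labels with fewer than 4 px are skipped as degenerate; a label split into
several 4-connected parts contributes its largest part (common for strongly
wiggled synthetic boundaries, logged).  Cells occupying any outer-border
pixel are flagged `touches_border` and excluded from all statistics by
default, because a cell cut by the map edge has no meaningful geometry.

**Adjacency**: two cells are neighbors if they share at least
`min_contact_px = 2` four-connected pixel faces; corner-only contact never
counts, and the 2-px floor suppresses spurious single-pixel contacts.  On
synthetic Voronoi tissues the resulting graph agrees with the Delaunay
triangulation of the seeds for >90 % of interior cells; the residual
disagreements are facets shorter than the pixel size, which no raster
convention can resolve.

## Map-projection correction

The metric is **diagonal**: per pixel, physical µm per map px along the two
axes, `(s_u, s_v)`.  This is exact for equirectangular/cylindrical
projections (sphere: `s_u = R·cos(lat)·Δlon`, `s_v = R·Δlat`; prolate
spheroid in reduced latitude β: `s_u = a·cosβ·Δλ`,
`s_v = √(a²sin²β + c²cos²β)·Δβ`); full 2×2 metrics are out of scope.
Areas are integrated pixel-wise with **exact partial-pixel coverage**
(polygon ∩ pixel clipping via shapely), which removes resolution-dependent
area bias; polyline lengths subdivide segments to ≤ 1 px and scale each by
the local metric.  Sanity anchors: the full sphere map integrates to 4πR²
(midpoint rule, ≲0.01 % at 192 rows), a cap above 30° latitude to ¼ of the
surface, and a flat metric reproduces Euclidean measures exactly.  When a
coverage fraction of the whole surface is reported, grid latitudes are best
chosen so region boundaries fall on row edges (the examples use 192 rows so
30° is a row edge); otherwise the half-row quantization (~1 % at 128 rows)
dominates the error.

## Shape index, elongation, alignment and fluidity

* `p = P/√A`, dimensionless and scale-invariant; the isoperimetric
  inequality bounds it below by 2√π ≈ 3.545 for exact polygons
  (raster-derived polygons respect the bound within 0.01 after staircase
  removal).
* **Cell elongation** is the log-aspect `½·ln(λ₁/λ₂)` of the polygon's
  area-normalized second central moment (gyration) tensor, computed in
  closed form from the shoelace moments — rotation-invariant, zero for any
  ≥3-fold-symmetric shape, and exactly `ln k` for a k:1 rectangle.  The
  anisotropy estimator for cells is a package choice; published analyses
  show cell anisotropy without fixing a formula.
* **Triangle elongation q**: for each triangle of the center mesh, the
  2×2 linear map S from a unit-area reference equilateral triangle
  (centroids aligned) to the observed triangle is solved exactly, and
  `q = ½·ln(σ₁/σ₂)` from its singular values, computed with the
  cancellation-free closed form (σ₁ = Q₁+Q₂, σ₂ = |Q₁−Q₂|); this agrees
  with a brute-force SVD oracle to 10⁻¹³ and is invariant to rotation,
  translation, uniform scaling and vertex order.
* **Center mesh**: triangles are the 3-cliques of the adjacency graph;
  where k ≥ 4 cells meet around one junction (a k-clique), a deterministic
  fan of k−2 triangles is emitted with apex at the lowest cell id and the
  rest ordered by angle — reproducibility is the only requirement there.
* **Alignment Q** of a cell averages q over its incident triangles with
  triangle-area weights.  Two modes ship because the literature's
  "weighted average" is ambiguous: `scalar` (default; mean of magnitudes)
  and `tensor` (mean of the traceless elongation tensors, whose magnitude
  is ≤ the scalar mean — opposing axes cancel).  Only immediately incident
  triangles are used; a larger neighborhood would smooth Q but the default
  keeps it local.
* **Thresholds**: `p_adj = p₀ + 4·b·Q²` with `p₀ = 3.94`, `b = 0.43`
  (anisotropy-adjusted mode, default), or the fixed isotropic critical
  value `3.81`.  **Fluidity** `f = p − p_adj`; cells with `|f| ≤ ε`
  (`ε = 0.02`, display choice — "near the transition" is not quantified in
  the source analyses) are labeled `transition`, above `fluid`, below
  `solid`.  Classification is monotone in p at fixed Q by construction.

## Dynamics

A **T1 event** between consecutive frames is a quartet (A, B | C, D): the
A–B contact exists at t and not at t+1, the C–D contact appears at t+1, and
C, D were common neighbors of A and B at t.  The common-neighbor condition
and the exclusion of cells that appear/disappear between frames suppress
segmentation flicker.  **Rim cells** share at least one pixel edge with the
window — the background component containing a user-supplied seed point
(robust to unrelated background at map edges); an **eviction** is a cell
that leaves the rim set while remaining in the tissue.  **Cable metrics**
integrate intensity over a fixed band of half-width 2 px around the cable
polyline (the sampling width is a package default, recorded in the run
manifest) and divide by the metric-corrected length.  A greedy
nearest-centroid **label linker** (max displacement gate, fresh ids for
unmatched cells, deterministic closest-first matching) is provided for
untracked input; synthetic data is tracked by construction and does not use
it.

## Recoil rheology

Each cut yields 1–3 tracks of the two severed edge positions.  The
**initial recoil velocity** is the total distance moved by both edges
between the first two post-cut frames divided by the inter-frame time
(interpreting the conventional "divide by frame rate" phrasing as division
by the frame interval, which the units require), averaged over tracks.
The **power law** `D·(t − t₀)^α` is fitted to the track-averaged edge
separation by least squares in log–log space over the first 10 s
post-ablation: deterministic, with an exact noiseless oracle (a noiseless
power law is recovered to 10⁻⁹), and α is clipped to [0, 1] with a logged
flag.  *Displacement* is the default fitted quantity: a displacement
exponent lives naturally in [0, 1] with α→0 elastic and α→1 viscous,
whereas a decaying velocity would have a negative exponent; a `velocity`
mode (finite-difference) is provided, and every fit records which quantity
was used.  Qualitative reading: α < 1/3 solid-like, α > 2/3 fluid-like.
Recoil statistics across different ablation hardware are not comparable;
traces carry a `setup_tag` for that reason.

## Statistics

Two-sided Wilcoxon rank-sum (exact null distribution for n ≤ 25 without
ties — verified against exhaustive permutation enumeration — otherwise the
tie-corrected normal approximation) and Welch's unpaired t test; per-group
Shapiro–Wilk normality screening is reported alongside.  Significance
bands: `***` p < 0.001, `**` p < 0.01, `*` p ≤ 0.05, else `ns`.  The
conventional printed coding leaves (0.009, 0.01) unassigned; `**` extends
to p < 0.01 for continuity, and p = 0.01 maps to `*`.  The sd uses the n−1
denominator; a single observation reports sd 0 with a degenerate-sample
flag.  No multiple-testing correction is applied.

## Synthetic tissues: what they emulate and what they do not

Tissues are Voronoi tessellations of seeded random points on the pixel
grid.  The knobs map onto the features the analysis is sensitive to:

* `lloyd_iterations` — hexagonal order; mean p falls monotonically with
  relaxation (≈4.08 unrelaxed → ≈3.78 at 20 iterations for ~350 px²
  cells), emulating ordered versus disordered packing.
* `stretch_field` — a position-dependent 2×2 tensor applied to the
  assignment metric; coherent stretch raises cell elongation, triangle q
  and alignment Q together.  Note that affine stretch alone does *not*
  create fluid classifications: p and p_adj rise together — that is the
  anisotropy correction working as intended.
* `wiggle_amp` / `wiggle_scale` — a smooth random warp of the tessellation
  (displacement field, Gaussian correlation length in px) that wiggles
  interfaces, raising perimeter and p while leaving cell centers (hence Q)
  nearly unchanged: the planted signature of fluid-like irregular cells.
  Default fluid-band fixture: amplitude 3.5 px, correlation 4 px, in a
  central band of half-width 40 px over a bulk relaxed for 8 iterations —
  chosen to produce a clearly bimodal tissue (band p ≈ 4.7, bulk ≈ 3.8).
* A **closing window** is a background disk with a monotone non-increasing
  radius schedule.  The tessellation is static between frames (labels are
  tracked trivially); seeds are rejected from the initial disk, which makes
  every cell's region reach outside it, so rim sets are nested as the
  window shrinks and rim counts are monotone non-increasing to zero by
  construction, not by luck of the seed.
* **Planted T1s** relabel the contact strip between the losing pair to the
  two gaining common neighbors (validated against the evolving tissue;
  edits persist).  **Planted evictions** relabel a rim cell's window-facing
  pixels to its nearest neighbors, exactly as a cell leaving the leading
  edge while staying in the tissue.  The generator's ground-truth sidecar
  also records the rim exits the shrinking window itself produces, computed
  from its own window masks.
* **Recoil traces** sample `D·(t−t₀)^α` plus i.i.d. Gaussian noise, split
  symmetrically over the two edges.  The standard simulation (D = 2 µm/s^α,
  σ = 0.1 µm, 0.5 s sampling over 10 s) matches the regime where a
  log–log fit is appropriate.

What the generator does **not** emulate: photorealistic image texture or
segmentation errors (cells are exact partitions), cell motion between
frames (real tissues flow; the linker is therefore tested on shifted
frames, not on the generator), curvature-induced distortion of the
tessellation itself, and any force-based mechanics — planted events are
kinematic.  Passing tests therefore demonstrate that the *measurement
chain* is correct on data with the assumed statistical structure, not that
a real tissue satisfies those assumptions.

## Determinism and numerical choices

One seeded `numpy` generator per stochastic call; identical parameters and
seed give bit-identical rasters and traces, and a pipeline rerun from the
same manifest reproduces its CSVs exactly.  Tie-breaks are fixed
(triangle fans from the lowest id, closest-first greedy matching,
event ordering by lost-pair ids).  Degenerate inputs error early with the
offending frame/cell named (collinear triangles, zero-area polygons,
windows larger than the domain, planted events referencing missing or
non-rim cells).  Default problem sizes — ~140–160 cells on 220² px, ten
frames per closure, 100 replicate recoil traces — are the package's demo
scale; every routine is linear or near-linear in pixels and cells and has
been run at several times that size.

## Known limitations

* The diagonal metric cannot represent shear distortion of arbitrary
  projections; measurements on such maps need a resampling step first.
* Perimeter (hence p) of raster cells is estimator-dependent at the
  1 % level; the frozen simplification default targets polygonal cells,
  and strongly curved real cell boundaries would warrant the Gaussian
  mode with a re-measured bias.
* The scalar-vs-tensor Q ambiguity is unresolved upstream; both modes are
  reported, and the adjusted-threshold constants are applied as published,
  not re-derived.
* Eviction detection is purely geometric (rim-set exit); it cannot
  distinguish a biological eviction from a segmentation artifact that
  detaches a cell from the window for one frame.
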