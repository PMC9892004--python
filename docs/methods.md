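# Methods

This note records the models behind each metric, the estimator
definitions, the parameters that matter (units and defaults), what the
synthetic generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Conventions

All volumes are indexed (z, y, x), 0-based, with voxel sizes
(dz, dy, dx) in µm; index (0, 0, 0) is the first voxel and physical
coordinates refer to voxel centres.  A 2D image is a stack with z-extent
1.  Every metric works in physical units, so strongly anisotropic confocal
geometries (10 µm z-steps over sub-micron pixels) are handled uniformly
and the main source of anisotropy bugs — mixing pixel and µm reporting —
is removed at the type level.

## Binarization

The default is Otsu's threshold computed per z-slice per channel, with a
global-scope and a fixed-threshold mode for reproducibility; a voxel is
foreground iff its intensity strictly exceeds the threshold.  A
constant-intensity slice cannot be split by Otsu: it is marked background
with a warning rather than failing the stack.  The thresholding protocol
of interactive tools is typically unstated; the per-slice Otsu default is
declared here as the algorithmic equivalent, not inferred from any
particular tool.

## Sub-pixel contours and the perimeter estimator

Perimeters come from marching-squares contours, not boundary-pixel
counting (pixel counting biases circularity upward).  The raw 0.5 level
set of a *binary* field still carries a staircase bias — it overestimates
a rasterized disc's circumference by ~5%, which would push a perfect
disc's circularity to ~1.10.  `extract_contour` therefore mollifies the
binary field with a small Gaussian (default sigma: one pixel) before
taking the level set.  Measured accuracy: disc perimeter +0.6%, square
−0.4%, 30°-rotated thin rectangle −0.9%; disc circularity 1.010.  The
cost is a curvature shrinkage of order (sigma/r)² and corner rounding; for
shapes dominated by thin protrusions pass `smooth_um` of about half a
pixel (the protrusive-footprint tests use this), and for convergence
studies across resolutions hold `smooth_um` fixed in physical units.
Contours are closed, counter-clockwise, in µm; holes are filled before
contour extraction, and masks smaller than 2×2 px are rejected as
degenerate.

## Doublet contact angle

The model treats each cell of a doublet as a circular arc meeting the
other at a common chord (the lens geometry).  The estimator:

1. **Interface.**  Interface pixels are boundary pixels of either label
   within one pixel (8-connectivity) of the other label.  The two contact
   points are the extremal interface pixels, refined to sub-pixel by
   averaging the nearest vertices of the two cells' contours.  Labels that
   never touch give a "no contact" result (chord length 0), not an error.
2. **Free contours.**  Each cell's contour minus points adjacent to the
   other cell and minus a window of 3 pixels around either contact point,
   keeping interface curvature out of the circle fit.
3. **Circle fit.**  Algebraic (Kåsa) least squares per cell; collinear
   degenerate contours raise a fit error.
4. **Angle.**  With s_i the signed distance from fitted centre i to the
   chord line (positive on cell i's own side, as determined by the cell's
   mask centroid) and r̂_i the fitted radius:
   alpha_i = arccos(s_i / r̂_i); theta_pair = alpha_1 + alpha_2.
   A centre on the far side of the chord (s_i < 0) gives alpha_i > 90°,
   handling partial engulfment; |s_i| > r̂_i is reported as a geometry
   inconsistency.  The intersection angle of the two fitted circles is
   attached as a diagnostic; the signed-distance value is normative.

The reported theta_pair is the **full (two-sided) opening angle**: 0° for
a tangent pair, 120° for equal 50 µm cells at 50 µm separation
(2·arccos(d/2r)), approaching 180° toward complete merging.  Any
comparison against half-opening-angle conventions must divide by two.

Doublets are analyzed on 2D max projections, matching the standard
confocal figure pipeline; no 3D contact-surface reconstruction is
attempted.  Measured accuracy on rendered doublets (0.4 µm pixels): worst
error 0.05° over d/r ∈ [0.2, 1.8], 0.6° on a strongly asymmetric
engulfment fixture.

## Interface enrichment

The membrane band is the set of pixels within band_width/2 of the cell's
boundary (default band_width: 3 px); the interface band is its subset
within interface_dilation (default 2 px) of the other cell.  Distances
come from Euclidean distance transforms with the half-pixel correction —
the true boundary lies half a pixel before the first opposite-phase pixel
centre, so EDT distances are shifted by dy/2 (without this, band-edge
pixels drop out on exact ties and the estimator loses up to 20% of the
interface signal).  The mean intensity of pixels far (> 2·band_width)
from every cell is subtracted before summing (`subtract_background`,
default on): noise floors otherwise inflate the band total and bias f
toward the band-area ratio.  f is clipped to [0, 1]; a band with zero
total signal is an error.  Measured recovery at 5% noise: within 0.026
across f ∈ {0, 0.25, 0.5, 0.75, 1}.

## Spreading kinetics

A = b·t^alpha with alpha = 1/4 by default (the established spreading law
for cells on adhesive surfaces; b in µm²·min^−alpha).  The fixed-exponent
fit is through-origin least squares in closed form,
b = Σ A_i t_i^(1/4) / Σ t_i^(1/2) — through the origin because A(0) = 0
physically; an intercept variant is not fitted, and t = 0 or A = 0 frames
are excluded (and counted) from the log–log free-exponent fit.  Multiple
footprint components are unioned (cells can fragment at threshold), with
the component count recorded.  Roundness, used for 2D-layering assays, is
4πA/p² per the common imaging-software convention — the reciprocal of
circularity.

## Radial sorting

The cluster COM is the unweighted mean physical position of the union of
channel-foreground voxels.  g_c(r_k) is, per radial bin of width
bin_width (default: max(dz, dy, dx)), the fraction of union voxels
belonging to channel c — "normalizing to the density of pixels within the
cluster" read as a per-bin occupancy, which is bounded, shell-volume-free
and scale-stable.  A raw per-channel histogram normalization is available
(`normalization="count"`).  Voxels claimed by several independently
binarized channels count for each; the overlap fraction is logged as QC.
Zero-union bins are flagged invalid and excluded.

The score S = rbar(x) − rbar(y) subtracts the channels' g-COMs; with
x = BFP-like and y = mCherry-like roles, large S means the mCherry-like
channel is central.  **Weighting choice (important):** the g-COM can
weight bins by g alone or by g times the union count.  Bin-only weighting
gives a bin holding three voxels the same influence as one holding
thousands; for clusters of a few dozen cells the innermost and outermost
bins are exactly such bins, and the mixed-configuration score then swings
by 10–20 µm between seeds.  The package therefore defaults to
count-weighting (`weighting="count"`, equivalent to the voxel-weighted
mean channel radius), which is stable at desk scale; `weighting="g"` is
retained for large, densely sampled clusters.  On the solid core–shell
phantom (core 20 µm / shell 40 µm, voxels 10×0.6×0.6 µm) the defaults
give S = 17.95 µm against the 20 µm equal-bin continuous limit; the
difference is the r²-volume weighting of voxels within each region.
The score is computed once per 3D stack (per-slice binarization feeding a
single 3D distance computation), and S is exactly antisymmetric under
channel swap.

The centroid-level exclusion distance uses the mean position of **all**
cells as the assembly centre, then compares two groups' mean Euclidean
distances; positive difference = first group excluded.

## Contact graphs and probability tables

The contact criterion is a declared rule, recorded on the graph: fixed
threshold tau, or radius-scaled k·(rho_i + rho_j) with default k = 1.1
when radii exist; both inclusive at the boundary.  Probabilities are
normalized globally over unordered type pairs (homotypic contacts counted
once), so the table entries form one distribution summing to 1;
row-normalization (conditional contact distribution per type) is behind a
flag.  Whether interactive software counts contacts per cell or per pair
is generally unknowable; per-unordered-pair is normative here.

## Synthetic generator

The generator emulates, with exact truth:

* **Doublets** — two overlapping circles split at the radical chord;
  cytosolic channels per cell plus a membrane channel painted as a band
  (width 1.6 µm) on the designated cell's boundary.  Interface enrichment
  is set exactly by scaling the chord-band intensity; the "uniform" mode
  fixes f at chord/(chord + free arc) — 0.2926 for the symmetric
  half-overlap doublet.  Truth records angles, chord, f, and per-cell
  masks.  Intensities before noise: background 0, cytosol 100, membrane
  200; Gaussian noise is a fraction of the channel's foreground level,
  clipped at 0.
* **Spreading series** — per timepoint, the exact-area footprint of
  A = b·t^alpha as a disc (expansive) or as a "fried egg" (protrusive): a
  core disc holding 70% of A plus n thin radial rays holding 30%, ray
  inner edges on the core chord so the union is simply connected and its
  area exactly A.  The 70/30 split is a declared fixture property (the
  real morphology is only qualitative); perimeter and circularity truth
  are closed-form, cross-checked by a shoelace oracle on the explicit
  polygon.
* **3D assemblies** — non-overlapping spheres (seeded rejection sampling,
  minimum centre distance 2·cell_radius, 10⁴-attempt budget) in mixed,
  core–shell (channel A centres within half the assembly radius) or
  bilobed configurations, voxelized at (10, 0.6, 0.6) µm by default.
  Defaults — cell radius 6 µm, assembly radius 60 µm, 20 cells per
  channel — model a small aggregate of ~12 µm cells.  A continuous solid
  core–shell phantom (no individual cells) provides the geometry oracle.
  Placement is static: no adhesion dynamics, no Potts/vertex simulation.
* **Contact patterns** — alternating A/B chains, bridging A-B-C-B chains
  (A never adjacent to C), and a 3-coloured triangular lattice for cyclic
  patterns (every unit triangle carries all three types); truth tables are
  enumerated from the jitter-free adjacencies, and jitter is bounded below
  spacing/2 so adjacency stays valid.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: optical blur and the microscope PSF, uneven
illumination, z-dependent attenuation, cell shape irregularity, touching
cells requiring nontrivial segmentation, partial voxel intensities, or
sorting dynamics.  Estimator accuracies quoted here are upper bounds for
idealized geometry plus Gaussian noise.

## Problem sizes

Test and acceptance runs use: doublets at 0.4 µm pixels (canvas ~500×260
px), five d/r ratios; 24-frame spreading series at 0.25 µm pixels
(protrusive checks at 0.125 µm); assemblies of 40 spheres on a
12×200×200-voxel grid, ten seeds per configuration; patterns of 2–24
cells; 1 500 points per group for the exclusion oracle.  The full suite
runs in a few seconds.

## Known limitations

* The contact-angle model assumes circular-arc cell outlines; strongly
  non-circular cells violate the fit (the free-contour window and the
  circle-fit residual are the diagnostics to watch).
* Radial statistics cannot distinguish bilobed from mixed configurations
  (both are radially near-symmetric); detecting bilobed architecture is
  out of scope.
* The g-only score weighting is unreliable below ~100 cells per channel
  (see above); the default count weighting trades the equal-bin reading
  of the g-COM for stability.
* No cell tracking across timepoints, no dense-tissue segmentation: the
  centroid tables consumed by the graph metrics may come from any
  external segmentation.
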