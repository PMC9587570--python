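# Methods

This note documents the models, numerical choices and study conditions
behind `angioseg`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Conventions

Images are 2-D `uint8` arrays, `(row, col)` indexed, row 0 at top. Vessels
are the *low*-intensity class (contrast agent absorbs X-rays); in mask
files vessel is stored as 0 (black) and background as 255, so masks render
like conventional binarized angiograms. Binary masks in memory are boolean
arrays with `True` = vessel. 16-bit input rasters are linearly rescaled to
8 bits with a logged warning.

## Tiling

The frame is partitioned into `tile_size` × `tile_size` subimages
(default 32, giving a 16 × 16 grid on 512 × 512 frames — small enough for
locally valid statistics, large enough that a tile crossed by a vessel
contains both classes). Dimensions not divisible by the tile size are
rejected rather than padded: padding would contaminate the per-strategy
pixel accounting. Tile neighbourhoods are the 3 × 3 block clipped at grid
borders — clipping is the only policy that keeps all reads in bounds.

## Tile classification

The classification stage maps every tile to vascular/nonvascular and is
deliberately pluggable (`heuristic`, `oracle`, `external`), because any
sufficiently good per-tile detector — including a trained CNN — can drive
the rest of the pipeline through the per-tile label CSV interface.

The reference heuristic reuses the exact two-cluster threshold (below) per
tile and demands (a) a non-degenerate split, (b) centre separation
≥ `min_contrast` = 40 gray levels (well above the noise scale of 8, well
below the nominal vessel/background contrast of ~120), and (c) a dark
fraction within [`min_fraction`, `max_fraction`] = [0.05, 0.80], excluding
tiles with a vanishing dark area (edge clips, speckle) and near-all-dark
tiles (deep shadow). The downstream expansion makes the pipeline robust to
classifier misses: a vascular tile labelled nonvascular is recovered
whenever one of its 8 neighbours is labelled, which the suite checks by
deliberately flipping 20 % of vascular labels.

The `oracle` classifier (vascular iff the ground-truth vessel fraction of
the tile ≥ `min_fraction`) exists for phantom experiments only.

## Exact 1-D two-means threshold

For scalars, the optimal two-cluster partition under within-cluster sum of
squares is an interval split of the sorted values, so the global optimum is
found by scanning all cuts between adjacent distinct values. For integer
intensities the scan compares candidate cuts in exact integer arithmetic
(cross-multiplied rationals), making the argmax immune to floating-point
ties; cluster means and the threshold δ = (mean_dark + mean_bright)/2 are
then computed in floats. δ at the midpoint makes `intensity < δ` identical
to nearest-centre assignment; the strict inequality sends midpoint ties to
background (conservative vessel calls). Degenerate inputs (< 2 distinct
values) raise a dedicated error; callers treat such tiles as vessel-free.

## Regional parameter expansion

Three strategies are implemented; `flood_fill` is the method, the other
two are the baselines it is compared against:

* `flood_fill` (default): per vascular tile, δ from the tile's own pixels;
  seeds = the tile's pixels < δ; growth by 8-connected flood fill over
  pixels < δ within the clipped 3 × 3 tile block; union over tiles.
  8-connectivity preserves the diagonal continuity of thin vessels. The
  union is a set union, hence independent of tile order (tested by
  shuffling).
* `merged_block`: pool the 3 × 3 block, one δ, threshold the block.
* `single_tile`: an independent two-means threshold in **every** subimage
  of the frame. Forcing a two-way split onto vessel-free tiles floods the
  output with background noise; this is precisely the failure the
  expansion strategy is designed to avoid, and the suite asserts the
  resulting ordering of mean vessel-pixel counts
  (flood_fill ≤ merged_block ≤ single_tile) and of false positives.

A whole-image two-means baseline (`segment_whole_image_kmeans`) is kept
for comparison; under strong illumination gradients its single global
threshold misclassifies shaded background en masse.

## Optimal cover tree

**Covers.** From each region-boundary pixel (a vessel pixel whose
4-neighbourhood is not all vessel, with frame borders counting as
background), candidate chords are cast along five directions — S, N, E,
SE, NE. A direction qualifies if its first step stays on vessel; the span
is maximal; the length is span (axial) or span·√2 (diagonal). If no
direction qualifies (isolated pixel), every configured direction yields a
degenerate span-1 candidate. A chord stopped by the *image border* rather
than by the region's edge does not join two edge pixels of the region;
such clipped candidates are only eligible when no region-terminated
candidate exists. Without this rule, border-truncated runs are spuriously
short and win the shortest-chord test near the frame edge, seeding chains
of along-vessel chords.

**Selection rules.** With no previous cover the shortest candidate wins
(ties broken by the fixed priority E, S, N, SE, NE — arbitrary but
documented and stable). Otherwise a candidate is *admissible* when its
undirected orientation (E = 0°, SE = 45°, S/N = 90°, NE = 135°; distance
mod 180°) differs from the previous cover's by ≤ `max_angle_step` (45°)
and its length agrees within a tolerance. If exactly one candidate is
admissible it is chosen; if none or several are, the candidate with the
previous cover's exact direction is preferred, else the shortest overall.
A selection that itself violates the rules is counted as a fallback event
and logged. The length tolerance defaults to the hybrid bound
max(2 px, 0.25 × previous length) — absolute floor for thin vessels,
relative bound for thick ones; a running-window variant
(max(2 px, 2 × sd of the last 5 lengths)) is available via
`tolerance_mode: window`.

**Chaining.** Boundary pixels are visited in raster-scan order; pixels
already lying under a selected cover are skipped. The "previous" cover
for the rules is the most recently selected cover whose pixels touch
(8-adjacency) the current anchor; where no selected cover touches the
anchor the chain starts afresh with the shortest-candidate rule.
Continuity constraints are meaningful only between spatially adjacent
covers: carrying the chain across a scan-order jump lets a stale length
or direction veto the locally correct chord, which manifests as chains of
along-vessel covers on oblique vessels.

**Trees, merging, pruning.** Each region's covers form one spanning tree
(each new cover linked to its adjacent predecessor, so the structure stays
acyclic and connected). Trees whose covers contain 8-adjacent pixels are
merged transitively (one connecting edge per union, preserving
acyclicity); merging is idempotent. The tree maximising the longest node
path is the main vessel — path length, not node count, so a long thin
vessel beats a compact blob of equal cover count; ties break by node
count, then earliest anchor in scan order. All black regions without a
cover in the main tree are removed. This deliberately deletes genuinely
disconnected secondary vessels along with the noise; `keep_top_n` (default
1) retains the n best trees for users who want them.

## Diameter profile and visualisation

The profile is one sample per cover on the main tree's longest path:
position = cover midpoint (a centreline proxy), diameter = cover length in
pixels (no mm calibration — angiography frames carry none here). Covers
crossing an oblique vessel not exactly perpendicular overestimate the
local diameter by up to the secant factor of the angle error, bounded by
the 45° direction grid; on 45° bars the expected rasterization error of a
diagonal chord is ≲ √2 px. The overlay paints every cover of the main
tree with the colour of its diameter's quantile bin (bin edges are
quantiles of the tree's cover lengths so the palette adapts per image; the
8-colour blue→yellow palette is fixed in `diameter.PALETTE`). Uncovered
pixels show the grayscale frame.

## Synthetic phantoms

The generator emulates the properties of angiography frames that the
method must survive, with exact ground truth:

* **Vessels**: bounded-curvature random-walk centrelines (heading noise
  0.03 rad/step) entering at the top border and spanning ≥ 70 % of the
  frame, as a main coronary branch crosses most of a frame; width
  9–15 px base with a ± 2 px slow sinusoidal wobble, optionally a Gaussian
  stenosis (location, severity, 20 px arc scale). Widths below 3 px are
  rejected. Vessels are rendered by stamping strict-interior disks of
  radius width/2 along the centreline, so the perpendicular chord width of
  the truth mask matches the requested profile within 1 px and ground
  truth is exact (no anti-aliasing).
* **Background**: level 190 with a random low-order polynomial
  illumination field of amplitude 30 (80 in the strong-gradient tests) and
  additive Gaussian noise (sd 8, clipped at ± 3 sd so the nominal 120-level
  vessel/background contrast is never bridged).
* **Distractors**: dark blobs (radius 3–10 px) and guidewire-like thin
  curves, rendered at vessel-like intensity but excluded from the truth
  mask and kept disconnected from the vessels — the structures pruning
  must remove.

Deterministic geometric masks complement the generator: exact rectangles
for axis-aligned width recovery; a 45° bar stamped along the anti-diagonal
(whose perpendicular, SE, lies in the direction set) crossing the top and
left borders away from a corner, so no chord is frame-truncated; a
U-shaped vessel whose arms enter at the top border (rounded end caps are
not how vessels terminate in real frames and would seed degenerate
chains); and a jagged vertical bar whose ± 1 px edge jitter is spatially
correlated (Gaussian-smoothed, scale 1.5 rows) — binarization jitter rides
on a smooth underlying edge, so per-row independent noise would model a
rougher boundary than thresholding produces.

What phantom results do **not** show: performance under real X-ray
physics (scatter, motion blur, contrast washout), overlapping vessels, or
clinically calibrated diameters. Passing phantoms demonstrates the
algorithmic properties — locality of thresholds, noise ordering of the
strategies, cover validity, pruning exactness, monotone stenosis
response — not clinical accuracy.

## Problem sizes and determinism

The test suite and acceptance script use 20 phantoms (512 × 512) for the
strategy comparison, 50 random masks ≤ 64 × 64 for cover validation, bars
of width 3–25 px for diameter recovery, and stenosis severities
{0, 25, 50, 75} % on a 15 px vessel — sizes chosen so the whole suite runs
in seconds while every statistic is computed on hundreds to thousands of
events. All randomness flows through `numpy.random.default_rng` seeds;
outputs are integer rasters and exact chord lengths, so repeated runs are
bit-identical, which the suite asserts on the full artifact bundle.

## Known limitations

* Covers measure oblique vessels with the nearest of four orientations;
  diameters on vessels far from the direction grid carry a secant bias.
* The longest-path criterion can prefer a long thin distractor over a
  short true vessel if the distractor's cover chain is longer; in the
  phantom family this is avoided by realistic vessel extents, not by the
  algorithm.
* Pruning removes disconnected true vessels (by design, matching the
  single-main-tree rule).
* The scan-order edge walk is one concrete choice among several the
  method's description admits; covers and trees are deterministic given
  that choice.
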