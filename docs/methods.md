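# Methods

`organelle3d` quantifies organelle morphology and inter-organelle membrane
proximity in instance-labeled 3D volumes of plant mesophyll cells, of the
kind produced by serial-section scanning electron microscopy (100 nm
sections, 10 × 10 nm pixels) after manual segmentation. This note records
the models, conventions and numerical choices behind each module, what the
synthetic phantom generator does and does not emulate, and the known
limitations.

## Labeled volumes

A cell is a `(z, y, x)` integer grid with anisotropic spacing
`(dz, dy, dx)` in nanometres (default `(100, 10, 10)`, matching section
thickness and pixel size). Label 0 is unlabeled background; every other
label is one organelle instance with a class in {chloroplast, peroxisome,
mitochondrion, nucleus, vacuole, cell_background}. The `cell_background`
class labels the cytoplasmic remainder of the cell, so the cell volume is
the sum of all labeled voxels. Metadata (spacing, label→class map, cell
id, light condition) travels in a JSON sidecar next to the TIFF stack:
sidecars are bit-exact and dialect-free, unlike TIFF tags. Labels, not
connected components, define identity: a label whose voxels fall into
several 26-connected pieces stays one instance (with a warning), because
segmentation decides what an organelle is.

## Morphometry

* **Volume** is exact: `V = n_voxels · dz·dy·dx`, converted nm³ → µm³.
* **Surface area** comes from a marching-cubes isosurface (level 0.5) of
  the padded binary mask with physical vertex coordinates, summing
  triangle areas. Meshing *raw* binary data systematically overestimates
  smooth surfaces by ≈9% (staircase facets), so the mask is first smoothed
  with a small Gaussian in index space: σ = 0.7 voxels by default, reduced
  to σ = 0.5 for marginally resolved objects (largest inscribed radius
  < 4.5 voxels) where stronger smoothing would erode the shape. With these
  defaults, digitized balls of radius ≥ 20 voxels are within ≈1% of
  4πr² (a residual mesh bias of this order persists at all radii — the
  estimate converges onto the theoretical sphere curve from the
  under-resolved side but does not go to zero error), boxes are within
  ≈5% (corners round off), and small anisotropic spheres the size of a
  peroxisome keep sphericity within 2% of 1. Objects too thin to survive
  smoothing are meshed unsmoothed; degenerate meshes fall back to summed
  exposed voxel-face areas with a warning.
* **Sphericity** is Wadell's `ψ = π^{1/3}(6V)^{2/3} / SA` — exactly 1 when
  `(V, SA)` lies on the theoretical sphere curve
  `SA = (36π)^{1/3} V^{2/3}`, and smaller for flattened, elongated or
  branched shapes. Discretization can push ψ slightly above 1; the
  tolerated excess is ε = 0.02.
* **MCI** (mitochondria complexity intensity) is normalized here as
  `MCI = SA³/(36π V²) = ψ⁻³`: exactly 1 for a sphere, invariant under
  uniform rescaling (so "not affected by volume"), strictly increasing
  with elongation and branching. The literature does not fix the
  multiplicative constant; the sphere-normalized form is chosen because it
  makes the `MCI·ψ³ = 1` identity exact and unit-free.
* **Mitochondrial length** is the longest geodesic path through the 3D
  thinning skeleton: skeleton voxels are graph nodes, 26-neighbor edges
  carry anisotropic Euclidean weights, and the length is the graph
  diameter (exact all-pairs Dijkstra up to 600 nodes, double-sweep beyond
  — exact on trees, which thinned tubes are). Thinning itself runs in
  index space, so strongly anisotropic voxels bias very thin structures;
  at the tube radii used here the error stays within ~10%. An instance
  that thins to nothing falls back to its maximal physical extent, with a
  warning.

## Membrane-proximity (contact) detection

Two organelles are in proximity where a one-voxel shell grown outside the
primary organelle overlaps the secondary organelle's surface voxels:

* *surface voxels*: mask voxels with ≥1 face neighbor outside the mask
  (grid boundary counts as outside, making results invariant to padding);
* *shell*: the one-voxel-thick background layer grown from the surface
  with **face (6) adjacency** by default — the tightest reading of
  "within one voxel", anisotropic in physical units by construction
  (≤ dz in z, ≤ dx,dy in-plane). 18/26-connectivity are available.
* *area*: `A = n_overlap · dx·dy` (XY pixel area, nm² → µm²). This is
  deliberately orientation-blind — the convention used by the
  surface-contact tools this reproduces — and under-weights
  z-facing contact patches; it is reproduced exactly rather than replaced
  by an orientation-aware estimate.
* *sites*: 26-connected components of the overlap voxel set; site overlap
  counts sum exactly to the pairwise overlap.

The algorithm is directional (shell on the primary, surface on the
secondary). Near-symmetry holds but is not exact, so a fixed convention
makes results deterministic: for each unordered class pair the
alphabetically first class (chloroplast < mitochondrion < peroxisome) is
the shell-bearing primary. Organelle partner sets (used for complex
classification) are taken from the canonical direction; face adjacency is
detected identically in either direction, so partner sets do not depend on
the convention.

## Complex classification

Each chloroplast, peroxisome and mitochondrion is categorized by the set
of *other* classes it touches (any site with ≥1 overlap voxel counts; no
area threshold): Alone, one binary category per partner class, or the
ternary category. Same-class contacts are ignored. Fractions are pooled
over the organelles of a condition (all cells together), not averaged per
cell, matching how population percentages with per-class n's are usually
reported; because one organelle may touch several partners of one class,
reciprocal categories need not be symmetric.

## Statistical battery

* Mann–Whitney U (two-sided) for pooled per-instance distributions
  (volume, sphericity, MCI, length) and per-site proximity areas: exact
  enumeration when min(n) ≤ 8 without ties, else the tie-corrected normal
  approximation without continuity correction (so symmetric inputs give
  p = 1 exactly).
* Welch's unequal-variance t (Satterthwaite df, two-sided) for per-cell
  totals — site counts and total proximity area per class pair, n = cells
  per condition. Skipped with a warning when a condition has < 2 cells.
* Fisher's exact test (two-sided, probability-mass rule: summing
  hypergeometric probabilities of tables no more probable than the
  observed one — the mainstream software convention; sample odds ratio
  reported) for alone-vs-engaged counts per class.
* Pearson correlation with t-distribution p (Spearman available by
  config) for median-chloroplast-volume vs cell volume across cells and
  peroxisome volume vs chloroplast-proximity area per condition.
* Two-sided throughout; no multiple-testing correction is applied, and the
  report lists raw p values.
* Median percent change between conditions is
  `(median_light − median_dark)/median_dark × 100`.

All CSV outputs are written with fixed float formatting (`%.10g`), so a
given input panel and configuration reproduce byte-identical tables.

## Synthetic cell generator

Real reconstructions of this kind are not publicly deposited, so the
package ships a first-class phantom generator that emulates the study's
*statistical structure* and provides exact ground truth.

**Geometry.** One ellipsoidal cell per grid — default grid
`(56, 176, 176)` voxels at `(100, 50, 50)` nm, cell semi-axes
`(2.6, 4.2, 4.2)` µm jittered per cell by a uniform scale in
`[0.84, 1.02]`. That is roughly half the linear size of a real
1000–2500 µm³ mesophyll cell; organelle *counts* stay at realistic values
while organelle linear sizes are scaled ≈½, because a full-size cell at
10 nm XY pixels (~10¹¹ voxels) is not desk-scale and every algorithm is
resolution-independent. Chloroplasts are oblate spheroids (equatorial
radius ~1 µm scaled with the cell, flattening 0.53–0.62) tiled
tangentially along the cell surface on a randomly rotated Fibonacci
lattice with adaptive shrinking — mesophyll chloroplasts tile the
periphery too densely for independent rejection sampling. Their placement
depth accounts for the sagitta of a flat disc against the curved wall.
The nucleus is an ellipsoid; peroxisomes are spheres; mitochondria are
tubes swept along persistent random walks (z-damped, reflected off the
cell boundary), optionally with one branch. The vacuole fills whatever
interior remains (capped by a super-ellipsoid) minus a one-voxel moat
around every organelle and a two-voxel cytoplasm layer under the wall —
as in real cells, where the vacuole is the space-filling compartment;
chloroplast+vacuole occupancy lands above 60%. The cytoplasmic remainder
becomes the `cell_background` instance.

**Contact design.** Every peroxisome and mitochondrion draws
Alone/engaged from per-class Bernoulli probabilities; chloroplasts draw
Alone and (among engaged ones) ternary-anchor status. Engaged organelles
are attached to anchors by sliding a freshly grown shape inward along a
surface ray until the first disjoint, face-adjacent position — sliding
from a disjoint non-adjacent position provably passes through face
adjacency before overlap — then "wrapped": grown voxel-layer by
voxel-layer along the anchor's shell until the overlap count reaches a
per-condition target (`site_area_vox`). Peroxisome targets scale with the
peroxisome's cross-section, so proximity area correlates with peroxisome
volume as observed in real cells. Ternary mitochondria are wrapped
against chloroplast and peroxisome separately (the peroxisome seam gets
half the target). Every placement forbids overlap with anything and face
adjacency to anything but its designed anchors, and detection under the
default 6-connected shell *is* face adjacency — so the recorded ground
truth predicts the contact table's partner sets exactly. Jobs that fail
on a crowded anchor are retried by later organelles of the same class
(pending-job queues); in the rare residual case (~0.2% of engaged
organelles) the organelle is placed free and recorded as Alone, keeping
ground truth truthful.

**Dark/light presets.** Counts per cell are drawn uniformly from the
published per-condition ranges (chloroplasts 15–22 / 17–21, peroxisomes
9–13 / 11–16, mitochondria 34–45 / 36–51 for dark / light). Alone
probabilities (0.096, 0.226, 0.347) dark vs (0, 0.05, 0.147) light for
chloroplasts / peroxisomes / mitochondria, and chloroplast ternary
anchoring 0.33 vs 0.57, are taken from the published population
percentages. Light cells additionally get larger peroxisomes (radius
0.28–0.42 vs 0.22–0.34 µm), shorter (0.7–1.4 vs 1.2–2.4 µm), less
branched (branch probability 0.15 vs 0.5) and slightly fatter
mitochondria, and larger per-site area targets (55 vs 30 overlap voxels,
≈ +80%, of the order of the published 62–67% median per-site increases for
the chloroplast pairs). Size *distributions* within the printed ranges
(uniform radii, log-uniform-ish realized volumes) are the generator's own
invention — the source reports only ranges and figures.

**What passing tests show — and what they do not.** The phantoms have
clean labels, designed contacts with no incidental adjacencies, and
analytic shapes. Tests against them validate the measurement and
statistics machinery (detection exactness, recovery of designed fractions
and effect directions), not robustness to segmentation noise, touching
same-class organelles, membrane invaginations, ER-mediated geometry or
registration artifacts of real serial-section data.

## Problem sizes

Default test and acceptance runs use: single cells or 2+2 panels of
reduced-size cells (32×96×96 grids) for unit and determinism tests, and
20 seeds × (3 dark + 3 light) full default cells for parameter recovery
(the acceptance script uses 8 seeds). These sizes were chosen as the
smallest panels at which the binomial recovery checks have useful power.

## Known limitations

* The contact-area formula ignores surface orientation (by design, to
  match the convention it reproduces); z-normal contact patches are
  under-weighted relative to their physical area.
* Surface-area and sphericity estimates carry a ~1% mesh bias that does
  not vanish with size; sphericity may exceed 1 by up to 0.02 for small
  objects.
* Skeleton length is biased low for tubes only 2–3 voxels thick in z and
  is reported as the largest-component diameter for fragmented skeletons.
* The generator cannot reproduce arbitrary combinations of occupancy,
  counts and contact targets in a scaled-down cell; extreme parameter
  choices raise `PlacementError` rather than silently degrade.
* Fractions are pooled over cells; per-cell mixed-effect analyses are out
  of scope.
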