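# Methods

This note documents the models, algorithms and numerical choices behind
`osteogrid`, a pipeline for whole-bone cortical and trabecular
microarchitecture analysis of micro-CT volumes of short bones (the design
case is the hominoid capitate), validated end to end on synthetic phantoms
with known ground truth.

## The measurement problem

A short bone is a thin, often porous cortical shell around a trabecular
lattice; there is no medullary canal, so the cortical–trabecular boundary
must be constructed rather than read off. Comparative studies quantify
seven parameters per bone and per volume of interest (VOI): trabecular
BV/TV, total BV/TV, degree of anisotropy (DA), trabecular thickness
(Tb.Th), number (Tb.N = 1/(Tb.Th+Tb.Sp)), separation (Tb.Sp), and cortical
thickness (Ct.Th), then compare them across taxonomic/behavioural groups
and against body size. Because no real scan collection is redistributable,
every stage here is exercised on phantoms whose true values are known by
construction.

## Compartment segmentation

1. **Bone/background**: two-class Lloyd (k-means) iteration on intensity;
   the threshold is the midpoint of the converged class means. A fixed
   threshold is available for pre-binarised input. Constant-intensity
   volumes raise a degenerate-clustering error.
2. **Component cleaning**: the largest 26-connected component is always
   kept; other components survive only above a configurable size cut
   (`min_component_mm3`, default 0.002 mm³ in the pipeline — large enough
   to drop segmentation speckle, small enough to keep genuine trabeculae
   that happen to be disconnected in a phantom).
3. **Enclosed volume (TV)**: the bone is closed with a Euclidean ball
   (radius below), the outside background is the 6-connected complement
   component touching the lattice border, and TV is its complement. TV is
   by construction a superset of the bone; bone touching the border is an
   error.
4. **Closing radius**: `k ×` mean maximal-sphere thickness of the bone
   phase, computed on a 2×-strided copy for speed, plus one coarse voxel
   to offset the surface-offset bias of the thickness map on structures a
   few voxels wide; clamped to ≥ 2 voxels. The default `k = 2` is
   configurable. If this radius turns out to obliterate the endosteal
   region (possible on very dense synthetic lattices), the chain retries
   deterministically with a halved radius, twice, before declaring the
   specimen degenerate.
5. **Periosteal wall by ray casting**: along the 6 axis directions every
   lattice line is marched inward; from the first bone voxel, consecutive
   bone voxels are marked until the first non-bone voxel. The union over
   directions is the wall candidate. Six directions are a deterministic,
   fast choice; the direction set is a documented parameter of the
   provenance record.
6. **Shell restriction**: the candidate is closed with the ball above and
   intersected with TV. Two corrections then release material the closing
   grabbed but should not keep:
   * non-bone pockets of the closed wall whose connection to the marrow
     survives a ~2-voxel erosion of the non-bone space are *bridged*, not
     enclosed, and drain back to the endosteal region (a genuine cortical
     pore communicates through channels narrower than that, or not at
     all);
   * bone fingers far thinner than the wall (trabeculae bridged onto it)
     are removed by an opening of the cortex region with a ball of a
     quarter closing radius; trimmed patches on the periosteal surface
     stay cortical.
   The endosteal region is whatever of TV remains outside the cortex;
   cortical pores are retained inside the cortex compartment so porosity
   stays measurable. Labels: background 0, cortical bone 1, cortical
   pore 2, trabecular bone 3, internal (marrow) 4. The five codes
   partition the lattice, and (cortical ∪ trabecular bone) equals the
   cleaned input bone mask exactly.
7. **Quality control**: `cortical_porosity` = pores/(pores + cortical
   bone); `boundary_confidence` = fraction of endosteal-traversing axis
   rays whose first bone run is at least 3 voxels long and ends at a
   non-bone voxel inside TV. A specimen is flagged when porosity exceeds
   0.30 or confidence falls below 0.80; flagged specimens are excluded
   from comparative statistics, mirroring how real porosity-compromised
   specimens are dropped.

This close-then-restrict scheme is one concrete reading of "morphological
filters sized by average trabecular thickness"; the erosion-gated release
and opening trim are this package's own constructions and are validated
against phantom truth (pore-free shells: porosity ≈ 0, cortex
precision/recall ≥ 0.9, Ct.Th within 20%).

## Morphometry

* **BV/TV** is a voxel count ratio, bone/total, per region. "Trabecular
  BV/TV" uses the trabecular+internal compartments; "total BV/TV" pools
  cortical and trabecular bone over the enclosed volume and is always
  computed as a direct count (it is defined on the unpartitioned
  segmentation).
* **Local thickness** (Tb.Th, Ct.Th, Tb.Sp) is maximal-inscribed-sphere
  thickness: the inscribed radius at a voxel is its Euclidean distance
  transform minus half a voxel (distance to the phase surface rather than
  the next outside voxel centre), and the thickness at a voxel is the
  diameter of the largest such sphere covering it. Implementation: sweep
  radii descending, one bounding-box-restricted distance transform per
  level. With `max_levels=None` every distinct radius is used and the
  result matches a brute-force search exactly; bounded level counts
  (default 64, 24 in phantom pipelines) floor-bin radii and underestimate
  by at most one bin. Known bias: structures an even number of voxels
  wide measure one voxel thin, and rods thinner than ~5 voxels in
  diameter are underestimated by up to a voxel — phantom tests use
  adequately resolved structures, and comparisons across specimens are
  unaffected because the bias is shared.
* **Tb.Sp** is the same measure on the non-bone phase restricted to the
  region of interest; voxels outside the region bound the spheres, which
  biases region-edge values low (documented, shared across specimens).
* **MIL fabric / DA**: for each of `n_directions` unit directions
  (Fibonacci sphere, default 128), parallel test lines are laid on a
  square raster through the sampling sphere and sampled along their
  length; a crossing is a bone↔non-bone transition between consecutive
  valid samples (samples outside the sphere, lattice or region break the
  line). MIL(d) = total valid line length / (crossings/2). The tensor H
  of the ellipsoid n·H·n = 1/MIL² is fitted by least squares over the
  directions with at least one intercept (≥ 6 required, rank-complete);
  the fabric eigenvalues are the ellipsoid semi-axes 1/√eig(H) in
  descending order and DA = 1 − smallest/largest ∈ [0, 1). Near-total
  anisotropy drives small eigenvalues to numerical zero; they are clamped
  at 10⁻⁴ of the largest (capping DA at 0.99), while fits negative beyond
  roundoff are rejected as undefined. Defaults: line spacing = voxel
  spacing and sample step = half a voxel, auto-coarsened for large
  spheres (~40 lines and ~100 steps across the diameter) to bound cost.
  Axis-aligned directions with voxel-aligned rasters reproduce a
  brute-force per-row crossing count exactly, which the tests exploit.
* **Background grid**: nodes of a regular grid (default 2.5 mm spacing)
  cover the TV bounding box; at each node a sampling sphere (default 5 mm
  diameter — the conventional grid/sphere scheme) measures the trabecular
  parameters where it overlaps the trabecular+marrow region by ≥ 30% of
  its volume, and Ct.Th where it overlaps the cortex by ≥ 10% (a thin
  shell cannot fill 30% of a sphere; the separate threshold is this
  package's addition, both configurable). Invalid measures are flagged,
  never zero-filled; Tb.N = 1/(Tb.Th+Tb.Sp) holds exactly at every valid
  node by construction.
* **Region summaries** come in two modes: `grid-mean` (unweighted mean of
  valid node values with centres in the region — the default, matching
  how grid-based tools report VOI values) and `direct` (single-pass
  counts/means over the region, one MIL fit over the whole region).
  Cross-mode agreement on homogeneous phantoms is part of the test suite.

## Regions and ratios

Each specimen is split at a cut plane orthogonal to the proximodistal
axis; the plane's voxel layer belongs to the distal mask so the two VOIs
partition TV exactly. The anatomical landmark defining the plane in real
bones cannot be auto-detected, so the index is per-specimen input;
phantoms default to 40% of the proximodistal extent from the proximal
end (the proximal VOI is the smaller "head" segment). Ratio variables:
distal/proximal per parameter, plus total-BV/TV / trabecular-BV/TV within
each segment (the relative cortical contribution). Invalid components
propagate as missing, never as 0 or 1.

## Statistics

* **Group comparisons** are nonparametric: Kruskal–Wallis (tie-corrected,
  chi-square p on k−1 df; all-tied data returns H = 0, p = 1 by
  convention) and pairwise two-sided Wilcoxon rank-sum tests with Holm
  step-down adjustment per family. Exact null distributions are used for
  tie-free samples up to n = 25 per group, otherwise the normal
  approximation with continuity and tie correction. Ratio departures from
  1 use the Wilcoxon signed-rank test on (ratio − 1), zero differences
  dropped (classical convention), exact/approximate by the same rule; the
  reported V is the sum of positive ranks.
* **Allometry**: reduced major axis regression of log₁₀(parameter) on
  log₁₀(cube-root bone volume). Slope = sign(r)·sd(y)/sd(x) (positive at
  r = 0 by convention), intercept through the means, r² the squared
  Pearson correlation, p the two-sided t test of r = 0 (deterministic; a
  permutation alternative common in model-II software would introduce
  Monte-Carlo noise for no inferential gain here), and 95% CI by the
  standard model-II factor B·(√(F+1) ∓ √F), F = t²₀.₉₇₅(1−r²)/(n−2).
  Log base only rescales the intercept; slope and category are
  base-invariant. Bone volume is the TV voxel count × spacing³ — a
  voxel-count substitute for surface-mesh integration, exact for the
  counting definition used throughout.
* **Classification**: shape-like parameters (BV/TV, total BV/TV, DA,
  Tb.N) have isometric slope 0; size-like (Tb.Th, Tb.Sp, Ct.Th) have 1.
  A fit with p > 0.05 is Uncorrelated; otherwise Positive/Negative when
  the CI lies entirely above/below the isometric slope and Isometry when
  the CI straddles it. Significance uses p ≤ α with α = 0.05. The rule
  reproduces all 35 rows of the bundled published capitate regression
  table.

## Synthetic phantoms

`PhantomSpec` describes one bone: an ellipsoidal outer surface (optional
waist pinch), a shell whose thickness grades linearly from a proximal to
a distal value (measured by Euclidean distance from the outer surface, so
truth is controlled directly), spherical pores with centres uniform in
the shell matched to a target porosity by expected carved volume (overlap
makes the realised porosity slightly lower), and an interior lattice of
cylindrical rod segments (length = lattice spacing − 4r/3 so the capsule
volume equals the ideal cylinder volume πr²s per cell) with directions
from a rejection-free von Mises–Fisher sampler (κ = 0 uniform; κ > 700
collapses to the mean axis). The greyscale channel is bone/background
intensity plus additive Gaussian noise (default sd = 5% of contrast) —
enough to exercise two-class segmentation; no beam hardening, ring
artifacts, plate-like trabeculae or marrow texture are modelled, so
passing tests demonstrate recovery of geometry and statistics under
idealised imaging, not robustness to scanner physics.

Default dimensions are roughly half-scale relative to real hominoid
capitates (~6–8 mm extent, 0.05 mm voxels) so a cohort is desk-sized;
`RunConfig.for_phantoms` scales the grid/sphere to 1.25/2.5 mm (keeping
the conventional 2:1 ratio) so dozens of valid nodes exist per specimen.
Cohorts draw per-specimen parameters from group means with a stated CV
(default 5%), an optional log-uniform size spread, and an optional
power-law link tying one parameter to linear size for allometry-recovery
experiments.

`make_allometric_series` generates log-log series for regression tests
using the symmetric errors-in-both-variables model (noise of sd σ in y
and σ/|b| in x): under a y-noise-only model the RMA slope estimates b/|r|
— a ~47% upward bias at r² ≈ 0.46 — whereas under the symmetric model it
is consistent for b, which is the estimand model-II regression is built
for. `noise_sd_for_r2` inverts the implied correlation (r = √r²
relation) so simulations can target a published r².

Ground truth (shell/interior masks, thickness field, counted volume
fractions, fabric axis) is produced by direct counting on the binary
truth volume with the same counting rules as the measurement modules, so
recovery tests can assert exact equality where no estimation is involved.

## Determinism and runtime

Everything is deterministic given (config, seed): phantom generation uses
`numpy.random.default_rng` seeded per specimen from the cohort seed, and
no stage uses unordered iteration or wall-clock state. Cohort runs write
per-specimen timings to a separate `timings.txt`, the one output file
outside the byte-determinism contract. Problem sizes in the tests and
acceptance script (≤ 160³ voxel specimens, 2000-cohort null simulations,
500-replicate regression recovery) were chosen so the whole suite runs on
one CPU in well under half an hour while leaving every statistical
criterion adequately powered.

## Known limitations

* The intensity k-means segmentation is a deliberate simplification of
  fuzzy-clustering segmentation used on real scans; it is adequate for
  bimodal synthetic histograms and pre-binarised input, not for real
  beam-hardened data.
* Thickness values carry the voxelization biases described above.
* The cortex restriction is validated on shell-plus-rod geometry; highly
  plate-like or extremely porous real cortices may behave differently —
  the QC flags are the guard.
* Phantom rod lattices need not be globally connected, unlike real
  trabecular networks; the component-size cut exists for exactly this
  reason.
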