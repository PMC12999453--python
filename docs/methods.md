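# Methods

## Model

The package treats a segmented tissue as a binary microstructure on an
isotropic voxel grid and summarizes its directional organization with
mean-intercept-length (MIL) stereology.  For a unit direction **n**, a
family of parallel test lines is traced through the volume; an
*intercept* is a maximal run of material samples along one line, and
MIL(**n**) is the total material length divided by the number of
intercepts.  Elongated structures give long intercepts along their axis
and short ones across it.

The directional profile is condensed into a second-order fabric tensor by
a least-squares fit of the ellipsoid form `1/MIL(n)² = nᵀ M n` over all
sampled directions with a defined MIL.  Eigenvalues are reported on the
length scale `λᵢ = 1/√mᵢ` (µm, sorted descending) so λ₁ is the longest
characteristic intercept length; the matching unit eigenvectors are the
principal material directions.  Three derived scalars are exposed:

* **dominant direction** — the primary eigenvector e₁ (axial: e₁ and −e₁
  are the same fiber direction);
* **magnitude** — λ₁ in µm, the coherence/extent of alignment along e₁;
* **anisotropy index** — `DA = 1 − λ₃/λ₁ ∈ [0, 1]`, the exclusivity of
  that direction (0 for equal eigenvalues, → 1 for extreme alignment).

A second-order fabric tensor assumes at most orthotropic symmetry: it
captures one dominant axis and the spread about it per window, not
multimodal orientation mixtures within a window.  Mixtures are resolved
spatially instead, by evaluating the fabric in sliding windows and
reducing the resulting eigenvector field statistically.

## Sampling geometry and numerical choices

* **Direction set** — deterministic spherical-Fibonacci lattice on the
  upper hemisphere (axial data), default n = 128.  At n = 128 the mean
  outer product of the symmetrized set deviates from isotropy by < 0.003
  per entry, and the fit design is well conditioned.
* **Line families** — perpendicular line spacing 2 voxels (default),
  line grid covering the volume half-diagonal, half-voxel sampling steps
  with nearest-voxel lookup.  Sampling bias is below half a voxel and is
  covered by the stated tolerances.  Runs truncated by the volume
  boundary count as one intercept; this matters only in the solid-volume
  limit, where MIL equals the mean chord length of the bounding box.
* **Degenerate inputs** — directions with zero intercepts are dropped
  from the fit, never imputed.  A fit needs ≥ 6 defined directions
  spanning a full-rank design; a fitted form that is not positive
  definite raises a degenerate-fabric error carrying the tensor.  Both
  conditions skip (and count) the window in field mapping.
* **Sign canonicalization** — each eigenvector is flipped so its
  largest-magnitude component is positive; ties break X before Y before
  Z.  All axial statistics are invariant under per-sample sign flips.
* **Windows** — default edge 32 voxels, stride 16 (50% overlap), minimum
  material fraction 0.05.  At a 6.48 µm voxel size this gives ~0.2 mm
  windows, the scale at which fiber bundles remain locally unidirectional
  in fibrocartilage.  Each retained window contributes one vector at its
  geometric center; there is no sub-window refinement.
* **Anatomical frame** — X lateral–medial, Y ventral–dorsal, Z
  cranial–caudal.  Storage order is metadata-free; an `axis_map` carries
  the anatomical meaning, and volumes are brought into (X, Y, Z) order
  before windowing, which makes the field exactly invariant under joint
  permutations of array axes and axis map.
* **Plane statistics** — in-plane angles are measured from the plane's
  first axis (sagittal: +Y→+Z, frontal: +X→+Z, transverse: +X→+Y) and
  folded into [0°, 180°) because fibers are axial; samples with in-plane
  norm < 1e−6 are excluded and counted.  Rose histograms always carry
  both weightings: per-bin counts (fiber frequency) and per-bin summed λ₁
  (sum magnitude).  Per-axis magnitude panels report both the sum and the
  mean, labelled distinctly, since either convention is found in
  practice.  Window statistics are unweighted (each retained window is
  one vector).
* **Thickness/separation** — largest-inscribed-sphere (Hildebrand-style)
  local thickness from the Euclidean distance transform: a center c
  carries a sphere covering voxels with |p − c| < dt(c) of diameter
  2·dt(c) − 1 voxels (the material surface lies half a voxel beyond the
  last material voxel center).  A single isolated voxel therefore has
  thickness exactly one voxel spacing; even-width slabs are measured one
  voxel under their nominal width, within the ±1 voxel discretization
  tolerance used throughout.  Redundant sphere centers are pruned by a
  26-neighbor domination test, which preserves the thickness maximum
  exactly.  Separation is thickness of the void phase within the ROI;
  void regions open to the volume boundary are not edge-corrected, so
  ROIs should be chosen with bounded void phases.  Radii are handled in
  physical units and assume isotropic spacing.

## Synthetic phantoms

The generators emulate the study conditions of segmented fiber volumes
with known ground truth:

* **parallel_fibers** — hard-capsule cylinders (default radius 4 vox)
  along a chosen axis with a bounded orientation jitter; fibers are added
  until the target volume fraction (default 0.3) is realized, so the
  realized fraction is within one fiber volume of the target.
* **crossed_fibers** — space tiled into cubic blocks, each filled by one
  of two orthogonal families; the primary family occupies a fraction of
  blocks equal to the mixing fraction (rounded to block count).  Blocks
  are segregated rather than interpenetrating so window-level truth is
  well defined; the block edge should exceed the window edge.
* **isotropic_blobs** — a Boolean model of spheres with germ intensity
  solved from 1 − exp(−nv/V) = target fraction, sown in a padded box for
  uniform boundary coverage.
* **trabecular** — a Gaussian random field (correlation length =
  `fiber_radius_vox`, optionally stretched along a primary axis)
  thresholded at the exact quantile of the target fraction.
* **disc** — a superellipse footprint (exponent 2.5, semi-axes 0.45/0.42
  of the in-plane extents) with a biconcave thickness profile along Z
  (35% of the Z extent centrally, 85% at the rim); rim fibers follow the
  local circumferential tangent with 3° jitter, center fibers are drawn
  uniformly on the sphere and blended toward the tangent by
  `center_alignment`.  Fiber segments are 30 voxels long — the analysis
  window scale — approximating locally straight stretches of continuous
  collagen bundles; drawn directions are stored per region as ground
  truth.  In-disc material fraction is fixed at 0.30.

Random streams are derived per fiber from `(seed, fiber_index)` so that
identical specs are bit-reproducible and adding fibers never reshuffles
earlier ones.

The phantoms reproduce geometry and topology, not imaging physics: there
is no noise, partial-volume blur, reconstruction artifact or segmentation
error, fiber radii are uniform and uncalibrated to tissue (real diameter
distributions are not published), and fibers are straight at the segment
scale.  Passing phantom tests therefore demonstrates that the estimator
chain recovers known geometric truth — not that segmentation of real
scans is accurate.

## Validation sizes

The test suite and `scripts/acceptance.py` run the recovery studies on
128³ phantoms with 32/16 windows (343 windows), the disc contrast on
192 × 192 × 48, and the end-to-end determinism run on 128 × 128 × 48 —
sizes at which every study completes in minutes on one CPU while leaving
≥ 200 windows per field for stable statistics.  Oracle-equivalence checks
(naive per-line MIL, exhaustive inscribed-sphere thickness) run on 32³
and ≤ 14³ masks respectively, where the naive references are exact.

## Design choices on open points

* The anisotropy index is fixed as `1 − λ₃/λ₁`, which maps isotropy to 0
  and extreme alignment to 1 on the required 0–1 scale; the magnitude is
  fixed as λ₁ in µm.  Other eigenvalue ratios in use (λ₁/λ₃, 1 − λ₃/λ₁
  on the tensor scale) are monotone transforms of the same spread.
* Direction count, line spacing, and the window scheme are free
  parameters of any MIL implementation and are exposed in the
  configuration with the defaults above.
* The field CSV schema
  (`cx_um,...,e1x,...,l1_um,...,anisotropy_index,material_fraction`,
  9 significant digits, Z-major row order) is this package's own
  documented contract.
* Empty dominant-axis groups are omitted from per-axis summaries rather
  than raised, since grouping is data-driven; explicitly requested
  regions with no samples do raise.
* `summarize` standard deviations use the sample (n − 1) convention with
  sd = 0 at n = 1.

## Limitations

MIL fabric is a second-order summary: within-window crossings bias e₁
toward the stronger family and depress DA rather than reporting two
axes.  Results on real data depend on direction count, line density and
window scheme; cross-tool comparisons should state all three.  Thickness
is voxel-discretized (±1 voxel); extents are axis-aligned bounding boxes
in the anatomical frame, not oriented boxes.  Per-voxel orientation,
streamline tracing and gray-scale (unsegmented) MIL are out of scope.
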