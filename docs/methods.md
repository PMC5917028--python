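# Methods

This note records the model, the numerical choices and the known limits
of the pipshape pipeline, in the order the data flows.

## Canonical pose

The seed is modelled as a uniform-density solid. For watertight meshes
the centre of gravity and inertia tensor are exact polyhedron integrals
(divergence theorem, per-triangle); open meshes fall back to uniform
point masses on the vertices and are flagged — all downstream solid
integrals then inherit the point-cloud approximation. The canonical
frame maps the eigenvector of the smallest principal moment (the
elongation axis) to +z, the middle one to +x and completes +y by
right-handedness.

Eigenvectors have no intrinsic sign, so signs are fixed by skewness: the
third central moment of the solid along the elongation axis is made
positive. A pip's beak is a thin tapering extension of the body, i.e. a
long upper tail of the mass distribution along the length axis, so
"positive skewness" means "beak up". The cubic moment is computed
exactly by signed tetrahedral decomposition (for a linear function with
tetra-vertex values cᵢ, ∫ℓ³ dV = V(S₁³ + 3S₁S₂ + 2S₃)/120, Sₖ = Σcᵢᵏ).
The same rule orients the broad axis when its skewness is resolvable;
ties (bilaterally symmetric seeds) are left as computed, which is safe
because the retained descriptors are reflection-invariant. When two
principal moments agree to better than 1e-6 relative, the eigenplane is
scanned on a 1° grid for the direction of maximal |skewness| and a
warning is recorded; a perfect sphere therefore canonicalizes
deterministically but meaninglessly, and says so.

## Curves

Sections are cut at the five interior fractions k/6 of the canonical z
extent — the equidistant interior planes that avoid the degenerate pole
caps. Per plane the intersection loop of largest enclosed area is kept
(debris and detached beak loops lose). The silhouette is, by default,
the outer boundary of the orthogonal projection onto the (x, z) plane:
faces are rasterized (512 px along the larger extent, PIL), the
occupancy contour is traced with sub-pixel interpolation
(skimage.find_contours), and the largest contour is kept. A mid-sagittal
planar cut (y = 0) is available as a config switch
(`silhouette_method: section`) for users who prefer the cut reading of
the broad view; the projection is the default because the silhouette of
a convex-ish seed is what a rendered broad view shows.

Each curve is resampled at N = 1024 uniform arc-length points. The
profile origin starts at the polygon centroid and takes Newton steps on
the first-harmonic pair (a₁, b₁) — whose Jacobian with respect to the
origin is the projection of the unit radial directions onto cos s,
sin s — until amplitude₁/r₀ < 1e-6 (max 50 iterations; typically 3–5).
Because the sample points depend only on arc length, only the radii move
during the iteration. Star-shapedness about the final origin is enforced
by requiring the polar angle of the traversal to wind monotonically once
around it; backtracks up to half the mean angular step are tolerated
(raster-traced contours jitter at the sub-pixel level without folding),
anything larger is an error rather than a silently wrong radius
function.

## Harmonic descriptors

With N uniform samples, a₀ is the sample mean and aₖ, bₖ the standard
real DFT coefficients; Parseval's identity is used as a self-check in
the tests. Descriptors keep the rotation-of-start-point invariant
amplitudes rₖ = √(aₖ²+bₖ²) for k ∈ {0, 2…7}; r₁ is zero by the origin
construction and excluded. Phases are retained internally only for
truncated-curve reconstruction (displayed polar-wise against the
arc-length parameter). K = 32 harmonics are stored; for smooth seed
outlines the energy beyond k = 7 is a fraction of a percent of r₀
(printed by `examples/02_fourier_descriptors.py`).

Amplitudes measured against arc length differ from the same shape's
polar-angle amplitudes at second order (O(amp²/r₀), measured ≈ 4%
relative at r₂/r₀ = 0.2). The generator's ground truth is therefore
evaluated in the arc-length convention — the one the pipeline measures —
by profiling the analytic section curves at high resolution before any
mesh exists.

## Features, distance, classification

The 42-vector is six (r₀, r₂…r₇) blocks: sections bottom-to-top, then
the silhouette. Features stay in raw millimetres; no standardization,
because the weighting of absolute size is intentional. The default
weight schedule is 25/25/50 (percent on the six r₀, the six r₂, the
remaining 30 parameters, split equally within each class) for iteration
1 and 15/25/60 for iterations 2 and 3.

Clustering is agglomerative with average linkage by default (complete
and Ward are configurable); ties in the merge order are broken by scipy's
deterministic ordering of the condensed matrix, so results are stable for
a fixed input order, and the tests additionally verify that the final
grouping is invariant to input permutation. The iterative procedure cuts
the iteration-1 tree into k₁ = 3 main branches, then within every branch
of ≥ 3 seeds evaluates 2- and 3-way splits under the next iteration's
weights and accepts the best one only if it raises the mean silhouette
width of that branch's seeds — evaluated against the global partition
with the current distance matrix — by at least 0.05. This rule is
deliberately conservative: splitting a tight, well-isolated branch makes
the sibling sub-branch the nearest neighbour and lowers silhouette, so
only splits supported by real within-branch structure are taken.
The final dendrogram grafts accepted sub-trees onto the iteration-1
skeleton; because sub-trees live in a different weight space, skeleton
heights are raised where necessary to keep merge heights monotone.

Weighted PCA scales feature i by √ωᵢ and centres columns; component
signs are fixed by making each component's largest-magnitude loading
positive. At full rank the score distances equal the weighted distance
to machine precision — used as an invariant test.

## Validation

Both MANOVA and the blind test operate on the first m = 5 weighted-PCA
scores: with 42 raw features and single-digit per-group counts the
within-group covariance is singular, so dimension reduction is a
statistical necessity, and m is config-exposed. Pairwise MANOVA forms
Wilks' Λ = det(W)/det(W+B) and Rao's F approximation (exact for two
groups); a singular within matrix reduces m for that pair and records it.
The blind test uses stratified half splits (floor/ceil per group,
alternating across runs — unstratified splits can empty a group of ten
and leave the discriminant undefined), fits a pooled-covariance linear
discriminant with a 1e-6·trace ridge on the training half and labels the
sample half; the PCA embedding is computed once on the whole assemblage,
which leaks no label information because it is unsupervised. Counts
accumulate per seed over 1000 runs by default and are fully determined
by the run seed.

## Synthetic seeds

The generator emulates prolate, beaked, bilaterally quasi-symmetric pip
bodies: a radius field R(z, θ) = c₀(z)(1 + Σₖ relative harmonics(z)) +
beak(z), with c₀ a monotone-cubic (pchip) envelope through the five
section mean radii, clamped to zero at both poles; relative harmonic
coefficients are pchip-interpolated through the sections and held flat
beyond them, so the star-shape bound (Σ amplitudes ≤ 0.5 r₀, enforced at
the archetype level) is inherited everywhere. The beak is a Gaussian
radial bump on the top tenth of the height. Surfaces are triangulated on
a 200×200 (z × θ) grid — rings plus two pole fans, watertight by
construction. Per-seed parameters are Gaussian draws around the
archetype means, truncated at ±3 SD, redrawn (max 10 times) if the
star-shape budget is violated.

The default preset has seven varieties with lengths 5.5–7.5 mm,
mid-section mean radii 1.3–1.9 mm, section eccentricities r₂/r₀ up to
≈ 0.18, small higher harmonics, within-variety SDs of 0.18 mm (length)
and 0.05 mm (radii), and group sizes 13, 12, 13, 10, 10, 11, 14 —
a realistic assemblage-scale study design. A `separation` multiplier
scales all archetypes toward their common mean; 0 collapses them into a
single population, the null used for chance-level checks.

What the generator does *not* emulate: scanner noise and holes, distinct
anatomical structures (chalaza, fossettes, raphe), non-star-shaped
outlines, and within-variety covariance structure beyond independent
Gaussian perturbations. Passing tests therefore demonstrate the
correctness and calibration of the machinery on seed-like geometry, not
identification accuracy on real scanned pips.

## Problem sizes and tolerances

The test suite and the acceptance script use the seven-variety preset at
full mesh resolution (200×200) for recovery benchmarks — 83 seeds,
roughly a minute end to end — and coarser grids (80–120) for smoke
tests; mesh resolution only affects discretization error, which the
recovery benchmark bounds directly (median pipeline-vs-truth discrepancy
≤ 2% of the matching r₀; measured ≈ 0.003%). Monte-Carlo inertia checks
use 4×10⁵ box samples against the analytic interior at 3 standard
errors. "Exact" equivariances (scaling, cyclic shifts, PCA/distance
equality) are asserted at 1e-9–1e-12 relative, the realistic floor after
eigendecompositions in float64.

## Known limitations

- Real scan meshes with large holes fall back to vertex point masses for
  the pose; a strongly non-uniform vertex density then biases the frame.
- The radius representation requires star-shaped curves; strongly
  concave outlines (e.g. broken pips) are rejected rather than
  approximated.
- The silhouette's raster resolution (default 512 px) bounds its
  descriptor precision at roughly extent/512 per coordinate.
- The split-acceptance rule and its 0.05 margin are a documented
  convention; assemblages whose varieties differ only marginally in
  shape under-split rather than over-split (see the classification
  example, where two shape-similar varieties stay merged).
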