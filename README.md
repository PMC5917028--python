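# pipshape

3D geometric morphometrics of grape pips (seeds of *Vitis vinifera*), for
archaeobotanists and ampelographers who want to identify grape varieties
from seed shape alone. Given a triangle mesh of a single scanned seed
(PLY/OBJ/STL, millimetres), the package computes a scanner-independent
shape summary and classifies and validates whole assemblages of seeds.

## The method

1. **Canonical pose.** The seed is treated as a uniform-density solid;
   the eigenvectors of its inertia tensor, ordered by ascending principal
   moment, define an intrinsic, repeatable coordinate frame with the
   origin at the centre of gravity. The elongation axis becomes +z
   ("beak up", fixed by the sign of the third central moment along the
   axis), the broad axis +x.
2. **Six planar curves.** Five horizontal cross-sections at interior
   fractions k/6 of the height, plus the silhouette — the outer boundary
   of the projection onto the broad (x, z) plane.
3. **Radial Fourier descriptors.** Each closed curve is written as radius
   versus normalized arc-length, r(s), s ∈ [0, 2π), with the origin
   chosen so that the first harmonic vanishes (making the representation
   unique and translation-free). From the series
   r(s) = a₀ + Σₖ (aₖ cos ks + bₖ sin ks), the descriptor keeps the
   amplitudes rₖ = √(aₖ² + bₖ²) for k ∈ {0, 2, …, 7}: r₀ is the mean
   radius (absolute size, mm), r₂ tracks the eccentricity of the best
   fitting ellipse, r₃–r₇ finer deformations. Higher harmonics are noise
   for variety identification and are dropped.
4. **42-value feature vector.** Six curves × seven amplitudes, ordered
   sections bottom-to-top then silhouette: v = [v₁ … v₄₂].
5. **Weighted distance.** d(α, β) = √(Σᵢ ωᵢ (v_{αᵢ} − v_{βᵢ})²) with
   ωᵢ ≥ 0, Σωᵢ = 1. Features stay in raw millimetres: size is weighted
   deliberately.
6. **Iterative classification.** Iteration 1 (ω: 25% on the six r₀, 25%
   on the six r₂, 50% on the rest) clusters the assemblage and cuts the
   tree into k₁ = 3 main size branches; iterations 2–3 (15% / 25% / 60%)
   re-cluster within branches on shape, accepting a split only if it
   improves the branch's mean silhouette width. A weighted PCA (features
   scaled by √ωᵢ) provides the ordination; its full-rank score distances
   equal the weighted distance exactly.
7. **Validation.** Pairwise MANOVA (Wilks' Λ, Rao's F) on the leading
   weighted-PCA scores, and a repeated blind test: 1000 random half
   splits, a linear discriminant fitted on one half labels the other;
   per-seed assignment fractions show which seeds are stably identified.

A synthetic seed generator (`pipshape.synthetic`) produces watertight,
star-shaped, beaked seed meshes with known ground-truth descriptors and a
seven-variety preset mirroring a realistic study design (10–16 seeds per
variety), so the whole pipeline runs and is tested without any scan data.

## Worked example

```sh
python examples/01_canonical_pose.py
```

```
seed 'demo' of variety A:
  watertight=True, volume=47.62 mm^3
  principal moments (mm^5): [ 69.1 127.  140.4]
  third central moment along axis 1: 0.463 mm^3  (> 0: beak up)
  canonical z extent: [-3.18, 3.64] mm
```

The positive third moment is what orients the beak upward; the asymmetric
z extent reflects the centre of gravity sitting below the middle of a
tapering seed. Continuing with `examples/03_classify_assemblage.py`
(seven varieties, six seeds each):

```
iteration 1: 3 branches, ARI vs truth = 0.379
iteration 2: 5 branches, ARI vs truth = 0.699
iteration 3: 5 branches, ARI vs truth = 0.699

PCA variance explained by PC1-PC2: 88.3%
```

Iteration 1 separates the three size classes; the shape-weighted
iterations split them further toward the true seven varieties (adjusted
Rand index rising from 0.38 to 0.70 on this small assemblage).
`examples/04_blind_test_validation.py` prints the pairwise Wilks' Λ
p-values (~1e-13 for three well-separated varieties) and a blind test in
which every seed is correctly labelled in 100% of its sampled runs.

## Command line

```sh
pipshape simulate --out seeds/ --seed 1          # synthetic assemblage
pipshape run seeds/manifest.csv --out run1/      # extract + classify + validate
```

Artifacts: per-seed canonical transforms (JSON), curve CSVs, the feature
table, per-iteration distance matrices, the cluster tree (Newick), PCA
scores, the MANOVA p-value matrix and the blind-test fractions — all
stamped with a hash of the run configuration.

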