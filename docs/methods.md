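# Methods

## Model

A structural connectome is an undirected weighted graph on N gray-matter
regions. From directed streamline counts S and region volumes V the
adjacency is A_ij = (S_ij + S_ji) / (2 (V_i + V_j)): the volume
normalization stops large regions from dominating purely by seeding or
receiving more streamlines, and weights stay on the raw streamline-density
scale (no global normalization), so eigenvalues are unitless but
scale-bearing. The graph Laplacian L = D − A (D the diagonal of weighted
degrees) governs linear diffusion dx/dt = −βLx; with L = QΛQᵀ the solution
is x(t) = Q e^{−Λβt} Qᵀ x(0). 1/λ_i is the characteristic time of mode i,
so the low modes carry the persistent whole-brain spread patterns. β only
rescales time and defaults to 1; all spectra and importance values are
computed on L itself.

Laplacian facts the package leans on: L is symmetric PSD; λ₁ = 0 with the
constant eigenvector on a connected graph; a disconnected graph repeats the
zero eigenvalue once per component; decreasing any edge weight produces a
PSD difference, so no eigenvalue can increase (Weyl monotonicity).

## Mode matching and angle variance

Eigenvalue order can swap between subjects (or under perturbation) when
neighbouring eigenvalues are close, and eigenvectors are sign-ambiguous.
Cross-subject comparison therefore matches a reference eigenvector v̄
against candidate modes by maximizing |v̄ᵀv_j| within a window of ±2 ranks
around the reference rank (configurable; ∞ searches all modes). The
per-subject angle variance of a mode is acos of the matched absolute inner
product, in degrees, with the acos argument clipped to [−1, 1]. Degenerate
eigenvalues are returned as an orthonormal basis and matching operates on
the absolute inner products across the window, so near-ties resolve to
whichever basis vector best aligns with the reference.

Spectra are compared after dividing by the spectrum mean. The zero
eigenvalue is included in the mean by default (an exclude-zero option exists
for sensitivity analysis); group comparisons report both.

## Geometric null networks

Node pairs are sorted by Euclidean inter-centroid distance and grouped into
bins — quantile bins by default so every bin has shuffle partners (100 bins
by default; 10 and 1000 behave equivalently) — and edge weights are permuted
uniformly within each bin. Zero-weight pairs participate, which preserves
connection density per distance stratum. The binned distance–weight curve
is preserved exactly; any organisation beyond the cost–wiring profile
(hemispheric structure, hubs) is destroyed. The bin count must be well
below the pair count, or bins of size one make the null collapse onto the
input.

## Virtual lesions and importance maps

A lesion is a sphere (default diameter 12 mm) placed at a white-matter
voxel. Each edge's anatomical embedding is its consensus mask: per tracking
direction, the top 95% of non-zero trajectory voxels ranked by streamline
count (ceil rounding, ties broken lexicographically for determinism), then
the union of the two directions. The lesion weakens each traversing edge by

    A_ij → A_ij (1 − stoppage · f),   f = |mask ∩ sphere| / |mask|,

with stoppage ∈ (0, 1] expressing how completely damaged tissue blocks
streamlines. Edge "volume" is the count of unique consensus voxels (uniform
voxel volume). The importance of the voxel for mode k is λ_k(reference) −
λ(matched mode of the lesioned Laplacian), using full re-eigendecomposition
plus inner-product matching — not a first-order approximation; the
first-order formula v̄ᵀ(L − L_lesioned)v̄ serves only as an independent test
oracle, which agrees within 10% (empirically ~0.5%) when stoppage·f ≤ 0.05.
Matched importance can be slightly negative in degenerate near-tie cases;
values are reported unclipped. Importance maps evaluate the lesion at every
white-matter voxel (the union of consensus masks), optionally strided; maps
share the lesion geometry across modes and stoppages, so the cost is one
80×80 eigendecomposition per lesion centre per stoppage.

## Reliability (ICC)

Importance is averaged over the voxels of each tract of a label volume
(evaluated lesion centres only, so strided maps are not diluted by
structural zeros), giving i_{s,r,scan} per subject s and tract r. With two
scans per subject,

    σ1_r = mean_s Var({i_{s,r,1}, i_{s,r,2}})      (within-subject)
    σ2_r = Var_s( (i_{s,r,1}+i_{s,r,2})/2 )        (between-subject)
    ICC_r = σ2_r / (σ1_r + σ2_r).

Sample variance (n−1) is used throughout; with two scans and an equal
design the ICC ratio is convention-invariant, but σ values themselves need
the convention fixed. This is the plain variance-ratio ICC, not the ANOVA
ICC(2,1); for more than two scans the same formulas apply with the
per-subject variance over all scans (an extension beyond the two-scan
design). Reporting bands: < 0.4 poor, 0.4–0.75 fair-to-good, > 0.75
excellent — labels only, no computation depends on them.

## Rich club and edge density

Rich nodes default to the top 15% of nodes by binary degree, with a
weighted-degree option and an explicit-set override as the primary pathway
(the synthetic generator knows its planted hubs). Edges are rich-club (both
endpoints rich), feeder (exactly one), or local (neither); only nonzero
edges are classified. A density map counts, per voxel, the edges of a class
whose consensus mask covers it; the RC, FC, and LC maps sum voxelwise to the
all-edges map by construction. Density and importance maps are compared by
Pearson correlation over a white-matter mask with a Fisher-z 95% CI.
Normalized rich-club coefficients against rewired nulls are out of scope.

## Callosotomy and callosal agenesis

The corpus callosum is modelled as the midsagittal plane x = x₀ (default
0): an edge is callosal if its consensus mask contains a voxel whose centre
lies within half an x-spacing of the plane. A virtual callosotomy zeroes
callosal edges entirely (exclusion-mask semantics — streamlines through the
callosum are removed — rather than proportional weakening). Group
comparison extracts each subject's normalized second eigenvalue after
matching to the control-group mean connectome's mode 2, reports group means
with t-based 95% CIs, and runs pairwise two-sample t-tests at α = 0.05
without multiple-testing correction. Mode *splitting* is declared for a
control mode when (a) it projects substantially onto two lesioned modes
(each |inner product| ≥ 0.35; an exact half-half split gives 1/√2 ≈ 0.71
each — the floor rejects spurious "splits" where the second-best match is
noise) and (b) those two modes each carry ≥ 0.9 of their squared mass in
opposite hemispheres (the block-diagonal limit gives exactly 1.0; 0.9
tolerates residual coupling).

## Synthetic data: what it emulates, what it does not

The generator produces the statistical structure the analyses assume, not
diffusion-MRI physics:

- **Geometry.** 80 regions (40 per hemisphere) mirrored about x = 0 on a
  64³ grid at 2 mm. Node clouds have brain-like anisotropy
  (anterior–posterior > superior–inferior > per-hemisphere medial–lateral
  extent), which separates the slow intrahemispheric gradient modes the way
  real connectome spectra are separated; an isotropic cloud would leave
  modes 3–5 nearly degenerate like the harmonics of a square membrane.
  Centroids keep a minimum separation of 12 mm — regions of ~100 voxels
  (800 mm³, equivalent-sphere diameter ≈ 11.5 mm) cannot overlap — which
  also keeps every edge longer than one lesion diameter.
- **Connectivity.** Connection probability and expected streamline count
  decay exponentially with distance (e-folding 30 mm); interhemispheric
  pairs are attenuated ×0.2 (the callosal bottleneck that makes left–right
  diffusion the slowest mode); homotopic mirror pairs are always connected;
  counts between planted hub pairs are boosted ×3 (×√3 for hub–non-hub).
  Directed counts are Poisson draws (≥ 1 on the support).
- **Trajectories.** Polyline routes between centroids — straight within a
  hemisphere, a superior midline bend for callosal edges (guaranteed to
  contain x = 0 voxels), an inferior detour that excludes the midline voxel
  column for non-callosal commissural routes — dilated into tubes of radius
  4 mm. The tube radius matters: white-matter bundles have finite
  cross-sections, and the importance method assumes a 12 mm lesion removes
  only a modest fraction of an edge's volume; 1-voxel-thin trajectories
  would invert that regime.
- **Cohorts.** All subjects share one template (atlas-like common
  geometry, edge support, routes); per-subject streamline counts carry a
  per-edge log-normal subject effect (σ = 0.2) and each scan multiplies the
  latent weights by log-normal noise (σ = 0.1, re-symmetrized) — so
  between-subject variance exceeds within-subject variance, as in
  test–retest designs. Noise is multiplicative because streamline densities
  are positive and right-skewed; additive Gaussian noise would break
  non-negativity.
- **Callosal-agenesis variant.** Callosal edges are zeroed and a fraction
  c ∈ [0, 1] of each removed weight is restored on the same node pair via a
  detour trajectory avoiding the midline column, emulating compensatory
  non-callosal routes; c may not exceed 1 (no more weight restored than
  removed).
- **Toy atlas.** The union of consensus masks partitioned into 8 spatial
  octant blocks by coordinate medians — a desk-scale stand-in for a
  48-tract white-matter atlas, synthetic and not anatomically meaningful.

A green test on this world establishes that the pipeline's spectral logic,
matching, lesion bookkeeping, and statistics behave as specified under the
stated structure; it does not validate tractography, registration, or any
anatomical claim.

## Numerical choices

- Symmetry, row-sum, and PSD checks at 1e-9 relative tolerance
  (double-precision eigensolves are accurate to ~1e-14).
- Eigenvalues sorted ascending with stable ties; eigenvector signs fixed by
  making the largest-magnitude entry positive, for reproducible output.
- acos arguments clipped to [−1, 1]; connected-component counting uses a
  relative threshold on eigenvalues.
- Consensus-mask thresholding keeps ceil(0.95 · n) voxels per direction —
  the highest-count 95% of the *non-zero voxels*, not 95% of streamline
  mass, because voxels are what is counted; configurable.
- All randomness flows from `numpy.random.SeedSequence` substreams: one
  root seed reproduces a whole cohort or pipeline run bitwise.

## Known limitations

- Single-subject importance maps at desk scale are noisier than
  cohort-averaged maps: a 12 mm lesion on a ~300-voxel edge mask removes a
  far larger volume fraction than on real millimetre-resolution tract
  masks, so at full stoppage a handful of voxels leave the small-
  perturbation regime. Where that mixes near-degenerate modes (3–4), the
  argmax-inner-product matching can jump between eigenvalue branches,
  producing isolated outliers (including occasional negative matched
  importance, reported unclipped). Same-mode map correlations across
  stoppage settings are therefore ≥ 0.999 for mode 2 but range ~0.75–0.999
  for modes 3–4 depending on the generator seed — a handful of voxels out
  of thousands drive the low values, and removing the single worst voxel
  restores r ≥ 0.99.
- The stoppage-sweep Pearson correlations are computed on one connectome's
  evaluated lesion-centre voxels, not on cohort-averaged registered maps.
- No tractography-level lesioning: streamlines are not re-tracked around a
  lesion (edge weights are scaled instead).
- The generator plants the structure the rank-property tests check (hubs,
  callosal bottleneck, AgCC compensation); those tests are
  generator-conditional consistency checks, not external validation.
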