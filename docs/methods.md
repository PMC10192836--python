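# Methods

## The synthetic cohort model

The generator stands in for a multi-run surface-fMRI cohort at desk
scale. Its pieces, and what each emulates:

**Mesh.** A connected graph replaces the cortical surface: a ring, a
4-neighborhood lattice (default), or a subdivided icosahedron (degrees
5–6, vertex counts 10·4^s + 2; a request is snapped up to the smallest
admissible count). No geometry beyond adjacency is used downstream, so
graph distance plays the role of geodesic distance.

**Topography.** A group atlas of `K_group` contiguous parcels is grown
by seeded multi-source BFS (graph Voronoi). Each parcel is assigned to
one of `n_latent` latent functional networks (every network used).
Soft latent maps are distance-kernel smoothings of the network regions,
`w(v, l) ∝ exp(−d(v, region_l)/scale)`, rows normalized to 1.
Individual topography is produced by a seeded boundary random walk of
length `topo_shift`: each step reassigns one boundary vertex to a
neighboring parcel if the donor parcel stays nonempty and contiguous.
The expected displaced-boundary mass grows with `topo_shift`, which is
the sense in which individual-specific topography is "stronger" at
higher values.

**Time series.** A run is `X = A·S + E`: `A` the subject's
vertex-by-latent loading matrix (the smooth soft maps by default;
one-hot hard assignments are available), `S` stationary AR(1) latent
series with lag-1 autocorrelation `ar_coef` and stationary covariance
equal to the subject's latent correlation matrix, `E` iid Gaussian with
`noise_sd`. Exactly `⌊censor_frac·T⌋` random frames per run are
censored; a fraction ≥ 0.5 is rejected outright, mirroring the
convention of discarding majority-censored runs. Censoring is uniform
rather than motion-locked — only the bookkeeping (masks, retained-frame
counts) matters to the downstream contracts.

**Individual connectivity.** With shared latent dynamics the model
would produce no between-subject connectivity differences, so each
subject receives their own latent correlation matrix: the group matrix
plus a symmetric Gaussian perturbation of scale `fc_sd`, eigenvalue-
clipped and rescaled back to a valid correlation. The strictly-lower
triangle of this matrix is the subject's ground-truth edge vector.

**Behavior and confounds.** Each behavior is
`y = √es·z(edges·β) + √cs·z(C·γ) + √(1−es−cs)·ε` with `β`, `γ` drawn
once per behavior and recorded. `es` (`effect_size`) is therefore the
expected variance share explained by true connectivity — an OLS oracle
on the ground-truth edges recovers it to Monte-Carlo accuracy at
n ≥ 500 — and `cs` (`confound_share`) the share carried by the
confounds. Confounds are age ~ U(20, 40), sex ~ Bernoulli(0.5), and
lognormal FD/DVARS motion summaries. Families and site clusters are
balanced random partitions (sizes differing by at most one).

**Defaults.** 200 subjects, 500-vertex lattice, 4 runs × 200 frames,
6 latent networks over 20 parcels, `ar_coef` 0.3, `noise_sd` 1.0,
`censor_frac` 0.1, `topo_shift` 5, `fc_sd` 0.25, `effect_size` 0.3,
`confound_share` 0.1, 100 families, 9 site clusters. These are the
study conditions used by the acceptance checks; run lengths are chosen
as plausible desk-scale stand-ins, not as a claim of fidelity to any
specific acquisition protocol.

What the generator does **not** emulate: hemodynamics, spatially
structured noise, motion artifacts beyond scalar covariates, surface
geometry, scanner/site effects on the signal itself (site labels are
pure grouping structure), and non-linear behavior–connectivity
coupling. Passing tests show the pipeline recovers planted linear
signal under these idealized conditions; they say nothing about
robustness to the real artifacts listed above.

## Feature construction

**Node time series.** Hard parcellations average vertices within each
parcel; soft parcellations use stage-1 dual regression (per-frame least
squares of the vertex pattern onto the spatial maps). In both routes,
censored frames are dropped and every node series is z-normalized per
run before concatenation, so run-mean offsets cannot masquerade as
connectivity and run order is irrelevant.

**Individualization.** The boundary-refinement loop reassigns each
boundary vertex to the adjacent parcel whose mean time course
correlates best with the vertex, keeping parcels contiguous and
nonempty, for up to `n_iter` iterations (default 3) or until a fixed
point. Because parcel means move between iterations, a raw k-means-like
sweep could in principle lower the global mean vertex-to-parcel
correlation; an iteration that would do so is rolled back and the loop
stops, making monotone non-degradation a property of the returned
labeling rather than a hope.

**Connectivity.** Full correlation is plain Pearson. Partial
correlation follows the ridge-regularized recipe: covariance scaled by
the RMS of its diagonal, precision of (C + ρI), partials
`−P_ij/√(P_ii P_jj)`. Default ρ = 0.1; ρ = 0 is permitted only for
well-conditioned covariance and reproduces classical partial
correlation (verified against a residualization oracle). No r-to-z
transform is applied before vectorization (exposed as a choice point;
left off because it only rescales features monotonically and the
similarity kernel is nearly invariant to it). Vectorization takes the
strictly-lower triangle in column-major order — any fixed order would
do; this one is frozen and recorded in the feature sidecar.

**Gradients.** Vertex connectivity profiles (correlations against all
vertices, a subset, or parcel means) are row-thresholded to the top
`sparsity` fraction (default 10%), and the affinity is the cosine
similarity of thresholded rows clamped at zero. The embedding uses
anisotropic normalization α = 0.5, eigen-decomposes the random-walk
operator through its symmetric conjugate, drops the trivial constant
eigenvector, rescales eigenvectors to unit norm, and scales component
i by λᵢ/(1−λᵢ) (diffusion time t = 0; other t exposed but not the
default). Signs are fixed by making each component's largest-magnitude
entry positive, so embeddings are reproducible before alignment. A
disconnected affinity graph triggers a warning and restriction to the
largest component. The group template is the embedding of the
cohort-average affinity; individuals are aligned to it by orthogonal
Procrustes (rotation/reflection only — no scaling or translation, so
eigenvalue-scaled magnitudes survive alignment).

**Local gradient.** The similarity matrix of profiles is differentiated
on the mesh: per reference column, the per-vertex RMS difference across
graph neighbors, averaged over reference columns. Graph differences
replace surface-geodesic derivatives deliberately — there is no true
geometry at desk scale. No watershed/edge-thinning step follows: the
raw magnitude map itself is the feature vector.

## Prediction

The KRR predictor is the similarity-weighted average of training
scores with an L2 penalty, solved in dual form
`α = (K + λI)⁻¹(y − ȳ)` on the training-mean-centered target; the
kernel is the Pearson correlation between subjects' feature vectors and
is not otherwise centered, keeping the fitted model interpretable as a
shrunken similarity-weighted average. LRR standardizes features with
training statistics and uses the closed-form ridge solution (the
single-λ path goes through scikit-learn; the λ-sweep inside the inner
loop reuses one SVD, and the two paths agree to numerical precision).

Hyperparameter grids: KRR λ ∈ {0, 1e−5, 1e−4} ∪ {0.001 : 0.003 : 1} ∪
{1.5 : 0.5 : 4} ∪ {5, 10, 15, 20}; LRR λ ∈ {0.05 : 0.05 : 1}.
Resolution grids default to 100–1000 (step 100) for the hard-parcel
routes, {50, 100, 200, 300} for the soft route, and
{1, 5, 10, 20, 40, 60, 80, 100} gradients; the local gradient has a
single map and enters as a one-point grid.

The outer loop is either family-preserving repeated k-fold (families
shuffled, then greedily packed into the currently smallest fold, so
fold sizes balance and no family is split; a family larger than n/k is
kept whole with a warning) or the full enumeration of
leave-`p_out`-of-n site-cluster splits. The inner loop is 10-fold
grouped CV on the training subjects (k-fold scheme) or
leave-one-training-cluster-out (site scheme). Every (resolution, λ)
pair is scored by mean inner-fold Pearson r; ties break toward smaller
λ, then smaller resolution. Confound regression and the behavior's
z-normalization are fit inside each training split and applied —
never refit — to the corresponding validation or test subjects, so no
statistic of a test fold ever touches training-side state. Constant
predictions (possible at extreme shrinkage) are recorded as accuracy 0
with a flag rather than NaN.

Accuracies are averaged over folds and replications with equal weight
(fold sizes vary by at most the grouping granularity; a size-weighted
mean was considered and rejected as a second-order refinement).
Category summaries average the fold-mean accuracies of member
behaviors; the per-fold category-mean series is retained because the
statistical comparisons need paired fold-level differences, not
behavior-level summaries.

## Statistical comparison

Fold accuracies from resampled CV are positively correlated across
folds (training sets overlap), so the per-fold variance understates the
sampling variance of the mean difference. The corrected resampled
t-test divides the mean difference by
`√((1/(k·r) + n₂/n₁)·σ̂²)` with k·r − 1 degrees of freedom, where
n₂/n₁ is the test/train size ratio of a typical fold — taken as the
modal fold sizes for k-fold, and the modal (≈ mean) sizes across the
enumerated site splits. The package also exposes the uncorrected
statistic purely as a foil: under a simulated null with two
equal-quality feature sets, the corrected test rejects at ≈ the nominal
5% while the naive test rejects an order of magnitude more often (this
is an acceptance check, recomputed at every test run).

Pairwise approach comparisons are run on per-fold category-mean
accuracy differences over matched folds; BH-FDR at q = 0.05 is applied
across all unique cells of a comparison matrix jointly (mirroring
report-wide correction). Cells are displayed as signed −log10(p) with
non-significant cells zeroed (plotted black). A category compared with
itself yields an identically zero difference series and is reported as
(t, p) = (0, 1) rather than an error, since the degenerate-variance
guard is meant for accidental constants, not self-comparison.

## Problem sizes used by the checks

The recovery and pattern checks run the default 200-subject cohort with
5 replications × 5 folds and the full KRR λ grid; the type-I study uses
300 null cohorts of 60 subjects with 10 × 5-fold CV. These sizes were
chosen so the whole suite runs comfortably on a single CPU while
leaving the Monte-Carlo bands (binomial CI for the type-I rate, ±0.05
slack on monotonicity) wide enough to be meaningful.

## Known limitations

- The individualization stage is a deliberately simple boundary
  refiner, not a hierarchical Bayesian model; it shares the interface
  and the recovery-direction behavior, not the statistical machinery.
- Spatial ICA estimation is out of scope: soft maps come from the
  generator (or smoothed hard parcels), and only stage-1 dual
  regression is implemented — stage-2 subject maps are never needed for
  network-matrix features.
- The embedding's affinity recipe (top-10% rows, cosine, α = 0.5)
  follows the standard diffusion-map literature; alternatives (PCA,
  Laplacian eigenmaps) are intentionally absent.
- All behavioral coupling is linear with Gaussian noise; effect sizes
  are variance shares, so accuracy ceilings are ≈ √es.
- `n2/n1` in the corrected test is a single typical ratio; schemes with
  strongly unequal cluster sizes stretch that approximation.
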