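# Methods

This note documents the models, parameters and design choices behind
`gliotex`, what the synthetic cohorts do and do not emulate, and the
numerical conventions the implementation fixes.

## Descriptor model (`lbp3d`)

**Sphere sampling.** Neighborhood directions come from a deterministic
Fibonacci spiral, giving near-uniform coverage with no randomness. The
default is `n_dirs = 64` per radius. Fewer directions are cheaper but make
the harmonic projection of the *binarized* (discontinuous) neighborhood
function noticeably orientation-dependent: the median relative band-norm
deviation between a textured volume and its 90°-rotated copy is ≈ 6% at 32
directions and ≈ 3.5% at 64, roughly following 1/√n_dirs. 64 keeps this
grid-rotation error under 5% while the degree-3 fit (16 coefficients)
remains well over-determined. The fast profile drops to 16 directions —
an exactly determined fit — trading rotation robustness for a 4× cheaper
extraction, which is acceptable when the descriptors feed a dictionary
rather than being interpreted individually.

**Radii.** 1, 2 and 3 mm, interpreted in world coordinates: at the 2 mm
isotropic spacing the analysis targets, the inner spheres are sub-voxel,
so intensities are sampled by trilinear interpolation with replicate
padding at image borders. Descriptors from the three radii are
concatenated.

**Binarization.** A neighbor maps to 1 iff strictly more intense than the
center voxel; ties map to 0. Values within a relative tolerance of 1e-12
count as ties so that interpolation round-off on locally constant data
cannot flip bits. Binarization makes the descriptor invariant to positive
affine intensity rescaling, which is the point: DTI intensity scales are
scanner-dependent, relative structure is not.

**Harmonic fit.** Real orthonormal spherical harmonics up to degree
L = 3; coefficients via a precomputed pseudo-inverse of the design matrix
(shared across radii, since all radii use one direction set). The
per-degree coefficient norms are exactly invariant under rotations for
band-limited inputs (verified to 1e-8 against analytically rotated
functions) and approximately so for binary inputs. The descriptor per
radius is the 4 band norms plus the Pearson kurtosis (m₄/m₂², not excess;
population moments; defined as 0 for zero-variance neighborhoods) of the
raw intensities — 15 values per voxel in total.

## Texture dictionary (`texture_dictionary`)

Training-cohort voxel descriptors are z-scored per dimension
(zero-variance dimensions get SD 1) and clustered with k-means: k = 50 per
channel, k-means++ initialization, 10 restarts, Lloyd iterations to
relative inertia tolerance 1e-6 (max 300), best inertia kept, fixed seed.
Standardization is fitted on the same training voxels and stored in the
dictionary so that assignment — nearest centroid in standardized Euclidean
distance, ties to the lowest index — is identical at training and
validation time. Validation descriptors never update centroids or the
standardizer. Each dictionary records a fingerprint of the descriptor
configuration and refuses descriptors computed under a different one.
Serialization is lossless (base64-encoded float64).

In the fast profile, dictionary learning subsamples the stacked training
descriptors to at most 100 000 rows (seeded, without replacement) purely
to bound k-means cost; assignment still covers every tumor voxel.

## Features and split (`feature_assembly`)

A tumor's feature row is its mask voxel count (a raw count, not mm³)
followed by the 50 + 50 relative pattern occurrences — 101 features. The
cohort splits 3:1 by simple label-blind randomization with validation size
`round(n/4)`, so 79 patients give 59/20. No stratification: across seeds
the validation genotype fraction fluctuates around the cohort fraction,
mirroring the chance imbalance such a design produces.

## Classifier (`neural_classifier`)

One hidden layer of logistic units, one logistic output. Inputs are
z-scored with training-row statistics (voxel count is orders of magnitude
larger than frequencies; without scaling the optimization is badly
conditioned). Training minimizes the summed cross-entropy plus
λ·Σw² — the penalty covers all connection weights but not biases — by
full-batch L-BFGS (max 500 iterations, gradient tolerance 1e-6), from
uniform(−0.5, 0.5) initial weights drawn from the training seed; the
analytic gradient is verified against finite differences in the test
suite. Non-convergence returns the best iterate with a logged warning.

`size` (hidden units) and `decay` (λ) are tuned by grid search — default
sizes {2, 4, 6, 8, 10} × decays {1e-4, 1e-3, 1e-2, 1e-1}; fast profile
{2, 6} × {1e-3, 1e-1} — scored by mean accuracy over 5×-repeated
stratified 5-fold cross-validation on the training cohort. Resampled
rather than resubstitution accuracy avoids degenerate selection of the
largest network. Ties prefer the smaller size, then the larger decay.
Prediction labels mutant when p ≥ 0.5 (boundary inclusive).

Garson importance for input *i*:
Q_i = Σ_j |W_ij|·|v_j| / Σ_k |W_kj|, normalized to percentages (biases
excluded). It is a weight-magnitude heuristic, not a causal decomposition;
the suite checks only its defining algebra and a rank-ordering sanity
property.

## Cohort statistics (`cohort_stats`)

- Fisher 2×2: two-sided point-probability method (sum of hypergeometric
  probabilities ≤ the observed one, relative slack 1e-7, log-space),
  matching the convention of mainstream exact-test implementations; checked
  against exact-rational enumeration on all tables with total ≤ 12.
- Rank-sum: exact permutation null when n₁+n₂ ≤ 20 without ties,
  otherwise the tie-corrected normal approximation with continuity
  correction; checked against full enumeration.
- Binomial tail P(X ≥ k): direct summation; used against the
  no-information rate of the validation cohort.
- Welch t with Satterthwaite degrees of freedom.
- ROC/AUC: Mann-Whitney pair counting with ties at 0.5; curve swept at
  midpoints between consecutive unique scores.
- Univariate logistic regression by IRLS (max 50 iterations, tolerance
  1e-8); complete separation is detected by a diverging linear predictor
  (|η| > 30) and resolved by a ridge fallback (λ = 1e-6), flagged in the
  output.
- PCA: column-centered SVD, component signs fixed so the
  largest-magnitude loading is positive.

## Synthetic cohorts (`synthetic_cohort`)

The generator emulates the statistical skeleton the analysis needs:

- **Composition**: n = 79 patients, P(mutant) = 0.77.
- **Geometry**: 64³ grids at 2 mm isotropic spacing; ellipsoidal masks
  with axis ratios uniform in [0.7, 1.3] rescaled to unit geometric mean
  (volume-preserving) and ±2 voxels of center jitter.
- **Size effect**: equivalent-sphere radii drawn per genotype from
  truncated normals (means 12 vs 9 voxels, SD 2, floor 3) — mutant tumors
  larger, detectable by the rank-sum test in ≥ 90% of seeds.
- **Texture effect**: inside the mask, intensity is a constant offset plus
  a unit-variance Gaussian random field made by smoothing white noise with
  a genotype- and channel-specific scale (defaults 2.0 voxels for mutant,
  0.5 for wild type, both channels). Normalizing to unit variance makes
  correlation *length* — not amplitude — the discriminating property,
  which is what the band-energy descriptors respond to. Backgrounds are a
  broad brain-like Gaussian blob plus iid noise; FA is clipped to [0, 1].
  Absolute intensity levels are free parameters (B0 ≈ 100 a.u., FA ≈ 0.4)
  since binarized descriptors only see relative structure.

All randomness derives from a single integer seed through spawned
generator streams, so cohorts are bit-reproducible and each patient's data
is independent of cohort size.

What the generator does **not** emulate: anatomy, diffusion tensor
physics, bias fields, motion, partial-volume effects, multi-site
variation, or any coupling between genotype and tumor location. Passing
tests therefore demonstrate that the pipeline recovers planted
size/texture signals of plausible magnitude — not clinical performance on
real MRI.

One consequence of the geometry worth stating: texture histograms are
*never* fully independent of tumor size, because the fraction of
boundary-adjacent voxels (whose neighborhoods straddle the mask edge)
scales like 1/r. Size-ablated texture experiments are honest, but
texture-ablated *size* experiments are not possible at the image level;
the importance-ranking sanity experiment therefore constructs its
size-only cohorts at the feature-row level (genotype-dependent voxel
counts, genotype-independent Dirichlet histograms).

## Pipeline (`pipeline`, `cli`)

Stages run in the order simulate → extract → split → learn-dict →
featurize → train → evaluate → report. The split precedes dictionary
learning so that centroids, standardizers and tuning only ever see
training-cohort data; the manifest records the patient ids each
training-side stage consumed, and a test asserts no validation id appears
there. Each stage skips itself when its outputs exist (restartability);
SHA-256 hashes of all artifacts make determinism checkable. Volumes are
written as uncompressed NIfTI-1 (`.nii`) with spacing in the header so
artifacts are byte-stable across runs; `.nii.gz` is accepted on input.
Masks binarize at > 0.5 on read, so any positive integer label counts as
foreground.

The `fast` profile changes problem sizes only, never algorithms: 16
sampling directions, the reduced tuning grid, and the 100k-row dictionary
subsample. Cohort dimensions (grid, n) always come from the cohort spec.
Reported experiment scales in the test suite: the study-analogue runs use
the full 79-patient cohort at 64³ with the fast profile (≈ 1 minute per
seed); unit tests use 8-24-patient cohorts on 28³-48³ grids.

## Known limitations

- The descriptor's rotation invariance is exact only for band-limited
  functions; for binarized neighborhoods it is approximate, with the
  residual set by the direction count (see above).
- Garson importance is unstable under strongly correlated inputs; the
  101 features are compositional (each histogram block sums to 1), so
  per-feature percentages should be read as a ranking, not as effect
  sizes.
- With 20 validation cases, accuracy and AUC have wide sampling
  variability; the exact binomial test against the no-information rate is
  the guard against over-reading them.
- k-means with 10 restarts is deterministic given the seed but not
  guaranteed to find the global optimum; dictionaries are therefore part
  of the serialized model state, not re-derivable from data alone.
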