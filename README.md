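# gliotex

Radiogenomic texture analysis for predicting *IDH* genotype in WHO grade
II/III ("lower-grade") gliomas from diffusion tensor imaging.

*IDH* mutational status separates lower-grade gliomas into two biologically
and prognostically distinct diseases, and knowing it *before* surgery can
change the resection strategy. `gliotex` implements a non-invasive
classifier for this decision: it quantifies whole-tumor texture in two
co-registered DTI-derived channels — the T2-weighted B0 image and the
fractional anisotropy (FA) map — and feeds it, together with tumor size, to
a small neural network. Because clinical MRI with genotype labels cannot be
redistributed, the package ships a seeded synthetic cohort generator with
the same statistical structure (genotype imbalance, larger mutant tumors,
genotype-dependent texture), so the entire analysis is runnable and
testable end to end out of the box.

## Method

For every voxel **p** inside the whole-tumor mask, intensities are sampled
at *n* directions on spheres of radius *r* = 1, 2, 3 mm around **p**
(trilinear, in world coordinates) and binarized against the center
intensity — a 3D local binary pattern. The binary function *b(θ, φ)* on
each sphere is least-squares projected onto real spherical harmonics
*Y*<sub>*lm*</sub> up to degree *L* = 3,

> *b* ≈ Σ<sub>*l*≤*L*</sub> Σ<sub>*m*</sub> *c*<sub>*lm*</sub> *Y*<sub>*lm*</sub>,

and summarized by the per-degree coefficient norms
‖*c*<sub>*l*·</sub>‖₂ — invariant to rotations of the neighborhood — plus
the Pearson kurtosis of the raw neighborhood intensities: a 15-dimensional
descriptor per voxel. Descriptors from all training-cohort tumor voxels
are clustered per channel with *k*-means (*k* = 50); the centroids are the
"learned texture patterns", and each tumor is represented by the relative
occurrence of each pattern among its voxels. The final feature vector has
**101 entries**: mask voxel count + 50 B0 pattern frequencies + 50 FA
pattern frequencies.

A cohort is split 3:1 (79 patients → 59 training / 20 validation). A
single-hidden-layer network with logistic activations and one logistic
output is trained on the training cohort by penalized maximum likelihood
(cross-entropy + weight decay λ‖**w**‖²), with hidden-layer `size` and
`decay` tuned by grid search under repeated stratified 5-fold
cross-validation. Per-feature relevance is summarized with Garson's
algorithm. Validation metrics are accuracy, ROC AUC, and an exact binomial
test against the no-information rate; tumor size is analyzed with the
Wilcoxon rank-sum test and a univariate logistic model.

## Worked example

Write a config and run the whole pipeline (simulate → extract descriptors →
split → learn dictionaries → featurize → tune/train → evaluate → report):

```yaml
# config.yaml
output_dir: run
profile: fast
cohort: {n_patients: 20, mutant_prob: 0.65, grid_shape: [40, 40, 40],
         mutant_size_mean: 8.0, wild_size_mean: 6.0, size_sd: 1.5, seed: 42}
k: 16
dict_seed: 42
split_seed: 42
train_seed: 42
tuning: {sizes: [2, 4], decays: [0.001, 0.1], seed: 42}
```

```sh
gliotex run-all --config config.yaml
cat run/report.md
```

which prints (abridged):

```
# Radiogenomic pipeline report

- Final network: 2 hidden units, decay 0.1
- Training accuracy: 1.000 (AUC 1.000)
- Validation accuracy: 1.000 (AUC 1.000)
- No-information rate 0.800; exact binomial p = 0.3277
- Tumor size, mutant vs wild type: rank-sum p = 0.08062
- Size-only logistic AUC: training 0.818, validation 0.500
- Genotype-by-cohort Fisher p = 1.000
```

Reading this: the tuned network separates the genotypes perfectly in both
cohorts of this 20-patient toy run, but with only 5 validation cases the
exact binomial test cannot distinguish that from always guessing the
majority class (p = 0.33) — at the study's scale (79 patients, below) the
same test is decisive. The mutant-vs-wild-type size difference trends in
the expected direction (rank-sum p = 0.081), yet a logistic model on size
alone is no better than chance on the held-out cases (AUC 0.5):
discrimination needs the texture features. Every stage is cached in
`run/`, every artifact hash is recorded in `run/manifest.json`, and
re-running with the same config reproduces all outputs byte for byte.

The same stages are available individually (`gliotex simulate`,
`extract`, `learn-dict`, `featurize`, `split`, `train`, `evaluate`,
`report`) and as library functions (`gliotex.lbp3d`,
`gliotex.texture_dictionary`, `gliotex.neural_classifier`,
`gliotex.cohort_stats`, ...).

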