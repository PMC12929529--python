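# Methods

## Problem and model

`prommf` classifies a patient's microsatellite status (MSI vs MSS, with MSI
the positive class) from two paired modalities: a *bag* of histology tile
embeddings (one 2048-dimensional vector per tile, as produced by the
global-average-pool layer of a pretrained 50-layer residual CNN) and a bulk
gene-expression profile. MSI status predicts benefit from immune-checkpoint
inhibition, and in stomach adenocarcinoma roughly 22% of patients are MSI,
which sets the class prevalence used throughout the synthetic studies.

### Image branch: gated attention MIL

Tiles carry no individual labels, so the image branch is a
multiple-instance learner. Each instance h is projected by a linear layer
to 512 dimensions and scored by a gated attention head

    a_m ∝ exp( wᵀ ( tanh(V h_m) ⊙ σ(U h_m) ) ),

normalised by a softmax over the patient's own bag (bags never mix
patients, consistent with batch size 1; the softmax subtracts the maximum
logit for overflow safety). The patient representation is the
attention-weighted sum h_patient = Σ_m a_m h_m. The attention weights are a
point on the simplex, the pooling is permutation-invariant in the bag, and
every coordinate of the pooled vector lies in the convex hull of the
instance values — all three are enforced by tests. The published form of
the gate writes a transpose on one branch's argument; both branches here
act on the same column vector h_m, the only shape-consistent reading. The
attention hidden width L defaults to 256 (configurable); dropout sits after
the instance projection.

### Expression branch

Raw counts are converted to TPM (CPM with a logged warning when gene
lengths are unavailable), log2(x+1)-transformed, and z-scored per gene with
moments estimated on the *training* patients only; zero-variance genes are
zeroed and flagged. Feature selection is a differential-expression screen
on the training split: genes with logFC > 2 and p < 0.05 are "up",
logFC < −2 and p < 0.05 "down" (both inequalities strict; nominal p-values
by design — the screen selects candidate features for a classifier, not a
biological gene set). logFC is log2 of the ratio of group means of
library-size-normalised counts with pseudocount 1 (raw, not shrunken). The
per-gene test is pluggable: Welch's t on log2 normalised counts (default)
or Wilcoxon rank-sum; a DEG table computed by external tooling can be
imported instead. If the screen selects nothing, a configurable top-k by
p-value fallback keeps the model runnable. Total-count library
normalisation is slightly biased under strongly asymmetric DE
(composition bias); with transcriptome-scale gene counts the effect is
negligible, and the importer exists for users who want a dedicated DE
package's normalisation.

### Fusion

Both branches are reduced to 32-d non-negative vectors (linear + ReLU for
the image side; a small MLP, 128 hidden units, then linear + ReLU for the
expression side). Two fusion operators:

* **Kronecker**: append 1 to each unimodal vector and flatten the outer
  product [h;1][g;1]ᵀ row-major into a 1089-vector. The last column of the
  33×33 matrix is the augmented histology vector and the last row the
  augmented expression vector, so fusion preserves unimodal information
  exactly while the remaining entries carry all pairwise cross-modal
  products.
* **Concat**: plain concatenation (histology block first, 64-d).

**Progressive (back-projection) refinement** maps the fused vector back to
each 32-d unimodal space through two learned affine maps, adds these
context vectors to the *original* unimodal features (unscaled addition),
and fuses again:

    f⁰ = fuse(h, g);   for t = 1..T:  (ĥ, ĝ) = backproject(f^{t−1}),
                                      f^t = fuse(h + ĥ, g + ĝ).

T counts refinement cycles after the initial fusion and is restricted to
1–5 with default 2 (the value that won the original hyperparameter search).
Back-projection weights are shared across iterations by default — the
unrolled refinement reads most naturally as a recurrent map — with a
per-iteration-weights switch for the alternative reading. The maps are
initialised at zero, so optimisation starts exactly at the single-pass
fusion model and learns the refinement; with the parameters at zero the
progressive model *equals* plain MMF for every T, which is both a test and
the model's adaptability story. The classifier head on the fused vector is
one hidden layer (64, ReLU, dropout 0.1) and a sigmoid.

Unimodal baselines: AMIL (pooled image vector into the same head shape) and
DMLP (expression MLP, 128→32, ReLU + dropout). Late fusion combines the two
unimodal probabilities as w·p_image + (1−w)·p_omic with w = 0.5 by default
or tuned on the validation split by AUC grid search (never on test data).

### Training protocol

Adam with learning rate 1e-4 and weight decay 5e-3 (L2 folded into the
gradient, the common framework convention), binary cross-entropy on the
logit (computed in the numerically stable log1p(exp) form), 100 epochs by
default, batch size 1 because bags differ in size, dropout 0.1. Each epoch
visits every training patient once in a fresh random order. When a
validation split exists, the checkpoint with the best validation AUC is
kept (the protocol leaves selection unstated; the validation split exists,
so it is used). An optional per-step tile cap subsamples large bags anew at
each visit. All randomness — initialisation, epoch order, dropout masks —
derives from one integer seed; two runs with the same seed are
bit-identical.

Patient-level splitting: shuffle patient ids at a fixed seed (2024 by
default) and cut 6:2:2 as floor/floor/remainder — 282 patients give
(169, 56, 57). Every tile and expression profile inherits its patient's
partition. The split is unstratified by default, mirroring a plain random
patient split; a stratified switch exists for small cohorts. k-fold CV
builds seeded patient-level folds (refolded with stratification if a fold
would miss a class) and reports per-fold AUC/precision/recall/F1 with
mean ± sample SD. A no-leakage audit checks on every finished run that the
DEG selection and the z-score moments reference training patients only.

### Networks without a deep-learning framework

All models run on a small reverse-mode autodiff core written on NumPy
(`prommf._tensor`, `prommf.nn`): a Tensor type recording the computation
graph for the dozen operations the models need, verified against finite
differences. The networks here are small (hundreds of thousands of
parameters, batch size 1), so this keeps the dependency surface to the
scientific Python stack. The gated-attention pooling additionally has a
pure-NumPy functional surface (`histomil.pool_bag` etc.), and the test
suite checks the two paths compute the same map.

## Paired model comparison

Two models scored on the same test patients are compared with:

* **Paired bootstrap** (default 2000 replicates): resample patient indices
  with replacement, apply the *identical* index vector to both score
  vectors, recompute both AUCs per replicate; 95% CIs by the percentile
  method (2.5th/97.5th). Single-class resamples are redrawn and counted.
* **Paired permutation test** (default 5000 replicates): each permutation
  independently swaps each pair's two scores with probability 0.5; the
  statistic is the mean per-patient score difference, two-sided p with
  add-one smoothing so p > 0. Comparing AUCs through mean score differences
  is an unusual choice; it is implemented literally as specified, and a
  recomputed-AUC-difference statistic is available behind
  `statistic="auc_difference"` for users who prefer it.
* **Paired Cohen's d**: mean difference over its sample SD (ddof 1);
  zero-SD cases are reported as undefined with the sign, never silently
  numeric.
* **Parametric Monte-Carlo power**: simulate paired differences from
  Normal(observed mean, observed SD²) and count replicates whose one-sample
  two-sided t statistic exceeds the critical value at α = 0.05.

AUC itself is the Mann-Whitney statistic with ties counting 1/2 (sklearn's
implementation, cross-checked against brute-force pair counting in tests;
a vectorised midrank implementation serves the resampling loops).
Precision/recall/F1 default to threshold 0.5 with zero-denominator cases
flagged as 0; subgroup metrics reuse the global definitions per group and
omit AUC (flagged) where a group lacks a class.

Calibration of this machinery is itself tested: empirical size of the
permutation test within the 99% binomial band of α = 0.05 over 500 null
datasets, bootstrap CI coverage of a known binormal AUC within 95% ± 4%
over 200 datasets, MC power matched to the noncentral-t closed form over a
3×3 (effect, n) grid.

## Synthetic cohorts

`syncohort` generates paired-modality cohorts with the structure the models
assume: Bernoulli labels at 22% prevalence; negative-binomial counts
(variance = μ + μ²·dispersion, gamma-Poisson sampling; dispersion 0 is
Poisson) with lognormal baseline means spanning orders of magnitude,
lognormal library-size variation, and a block of planted DE genes whose
means are multiplied by 2^(±logFC) in MSI patients (planted genes get
moderately expressed baselines, since a fold-change screen can only detect
expressed genes); bags of isotropic-Gaussian tiles in which MSI patients
have a Binomial(M_i, informative_fraction) number of informative tiles, all
shifted by one fixed composite unit vector (spread evenly over
`signal_dim` orthonormal directions) scaled by `image_effect` — the
standard MIL assumption that only some tiles reveal the label. MSS bags are
pure noise. `modality_balance` linearly rescales the two planted effects
(0.5 leaves the stated magnitudes untouched on both sides; 1.0 silences the
genes, 0.0 the images). Optional stage/treatment metadata is independent of
class, supporting subgroup-metric plumbing without asserting biology.
Identical spec + seed is bit-identical.

`generate_score_pairs` draws paired model scores from a binormal model
(unit-variance Gaussian classes, μ = √2·Φ⁻¹(AUC)) with a shared-noise
pairing correlation; with equal target AUCs the construction is
exchangeable between models, so it is the null-calibration harness for the
comparison statistics.

**What the generator does not emulate:** spatial correlation between tiles
of one slide, staining/scanner batch structure, realistic co-expression and
count correlation between genes, label noise in MSI calls, or any
dependence between bag size and class. Passing tests therefore demonstrate
that the algorithms recover the structure they assume, not clinical-grade
performance on real slides.

### Scaled-down recovery study

`syncohort.recovery_spec` freezes the two study conditions used by the
acceptance checks and `scripts/acceptance.py`, both 300 patients at 22%
prevalence with the signal split evenly across modalities and reduced
problem sizes (128-d embeddings, 6–16 tiles per bag, 2000 genes, 20
epochs) so a full multi-seed study runs in minutes on one CPU:

* **moderate** — 4 up + 4 down DE genes at logFC 2.3 under NB dispersion
  3.0; informative fraction 0.3 with image effect 4.0. Each unimodal model
  lands clearly below ceiling (test AUC roughly 0.8–0.9), leaving fusion
  headroom; the directional claim (fusion ≥ each unimodal model) is
  asserted on the mean over 5 seeds because single-seed test AUCs on 60
  held-out patients are noisy.
* **strong** — 30 + 30 DE genes at logFC 3.0, dispersion 0.5; informative
  fraction 0.4, image effect 6.0. The fusion model is expected above 0.9.

## Numerical choices and degenerate inputs

* Softmax and the logistic always use max-subtraction / |x|-based forms.
* TPM requires strictly positive lengths and non-zero library sizes;
  all-zero patient columns are an error (undefined normalisation).
* Genes with zero counts everywhere get logFC 0 and p 1 by convention;
  constant genes get p 1 (NaN-safe).
* Attention weights must sum to 1 within 1e-6 before pooling; BagEmbedding
  validation enforces h_patient = AᵀH.
* DEG ordering: by p ascending, then |logFC| descending.
* The permutation p-value is never 0 (add-one smoothing); the bootstrap
  redraws single-class resamples rather than dropping them.
* Late-fusion weights and probabilities are range-checked.

## Known limitations

* The image backbone is a plugin interface only; the package validates
  precomputed 2048-d embeddings and never ships weights.
* The default DE statistic is a per-gene two-sample test, not a
  count-model GLM; logFC normalisation is total-count, not
  median-of-ratios. For publication-grade DE, import an external table.
* The autodiff core is single-threaded NumPy; it is sized for this model
  family, not for general deep learning.
* CV reports sample SD over folds, which on 5 folds is itself noisy.
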