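# Methods

## The model

`cicnet` implements a family of multi-task autoencoders for bulk (or
pseudo-bulk) transcriptomes.  An encoder ψ maps a max-norm-normalized
mRNA expression profile x ∈ [0,1]^G to a low-dimensional latent vector —
the *cell identity code* (CIC) — and a decoder φ maps the CIC to four
outputs simultaneously:

1. the reconstructed mRNA profile x̃ (sigmoid head, MSE loss),
2. a predicted miRNA profile (sigmoid head, MSE loss),
3. a tissue-of-origin class (softmax head, cosine loss),
4. a disease-state class (softmax head, cosine loss), where one disease
   level is reserved for "Normal".

The classification loss is `1 − cos(y, ŷ)` between the one-hot target
and the predicted probability vector: 0 for a perfect prediction,
bounded above, and `1 − 1/√K` for a uniform prediction over K classes.
The total objective is the weighted sum

    J = 0.5·L_tissue + 0.5·L_disease + 1e-3·L_mRNA + 1e-3·L_miRNA + R

with an architecture-dependent regularizer R:

* **CAE / Dropout-CAE** — the contractive penalty λ·E‖J_ψ(x)‖²_F, the
  squared Frobenius norm of the encoder's input→CIC Jacobian.  λ defaults
  to 1e-4, which puts the penalty on the same order as the weighted
  regression losses at initialization on the default synthetic cohort; it
  is exposed as a hyperparameter.
* **VAE / Dropout-VAE** — the KL divergence of the Gaussian posterior
  q(z|x) = N(μ_z, diag exp(logvar_z)) from the standard-normal prior,
  with one reparameterized sample z = μ + σ⊙ε per datum per step.  The
  reconstruction term of the variational objective is realized by the
  weighted MSE heads (a Gaussian likelihood up to constants); the KL
  weight defaults to 1.

Every *building layer* is batch-normalization → dense → activation
(activations from {relu, linear, softplus}).  Dropout variants insert a
corruption layer (Bernoulli with inverted scaling, or multiplicative
Gaussian N(1, r/(1−r))) after the input and after each encoder building
layer; an optional additive Gaussian-noise layer with configurable SD
sits directly on the input.  Training against clean targets with these
corruption layers active realizes the denoising objective as a one-draw
stochastic approximation of the corruption expectation.  In inference
mode every stochastic layer is the identity and the VAE code is μ_z, so
the forward pass is a deterministic function of (parameters, input).

## Differentiation and the contractive penalty

The networks run on a small in-package reverse-mode automatic
differentiation engine over numpy arrays (`cicnet._autodiff`), with
Adam (lr 1e-3) as the optimizer.  The contractive penalty is assembled
analytically: in deterministic mode each building layer's Jacobian is
diag(s)·W·diag(a′(h)) with s the batch-norm scale γ/√(σ²+ε), so the
per-sample encoder Jacobian is the product of these factors, built from
the CIC side inward to keep intermediates small.  Because the factors
are graph nodes, the penalty's parameter gradients come out of the same
backward pass.  During training the batch-norm statistics inside the
penalty are treated as constants of the current batch; the penalty is
the Jacobian of the per-sample map, not of the batch-coupled map.  A
finite-difference oracle over the public `encode` confirms the analytic
penalty to ≤1e-4 relative error across toy encoders of every activation
family (the relu check stays away from the kink, where the derivative is
undefined).

Batch normalization uses ε = 1e-3 and running-statistics momentum 0.9;
training mode requires batch size ≥ 2 and updates the running statistics
that inference mode uses.

## Preprocessing

Expression tables are nonnegative samples×features matrices.
Normalization divides each **sample row** by its own maximum ("max-norm"),
so every profile lies in [0,1] with its top feature at exactly 1;
per-feature scaling is available via a flag, and the choice is recorded
in the matrix metadata.  All-zero rows are left at zero with a warning.
Paired datasets keep exactly the samples for which mRNA, miRNA and
annotations are all present (ID intersection, mRNA order preserved).
Because training requires partition sizes divisible by the batch size,
`split_and_trim` first trims the total to the nearest batch multiple by
seeded uniform removal, then performs a disease-stratified split, then
trims each partition down to its nearest multiple (the test partition of
cross-validation folds is never trimmed — every sample must be scored
exactly once).  Stratifying by disease keeps rare classes represented; a
non-stratified mode reproduces a plain shuffled split.

## The synthetic cohort generator

The generator emulates the regime of a pan-cancer compendium: paired
mRNA+miRNA profiles, a tissue→disease label hierarchy (several diseases
can share a tissue; one class is "Normal"), controllable class imbalance,
and values normalizable to [0,1].  Each disease class receives a latent
center μ_c ~ center_scale·N(0, I_d); samples scatter as
z ~ N(μ_c, within_class_sd²·I); both modalities are softplus images of
the same latent state (mRNA = softplus(Az+a)+noise, miRNA analogous)
under fixed seeded loadings, then max-norm normalized.  The softplus
link keeps expression nonnegative and the latent→mRNA map smooth, so the
contractive penalty is meaningful, and it ties the miRNA profile to the
mRNA profile through the shared latent state — ridge regression from
clean mRNA to miRNA reaches held-out R² ≥ 0.5 under the defaults, so the
miRNA head's task is solvable by construction.

Defaults (the `tiny` preset): 4 tissues × 2 diseases (one "Normal"),
100 samples per class (800 total), 300 mRNA + 40 miRNA features, true
latent dimension 8, center_scale 3.0, within_class_sd 0.5, observation
noise SD 0.05.  These dimensions were chosen so a full 200-epoch, 5-fold
protocol runs in minutes on one CPU while preserving the structural
features above; a `paper_shaped` preset provides the full 27-tissue /
34-disease / 19671+2588-feature geometry for users with more time.  An
`imbalanced` preset skews class sizes from 220 down to 12.

What the generator does **not** emulate: RNA-seq count noise (negative
binomial library-size effects), batch effects across studies, correlated
gene modules, or biologically meaningful feature identities.  Class
centers drawn in a well-separated latent space make the classification
tasks easy by construction — passing tests demonstrate that the pipeline
recovers structure that is present, not that the architecture would
reach any particular accuracy on clinical data.

## Evaluation

Balanced accuracy follows the adjusted-weight definition
ŵ_i = w_i / Σ_j 1(y_j = y_i) w_j with score Σ 1(ŷ_i = y_i) ŵ_i / Σ ŵ_i;
with uniform weights this is the mean of per-class recalls
(cross-checked against an independent confusion-matrix computation and
scikit-learn).  Confusion matrices are oriented predicted×true.
Cancer-subtype accuracy restricts the disease confusion matrix to the
diseases of tissues hosting ≥ 2 cancer types and reports
1 − misclassified/total within that restriction.

Cross-validation is stratified k-fold (default 5); pooled out-of-fold
predictions and CICs cover every sample exactly once.  The
dimensionality-reduction comparison reduces the raw mRNA matrix to the
CIC dimension with PCA, kernel PCA, sparse PCA and incremental PCA, and
scores every representation with the same soft-voting ensemble of a
calibrated SVM and a random forest under identical fold assignments, so
McNemar's test on the pooled predictions is a valid paired comparison.
McNemar uses the continuity-corrected χ² (|b−c|−1)²/(b+c) with 1 df,
falling back to the exact two-sided binomial tail when b+c < 25 (both
variants can be forced).

Robustness sweeps perturb **test inputs only** — zeroing a fraction of
entries (grid 0→0.50, step 0.01; 51 points) or adding Gaussian noise
(SD 0→0.25, step 0.01; 26 points) — run deterministic inference, and
measure all four task metrics against clean targets.  The zero-
perturbation point is bit-identical to the clean evaluation.

## Hyperparameter optimization

The search space is fully discrete (per-layer unit options, activation,
dropout kind/rate, input-noise SD, CIC size, batch size), so the
Bayesian optimizer is a tree-structured Parzen estimator specialised to
categorical dimensions: after a short random warm-up (default 5),
completed trials are split at the γ = 0.25 score quantile, per-dimension
categorical densities l (good) and g (bad) are fitted with add-one
smoothing, 24 candidates are drawn from l, and the candidate maximizing
l(h)/g(h) is evaluated — preferring candidates not already evaluated,
since a cached point only replays its score.  Incumbent scores are
monotone non-increasing by construction; NaN objectives are recorded as
+inf with a "diverged" status.  The objective for network search trains
on an 80/20 split (optionally at reduced epochs) and returns the average
total loss over all data.  Random search and exhaustive grid search
share the same trial/return contract and serve as baselines; the same
optimizer drives the per-algorithm tuning of the classical-classifier
comparison (KNN, extra trees, random forest, SGD, SVM) over declared
finite grids.

## Numerical and design notes

* Head activations are not dictated by the loss definitions; sigmoid
  heads match the [0,1] range of max-norm targets and softmax heads give
  the row-stochastic vectors the cosine loss compares to one-hot targets.
* Softmax is stabilised by a detached row-max shift; softplus uses
  `logaddexp`.  All arithmetic is float64.
* Training runs a fixed number of epochs (default 200) with no early
  stopping, learning-rate schedule or checkpointing.
* Reproducibility: dataset generation, splitting, fold assignment,
  initialization, corruption draws and the optimizers are all driven by
  explicit integer seeds; repeated runs are bit-stable up to BLAS
  non-determinism (loss values agree to ~1e-6 or better).
* Degenerate inputs are rejected loudly: empty ID intersections,
  negative expression, zero-norm rows under the cosine loss, batch-norm
  training batches of size 1, non-batch-multiple training sets.
* `fit` raises rather than silently trimming; trimming is the caller's
  explicit step via `split_and_trim` (cross-validation trims only the
  training side of each fold).

## Problem sizes used in the checked protocol

The automated checks run the full protocol on the `tiny` preset: 800
samples, 300+40 features, 8 classes, Dropout-CAE with encoder 64→32,
CIC 8, batch 50, 200 epochs, 5-fold cross-validation, three generator
seeds.  The TPE benchmark uses an 11-point discrete quadratic with a
25-trial budget over 20 replicates.  These sizes are the package's
reference configuration for a single-CPU workstation; all of them scale
up by configuration only.

## Known limitations

* Desk-scale numpy training: no GPU, no mixed precision, no
  parallel/asynchronous HPO trials.
* The generator's Gaussian latent-center geometry produces linearly
  well-separated classes; claims about nonlinear separability on real
  cohorts cannot be tested against it.
* Interpretability methods (feature attribution for the trained
  networks) are out of scope.
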