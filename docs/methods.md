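# Methods

## Overview

`neurofuse` implements a local-to-global multimodal fusion graph neural
network for case/control classification from three data channels per
subject: an ROI×time BOLD-like signal matrix (functional), a fixed-length
structural feature vector (radiomics-style), and a demographic record
(age, sex, education, acquisition site).  The package contains the full
training and evaluation stack — feature preparation, harmonization, the
local per-subject graph model, the global population model, the composite
objective, cross-validation harnesses, and interpretation procedures —
together with a synthetic multi-site cohort generator that plants known
ground truth, so every stage is testable end to end without any imaging
data.

## The local model (per-subject ROI graph)

Each ROI's standardized signal (z-scored per ROI) is encoded by a
shared-weight bidirectional GRU; the regional embedding `h_e ∈ R^{n×d}`
concatenates the final forward and backward hidden states (`d = 2·hidden`).
The learnable adjacency is

    A = n · softmax(h_e h_eᵀ)     (row-wise, max-subtracted softmax)

scaled by the ROI count `n` so edge weights do not shrink toward `1/n`.
Node features `F` are the columns of the subject's Pearson functional
connectivity matrix.  Three graph-convolution layers

    H_k = tanh(D^{-1/2} A D^{-1/2} H_{k-1} W_k)

propagate them, each `W_k` realized as a two-layer perceptron.  An ROI
attention readout forms the graph embedding: attention scores are
`n · softmax` of the row sums of the *pre-softmax* score matrix
`m = h_e h_eᵀ`, and the embedding concatenates each ROI's node embedding
scaled by its attention weight.  A batch-normalized MLP head gives the
local class prediction.

Using the Gram matrix rather than `A` itself as the attention input is a
deliberate choice: every row of `A` sums to exactly `n` by construction, so
attention computed from `A`'s row sums would be identically uniform.  Row
sums of the Gram matrix track each ROI's learned out-strength, which is
what the readout is meant to weight.

Because recurrent weights are shared across ROIs and every following step
is batched linear algebra, the whole local model is equivariant to ROI
permutation (verified by conjugation tests).

## Population graphs and the global model

All subjects — training and held-out — are nodes of three population
graphs (transductive protocol; held-out labels are masked from every
loss):

* functional and structural channels: per-node top-`k` cosine-similarity
  KNN graphs (`k = 10`), union-symmetrized, negative similarities clipped
  to zero.  Functional node features default to the concatenation of the
  flattened upper-triangle FC and the local model's graph embedding
  (`Corr`/`Emb`/`Concat` modes are selectable).
* demographic channel: a fixed KNN support on the cosine similarity of the
  demographic vector η (normalized age, one-hot sex, normalized education,
  one-hot site), re-weighted on every forward pass by a trainable pairwise
  association encoder, `w_ij = (cos(MLP(η_i), MLP(η_j)) + 1)/2`.

Self-loops are added before symmetric Laplacian normalization.  Each
channel runs through a *snowball* GCN — a densely connected stack where
layer `l+1` consumes `[H_0, …, H_l]` — with 9 layers by default,
`tanh` activations, a collapse layer over all scales, and a row-L2
normalized output (the optional `p = 1` flag applies one extra Laplacian
multiplication to the output).  The modality-specific block (MS-GCN) keeps
independent weights per channel; the modality-common block (MC-GCN) shares
its trainable matrices across channels behind per-channel linear input
projections (channels have different widths, so an unshared projection is
unavoidable) and combines the per-channel outputs with fixed equal weights
summing to one.  A softmax attention over the specific embeddings and the
common embedding — score logit per channel = mean over dimensions of
`tanh(W_a H + b)`, softmax per node — yields the fused representation,
classified by an MLP.  A site-classifier head behind a gradient-reversal
layer provides the adversarial branch.

## The objective

    L = L_cls + L_specific + L_common + L_domain
    L_cls      = CE_global + λ · CE_local            (λ = 0.2)
    L_specific = Σ_channels HSIC(H_s^ch, H_c)        (linear kernel)
    L_common   = Σ_pairs ‖N^a − N^b‖_F,  N = ĤĤᵀ (row-normalized)
    L_domain   = L_site + w_cmd · L_CMD

`HSIC(X, Y) = (m−1)^{-2} tr(K_Y R K_X R)` with the centering matrix
`R = I − eeᵀ/m`; a Gaussian kernel with median-heuristic bandwidth is
optional.  `L_site` is the cross-entropy of the site head through the
gradient-reversal layer (coefficient 1.0 by default; a ramp is
configurable).  `L_CMD` is the central moment discrepancy between per-site
fused-embedding distributions: features min-max rescaled to `[0, 1]` per
batch (rescaling constants detached), first raw moment plus central
moments `k = 2…5`, averaged over site pairs.

**CMD weighting.** The CMD term's global optimum is *identical* per-site
distributions, and after min-max rescaling the loss is scale-invariant, so
at full weight the optimizer reliably reaches the trivial solution: every
subject's embedding collapses to the same point (probabilities exactly
constant, classification cross-entropy pinned at `ln 2`, and — because a
constant embedding also defeats the site adversary — a stable fixed
point).  Ablations on the default synthetic cohort isolate CMD as the sole
collapse driver; every other term combination trains to AUROC ≈ 1.  The
domain alignment term therefore enters with a default weight of 0.3, the
largest value probed that trains stably; all per-term weights remain
exposed in the configuration for ablations.

## Harmonization

Structural features pass through location-scale empirical-Bayes
harmonization before the model: per-feature OLS removes covariate effects
(diagnosis, age, sex) and site indicator means; per-site standardized
locations shrink toward a normal prior and scales toward a moment-matched
inverse-gamma prior via the usual fixed-point iteration; the adjusted data
restore the covariate fit.  Harmonization is always fitted on the
training fold only.  Held-out subjects' diagnosis covariate enters as the
training prior mean (a centered-covariate NaN), so held-out labels are
never read.  Sites unseen at fit time pass through unchanged with a
warning — this is why leave-one-site-out performance degrades under
strong planted site effects, as it should.  After harmonization the
columns are z-scored with training-fold statistics, so a zeroed feature at
inference equals mean imputation; the character-masking protocol relies on
this.

## Training regimes and evaluation

*Two-stage*: the local model trains alone on its cross-entropy (stage 1),
is frozen, and its embeddings seed the functional graph; the global model
then trains with the full objective minus the local term.  *End-to-end*:
one Adam optimizer over all parameters and the complete objective;
gradients from the global loss reach the GRU and the graph generator
through the functional node features.

The optimizer is Adam at learning rate `1e-2`, halved every 100 epochs.
Desk-scale defaults are 40 global/end-to-end epochs and 20 local epochs
with a 16-unit recurrent hidden state — on the default synthetic cohort
the losses plateau well within these budgets, and a full 5-fold
end-to-end cross-validation completes in a few minutes on one CPU core.
All schedule constants are configurable; the local module's own default
hidden width is 32.

Cross-validation is stratified jointly by label and site (k-fold) or
leaves one site out wholly (LOSO).  Metrics (ACC, AUROC, precision,
recall, F1) are computed from the pooled per-subject probability table and
per fold; calibration uses equal-width probability bins.  Subgroup and
bootstrap-unbalanced evaluations recompute metrics on filtered or
resampled probability tables.

## Interpretation

Functional: after k-fold CV, each subject's learned adjacency is collected
from every fold in which the subject was a *training* sample (k−1 folds),
averaged, symmetrized (`(A + Aᵀ)/2`; softmax rows are asymmetric while the
report concerns undirected connectivity), and averaged within each class.
The case-minus-control differential matrix yields the top enhanced (most
positive) and diminished (most negative) upper-triangle edges, ties broken
lexicographically, and the highest-degree regions (degree = row sums of
the absolute differential).

Anatomical: each named character block of the structural vector is zeroed
at inference across all CV folds; because features are train-fold
standardized this equals mean imputation.  The structural KNN graph is
rebuilt from the masked features — in the transductive setting the graph
is part of inference-time input processing, and keeping the trained graph
frozen makes the AUROC drops indistinguishable from noise when the
functional channel alone nearly saturates performance.  Importance is the
pooled unmasked test AUROC minus the masked one, ranked descending.

**Depth probe.** The anti-oversmoothing property of the snowball stack is
probed within one trained model: after training on the default cohort, the
class silhouette of the 9th hidden layer exceeds that of the 1st.  Two
choices make this probe reproducible.  It is computed within a single
model rather than across separately trained depth-1 and depth-9 models
(the cross-model comparison flips sign on roughly half of the seeds), and
the probe model trains on the classification loss alone, because the
independence/similarity/domain terms deliberately reshape the hidden
geometry for goals orthogonal to class clustering.

## The synthetic cohort generator

The generator defines the study conditions:

* **Connectivity**: one cohort-level base covariance (random low-rank plus
  diagonal, rescaled to unit diagonal); cases receive `±edge_effect` on
  the planted enhanced/diminished ROI pairs, repaired to the nearest
  positive-definite matrix by eigenvalue clipping at `1e-6` and
  re-symmetrization.  Time series are i.i.d. multivariate-normal draws —
  subjects within a group share the same covariance, so the planted
  analytic correlations are exact test targets; subject-level variability
  comes from sampling noise over the `t = 120` timepoints.
* **Structural features**: per-feature baseline means, unit noise, and a
  `+struct_effect` (standardized units) case shift on five of ten named
  "character" blocks (60 features in equal contiguous blocks of 6).
* **Site effects** follow the ComBat generative form — per-feature
  additive `γ_site ~ N(0, site_shift_scale²)` and multiplicative
  `δ_site ~ LogNormal(0, site_scale_sd²)` on the structural features, and
  a per-ROI additive signal-mean offset on the time series (removed by
  per-ROI z-scoring, as mean offsets do not alter correlations; site
  information reaches the model through the structural and demographic
  channels).
* **Demographics**: age `N(34, 11²)` truncated to [18, 70], sex
  Bernoulli(0.6), education `N(13, 3²)` with cases shifted down by
  `demo_effect` standardized units; sites assigned balanced at random.

Default effect sizes are `edge_effect = 0.5`, `struct_effect = 0.8`,
`demo_effect = 0.5`, `site_shift_scale = 0.4`, `site_scale_sd = 0.2` on
300 subjects, 32 ROIs, 3 sites.  Everything is reproducible from a single
seed, and the spec (including the planted edge and character sets) rides
along in the bundle as ground truth.

What the generator does **not** emulate: hemodynamic response shapes,
temporal autocorrelation, scanner physics, motion artifacts, subject-level
covariance heterogeneity within a group, or realistic radiomics
correlation structure.  Tests passing on these cohorts demonstrate that
the pipeline recovers the statistical structure it models — planted
covariance differences, mean shifts, ComBat-form batch effects — not that
it would achieve comparable numbers on clinical data.

## Numerical choices

* All training runs in float32 on a small tape-based autodiff engine
  written for this package (the models are a few hundred thousand
  parameters on CPU); a float64 mode exists for oracle comparisons in the
  tests.  The GRU recurrence uses a vectorized forward pass and a
  numba-compiled backward kernel with a pure-numpy reference path; the two
  are asserted equal.
* Softmaxes subtract the row maximum; row L2 normalization and the
  Gram-similarity loss add `1e-12` inside square roots; covariance repair
  clips eigenvalues at `1e-6`.
* KNN ties break toward the lowest subject index (stable sort); top-edge
  ties break lexicographically on (i, j).
* Batch normalization refuses training-mode batches of one and directs to
  eval mode.
* Cross-validated determinism: with a fixed seed, repeated runs reproduce
  metrics to float32 round-off on a single thread.

## Known limitations

* The full-weight (weight-1) domain term is unusable at this scale (see
  the CMD note above); the rebalanced default is a package-level design
  choice, not a fitted constant.
* Empirical-Bayes harmonization is ill-posed for exactly constant
  features (zero pooled variance); the generator never produces them, but
  degenerate user inputs should disable harmonization.
* The demographic KNN support is dominated by the site one-hot block, so
  demographic graphs are nearly site-pure at the default cohort size —
  intra-site edges are denser than inter-site ones by construction as
  well as after PAE training.
* With both planted effects at their defaults the classification task is
  close to saturated (AUROC ≈ 0.98–1.0), which is intended: acceptance
  checks concern recovery of the planted structure, not fine-grained
  performance differences.
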