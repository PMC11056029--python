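# Methods

## Model

`pathattn` is a feed-forward classifier whose first layer is constrained
by prior knowledge.  For modality *z* (mRNA, SNV, miRNA), the binary
membership matrix **M**ᶻ ∈ {0,1}^{k×p} connects each of k features to the
pathways it belongs to; the pathway layer computes

    H^z = h(X^z (W^z ⊙ M^z) + b^z)

with h = ReLU by default (tanh/identity configurable).  The elementwise
mask guarantees that absent connections contribute nothing to the forward
pass, receive zero gradient, and are excluded from the L2 penalty — they
are structurally inert, not merely initialized at zero.  A `literal` mode
replaces the trainable W with fixed all-ones, which reduces the layer to
the plain propagation X M + b; it is kept because a parameter-free first
layer is a meaningful baseline, but the trainable masked form is the
default since attribution interprets *learned* behavior.

Cross-sample self-attention operates over the samples of a batch, per
modality: Q = HW^q, K = HW^k, V = HW^v (projection width d, the
`attn_dim` hyper-parameter, default 64), attention scores
α_ij = Q_i·K_jᵀ/√d, row-softmax weights w_ij, and output
B_i = Σ_j w_ij V_j.  The softmax runs over the key index j, so each
sample's output is a convex combination of the batch's value rows.
`attn_dim = 0` removes the block (B = H).  Per-modality outputs are
concatenated in fixed order (mRNA, SNV, miRNA — any subset works) and an
MLP head (hidden sizes 128/32, two softmax logits) produces the
recurrence probability.

The objective is class-weighted binary cross-entropy, weights
w_j = N/(2N_j) computed from the training labels, plus γ‖θ‖² over all
effective parameters.  Optimization is Adam (lr 1e-3) over shuffled
mini-batches of 32, fully seeded; a trailing 1-sample batch is merged
into its predecessor because a singleton degenerates the attention
softmax to identity.

### Numerical and initialization choices

* All computation runs in float64 on a small reverse-mode autodiff engine
  (`autodiff.py`) validated against central finite differences.
* Hierarchical and value/head weights: Glorot-uniform, biases zero,
  seeded.  Query/key projections use a gain of 32 on the Glorot limit:
  pathway representations are small at initialization, so unit-gain
  projections give near-zero attention scores, a uniform softmax, and
  batch-averaged outputs carrying almost no per-sample information — a
  plateau from which Adam recovers only very slowly.  The gain gives the
  initial scores enough spread for the softmax to distinguish samples.
* γ defaults to 1e-3.  Beyond overfitting control, ridge-style shrinkage
  spreads weight across correlated informative features, which makes the
  fused model's usage of the three modalities — and therefore the
  attribution's coverage of them — noticeably more even than 1e-4;
  1e-2 over-shrinks and costs accuracy.
* Probabilities entering logarithms are clamped at ε = 1e-7.  Metric
  denominators of zero yield 0 (logged).  Constant features min-max
  normalize to 0.  Chi-square ties break by original feature order.
* Training aborts on a non-finite loss rather than continuing silently.

### Prediction and attribution under batch coupling

Attention couples the samples of a batch, so "the prediction for sample
s" is only defined relative to a batch policy.  `self` (default,
faithful to batched training) lets the scored samples attend among
themselves — used for whole-fold evaluation.  `reference` scores each
sample alone against a stored bank of training samples, making
single-sample prediction well-defined and independent of co-submitted
samples.

Feature contributions follow gradient × difference-from-reference:
c_i^s = (∂y/∂x_i^s)(t_i − t_i⁰) with t⁰ = 0 — the gradient×input special
case of DeepLIFT's rescale rule, computed exactly (no sampling).  The
target y is the pre-softmax logit *margin* (recurrence minus
non-recurrence): with a two-logit softmax head only the difference is
identified, and probabilities are avoided because they saturate.  Under
the `self` policy each sample's own-input gradient row is extracted from
a whole-cohort batch; under `reference` only the query sample is
differentiated.  Importances C_i sum signed contributions over recurrence
samples (an |C| variant is available), are divided by each feature's
pathway out-degree, and accumulate into pathway scores P_i; when every
feature is annotated, Σ_p P_p = Σ_i C_i holds to machine precision and is
asserted in tests.

## Preprocessing

Delimited matrices are oriented to samples × features; duplicate sample
or feature identifiers are collapsed by arithmetic mean.  SNV counts
binarize at > 0.  Expression is optionally log2(x+1)-transformed and then
min-max scaled per feature to [0,1] — min-max rather than z-scoring
because the downstream chi-square selector requires non-negative inputs
(z-scoring is available but rejected in combination with selection).
Chi-square selection treats class-wise feature sums as observed counts
against class-prior expectations (the standard convention for
non-negative features; on 0/1 data it coincides with the two-way
contingency statistic) and keeps the top m per modality, fitted on
training samples only within cross-validation.  Only features matching
the pathway collection are retained (a catch-all column is available for
sensitivity analysis).  Identifier matching is exact and case-sensitive;
alias mapping is upstream.  Cohorts keep only samples present in every
modality and the label table.

Cross-validation is stratified 5-fold, repeated 5 times by default, seeded
as base_seed + repeat; selection, membership construction and training
are refitted per training split.  Summary tables report means with both
sd conventions (over the 25 folds and over the 5 repeat means).

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets:
100–400 samples with imbalanced binary labels (default 100 recurrence /
150 non-recurrence), feature pools of 1000/1000/400 for mRNA/SNV/miRNA,
and 25 pathways per modality drawn as random member sets of 8–20 features
with ~10% sharing (so out-degree > 1 occurs and redistribution is
exercised).  A configurable number of pathways per modality (default 3)
is planted with class signal.

Signal is deliberately heterogeneous: each planted pathway is active in
an independent `penetrance` (default 0.4) fraction of recurrence samples,
and only active samples' member features shift.  This mirrors tumor
subtype structure and creates the regime the method is built for —
pathways and modalities carry complementary signal, no single one
separates the classes, and recovery of *all* planted units is a
meaningful demand.  Fully redundant signal (penetrance 1) was rejected
because a trained model provably ignores modalities it does not need,
making per-modality recovery checks vacuous; a strict
one-driver-per-sample partition was rejected because nine pathways
sharing one driver slot dilute per-feature shifts below chi-square
detectability at n ≈ 300.

The effect size δ is interpreted in standardized units for every
modality: expression features shift by δ·σ in active samples; a binary
SNV feature with baseline rate b shifts to b + δ·√(b(1−b)) (capped at
0.95), the Bernoulli analogue of a δ-sd mean shift.  A log-odds shift was
considered and rejected because it is not commensurable with the
expression δ and systematically under-powers the SNV modality.
Expression baselines are Gaussian (per-feature means U(2,8), sd 1)
clipped at zero, with a log-normal alternative; SNV baselines have
mutation rates U(0.05, 0.25).

What the generator does **not** emulate: real marginal distributions
(FPKM skew, mutation hotspots), feature–feature correlation within
pathways beyond co-activation, batch effects, missingness, and copy-number
structure.  Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated model, not performance on
any real cohort.

## Validation protocols and problem sizes

Three pre-registered protocols (in `pathattn.study`) drive the tests and
the acceptance script, at sizes chosen to finish in minutes on one CPU:

* **Null calibration** — δ = 0, 200 samples per class, 5-fold CV:
  mean AUC must be within 0.5 ± 0.05.
* **Planted recovery** — δ = 2, 150 samples per class, 3 planted pathways
  per modality, chi-square selection to 300/300/100 features, 150 training
  epochs: 5-fold CV AUC, the planted fraction of the top-20 attributed
  features per modality, and the rank of every planted pathway.
* **Ablation panel** — the same cohort with single modalities and with
  `attn_dim = 0`.

The 150-epoch budget reflects that the attention block converges much
more slowly than the rest of the network.

## Known limitations

* **Attribution reflects model usage, not data content.**  On partially
  redundant multi-omics data the fused model can satisfy its objective
  while underweighting one modality (typically the binary SNV layer,
  whose per-feature information is lowest); its planted features then
  recover incompletely even though a single-modality model at identical
  conditions recovers them fully.  This is a property of gradient-based
  attribution through a jointly trained model, not an arithmetic error —
  the finite-difference, linearity and conservation oracles all hold.
* **The attention block has no residual path.**  B_i is a convex
  combination of batch value rows and cannot represent the identity map,
  so when between-sample structure is incoherent (fine-grained synthetic
  subtypes), the block can cost accuracy relative to its bypass; with
  coherent structure it matches or beats the bypass.  Published sweeps on
  real cohorts favor larger attention dimensions; both regimes are
  reproducible here via the sweep harness.
* Per-sample predictions under the `self` policy depend on fold
  co-members; `reference` mode exists for deployment-style scoring.
* No missing-value handling, batch correction, identifier mapping, or
  survival modelling; pathway collections are inputs, never fetched.
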