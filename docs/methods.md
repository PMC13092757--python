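# Methods

## Problem and data model

The package predicts binary drug response (sensitive vs resistant) for
(cancer cell line, drug) pairs. Responses come from log10-transformed
IC50 values with a three-way rule: values strictly below −3 are
sensitive, strictly above 3 resistant, and everything in between is
recorded as *uncorrelated* — kept in the tables and in class counts, but
excluded from training edges and from the classification loss, since the
task is defined only over confident responders and non-responders.
Thresholds are configurable; (−3, 3) is the default.

Cell lines carry six omics views in a fixed order — transcriptomics,
proteomics, copy number, mutations, DNA methylation, metabolomics. The
readers intersect cell IDs across views, median-impute missing values per
column and z-score per column. Drugs enter as SMILES and are parsed with
rdkit; multi-fragment inputs (salts) are reduced to the largest fragment
with a warning.

## Graph construction

Nodes are cells then drugs (0-based). Relations, each a sparse directed
adjacency: `sensitive` and `resistant` (cell→drug, one edge per labeled
pair), their materialized inverses (so drug nodes also receive messages),
and optional within-type similarity relations: each node is linked to its
k = 5 most similar peers (cosine over concatenated standardized omics for
cells; Tanimoto over 2048-bit Morgan fingerprints for drugs), symmetrized
by union, self-similarity excluded, per-edge scores retained. A conflict
— the same pair labeled both sensitive and resistant — is an error, not a
silent overwrite. Similarity edges can be disabled (`use_similarity`),
which reduces the relation set to response edges only.

A duplicate (cell, drug) record with the *same* label is tolerated and
deduplicated; the two response adjacencies are disjoint by construction.

## Encoders

*Omics.* The per-view transform is 1-D convolution (1→8 channels, kernel
7, stride 2) → ReLU → adaptive average pooling to 16 positions → linear
to F/6 = 16 features. The six blocks concatenate to F = 96. The pooling
bins are defined for any view width ≥ 7, so widths far apart (16,000-gene
expression vs a few hundred metabolites) produce the same block width.
Disabled views emit zero blocks of fixed width, keeping every downstream
shape stable across view ablations — the ablation helper only edits the
`enabled_views` tuple.

*Drugs.* Atom features are element one-hot (C, N, O, S, F, Cl, Br, I, P,
other), degree one-hot (0–5), aromaticity, formal charge and total-H
one-hot (0–4); width 23. Two layers of symmetric-normalized aggregation
with self-loops (D^-1/2 (A+I) D^-1/2), hidden width 64, mean readout,
linear head to F. Bond types are parsed and stored but do not enter the
message weights. The mean readout makes the embedding exactly invariant
to atom relabeling, which the tests assert over random permutations.

## Relational propagation

Each layer computes
`h_i' = σ(Σ_r Σ_{j∈N_i^r} (1/c_{i,r}) W_r h_j + W_0 h_i)` with messages
flowing along edge direction (incoming neighbours) and c_{i,r} the
in-degree under relation r — the standard normalizer; the source text for
this design only calls it "a constant". No basis decomposition is used:
with six relations the parameter count is small and regularization by
weight sharing would buy nothing. The node embedding H averages the
per-layer hidden states, reading "different sources of features" as
layer-as-source; the alternative (per-omics sources) is already fused by
the cell encoder before the graph stage, so it cannot be what the
aggregation ranges over. Depth defaults to l = 2 (the reported optimum of
the sensitivity analysis); σ = ReLU.

## Type-specific augmentation

Nodes incident to at least one sensitive edge form S_s; the rest are S_n.
Per training epoch two views are drawn with sub-seeds (seed·2+1,
seed·2+2):

* **Edge deletion** removes exactly ⌊rate·pool⌉ edges from the pool =
  resistant edges ∪ the lower-scored half of each similarity relation.
  Sensitive edges and high-similarity edges are never in the pool.
  Resistant edges are pooled by default because the deletion target named
  in the ablation discussion — "false non-responsive edges" — is exactly
  that relation, and protecting them would leave the pool nearly empty
  when similarity edges are off; `protect_resistant=True` flips this.
* **Feature masking** zeroes exactly ⌊rate·F⌉ feature dimensions per S_n
  node, drawn independently per node; S_s rows are untouched.

Sampling is count-based rather than Bernoulli, so realized rates equal
requested rates and the invariance tests are exact. Defaults: edge rate
0.40, mask rate 0.30 (the reported optima). The conditional-independence
requirement — predictions should depend on S_s information however S_n is
perturbed — is not an executable formula; it is embodied as the
protected-signal invariants (asserted bit-exactly per view) plus the
alignment loss below.

## Attention, fusion and the objective

A two-layer graph attention encoder with K = 3 heads (hidden layer
concatenates head outputs, final layer averages them; attention logits
`e_ij = LeakyReLU(a_src·W t_i + a_dst·W t_j)` softmaxed over N_i ∪ {i})
encodes both views with the *same* parameter storage. Fusion is the
elementwise product X_v = T_v ⊙ H — prediction needs per-node vectors, so
the "mean pooling" in the fusion step is read as the mean over the two
views, not over the graph. X = (X1 + X2)/2 feeds a 2-hidden-layer MLP
scorer `sigmoid(MLP([X_cell ‖ X_drug]))`.

Loss `L = L1 + L2`:

* `L1 = ω1 · mean_i ‖X1_i − X2_i‖ + ω2 · Σ_d [(s1_d − φ)² + (s2_d − φ)²]`
  with ω1 = ω2 = 1, s_v the per-dimension standard deviation of X_v, and
  φ the average per-dimension std of the unperturbed-graph embedding H,
  recomputed each epoch with stop-gradient. Row norms use
  `sqrt(x + ε) − sqrt(ε)` (ε = 1e−12), which is smooth at zero and makes
  the loss exactly zero for identical views. L1 covers both cell and drug
  rows.
* `L2` is the focal loss with α_t = 0.25 multiplying and γ = 2
  exponentiating, per the printed formula (the surrounding prose swaps
  the two parameter names; the formula is implemented as printed, with
  the conventional default values, which the source does not state).
  Labels: sensitive = 1, resistant = 0. Probabilities at exactly 0/1 are
  clamped to 1e−7 with a warning.

At inference the pipeline runs without perturbation; by default the
scorer reads the fused embedding T ⊙ H of the original graph
(`score_source="fused"`), with `"original"` exposing plain H.

## Training and evaluation

Adam (lr 1e−3, weight decay 1e−5), at most 300 epochs. A stratified 10%
of the training pairs is held out for early stopping on validation AUPR
with patience 30, armed only after epoch 100 (`min_epochs`): validation
AUPR on imbalanced data is noisy and typically dips before the
classification head starts learning, so un-warmed patience stops runs at
their worst point. Best parameters are restored. The message-passing
graph contains only training response edges; test pairs are never visible
to propagation.

Splits: `random_pair` (stratified 5-fold) and `disjoint_entity`
(cold start — cells and drugs each partitioned into folds; a fold's test
pairs use only its own entities; straddling pairs are dropped and
reported; train/test entity intersections are exactly empty). How a 10%
disjoint holdout should coexist with 5-fold cross-validation is left open
by the source; the package exposes both a fold plan and a single-holdout
helper and leaves the composition to the caller.

Metrics: AUC, AUPR (precision–recall step integration), accuracy,
precision, recall, F1 at threshold 0.5; fold aggregation reports mean,
sd and se. Significance: paired DeLong test on placement values
(two-sided normal p; zero variance → p = 1 with a warning) and a paired
one-sided bootstrap for AUPR (≥ 1,000 resamples; degenerate single-class
resamples are redrawn with a bounded retry budget).

## Synthetic cohorts

The generator plants exactly the structure the model assumes: cell
latents U ~ N(0, I_k); each omics view U·W_v plus Gaussian noise
(noise_sd, default 0.5); drug latents V are the leading principal
directions of the drugs' Morgan fingerprints (standardized, SVD signs
fixed deterministically), so structure genuinely predicts response;
response scores s = U·Vᵀ + b. The top `prevalence·(1−u)` quantile of s
maps to log IC50 in (−6, −3), the bottom band to (3, 6), and a middle
band of fraction u = 0.2 to (−3, 3) via piecewise-linear monotone
decreasing maps — so threshold labeling recovers the planted classes
exactly and the sensitive fraction among labeled pairs hits the target up
to quantile rounding. Labels are a deterministic function of (U, V);
noise enters through the omics readout, not the response table. Drugs
are drawn from a packaged library of 457 rdkit-validated SMILES (curated
common drugs plus a deterministic scaffold × substituent enumeration).
`degrade_cohort` masks an exact fraction of omics entries to NaN for
robustness experiments.

What this does *not* emulate: realistic pharmacology or dose–response
shapes, heavy-tailed or discrete omics marginals (copy number and
mutations are Gaussian here), batch effects, or cross-view missingness
patterns. Passing tests on these cohorts show the pipeline recovers a
planted bilinear signal under the stated noise; they do not certify
performance on real screening data.

## Problem sizes and numerical choices

End-to-end checks run at 100 cells × 80 drugs (8,000 pairs, ~6,400
labeled, 10% sensitive), k = 8, omics noise sd 0.3 — large enough that
prevalence calibration and fold stratification are stable, small enough
that a full training run takes about a minute on one CPU. All arithmetic
is float64 through a minimal reverse-mode autodiff engine; gradient
correctness is tested against central finite differences at 1e−6
tolerances. Count-based sampling uses half-up rounding ⌊x + 0.5⌋.
Determinism: every stage is a pure function of its seed (epoch sub-seeds
are derived as `(seed·1000003 + epoch) mod (2³¹−1)`), and the test suite
asserts bit-identical cohort files, loss histories and held-out scores
across repeated runs.

## Known limitations

* Cold-start (disjoint-entity) performance at desk scale is far below
  random-pair performance and unstable across seeds (AUC roughly in the
  0.35–0.6 range on ~250-pair test folds, vs ≈ 0.92–0.94 random-pair):
  with ~80 training cells and no response edges touching test entities,
  generalization rests entirely on the feature encoders. This is
  reported as measured, not tuned away.
* Dense adjacency operations bound practical graphs to a few thousand
  nodes; the per-atom Python loop over drugs bounds libraries to a few
  thousand molecules.
* The drug encoder ignores bond types and stereochemistry; the omics
  encoder treats all views with the same architecture regardless of their
  statistical character.
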