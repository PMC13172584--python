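# Methods

## Setting and model

The task is node scoring on an undirected PPI network G = (V, E) with
frozen per-node feature vectors x_i and a partial labeling: a set P of
labeled disease proteins and an unlabeled pool U = V \ P that mixes hidden
positives with true negatives. The scorer is a 3-layer graph convolutional
network over the symmetric-normalized adjacency with self loops,

    Â = D̃^{-1/2} (A + I) D̃^{-1/2},   D̃ = diag((A + I) 1),

with per-layer transform H_l = Dropout(ReLU(BatchNorm(Â H_{l-1} W_l + b_l)))
and a final linear + sigmoid head producing one score s_i ∈ (0, 1) per
node. Scores are ranking scores, not calibrated probabilities. Edge
confidence values are carried as metadata but message passing is unweighted;
the network is reduced to its largest connected component before training so
every node can receive messages.

Because no deep-learning framework is a dependency, the forward and backward
passes (including batch-norm and dropout) and the Adam optimizer are written
directly over NumPy/SciPy arrays. The backward pass is verified against
central finite differences in the test suite for every parameter tensor, in
both batch-statistics and running-statistics normalization modes, with and
without the graph operator.

### Architecture choices

- Hidden widths (256, 64, 16), tapering to the scalar output. Dropout
  p = 0.5 after each hidden layer.
- Conv → BatchNorm → ReLU → Dropout ordering.
- Initialization: uniform fan-in, U(−1/√fan_in, +1/√fan_in), from the run
  seed; fully deterministic.
- Batch-norm running-statistics momentum is 0.3 (eps 1e-5). The momentum is
  deliberately higher than the common 0.1: spy recall — the early-stopping
  and checkpointing signal — is evaluated on inference-mode scores after
  every epoch, and batch statistics move quickly during the first epochs of
  full-batch training. With momentum 0.1 the running estimates lag so far
  behind that inference scores are stale for longer than the 10-epoch
  early-stopping patience, and folds can stop essentially untrained.
- Full-batch training: one optimization step per epoch over the whole
  graph. At the intended scales (10^3–10^4 nodes) this is cheap and removes
  mini-batch sampling as a nondeterminism source.

## PU objectives

All four objectives decompose the risk into a positive term and a surrogate
negative term estimated from the unlabeled pool, with pointwise binary
cross-entropy ℓ on scores clipped to [ε, 1−ε], ε = 1e-7:

    R_PU(f) = π_p E_P[ℓ(f,1)] + ( E_U[ℓ(f,0)] − π_p E_P[ℓ(f,0)] ).

All expectations are arithmetic means over the supplied score sets.

**nnpu** clamps the surrogate negative risk at zero:
total = π_p E_P[ℓ(f,1)] + max(0, ·). When the clamp engages, the default
*defensive* update descends on the negated surrogate (pushing it back above
zero) rather than zeroing the gradient; a plain clamp is available by
config. Default prior π_p = 0.10.

**distpu** uses an unweighted positive risk plus three regularizers:
|E_U[s] − π_p| (distribution alignment), λ_ent E_U[H(s)] with H the binary
entropy (entropy minimization, λ_ent = 0.1), and mixup consistency
λ_mix E[(s_mix − y_mix)²] (λ_mix = 0.1). The trainer builds |U| virtual
nodes per epoch: pairs drawn uniformly from P ∪ U, features interpolated
with λ ~ Beta(1, 1), pseudo-label the λ-interpolation of hard labels with U
treated as 0. Virtual nodes have no edges, so they are scored with identity
aggregation and *running-statistics* batch norm — batch statistics over a
virtual batch would couple the regularizer to batch composition.

**pugnn** adds an edge-smoothness penalty to nnPU,
λ_graph · mean_{(i,j)∈E} (s_i − s_j)², λ_graph = 0.1, under a dual prior
schedule: π_p = 0.5 for the warm-up epochs, then 0.1. The warm-up length is
10 epochs — deliberately no longer than the early-stopping patience, since a
longer warm-up would let runs whose spy recall saturates immediately stop
before the main-phase prior ever engages.

**grab** removes the fixed prior. A belief state b (initialized to the
current scores, labeled positives pinned at 1) is refined once per epoch by
neighbor averaging, b_i ← (1−β) s_i + β mean_{j∈N(i)} b_j with β = 0.5, and
re-pinned. The prior is estimated each epoch as the fraction of unlabeled
beliefs above 0.5, clamped to [0.001, 0.05]; unlabeled nodes with refined
belief above 0.5 join the positive-side means as provisional positives
(the unlabeled-side mean is unchanged), and the nnPU risk is evaluated on
that partition. Belief refinement carries no gradient.

## Evaluation protocol

Known positives are shuffled once (seeded) and split into five contiguous
folds. In each fold, the fold's 20% become *spies*: their labels are
withheld and they are added to the unlabeled pool. After every epoch, spy
recall = |{spies with s > 0.5}| / |spies| is computed on inference-mode
scores; a score exactly at the threshold counts as missed. The parameters of
the best-recall epoch are kept (ties to the earliest), and training stops
once recall has not improved for 10 consecutive epochs (Adam, lr 0.001,
max 250 epochs). A surrogate F1 is also reported, with precision proxied by
π_p·r/q where q is the fraction of all nodes above the threshold.

Fold score vectors are combined by recall weighting,
c_i = Σ_f r_f s_{i,f} / Σ_f r_f, and the ranking is restricted to the
original unlabeled pool (ties broken by node ID, making outputs
byte-reproducible). Rankings of several objectives are merged by top-k
union (k = 100 by default) with per-node model votes. Sensitivity sweeps
rerun the whole protocol across a prior grid or a spy-fraction grid and
fingerprint the top-k set with a hash so stability of the candidate list is
directly comparable across settings. At the base fraction 1/k_folds the
spy-fraction sweep reuses the exact base folds; at other fractions each
fold takes a contiguous wraparound chunk of ⌈f·|P|⌉ positives from the same
shuffle.

## Baselines

- **RWR**: p ← c·e + (1−c)·Wᵀp with e uniform over the labeled positives,
  W column-normalized adjacency, restart c = 0.15, tolerance 1e-8 (L1).
  Agreement with the exact linear solve is a test oracle.
- **Feature-only MLP**: identical CV protocol and nnPU objective with the
  identity substituted for Â.
- **Graph-only model**: identical protocol with features replaced by four
  z-scored topology descriptors (degree, clustering coefficient, core
  number, mean neighbor degree).

## Enrichment refinement

Per annotation category, each term's members are intersected with the
full-network background; the candidate overlap is tested with the
upper-tail hypergeometric distribution (one-sided Fisher), fold enrichment
is the foreground/background rate ratio, and Benjamini–Hochberg correction
is applied within each category (matching standard enrichment-tool
behavior). A term is retained iff FDR ≤ 0.001, fold > 1, foreground count
≥ 5 and background count ≤ 500. A candidate survives refinement iff every
category with at least one retained term covers it by some retained term;
categories without retained terms are vacuous. The per-candidate coverage
report makes this intersection semantics auditable. No retained terms
anywhere yields an empty refined set with a warning, not an error.

## Synthetic benchmark

The generator emulates the features of real prioritization inputs that the
method actually exploits, at desk scale:

- *Topology*: Barabási–Albert preferential attachment (n = 2,000, m = 3)
  for heavy-tailed degrees, connected by construction. A planted module of
  60 nodes receives ⌈1.0 × 60⌉ extra uniformly sampled internal edges, so
  its internal density (~3.5%) exceeds background (~0.3%).
- *Features*: i.i.d. standard normal, 64 dims; 16 informative dims of
  module members shifted by +1.0.
- *Labels*: SCAR — a seeded uniform 60% of module members are labeled; the
  rest are hidden positives, the recovery target.
- *Annotations*: five categories; each has one signal term (module + noise
  members) and random terms whose sizes straddle the background-count cap
  scaled to the network (500/8,300 of the node count).

What it does **not** emulate: confidence-score distributions, tissue
specificity, language-model embedding geometry, literature bias in label
selection (real curated labels violate SCAR toward well-studied proteins).
Passing tests therefore demonstrate correct mechanics and recoverability
under the stated signal model, not performance on any real proteome.

## Numerical choices

- Probability clipping ε = 1e-7 everywhere; prior floor 0.001 for the
  dynamic prior estimator.
- Duplicate edges collapse to the maximum confidence; confidence filter is
  strict (> threshold); component-size ties go to the component containing
  the lexicographically smallest node ID.
- Node ordering is lexicographic everywhere; all randomness flows from
  explicit seeds through `numpy` generators (per-fold streams derived via
  `SeedSequence`), so identical config + seed gives byte-identical outputs.
- Weight decay 0; Adam β = (0.9, 0.999), eps 1e-8.

## Known limitations

- Spy recall saturates at 1.0 easily (any model scoring diffusely above the
  threshold recovers all spies), so early stopping can freeze training at a
  very early checkpoint; ranking-based metrics (Recall@K) are the sharper
  lens and are reported alongside.
- On the synthetic benchmark the informative features alone nearly saturate
  Recall@120, and graph aggregation slightly dilutes the own-feature signal
  of module members with few intra-module edges; the feature-only MLP is
  therefore a very strong comparator there (occasionally one rank ahead of
  the distribution-aligned objective), which is a property of the benchmark's
  signal mix rather than of the objectives.
- The training-set recall exceeds spy recall (overfitting direction), which
  is why model selection uses the spy set only.
- Fold metrics are not independent samples; no cross-model significance
  testing is performed.
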