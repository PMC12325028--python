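# Methods

## Problem setting

Given per-subject N×N functional-connectivity (FC) matrices — Pearson
correlations between regional BOLD time series, symmetric with unit
diagonal — and binary diagnostic labels, the package learns a
classifier that models interactions among *groups* of regions rather
than region pairs. Three hypergraph views of each subject share the
node set (one node per ROI; node i's features are row i of F) and are
fused at the decision level.

## Hypergraph views

**Prior.** A parcellation assigns each ROI to exactly one functional
subnetwork; each subnetwork is one hyperedge. Hyperedges are ordered
by first label appearance, are pairwise disjoint, and cover V. The
canonical scheme has eight subnetworks, but any partition file works:
the mapping from a specific atlas to subnetworks is user input.

**Local.** The FC matrix is binarised by |F(i,j)| ≥ t (absolute value,
so strong anticorrelations count as coupling; default t = 0.3 — no
canonical value exists, and 0.3 keeps typical correlation-level graphs
connected but sparse; config-exposed). The S highest-degree nodes
(S = ⌈√N⌉ by default, config `centers`) seed subnetworks; every node
joins its hop-nearest centre (ties → earlier centre, i.e. higher
degree; nodes unreachable from all centres fall back to the centre
with the nearest FC feature row). Each subnetwork is then recursively
split: the seed pair (u, v) maximises the sorted degree pair among all
pairs with hop distance > 2 inside the induced subgraph (disconnected
pairs qualify; remaining ties → smallest id pair), a two-seed BFS
assigns nodes to the seed reaching them first (ties and doubly
unreachable nodes → u's side), and the split is kept only when the
children's summed average degree 2|E|/|V| strictly exceeds the
parent's. Recursion also stops at ≤3 nodes (a split would create a
side of ≤2, below meaningful subnetwork size), at depth D_max
(default 4), or when no qualifying seed pair exists. All tie-breaks
are total orders on vertex ids, so the construction is deterministic;
leaves are recorded in a partition tree (members, centres, seeds, stop
reasons) exportable as JSON.

Two readings of the published procedure were genuinely open and are
fixed as follows: the seed-pair objective is read as lexicographic on
the sorted-descending degree pair (not the degree sum), and the depth
counter counts splits only — the initial centre-based assignment is
depth 0.

**Global.** One hyperedge per focal ROI: the ROI plus its k nearest
neighbours by Euclidean distance between FC rows (default k = 5).
The focal node is excluded before taking the k neighbours, so every
hyperedge has size k+1 and contains its focal node; distance ties go
to the smaller id; duplicate vertex sets from different focal nodes
are kept as separate incidence columns.

All views use unit vertex-in-edge weights w_e(v) = 1; the incidence
machinery accepts non-unit weights but nothing in the pipeline sets
them. Views can be fused structurally by column concatenation
(`concat_hypergraphs`), though the classifier keeps them separate and
fuses decisions instead.

## Classifier

Each branch applies two hypergraph convolutions
X' = δ(H·Mask(Hᵀ X Θ)) with ReLU, feature sizes N → 64 → 64 (hidden
size config-exposed; 64 is a conventional width for graph encoders at
this scale). With `normalize=true` (default) the operator is the
symmetric degree-normalised form D_v^{-1/2} H D_e^{-1} Hᵀ D_v^{-1/2},
which bounds the spectral radius and avoids activation blow-up on
dense views; `normalize=false` gives the literal unnormalised form.
Both reduce to δ(XΘ) when H = I.

`Mask` is hyperedge-feature dropout: during training each hyperedge's
intermediate feature row is zeroed independently with probability
`mask_rate` (default 0.2) and survivors are rescaled by 1/(1−rate);
at evaluation it is the identity. This is an interpretation of an
under-specified masking step — it regularises exactly the quantity
the convolution aggregates.

Pooling: prior and local branches mean-pool node features per
(disjoint) hyperedge and concatenate in hyperedge order. Because the
local view's hyperedge count varies per subject, its concatenation is
padded with zero blocks to a fixed `max_edges` slots
(default ⌈√N⌉·2^D_max capped at N) so the head's input size is
subject-independent. The global branch concatenates coordinate-wise
max and mean pools (2×64). Each branch ends in a one-hidden-layer MLP
(64 units, ReLU) producing 2 logits.

Fusion sums the three branches' *pre-softmax* logits and applies one
softmax. Summing post-softmax probabilities and re-normalising is
available as `vote: probs` but compresses scale; the default follows
the summed-logits form. Ties in the final argmax resolve to the lower
class index (control).

Branches do not share parameters: the views have different incidence
structure and pooling, and decision-level fusion presumes
independently specialised branches.

## Training and evaluation

The per-subject loss is cross-entropy of the fused probabilities plus
an equally weighted auxiliary cross-entropy per branch — without the
auxiliary terms, gradients reach a branch only through the sum of
logits and weak branches can free-ride. Optimisation is Adam
(lr 5·10⁻⁴, weight decay 10⁻⁵ added to gradients, β = (0.9, 0.999)),
minibatches of 16, up to 100 epochs. Early stopping watches a
stratified 20 % inner validation split of the training subjects:
the monitored score is validation accuracy with validation
cross-entropy as tie-break (accuracy alone is too coarse when the
inner split is a handful of subjects), patience 10 epochs, best
parameters restored. Training is deterministic given the seed; the
forward/backward passes are plain numpy with analytically derived
gradients, verified against finite differences in the test suite.

Evaluation is stratified k-fold cross-validation (default 5 folds);
hypergraph views are built once per subject and reused across folds
(construction never looks at other subjects, so no leakage), while
each fold trains from a fresh seeded initialisation. Metrics: ACC,
SEN (true-positive rate, patient = positive), SPE, F1 at the 0.5
probability threshold (strictly greater than 0.5 predicts patient,
matching the argmax tie rule), and AUC via the midrank
(Mann–Whitney) statistic; AUC is defined as 0.5 for constant scores.
Reports carry per-fold values with mean ± standard error
(sd/√folds). No class reweighting is applied.

An optional Fisher r-to-z transform of the FC features
(`fisher_z: true`, default off) is applied at feature extraction,
not inside the FC container, whose entries are bounded to [−1, 1];
raw correlations are the default because nothing in the method
requires variance-stabilised features.

## Synthetic cohorts

`simulate` draws each subject's T×N signals from a block-structured
Gaussian with unit variances: correlation `within_corr` (default 0.30)
inside each of `n_subnets` (8) contiguous, near-equal subnetwork
blocks of `n_rois` (200), `between_corr` (0.05) across blocks. For
patients, `effect_size` (0.25) is added to the within-block
correlation of the first `n_affected` (2) subnetworks — effects are
planted on correlations, not raw signals, so ground truth is stated in
FC units; if a perturbed target loses positive semidefiniteness it is
repaired by eigenvalue clipping and rescaling to unit diagonal.
Independent white noise with sd `noise_sd` (0.10, i.e. mild relative
to unit signal variance) is added, and the empirical FC of the
`t_points` (150) samples — not the population target — is what the
pipeline sees, giving realistic sampling variability. Cohorts are
balanced (`n_per_class`, default 40) and byte-reproducible from the
seed (per-subject seeds spawn from one seed sequence).

What this generator does *not* emulate: hemodynamic autocorrelation,
site/scanner batch effects, head-motion artefacts, subject-level
heterogeneity of the block structure, or negative-correlation
pathology. Passing tests therefore demonstrate that the pipeline
recovers localized covariance differences under sampling noise — not
that it attains any particular accuracy on real imaging cohorts.

## Numerical and degenerate-input choices

* Zero-variance ROIs get zero off-diagonal correlations (diagonal 1)
  with a warning, keeping the node set fixed.
* Supplied matrices with asymmetry ≤ 10⁻⁶ are symmetrised by
  averaging; larger asymmetry is an error.
* Fewer than 4 ROIs degenerates the local view to one hyperedge with
  a warning.
* Zero vertex/edge degrees invert to zero in the normalised operator.
* All randomness flows through `numpy.random.Generator` seeded from
  the run config; repeated runs are bit-identical.

## Problem sizes used in the shipped analyses

The cross-validated recovery analysis uses the generator defaults
(200 ROIs, 80 subjects, 5 folds) for both the planted-effect and the
null cohort; structural checks run at the same 200-ROI scale; the
oracle comparisons for the local decomposition enumerate 200 random
graphs of ≤ 10 vertices, where exhaustive pair enumeration is exact;
unit tests use smaller cohorts (12–60 ROIs) chosen to exercise every
code path quickly.

## Known limitations

* Binary classification only; the soft-voting head generalises to
  more classes but the metric suite assumes two.
* Dense incidence matrices: fine for N of a few hundred (the intended
  atlas scale), wasteful beyond.
* The local view's `max_edges` padding bounds, but does not adapt to,
  extreme fragmentation; with very low thresholds on large N the cap
  at N slots always suffices because leaves are disjoint.
* No hyperparameter search utilities; defaults are fixed and
  config-exposed.
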