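# umhl — unified multi-view hypergraph learning for brain-connectivity classification

`umhl` classifies subjects from their functional-connectivity (FC)
matrices — the N×N Pearson correlations between regional BOLD time
series — by modelling *high-order* interactions among brain regions
with hypergraphs. A plain graph edge links two regions; a hyperedge
links any number, which is what coordinated subnetwork activity looks
like. The package is aimed at researchers who have per-subject FC
matrices (or ROI time series), a region-to-subnetwork parcellation,
and binary diagnostic labels, and who want a reproducible multi-view
hypergraph classifier with interpretable hyperedge structure.

## The model

For each subject three hypergraph views are built over the same node
set V (one node per ROI, node *i*'s feature vector being row *i* of
the FC matrix **F**):

* **prior** (knowledge-driven): one hyperedge per predefined
  functional subnetwork — a disjoint cover of V from the parcellation;
* **local** (granularity-adaptive): threshold |F(i,j)| ≥ t into a
  binary graph, seed S = ⌈√N⌉ subnetworks at the highest-degree nodes,
  assign every node to its hop-nearest centre, then recursively
  bipartition each subnetwork with a two-seed BFS. A split of G into
  (G_l, G_r) is kept only if the summed average degree increases,
  2|E(G_l)|/|V(G_l)| + 2|E(G_r)|/|V(G_r)| > 2|E(G)|/|V(G)|, and
  recursion stops at depth D_max, at ≤3 nodes, or when no seed pair
  with hop distance > 2 exists. Leaves become disjoint hyperedges;
* **global** (kNN): for every focal node, a hyperedge of the node plus
  its k nearest neighbours by Euclidean distance between FC rows —
  overlapping, spatially unconstrained.

A hypergraph with incidence matrix **H** ∈ ℝ^{|V|×|E|}
(H(v,e) = w_e(v) if v ∈ e, else 0) is processed by two hypergraph
convolution layers

    X^(l+1) = δ( H · Mask( Hᵀ X^(l) Θ^(l) ) ),

optionally degree-normalised as D_v^{-1/2} H D_e^{-1} Hᵀ D_v^{-1/2};
`Mask` drops whole hyperedge-feature rows at random during training.
Prior/local views are mean-pooled per hyperedge and concatenated,
the global view concatenates max- and mean-pools; per-view MLP heads
emit class logits, fused by soft voting:

    Logits_final = Softmax(Logits_prior + Logits_local + Logits_global).

Training uses Adam (lr 5·10⁻⁴, weight decay 10⁻⁵, up to 100 epochs,
early stopping), and evaluation is stratified 5-fold cross-validation
reporting ACC, SEN, SPE, F1 and AUC as mean ± standard error.

Real cohorts are optional: `umhl.simulate` generates seeded synthetic
cohorts with block-structured correlations and a planted within-
subnetwork effect in the patient class, so the full pipeline runs
offline.

## Worked example

```python
from umhl import (SimSpec, TrainConfig, make_dataset, cross_validate,
                  recursive_partition, knn_hyperedges, build_prior_hypergraph)

spec = SimSpec(n_rois=60, n_subnets=6, n_per_class=15, effect_size=0.3,
               n_affected=1, t_points=150, seed=42)
cohort = make_dataset(spec)
fc = cohort.subjects[0]

prior = build_prior_hypergraph(cohort.parcellation)
local, tree = recursive_partition(fc, t=0.3, d_max=4)
glob = knn_hyperedges(fc, k=5)
print(f"prior view: {prior.n_edges} hyperedges (one per subnetwork)")
print(f"local view: {local.n_edges} hyperedges, "
      f"max depth {max(l.subnetwork.depth for l in tree.leaves())}")
print(f"global view: {glob.n_edges} hyperedges of size 6")

report = cross_validate(cohort, TrainConfig(seed=0, folds=5))
for m in ("acc", "sen", "spe", "f1", "auc"):
    print(f"{m}: {report.mean[m]:.4f} +/- {report.se[m]:.4f}")
```

prints

```
prior view: 6 hyperedges (one per subnetwork)
local view: 26 hyperedges, max depth 4
global view: 60 hyperedges of size 6
acc: 0.9667 +/- 0.0333
sen: 1.0000 +/- 0.0000
spe: 0.9333 +/- 0.0667
f1: 0.9714 +/- 0.0286
auc: 1.0000 +/- 0.0000
```

The three counts show the views at work: the prior view always has one
hyperedge per subnetwork, the local view adapts its granularity to
this subject's thresholded topology (26 leaves here, recursion reaching
the depth cap), and the global view has one overlapping hyperedge per
ROI. The cross-validated metrics say the planted 0.3 correlation shift
in one subnetwork is recovered almost perfectly on held-out subjects.

The same pipeline is scriptable from the shell:

```bash
umhl simulate --config config.yaml --out cohort/
umhl build --fc cohort/matrices/sub000.csv --view local --out sub000.local.tsv
umhl cv --config config.yaml --manifest cohort/manifest.tsv --out report/
```

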