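# gec — graphlet eigencentrality for molecular networks

`gec` measures how important a gene is in a molecular network — or in a
single pathway — using **graphlet eigencentrality**: eigenvector
centrality generalised from the ordinary adjacency matrix to *graphlet
adjacency matrices*. It is aimed at network biologists who work with
protein–protein interaction, co-expression or genetic-interaction
networks and want centrality notions that see more than direct
neighbours: hubs of triangles, members of dense cliques, anchors of
paw-shaped (triangle-plus-pendant) motifs, and so on.

## The method

A *graphlet* is a small, connected, non-isomorphic, induced subgraph;
the nine graphlets on 2–4 nodes are labelled G0 (a single edge) through
G8 (the 4-clique). For an undirected, unweighted network *H* = (*V*,
*E*) and a graphlet G<sub>i</sub>, two nodes *u*, *v* are *graphlet
adjacent* to the extent that they touch common induced occurrences of
G<sub>i</sub>:

    A_Gi(u, v) = c_uv / θ_i   for u ≠ v,   0 on the diagonal,

where `c_uv` counts the occurrences of G<sub>i</sub> containing both
*u* and *v* (once per node set) and θ<sub>i</sub> = k(G<sub>i</sub>) − 1
with k the graphlet's node count. The *graphlet degree* d<sub>u</sub>
counts the occurrences touching *u*; the θ scaling makes every row of
A<sub>Gi</sub> sum exactly to the node's graphlet degree, and for G0 the
matrix is the standard adjacency matrix. Centrality is the leading
eigenvector **c** of the symmetrically normalised matrix

    Ã_Gi = D^{-1/2} A_Gi D^{-1/2},      Ã_Gi c = λ c,

computed by a deterministic power iteration (see `docs/methods.md` for
the numerical details and the closed-form Perron solution used to
validate the solver).

Pathway-level machinery built on top of this:

* **local / global pathway centrality** — centrality computed inside the
  pathway-induced subnetwork, or computed on the full network and then
  restricted to the pathway's genes;
* **participation prediction** — repeated 5-fold cross-validation per
  pathway: hold out 20% of the member genes, score them against the
  neighbouring non-members by how central each candidate *would be* in
  the pathway if it belonged to it (an (m+1)×(m+1) candidate-augmented
  local matrix), and summarise with AUC-ROC / AUC-PR;
* **driver ranking** — unsupervised within-pathway ranking of genes by
  local or global centrality, evaluated against a driver-gene label
  list;
* **evaluation statistics** — stepwise average precision, the
  median/mean-absolute-deviation *normalized AUC-PR*, "described
  pathway" selection (normalized AUC-PR > 3), max-F1 correctly-predicted
  gene sets, Jaccard overlaps, and hypergeometric set enrichment with
  Benjamini–Hochberg correction;
* **synthetic data** — model networks (Erdős–Rényi, scale-free,
  geometric) with planted connected pathways of 10–100 genes,
  realistic pathway overlap (~6 pathways per annotated gene) and
  multiplicity-biased driver labels, so the whole pipeline runs without
  any downloads.

## Worked example

The 4-node fragment with edges a–b, b–c, b–e:

```python
from gec import Network, graphlet_adjacency, graphlet_eigencentrality, pair_count

net = Network(edges=[("a", "b"), ("b", "c"), ("b", "e")])
print("G0 pair count (a,b):", pair_count(net, 0, "a", "b"))
print("G1 pair count (a,b):", pair_count(net, 1, "a", "b"))

adj = graphlet_adjacency(net, 1)          # 3-node-path adjacency
print("G1 graphlet degrees:", dict(zip(adj.nodes, map(int, adj.degrees))))

vec = graphlet_eigencentrality(net, 1)
for gene, score in vec.top(4):
    print(f"  {gene}: {score:.4f}")
```

prints

```
G0 pair count (a,b): 1
G1 pair count (a,b): 2
G1 graphlet degrees: {'a': 2, 'b': 3, 'c': 2, 'e': 2}
  b: 0.5774
  a: 0.4714
  c: 0.4714
  e: 0.4714
```

Nodes a and b share one edge (G0) and two induced 3-node paths
(a–b–c and a–b–e), so the G1 adjacency weight between them is
2/θ = 2/2 = 1. Node b touches all three path occurrences and comes out
most central.

A full synthetic study — 20 pathways planted in an Erdős–Rényi
background (n = 500, p = 0.02), within-pathway edge density 0.6,
drivers biased toward multi-pathway genes:

```python
import numpy as np
from gec import generate_scenario, evaluate_participation, evaluate_driver_ranking

data = generate_scenario()               # default scenario, seed 7
records = evaluate_participation(
    data.network, data.pathways, graphlets=(0,), mode="local",
    iterations=10, folds=5, seed=7,
)
print("mean AUC-ROC:", round(float(np.mean([r.auc_roc for r in records])), 3))
driver_records, _ = evaluate_driver_ranking(
    data.network, data.pathways, data.drivers, graphlets=(0,), mode="global",
)
rocs = [r.auc_roc for r in driver_records if not np.isnan(r.auc_roc)]
print("driver mean AUC-ROC:", round(float(np.mean(rocs)), 3))
```

prints

```
mean AUC-ROC: 0.927
driver mean AUC-ROC: 0.643
```

— local G0 centrality recovers planted pathway membership almost
perfectly, and global centrality ranks the multiplicity-biased planted
drivers well above chance (0.5).

The same pipeline is available from the shell:

```sh
gec synth --out-dir fixtures/
gec adjacency --network fixtures/edges.tsv --graphlet 6 --out adj.tsv
gec centrality --network fixtures/edges.tsv --graphlet 3 --out scores.tsv
gec predict-participation --network fixtures/edges.tsv \
    --pathways fixtures/sets.gmt --graphlets 0..8 --mode local \
    --iterations 10 --folds 5 --seed 42 --out-dir run/
gec rank-drivers --network fixtures/edges.tsv --pathways fixtures/sets.gmt \
    --labels fixtures/drivers.txt --mode global --out-dir drivers/
```

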