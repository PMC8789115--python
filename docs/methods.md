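# Methods

This note documents the model, the numerical choices, and the design
decisions behind `gec`, together with what the synthetic-data tests do
and do not demonstrate about real molecular networks.

## Graphlet adjacency and graphlet degree

Graphlets are the nine connected, non-isomorphic, induced subgraphs on
2–4 nodes: G0 the edge; G1 the 3-path and G2 the triangle; G3 the
4-path, G4 the star (claw), G5 the 4-cycle, G6 the paw (triangle with a
pendant edge), G7 the diamond (4-clique minus an edge), G8 the
4-clique. An *occurrence* is a node set whose induced subgraph is
isomorphic to the graphlet, counted once per node set (not per
automorphism): on the fragment a–b, b–c, b–e the pair (a, b) touches G1
twice — via a–b–c and a–b–e — and that convention, fixed by the 3-path
case, is applied uniformly to all nine graphlets.

The pair count c<sub>uv</sub> (occurrences containing both nodes) is
scaled by θ = k − 1, the number of co-members each occurrence gives a
node. Consequently

    Σ_v A_Gi(u, v) = d_u^Gi   exactly,

the node's graphlet degree. This row-sum identity is the backbone of
the spectral analysis below and is asserted exactly (to 1e-12 in
floating point) in the tests. For G0, A equals the ordinary adjacency
matrix and d the ordinary degree.

**Enumeration.** Production counting enumerates connected node subsets
of size 3 and 4 by ESU-style neighbourhood expansion — each connected
subset is generated exactly once from its lowest-indexed root by
extending with exclusive neighbours above the root — and classifies the
induced subgraph by its (size, edge count, maximum degree) triple,
which separates all nine graphlets. The all-subsets brute force
(O(n⁴)) exists only as a test oracle; the two agree on every random
instance tried (graphs up to 14 nodes, all nine graphlets).

## Spectral normalisation and eigencentrality

The symmetrically normalised matrix is Ã = D^{-1/2} A D^{-1/2} with D
the diagonal graphlet-degree matrix. Nodes with zero graphlet degree
(common for G6/G8 in sparse networks) get zero rows/columns and exactly
zero centrality; this keeps the normalisation well defined without
dropping nodes from the matrix.

Because of the row-sum identity, Ã restricted to a connected component
of its support is similar to a row-stochastic matrix: its spectral
radius is exactly 1 and its Perron vector is proportional to
√d restricted to the component. Two numerical consequences:

* **Convergence.** Bipartite components also carry the eigenvalue −1,
  on which plain power iteration oscillates forever (already on the
  3-node path). The solver therefore iterates on (Ã + I)/2, which has
  the same eigenvectors, spectrum in [0, 1], and leading eigenvalue
  exactly 1 — so the iteration needs no per-step renormalisation and
  the successive-difference criterion (default tolerance 1e-12,
  at most 10,000 iterations, both configurable) is meaningful.
* **Degenerate spectra.** When the support has several components,
  eigenvalue 1 has multiplicity > 1 and "the" leading eigenvector is
  not unique. The uniform positive start vector fixes a unique,
  solver-independent answer: the limit is the orthogonal projection of
  the start onto the eigenvalue-1 eigenspace, i.e. per component
  (Σ√d / Σd) · √d. On a connected support this is exactly the globally
  normalised √d vector — the closed form the test suite uses as the
  primary oracle for the whole stack (agreement required to 1e-8, plus
  an independent ARPACK cross-check). On disconnected supports the
  per-component coefficients differ, and the tests pin the projection
  formula itself.

It follows that on a connected support the centrality *ranking* for a
given graphlet coincides with the graphlet-degree ranking; the measure
remains useful because the scores (not just ranks) feed the downstream
prediction machinery, because zero-degree nodes are excluded cleanly,
and because the relative weighting across components and candidates
differs from raw counting — but the near-monotonicity is a real
property of the symmetric normalisation and worth knowing when
interpreting single-network rankings.

The output vector is sign-fixed non-negative and L2-normalised. No
norm is canonical here; only relative scores are consumed downstream,
so the eigensolver convention was chosen.

## Pathway centrality

*Local*: induce the pathway's in-network genes on the full network,
build the graphlet adjacency of that subnetwork, and take its
eigencentrality. Genes annotated to the pathway but absent from the
network are dropped (with a log message) rather than inserted as
isolated nodes, matching how pathway filtering is defined on the
induced subgraph. A pathway in which the graphlet never occurs yields
an all-zero, degeneracy-flagged result instead of an exception, so
batch runs over many pathways complete and report NA.

*Global*: compute the full-network eigencentrality once per graphlet
and slice out the pathway genes, without renormalising the subvector
(renormalisation cannot change the within-pathway order, which is all
that is consumed).

Pathways enter the analysis only if their in-network genes induce a
connected subgraph of 10–100 nodes; connectivity is evaluated on the
plain (G0) subgraph, since the filter precedes any graphlet choice.

## Participation prediction

Per pathway, R = 10 iterations of K = 5-fold cross-validation (both
configurable): each iteration partitions the m in-network member genes
into five balanced folds (sizes differ by at most one); each fold in
turn is held out (~20%) as positives, and the negatives are every
network gene adjacent to at least one of the retained training genes,
excluding members. Fold membership is a pure function of the seed and
iteration number.

Local scoring builds, for each test gene t, the induced subgraph on
train ∪ {t} — an (m+1)×(m+1) adjacency containing train–train and
train–t edges only, so interactions outside the candidate pathway never
contribute — and records t's own entry of its graphlet
eigencentrality: how central t *would be* if it belonged. Candidates
scored per-candidate, independently; edges among test genes are never
read. If the training subgraph itself contains no occurrence of the
graphlet, the fold is flagged degenerate and scores are zero.

For G0 the per-candidate solves share the training adjacency and differ
only in the candidate's incidence column, so they are executed as one
vectorised power iteration over all candidates of a fold (columns of an
(m+1)×C state array). This is the same mathematics evaluated
column-wise — the per-candidate route remains the implementation for
G1–G8 and the two routes are asserted equal in the tests — and it keeps
full 10×5-fold runs over pathways of up to 100 genes in the
seconds-to-minutes range on one CPU.

Global scoring reads the candidate's entry of the cached full-network
vector.

Fold test sets are pooled within an iteration before curves are
computed; one AUC-ROC/AUC-PR pair per iteration is then averaged over
the R iterations. (Per-fold test sets are small — a fifth of a pathway
— so per-fold curves would be noisy; pooling within an iteration keeps
every gene's one prediction per iteration while averaging over the
random partitions.)

## Driver ranking

Unsupervised: within each pathway, genes are ranked by local or global
graphlet eigencentrality; genes labelled as drivers (e.g. known cancer
drivers) act as true positives only at evaluation time. Pathways with
no labelled gene, or with nothing but labelled genes, are reported as
NA rows rather than dropped.

## Evaluation statistics

* **AUC-ROC** — the Mann–Whitney rank statistic with average ranks
  (tied positive/negative pairs count half).
* **AUC-PR** — stepwise average precision: thresholds at distinct score
  values with ties grouped, Σ precision·Δrecall. Trapezoidal
  interpolation in PR space is a known upward bias and is not used.
* **Normalized AUC-PR** — per (graphlet, mode) stratum, subtract the
  stratum median and divide by the mean absolute deviation about the
  median (not the MAD-median and not deviation about the mean). NAs
  are excluded from the median/deviation and propagate unchanged. A
  pathway is *described* by a graphlet adjacency when its normalized
  AUC-PR exceeds 3, in analogy to the 99.7% interval of a standard
  normal.
* **Max-F1 positive sets** — sweep thresholds at distinct scores; ties
  in F1 resolve to the higher threshold (fewer predictions); the
  correctly predicted genes are the true positives at or above it.
* **Enrichment** — exact hypergeometric upper-tail p-values per
  annotation term, Benjamini–Hochberg adjusted across terms, enriched
  at adjusted p < 0.05. BH is the field default where "adjusted
  p-value" is otherwise unspecified.

## Synthetic data

The generator emulates the statistical structure of curated annotation
data on real molecular networks, with a known ground truth:

* background networks from Erdős–Rényi (edge probability p),
  Barabási–Albert (attachment count) or random geometric (radius)
  models;
* pathways as random-walk samples inside a shared connected pool of
  annotated genes, sized so that the mean pathway multiplicity of
  annotated genes is ≈ 6 — the overlap level curated pathway databases
  show — then densified internally to a target edge probability (0.6 by
  default). Random walks are used because uniform sampling of connected
  subgraphs is intractable; walk samples are biased toward dense
  regions, which is acceptable for planting functional modules. Every
  planted set is connected with 10–100 genes by construction, so all of
  them pass the standard pathway filter;
* driver labels drawn without replacement with probability ∝
  multiplicity^b (b = 2 by default), emulating the observation that
  driver genes participate in roughly twice as many pathways as
  non-drivers; the labelled fraction defaults to 0.15 of annotated
  genes, the rough ratio of catalogued driver genes to pathway-annotated
  genes in the human interactome.

The default scenario is an ER background with n = 500 and p = 0.02,
20 pathways, seed 7. All randomness derives from the single scenario
seed through named substreams, so each stage regenerates independently.

**What passing tests show, and what they do not.** Planted-signal
recovery (mean local-G0 participation AUC-ROC > 0.9; driver recovery
AUC-ROC > 0.6 by global centrality) demonstrates that the pipeline
detects the signal it was built to detect when that signal is present
by construction. Synthetic pathways are internally homogeneous ER-like
blobs; real pathways have heterogeneous internal topology (chains,
stars, bridged modules), annotation noise, and degree distributions the
generator does not reproduce, so absolute synthetic AUCs say nothing
about performance on real interactomes — only that the machinery is
internally consistent.

## Degenerate inputs and tie-breaking

* Empty graphlet support in a full network → an explicit error ("no
  node touches this graphlet"); in a pathway batch → flagged all-zero
  result, NA downstream.
* Zero-degree nodes → exactly zero centrality, never NaN.
* Normalization strata with < 2 finite values or zero spread → NA
  normalised scores with a warning (batch mode) or an explicit error
  (direct call).
* Balanced fold partition when m is not divisible by K: sizes differ by
  at most one.
* All enumeration, fold assignment and iteration orders are
  deterministic given the seed; reruns of a pipeline config are
  byte-identical.

## Known limitations

* Graphlets stop at 4 nodes; no orbit-resolved (automorphism-position)
  counting, no weighted or directed extensions.
* On connected supports the centrality ranking coincides with the
  graphlet-degree ranking (see above); analyses that need the two to
  diverge should look at disconnected supports, candidate augmentation,
  or cross-graphlet comparisons.
* The pathway filter and the prediction protocol assume gene
  identifiers already match between network and annotations; no symbol
  mapping is performed.
* Exact graphlet counting on networks much larger than ~10⁴ nodes with
  heavy-tailed degrees can be slow in pure Python; the desk-scale
  problem sizes used throughout the tests (hundreds of nodes) run in
  seconds.
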