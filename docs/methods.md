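# Methods

## The model

The toolkit is built around a sparsely connected autoencoder (SCA): a
single-hidden-layer autoencoder over a samples × features data matrix in
which every hidden node corresponds to a named metafeature and the weight
matrices are masked to known metafeature → feature relationships,

    h    = act((M ∘ W_e) x + b_e)
    x̂    = (Mᵀ ∘ W_d) h + b_d

with `M ∈ {0,1}^{K×F}` the connectivity mask and `∘` the elementwise
product. Because a metafeature node only ever sees its own target
features, its activation is an interpretable summary — a metagene — of
that target set's expression, and the decoder is not a black box.

Three instantiations share this core:

- **Pseudo-bulk** (`pseudobulk`): samples = genes, features = cells,
  hidden nodes = cell clusters, mask = cluster membership (a partition of
  the cells). After training, the hidden activation of gene *g* at
  cluster node *c* is a modeled average of *g*'s expression over the
  cells of *c*: a pseudo-bulk profile. Unlike raw single-cell profiles
  the pseudo-bulks are not zero-inflated. Training is repeated with
  independent weight initializations ("runs"); each run yields one
  pseudo-replicate per cluster (default 20 runs).
- **Metagenes** (`metagene`): samples = cells, features = genes, hidden
  nodes = TFs or miRNAs, mask = target relationships (GMT input). The
  cells × metafeatures hidden layers of many runs (default 100) are
  summed entrywise. The hidden layer retains the informative part of the
  signal while discarding much of the noise, so the cumulative sum
  amplifies metafeatures that distinguish cell subpopulations while
  uninformative ones stay near background; a `mean` flag divides by the
  number of runs for scale-sensitive downstream use.
- **Cross-experiment / cross-modality matching** (`similarity`):
  pseudo-bulks from two independent experiments (or from scRNA-seq and an
  scATAC-seq gene-activity matrix) are log2CPM-transformed, row-mean
  centered, correlated over their shared genes (Pearson), and each query
  cluster is paired with its best-matching reference cluster.

## Training choices

The relationship structure fixes the architecture but not the training
recipe, which is this package's own:

| choice | default | why |
| --- | --- | --- |
| input scaling | log1p then per-feature min-max to [0, 1] | bounded inputs stabilise full-batch training on counts; already-normalized input can be passed as-is (`prescaled`) |
| hidden activation | relu | nonnegative activations let pseudo-bulks be treated as pseudo-counts for CPM |
| output layer | linear | reconstruction of continuous scaled expression |
| loss | mean squared reconstruction error | |
| optimizer | Adam, lr 1e-3 | robust default for this scale |
| weight init | uniform Glorot, then multiplied by the mask | masked positions start and stay at exactly 0 |
| batching | full batch when samples ≤ 2048, else minibatch 128 with per-epoch shuffling from the run seed | bitwise determinism at desk scale, memory safety beyond it |
| epochs | exactly `n_epochs` (default 1000), no early stopping | reproducibility of the multi-run sums |

Masking is enforced by multiplying the weights by the mask in the forward
pass, so the gradient only flows through unmasked entries — equivalent to
hard-zeroing after every update but trivially verifiable: perturbing a
feature with `mask[k, j] = 0` changes hidden node *k* by exactly zero,
and the test suite checks this by finite perturbation of trained models.
"Runs" are independent re-initialization + retraining (not input
shuffling): run *r* uses seed `base_seed + r`, so any run can be
reproduced in isolation and run order is irrelevant.

The autoencoder is implemented directly in NumPy (forward/backward pass
and Adam), which keeps the package dependency-light and makes full-batch
training bitwise reproducible across platforms for a given seed.

## Preprocessing rules

A gene is called *present* in a cell when supported by ≥ 3 UMIs (the
threshold moderates UMI sequencing errors; configurable). Cells with
fewer than a threshold of present genes are removed (250 for the
scRNA-seq default, 400 for ATAC gene-activity matrices). Gene selection
is two-stage: rank genes by total raw count and keep the top 5000, then
rank the survivors by raw-count sample variance and keep the top 2500.
Both statistics are computed on raw counts — selection precedes any
normalization — with ties broken toward earlier input rows. A companion
`restrict_to_genes` reapplies one dataset's selected gene panel to
another so paired experiments are compared over the same genes.

Normalization: CPM scales every column to 1e6 (zero-sum columns map to
zero with a warning); log2CPM is `log2(CPM + 1)` — the pseudocount is a
convention choice, exposed as a parameter, needed because pseudo-bulk
edge cases guarantee zeros; row-mean centering subtracts each gene's mean
across profiles. Bulk reference TPM tables are consumed as published and
never recomputed.

## ATAC gene activity

Peaks (BED, 0-based half-open) are assigned to every gene locus (GTF,
1-based inclusive; converted to half-open at the boundary) they overlap
by ≥ 1 bp, strand ignored, chromosome-name styles ("chr1" vs "1")
harmonized first. A peak overlapping several loci contributes its full
count to each — no fractional splitting; an `extend_upstream` option
widens loci on the 5' side but defaults to 0 (gene body only). Gene
activity of gene *g* in cell *i* is the sum of counts of the peaks
assigned to *g*. Cells then pass the ≥ 400-present-genes / ≥ 3-count
filter before clustering or pseudo-bulk generation.

Gene loci come from GTF `gene` rows when present; otherwise the span
min(start)..max(end) over all rows sharing a `gene_id`. Both attribute
dialects (`gene_id "X";` and `gene_id=X`) are accepted.

## Similarity and hierarchical clustering

Pearson correlation is computed column-vs-column over the intersection of
feature IDs (Ensembl version suffixes stripped by default, since
GTF-derived IDs carry versions and expression tables often don't), in a
fixed sorted order. Zero-variance profiles yield missing (NaN) entries,
never a silent 0, so one degenerate cluster cannot poison a matrix.
`best_match` is row-directional — each query cluster is matched into the
reference set — with the runner-up correlation and margin reported and
ties (within 1e-12) flagged ambiguous rather than broken. Hierarchical
clustering of combined pseudo-bulk + bulk reference profiles is UPGMA
(unweighted average linkage) on Euclidean distances, backed by scipy's
linkage and cross-checked in the tests against an independent brute-force
implementation.

## The synthetic-data generator

`simulate_counts` draws gene *g*, cell *i* as negative binomial
(gamma–Poisson) with mean

    μ[g, i] = baseline_mean · Π_{modules M ∋ g} multiplier(M, cluster(i)) · libsize(i)

followed by independent dropout. The reference design (`default_design`)
is 5 clusters × 150 cells, 800 genes, one TF module of 40 genes per
cluster with multiplier 6 in its own cluster and 1 elsewhere,
`baseline_mean` 0.3, NB dispersion θ = 2, dropout 0.3, log-normal library
sizes with σ = 0.25. These emulate a mixture of distinct cell lines —
strongly separated expression programs — profiled by droplet scRNA-seq
with moderate overdispersion and heavy technical zero inflation (the
reference design observes ~80% zeros). Paired experiments reuse a subset
of cluster labels with identical module multipliers and an independent
seed, giving a known cross-experiment correspondence; the ATAC fixture
lays non-overlapping gene loci on a toy genome and places peaks inside,
between, and spanning locus boundaries with the true region → gene
assignment recorded.

What the generator deliberately does **not** emulate: batch effects,
doublets, ambient RNA, gene–gene correlation beyond the planted modules,
and realistic gene-length or GC structure. Passing recovery tests
therefore show that the pipeline recovers planted cluster/module
structure under zero-inflated overdispersed noise — not that it is robust
to every artefact of real experiments.

## Verification at a glance

The test suite checks, on planted data at reduced sizes chosen so the
whole suite runs in a few minutes on one CPU:

- exact mask-respect of trained models (perturbation tolerance 1e-12),
  bitwise run reproducibility, hidden nonnegativity, loss decrease
  (median over 10 seeds);
- ≥ 95% of pseudo-bulk replicates (5 clusters × 150 cells × 20 runs ×
  200 epochs) correlating best with their own cluster's true mean
  profile, and within-cluster replicate correlation exceeding
  between-cluster for every cluster;
- full recovery of the planted cross-experiment correspondence (5 vs 3
  shared types) by pseudo-bulk correlation best-matching;
- k-means on the 25-run cumulative metagene matrix reaching ARI ≥ 0.8
  against the planted partition, with the planted metafeatures' F-ratio
  growing from 1 run to 25;
- the exact invariants: CPM column sums, centered row means, naive
  pseudo-bulk count conservation, UPGMA vs brute force, GTF/BED
  coordinate conventions.

`scripts/acceptance.py` recomputes all of these from scratch at the full
reference design sizes and writes the measured numbers to JSON.

## Numerical and degenerate-input choices

- Zero-sum columns in CPM: mapped to zero columns with a warning (not an
  error) — pseudo-bulk replicates of a dead hidden node produce them.
- Dead relu nodes: possible at low rates; they surface as a pseudo-bulk
  replicate with near-zero correlation everywhere and are the reason the
  recovery contract is ≥ 95% rather than 100%.
- Cells with no cluster label are dropped (not given their own cluster);
  a cluster losing all its cells in the intersection is an error.
- k-means labels are reported in decreasing cluster-size order
  (`m1..mk`) so label names are stable across seeds of equal partitions.
- Cluster labels are opaque strings throughout and never parsed as
  numbers; ordering is first appearance.

## Known limitations

- The NumPy trainer is single-threaded-friendly but not GPU-capable;
  very large matrices (≫ 10⁴ cells × 10⁴ genes) will be slow at 1000
  epochs.
- No variational variant of the architecture is provided.
- TF/miRNA target catalogs are user-supplied inputs (GMT); the package
  ships only synthetic module tables emitted by its own generator.
- SAVER-style imputation, Seurat clustering/integration, marker-panel
  selection and network/GO analysis are consumed or contrasted with, not
  reimplemented; the toolkit takes cluster labels as input and offers
  only a k-means convenience for self-contained runs.
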