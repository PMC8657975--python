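# sca-toolkit

Sparsely connected autoencoders (SCA) for single-cell omics.

An SCA is a masked autoencoder whose hidden nodes are interpretable
metafeatures — transcription factors, miRNAs, or cell clusters — and whose
encoder/decoder weights are zeroed outside the known metafeature →
target-gene relationships:

    h  = act((M ∘ W_e) x + b_e),        x̂ = (Mᵀ ∘ W_d) h + b_d

with `M` the binary metafeatures × genes connectivity mask. Because each
hidden node only sees its own target genes, its activation is a readable
summary (a *metagene*) of that gene set, and the trained hidden layer is
the analysis product rather than a black box. On this core the toolkit
builds, for people analysing scRNA-seq / scATAC-seq cluster structure:

- **Pseudo-bulk pseudo-replicates** — with clusters as hidden nodes
  (samples = genes, features = cells), each independent training run
  yields one non-zero-inflated pseudo-bulk expression profile per
  cluster; repeated runs give replicates suitable for bulk RNA-seq
  machinery. A naive counts-summing baseline is included.
- **TF/miRNA metagene matrices** — with TFs or miRNAs as hidden nodes
  (samples = cells), the cells × metafeatures hidden layers of many runs
  are cumulatively summed, amplifying metafeatures that distinguish cell
  subpopulations over uninformative ones.
- **Cross-experiment and cross-modality cluster matching** — pseudo-bulk
  profiles from independent experiments are log2CPM-transformed,
  row-mean centered, Pearson-correlated over shared genes, and clusters
  are paired by best match.
- **scATAC gene activity** — peak × cell counts are mapped to gene × cell
  activity by ≥ 1 bp overlap of peaks with GTF gene loci, then filtered
  to cells with ≥ 400 genes supported by ≥ 3 counts.
- **Preprocessing** — the 3-UMI present call, minimum-present-genes cell
  filter, and "2500 most variant of the 5000 most expressed" gene
  selection; CPM / log2CPM / row-mean centering.
- **A synthetic-data generator** — clustered zero-inflated negative
  binomial counts with planted TF-driven modules, paired experiments
  with known cluster correspondence, and toy ATAC fixtures, so the whole
  pipeline is testable offline.

## Worked example

Simulate a 3-cluster experiment with planted TF modules, generate 5
pseudo-bulk replicates per cluster, and match the run-averaged profiles
against the true cluster mean programs:

```python
import sca_toolkit as sca
from sca_toolkit.preprocess import ExpressionMatrix, log2cpm, row_mean_center

design = sca.default_design(n_clusters=3, cells_per_cluster=60, n_genes=240,
                            module_size=30, seed=0)
counts, truth, modules = sca.simulate_counts(design)
clusters = sca.ClusterAssignment(truth.cell_clusters)

pb = sca.pseudobulk_replicates(counts, clusters,
                               sca.SCAConfig(n_epochs=200, base_seed=1), n_runs=5)
profiles = sca.summarize_pseudobulk(pb, "mean_over_runs")

bulk = row_mean_center(log2cpm(ExpressionMatrix(
    truth.cluster_mean_expression, truth.gene_ids, truth.cluster_labels)))
sim = sca.pearson_matrix(profiles, bulk)
print(sim.to_frame().round(3))
print(sca.best_match(sim).to_string(index=False))
```

Output:

```
       K1     K2     K3
K1  0.734 -0.319 -0.414
K2 -0.248  0.653 -0.404
K3 -0.401 -0.308  0.710

query best_match        r  runner_up_r   margin  ambiguous
   K1         K1 0.733754    -0.319382 1.053135      False
   K2         K2 0.652682    -0.248478 0.901161      False
   K3         K3 0.709574    -0.308270 1.017844      False
```

Each pseudo-bulk cluster profile correlates positively (r ≈ 0.65–0.73
under 80% zero inflation) with its own cluster's true expression program
and negatively with the others, so the row-wise best match recovers the
planted identity of every cluster with a wide margin and no ambiguity —
the same read-out used to pair clusters across independent experiments.

The same pipeline is available from the shell:

```bash
sca simulate counts --seed 111 --out-dir fixtures/
sca pseudobulk --counts fixtures/counts.tsv --clusters fixtures/clusters.tsv \
    --runs 20 --epochs 1000 --seed 111 --out pb.tsv
sca similarity --a pb.tsv --b other_pb.tsv --out sim.tsv --pairs pairs.tsv
```

plus `sca preprocess`, `sca metagene`, `sca atac-activity`, `sca hclust`,
`sca convert`, `sca validate`.

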