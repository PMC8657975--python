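"""Synthetic single-cell data with planted structure.

Generates clustered zero-inflated UMI count matrices in which cell
subpopulations are distinguished by TF-driven gene modules, paired
"independent experiments" sharing a subset of cell types, and toy ATAC
fixtures (genome + peaks) with known region->gene assignments — so every
stage of the toolkit can be exercised without downloading anything.

The count model: gene g in cell i has mean

    mu[g, i] = baseline_mean * prod_{modules M with g in targets(M)}
               multiplier(M, cluster(i)) * libsize(i)

with library sizes log-normal, counts negative-binomial with a gamma-
Poisson parameterization (dispersion theta: var = mu + mu^2 / theta), and
independent dropout zeroing each observation with a fixed probability —
the minimal structure needed to emulate clusters, regulatory modules and
the zero inflation of droplet scRNA-seq. It does not emulate batch
effects, doublets or ambient contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CountMatrix, GeneLocusIndex, RegionSet, RelationshipTable


@dataclass
class SimulationDesign:
    """Parameters of one synthetic experiment.

    cells_per_cluster
        cluster label -> number of cells.
    modules
        metafeature -> (target gene ids, cluster label -> activity
        multiplier); multipliers default to 1 for unlisted clusters.
    baseline_mean
        mean UMI count of an unmodulated gene at library size 1.
    nb_dispersion
        negative-binomial dispersion theta (larger = closer to Poisson).
    dropout_rate
        probability that an observation is zeroed independently.
    library_size_spread
        sigma of the log-normal per-cell library-size factor.
    """

    cells_per_cluster: dict[str, int]
    n_genes: int
    modules: dict[str, tuple[list[str], dict[str, float]]]
    baseline_mean: float = 0.3
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.3
    library_size_spread: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("baseline_mean and nb_dispersion must be > 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.library_size_spread < 0:
            raise ValueError("library_size_spread must be >= 0")
        genes = set(self.gene_ids)
        for mf, (targets, mult) in self.modules.items():
            if not set(targets) <= genes:
                raise ValueError(f"module {mf}: targets outside the gene set")
            if any(not np.isfinite(v) or v < 0 for v in mult.values()):
                raise ValueError(f"module {mf}: multipliers must be finite and >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_genes)]

    @property
    def cluster_labels(self) -> list[str]:
        return list(self.cells_per_cluster)


@dataclass
class GroundTruth:
    """What the generator planted: the answers downstream stages must find."""

    cell_clusters: dict[str, str]
    metafeature_activity: dict[str, dict[str, float]]
    gene_modules: dict[str, list[str]]
    cluster_mean_expression: np.ndarray  # genes x clusters (pre-noise mu at libsize 1)
    cluster_labels: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)


def _module_multiplier_matrix(design: SimulationDesign) -> np.ndarray:
    """genes x clusters product of module multipliers."""
    genes = design.gene_ids
    row = {g: i for i, g in enumerate(genes)}
    mult = np.ones((design.n_genes, len(design.cluster_labels)))
    for _mf, (targets, per_cluster) in design.modules.items():
        for ci, lab in enumerate(design.cluster_labels):
            m = per_cluster.get(lab, 1.0)
            if m != 1.0:
                for g in targets:
                    mult[row[g], ci] *= m
    return mult


def simulate_counts(
    design: SimulationDesign,
) -> tuple[CountMatrix, GroundTruth, RelationshipTable]:
    """Draw one clustered zero-inflated count matrix from a design.

    Fully reproducible from ``design.seed``. Also returns the planted
    module table as a relationship table (GMT-compatible) so the metagene
    stage can be run against the truth.
    """
    rng = np.random.default_rng(design.seed)
    labels = design.cluster_labels
    mult = _module_multiplier_matrix(design)
    mu_cluster = design.baseline_mean * mult  # genes x clusters

    cell_ids: list[str] = []
    cell_clusters: dict[str, str] = {}
    cols: list[np.ndarray] = []
    theta = design.nb_dispersion
    for ci, lab in enumerate(labels):
        n = design.cells_per_cluster[lab]
        lib = np.exp(rng.normal(0.0, design.library_size_spread, size=n)) \
            if design.library_size_spread > 0 else np.ones(n)
        mu = np.outer(mu_cluster[:, ci], lib)  # genes x n
        # gamma-Poisson = negative binomial with mean mu, dispersion theta
        lam = rng.gamma(shape=theta, scale=mu / theta)
        counts = rng.poisson(lam)
        if design.dropout_rate > 0:
            keep = rng.random(counts.shape) >= design.dropout_rate
            counts = counts * keep
        for j in range(n):
            cid = f"{lab}_c{j + 1}"
            cell_ids.append(cid)
            cell_clusters[cid] = lab
        cols.append(counts)
    values = np.hstack(cols).astype(np.int64)
    matrix = CountMatrix(values, design.gene_ids, cell_ids)
    truth = GroundTruth(
        cell_clusters=cell_clusters,
        metafeature_activity={
            mf: {lab: per.get(lab, 1.0) for lab in labels}
            for mf, (_t, per) in design.modules.items()
        },
        gene_modules={mf: list(t) for mf, (t, _p) in design.modules.items()},
        cluster_mean_expression=mu_cluster,
        cluster_labels=labels,
        gene_ids=design.gene_ids,
    )
    rel = RelationshipTable({mf: set(t) for mf, (t, _p) in design.modules.items()})
    return matrix, truth, rel


def default_design(
    n_clusters: int = 5,
    cells_per_cluster: int = 150,
    n_genes: int = 800,
    module_size: int = 40,
    activity: float = 6.0,
    seed: int = 0,
    **overrides,
) -> SimulationDesign:
    """The toolkit's reference design: one TF module per cluster.

    Cluster k's module controls ``module_size`` dedicated genes with
    activity multiplier ``activity`` in its own cluster and 1 elsewhere —
    the sharp, cell-line-like separation the pseudo-bulk and metagene
    stages are meant to recover. Noise defaults (NB dispersion 2, 30%
    dropout, log-normal libraries with sigma 0.25) are typical of droplet
    scRNA-seq.
    """
    if n_clusters * module_size > n_genes:
        raise ValueError("not enough genes for disjoint modules")
    labels = [f"K{k + 1}" for k in range(n_clusters)]
    genes = [f"g{i + 1}" for i in range(n_genes)]
    modules: dict[str, tuple[list[str], dict[str, float]]] = {}
    for k, lab in enumerate(labels):
        targets = genes[k * module_size : (k + 1) * module_size]
        modules[f"TF{k + 1}"] = (targets, {lab: activity})
    return SimulationDesign(
        cells_per_cluster={lab: cells_per_cluster for lab in labels},
        n_genes=n_genes,
        modules=modules,
        seed=seed,
        **overrides,
    )


def simulate_paired_experiments(
    design_a: SimulationDesign,
    design_b: SimulationDesign,
    shared_types: list[str],
) -> tuple[
    tuple[CountMatrix, GroundTruth],
    tuple[CountMatrix, GroundTruth],
    list[tuple[str, str]],
]:
    """Two independent experiments with a known cell-type correspondence.

    ``shared_types`` must exist in both designs with identical module
    multipliers (so the shared types genuinely have the same expression
    program); the returned correspondence table pairs each shared label
    with itself across the two experiments.
    """
    for lab in shared_types:
        if lab not in design_a.cluster_labels or lab not in design_b.cluster_labels:
            raise ValueError(f"shared type {lab!r} missing from a design")
    for mf in set(design_a.modules) & set(design_b.modules):
        _, pa = design_a.modules[mf]
        _, pb = design_b.modules[mf]
        for lab in shared_types:
            if pa.get(lab, 1.0) != pb.get(lab, 1.0):
                raise ValueError(
                    f"shared type {lab!r} has different {mf} activity in the two designs"
                )
    ma, ta, _ = simulate_counts(design_a)
    mb, tb, _ = simulate_counts(design_b)
    # disambiguate barcodes across experiments
    ma = CountMatrix(ma.values, ma.feature_ids, [f"A.{c}" for c in ma.cell_ids])
    mb = CountMatrix(mb.values, mb.feature_ids, [f"B.{c}" for c in mb.cell_ids])
    ta.cell_clusters = {f"A.{c}": lab for c, lab in ta.cell_clusters.items()}
    tb.cell_clusters = {f"B.{c}": lab for c, lab in tb.cell_clusters.items()}
    pairs = [(lab, lab) for lab in shared_types]
    return (ma, ta), (mb, tb), pairs


@dataclass
class AtacFixture:
    """A toy genome with peaks of known gene assignment."""

    peaks: CountMatrix
    regions: RegionSet
    gtf_text: str
    loci: GeneLocusIndex
    true_assignment: dict[str, set[str]]


def simulate_atac_fixture(
    n_genes: int = 10,
    n_regions: int = 20,
    n_cells: int = 30,
    seed: int = 0,
    mean_count: float = 2.0,
) -> AtacFixture:
    """Toy scATAC input: non-overlapping gene loci on two chromosomes and
    regions placed inside, between, and spanning adjacent loci, with the
    true region->gene assignment recorded."""
    if min(n_genes, n_regions, n_cells) < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    gene_len, gap = 2000, 1000
    loci: dict[str, tuple[str, int, int, str]] = {}
    gtf_lines = []
    for i in range(n_genes):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        rank = i // 2
        start = 1 + rank * (gene_len + gap)  # 1-based inclusive
        end = start + gene_len - 1
        strand = "+" if i % 3 else "-"
        gid = f"G{i + 1}"
        loci[gid] = (chrom, start, end, strand)
        gtf_lines.append(
            f'{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\tgene_id "{gid}";'
        )
    gene_list = list(loci)

    regions: list[tuple[str, int, int]] = []
    ids: list[str] = []
    truth: dict[str, set[str]] = {}
    for r in range(n_regions):
        rid = f"r{r + 1}"
        kind = r % 3
        gid = gene_list[r % n_genes]
        chrom, gstart, gend, _ = loci[gid]
        g0, g1 = gstart - 1, gend  # 0-based half-open
        if kind == 0:  # inside a locus
            start = g0 + 100 + int(rng.integers(0, 500))
            end = start + 400
            assigned = {gid}
        elif kind == 1:  # in the gap after the locus
            start = g1 + 100
            end = start + 300
            assigned = set()
        else:  # spanning the locus 3' boundary into the gap
            start = g1 - 200
            end = g1 + 200
            assigned = {gid}
        regions.append((chrom, start, end))
        ids.append(rid)
        truth[rid] = assigned
    counts = rng.poisson(mean_count, size=(n_regions, n_cells)).astype(np.int64)
    peaks = CountMatrix(counts, ids, [f"bc{j + 1}" for j in range(n_cells)])
    return AtacFixture(
        peaks=peaks,
        regions=RegionSet(regions, ids),
        gtf_text="\n".join(gtf_lines) + "\n",
        loci=GeneLocusIndex(loci),
        true_assignment=truth,
    )
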