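"""Gene-activity matrices from scATAC-seq peak counts.

Open-chromatin regions (peaks) are assigned to every gene locus they
overlap by at least 1 bp; a gene's activity in a cell is the sum of the
counts of its assigned regions. Gene loci come from a GTF (1-based
inclusive) and peaks from BED (0-based half-open); both are converted to
0-based half-open before the overlap test. Strand is ignored —
accessibility is unstranded. Cells are then filtered on the number of
genes with at least ``min_umi`` counts.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
from intervaltree import IntervalTree

from .io import CountMatrix, GeneLocusIndex, RegionSet
from .preprocess import EmptyResultError, filter_cells

logger = logging.getLogger(__name__)

RegionGeneMap = dict[str, set[str]]


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def assign_regions_to_genes(
    regions: RegionSet,
    loci: GeneLocusIndex,
    extend_upstream: int = 0,
) -> RegionGeneMap:
    """Map each region to every gene locus it overlaps by >= 1 bp.

    Chromosome names are harmonized ("chr1" == "1") first; gene loci are
    converted from 1-based inclusive to 0-based half-open. A region
    overlapping several loci maps to all of them; regions overlapping
    none map to the empty set. ``extend_upstream`` widens each locus on
    its 5' side (strand-aware) before the test; the default of 0 uses the
    gene body alone.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene_id, (chrom, start, end, strand) in loci.loci.items():
        lo, hi = start - 1, end  # to 0-based half-open
        if extend_upstream:
            if strand == "-":
                hi += extend_upstream
            else:
                lo = max(0, lo - extend_upstream)
        trees[_norm_chrom(chrom)].addi(lo, hi, gene_id)
    out: RegionGeneMap = {}
    for rid, (chrom, start, end) in zip(regions.region_ids, regions.regions):
        hits = trees[_norm_chrom(chrom)].overlap(start, end)
        out[rid] = {iv.data for iv in hits}
    return out


def gene_activity_matrix(peaks: CountMatrix, region_map: RegionGeneMap) -> CountMatrix:
    """Sum peak counts into per-gene activity counts.

    Every region must appear in the map; a region mapped to several genes
    contributes its full count to each of them (no fractional splitting).
    Genes with no mapped region are absent from the output. Gene order is
    first-appearance order over the input regions.
    """
    unknown = [r for r in peaks.feature_ids if r not in region_map]
    if unknown:
        raise KeyError(f"regions missing from the region->gene map: {unknown[:5]} ...")
    gene_order: list[str] = []
    for rid in peaks.feature_ids:
        for g in sorted(region_map[rid]):
            if g not in gene_order:
                gene_order.append(g)
    if not gene_order:
        raise EmptyResultError("no region maps to any gene")
    row = {g: i for i, g in enumerate(gene_order)}
    values = np.zeros((len(gene_order), peaks.n_cells), dtype=peaks.values.dtype)
    for i, rid in enumerate(peaks.feature_ids):
        for g in region_map[rid]:
            values[row[g]] += peaks.values[i]
    n_unmapped = sum(1 for rid in peaks.feature_ids if not region_map[rid])
    logger.info(
        "gene_activity_matrix: %d genes from %d regions (%d unmapped regions)",
        len(gene_order), peaks.n_features, n_unmapped,
    )
    return CountMatrix(values, gene_order, list(peaks.cell_ids))


def filter_atac_cells(m: CountMatrix, min_genes: int = 400, min_umi: int = 3) -> CountMatrix:
    """Keep cells with at least ``min_genes`` gene loci supported by at
    least ``min_umi`` counts (boundary inclusive)."""
    out = filter_cells(m, min_present_genes=min_genes, min_umi=min_umi)
    logger.info("filter_atac_cells: %d/%d cells pass", out.n_cells, m.n_cells)
    return out
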