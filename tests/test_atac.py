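"""scATAC gene activity: region->gene interval assignment, count
aggregation, and the present-gene cell filter."""

import numpy as np
import pytest

from sca_toolkit import (
    CountMatrix,
    GeneLocusIndex,
    RegionSet,
    assign_regions_to_genes,
    filter_atac_cells,
    gene_activity_matrix,
    simulate_atac_fixture,
)
from sca_toolkit.preprocess import EmptyResultError


@pytest.fixture
def loci() -> GeneLocusIndex:
    # 1-based inclusive; G1 half-open = [149, 300)
    return GeneLocusIndex({
        "G1": ("chr1", 150, 300, "+"),
        "G2": ("chr1", 301, 400, "-"),
        "G3": ("chr2", 100, 200, "+"),
    })


# ---------------------------------------------------------------------------
# region -> gene assignment
# ---------------------------------------------------------------------------


def test_overlap_by_one_bp_assigns(loci):
    rs = RegionSet([("chr1", 99, 200)], ["r1"])
    assert assign_regions_to_genes(rs, loci)["r1"] == {"G1"}


def test_boundary_touch_is_not_overlap(loci):
    # region [99, 149) ends exactly where G1's half-open interval begins
    rs = RegionSet([("chr1", 99, 149)], ["r1"])
    assert assign_regions_to_genes(rs, loci)["r1"] == set()


def test_region_spanning_two_loci_maps_to_both(loci):
    rs = RegionSet([("chr1", 250, 350)], ["r1"])
    assert assign_regions_to_genes(rs, loci)["r1"] == {"G1", "G2"}


def test_chrom_prefix_harmonized(loci):
    with_prefix = RegionSet([("chr1", 160, 170)], ["r1"])
    bare = RegionSet([("1", 160, 170)], ["r1"])
    assert (assign_regions_to_genes(with_prefix, loci)
            == assign_regions_to_genes(bare, loci) == {"r1": {"G1"}})


def test_assignment_invariant_to_region_order(loci):
    fwd = RegionSet([("chr1", 160, 170), ("chr2", 110, 120)], ["a", "b"])
    rev = RegionSet([("chr2", 110, 120), ("chr1", 160, 170)], ["b", "a"])
    assert assign_regions_to_genes(fwd, loci) == assign_regions_to_genes(rev, loci)


def test_extend_upstream_is_strand_aware(loci):
    rs = RegionSet([("chr1", 100, 140)], ["r1"])  # upstream of G1 (+ strand)
    assert assign_regions_to_genes(rs, loci)["r1"] == set()
    assert assign_regions_to_genes(rs, loci, extend_upstream=20)["r1"] == {"G1"}
    downstream_of_g3 = RegionSet([("chr2", 205, 215)], ["r1"])  # 3' of + strand G3
    assert assign_regions_to_genes(downstream_of_g3, loci, extend_upstream=20)["r1"] == set()


# ---------------------------------------------------------------------------
# gene activity aggregation
# ---------------------------------------------------------------------------


def test_activity_sums_regions_per_gene():
    peaks = CountMatrix(np.array([[5], [3]]), ["r1", "r2"], ["c1"])
    activity = gene_activity_matrix(peaks, {"r1": {"G1"}, "r2": {"G1"}})
    assert activity.feature_ids == ["G1"]
    assert activity.values[0, 0] == 8


def test_multi_gene_region_contributes_fully_to_each():
    peaks = CountMatrix(np.array([[4]]), ["r1"], ["c1"])
    activity = gene_activity_matrix(peaks, {"r1": {"G1", "G2"}})
    assert activity.to_frame().loc["G1", "c1"] == 4
    assert activity.to_frame().loc["G2", "c1"] == 4


def test_activity_matches_double_loop_oracle(rng):
    n_regions, n_cells = 12, 6
    peaks = CountMatrix(
        rng.poisson(3.0, size=(n_regions, n_cells)),
        [f"r{i}" for i in range(n_regions)],
        [f"c{j}" for j in range(n_cells)],
    )
    genes = [f"G{k}" for k in range(5)]
    region_map = {
        f"r{i}": set(rng.choice(genes, size=rng.integers(0, 3), replace=False))
        for i in range(n_regions)
    }
    activity = gene_activity_matrix(peaks, region_map)
    # independent accumulation oracle
    expected = {g: np.zeros(n_cells, dtype=int) for g in genes}
    for i in range(n_regions):
        for g in region_map[f"r{i}"]:
            for j in range(n_cells):
                expected[g][j] += peaks.values[i, j]
    for g in activity.feature_ids:
        np.testing.assert_array_equal(activity.to_frame().loc[g].to_numpy(), expected[g])
    absent = set(genes) - set(activity.feature_ids)
    assert all((expected[g] == 0).all() for g in absent)


def test_unknown_region_id_rejected():
    peaks = CountMatrix(np.array([[1]]), ["rX"], ["c1"])
    with pytest.raises(KeyError):
        gene_activity_matrix(peaks, {"r1": {"G1"}})


def test_single_assignment_conservation():
    """With every region mapped to <= 1 gene, activity totals never exceed
    peak totals; equality iff nothing is unmapped."""
    peaks = CountMatrix(np.array([[2], [3], [4]]), ["r1", "r2", "r3"], ["c1"])
    all_mapped = gene_activity_matrix(peaks, {"r1": {"G1"}, "r2": {"G1"}, "r3": {"G2"}})
    assert all_mapped.values.sum() == peaks.values.sum()
    some_unmapped = gene_activity_matrix(peaks, {"r1": {"G1"}, "r2": set(), "r3": {"G2"}})
    assert some_unmapped.values.sum() < peaks.values.sum()


# ---------------------------------------------------------------------------
# cell filter
# ---------------------------------------------------------------------------


def test_filter_boundary_inclusive(rng):
    n_genes = 500
    values = np.zeros((n_genes, 2), dtype=int)
    values[:400, 0] = 3  # exactly 400 present genes -> kept
    values[:399, 1] = 3  # 399 -> removed
    m = CountMatrix(values, [f"G{i}" for i in range(n_genes)], ["keep", "drop"])
    out = filter_atac_cells(m, min_genes=400, min_umi=3)
    assert out.cell_ids == ["keep"]


def test_filter_zero_threshold_is_identity(rng):
    m = CountMatrix(rng.poisson(1.0, size=(10, 5)),
                    [f"G{i}" for i in range(10)], [f"c{j}" for j in range(5)])
    assert filter_atac_cells(m, min_genes=0).cell_ids == m.cell_ids


def test_filter_matches_present_count_oracle(rng):
    m = CountMatrix(rng.poisson(2.0, size=(20, 5)),
                    [f"G{i}" for i in range(20)], [f"c{j}" for j in range(5)])
    out = filter_atac_cells(m, min_genes=6, min_umi=3)
    survivors = [
        cid for j, cid in enumerate(m.cell_ids)
        if sum(int(m.values[i, j] >= 3) for i in range(20)) >= 6
    ]
    assert out.cell_ids == survivors


def test_filter_all_fail_is_error():
    m = CountMatrix(np.ones((5, 2), dtype=int), [f"G{i}" for i in range(5)], ["c1", "c2"])
    with pytest.raises(EmptyResultError):
        filter_atac_cells(m, min_genes=3, min_umi=3)


# ---------------------------------------------------------------------------
# end-to-end on the synthetic fixture
# ---------------------------------------------------------------------------


def test_fixture_assignments_match_ground_truth(tmp_path):
    from sca_toolkit.io import read_gtf_gene_loci

    fx = simulate_atac_fixture(n_genes=8, n_regions=18, n_cells=10, seed=3)
    gtf = tmp_path / "genes.gtf"
    gtf.write_text(fx.gtf_text)
    loci = read_gtf_gene_loci(gtf)
    assert loci.loci == fx.loci.loci
    assignment = assign_regions_to_genes(fx.regions, loci)
    assert assignment == fx.true_assignment


def test_fixture_conservation_when_all_inside():
    fx = simulate_atac_fixture(n_genes=6, n_regions=18, n_cells=5, seed=1)
    inside = {rid: genes for rid, genes in fx.true_assignment.items() if genes}
    keep = [i for i, rid in enumerate(fx.peaks.feature_ids) if rid in inside]
    peaks = CountMatrix(fx.peaks.values[keep],
                        [fx.peaks.feature_ids[i] for i in keep],
                        fx.peaks.cell_ids)
    activity = gene_activity_matrix(peaks, inside)
    assert activity.values.sum() == peaks.values.sum()
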