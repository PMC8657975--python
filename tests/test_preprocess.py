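"""Filtering and normalization rules: present calls, cell/gene filters,
CPM/log2CPM/centering, and the pipeline-order contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sca_toolkit import CountMatrix
from sca_toolkit import preprocess as pp


def _random_counts(rng, n_genes=50, n_cells=20, lam=2.0) -> CountMatrix:
    values = rng.poisson(lam, size=(n_genes, n_cells))
    return CountMatrix(values, [f"g{i}" for i in range(n_genes)], [f"c{j}" for j in range(n_cells)])


# ---------------------------------------------------------------------------
# present call and cell filter
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "min_umi,expected",
    [(3, [False, False, True, True]), (1, [False, True, True, True])],
)
def test_call_present_threshold(min_umi, expected):
    m = CountMatrix(np.array([[0, 2, 3, 5]]), ["g1"], ["c1", "c2", "c3", "c4"])
    assert pp.call_present(m, min_umi).values.tolist() == [expected]


def test_all_zero_matrix_all_absent():
    m = CountMatrix(np.zeros((3, 2), dtype=int), ["g1", "g2", "g3"], ["c1", "c2"])
    assert not pp.call_present(m).values.any()


def test_filter_cells_against_per_cell_count_oracle(rng):
    m = _random_counts(rng)
    threshold = 3
    filtered = pp.filter_cells(m, min_present_genes=threshold)
    # brute-force per-cell count of genes with >= 3 UMIs
    survivors = [
        cid
        for j, cid in enumerate(m.cell_ids)
        if sum(int(m.values[i, j] >= 3) for i in range(m.n_features)) >= threshold
    ]
    assert filtered.cell_ids == survivors
    assert filtered.feature_ids == m.feature_ids


def test_filter_cells_threshold_zero_is_identity(toy_counts):
    out = pp.filter_cells(toy_counts, 0)
    np.testing.assert_array_equal(out.values, toy_counts.values)
    assert out.cell_ids == toy_counts.cell_ids


def test_filter_cells_idempotent(rng):
    m = _random_counts(rng)
    once = pp.filter_cells(m, 4)
    twice = pp.filter_cells(once, 4)
    assert once.cell_ids == twice.cell_ids


def test_filter_cells_empty_result_is_explicit_error(toy_counts):
    with pytest.raises(pp.EmptyResultError, match="all 4 cells removed"):
        pp.filter_cells(toy_counts, 1000)


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------


def test_select_genes_two_stage_forced_example():
    # totals [10, 5, 1]; top_expressed=2 keeps g1,g2; variances then decide
    values = np.array([[5, 5], [1, 4], [1, 0]])
    m = CountMatrix(values, ["g1", "g2", "g3"], ["c1", "c2"])
    out = pp.select_genes(m, top_expressed=2, top_variant=1)
    assert out.feature_ids == ["g2"]  # var 4.5 beats var 0


def _select_genes_oracle(m: CountMatrix, top_expressed: int, top_variant: int) -> list[str]:
    """Independent two-stage sort: sort by (total desc, index asc), then the
    survivors by (variance desc, index asc); report in input row order."""
    totals = [(float(m.values[i].sum()), i) for i in range(m.n_features)]
    stage1 = sorted(range(m.n_features), key=lambda i: (-totals[i][0], i))[:top_expressed]
    var = {i: float(np.var(m.values[i], ddof=1)) for i in stage1}
    stage2 = sorted(stage1, key=lambda i: (-var[i], i))[:top_variant]
    return [m.feature_ids[i] for i in sorted(stage2)]


def test_select_genes_matches_bruteforce_oracle(rng):
    m = _random_counts(rng, n_genes=50, n_cells=20)
    out = pp.select_genes(m, top_expressed=30, top_variant=12)
    assert out.feature_ids == _select_genes_oracle(m, 30, 12)


def test_select_genes_invariant_to_cell_permutation(rng):
    m = _random_counts(rng)
    perm = rng.permutation(m.n_cells)
    shuffled = CountMatrix(m.values[:, perm], m.feature_ids, [m.cell_ids[j] for j in perm])
    assert (
        pp.select_genes(m, 30, 10).feature_ids
        == pp.select_genes(shuffled, 30, 10).feature_ids
    )


def test_select_genes_bad_thresholds(toy_counts):
    with pytest.raises(ValueError):
        pp.select_genes(toy_counts, top_expressed=2, top_variant=3)
    with pytest.raises(ValueError):
        pp.select_genes(toy_counts, top_expressed=10, top_variant=2)


def test_pipeline_order_matters(rng):
    """Filtering cells first then selecting genes is generally different
    from the reverse order: cell survival depends on all genes, not just
    the selected ones."""
    m = _random_counts(rng, n_genes=60, n_cells=30, lam=1.0)
    a = pp.select_genes(pp.filter_cells(m, 5), top_expressed=40, top_variant=20)
    try:
        b = pp.filter_cells(pp.select_genes(m, top_expressed=40, top_variant=20), 5)
    except pp.EmptyResultError:
        return  # reversed order removed every cell: orders clearly differ
    assert a.cell_ids != b.cell_ids or a.feature_ids != b.feature_ids


# ---------------------------------------------------------------------------
# restrict_to_genes
# ---------------------------------------------------------------------------


def test_restrict_identity_and_reorder(toy_counts):
    same = pp.restrict_to_genes(toy_counts, toy_counts.feature_ids)
    np.testing.assert_array_equal(same.values, toy_counts.values)
    swapped = pp.restrict_to_genes(toy_counts, ["g2", "g1"])
    assert swapped.feature_ids == ["g2", "g1"]
    np.testing.assert_array_equal(swapped.values, toy_counts.values[[1, 0]])


def test_restrict_missing_gene(toy_counts):
    with pytest.raises(KeyError):
        pp.restrict_to_genes(toy_counts, ["g1", "gX"])
    out = pp.restrict_to_genes(toy_counts, ["g1", "gX"], allow_missing=True)
    assert out.feature_ids == ["g1"]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_cpm_closed_form():
    m = CountMatrix(np.array([[2], [3], [5]]), ["g1", "g2", "g3"], ["c1"])
    out = pp.cpm(m)
    np.testing.assert_allclose(out.values[:, 0], [200000, 300000, 500000])


def test_cpm_zero_column_warns_and_maps_to_zero():
    m = CountMatrix(np.array([[0, 1], [0, 1]]), ["g1", "g2"], ["c1", "c2"])
    with pytest.warns(UserWarning, match="zero-sum"):
        out = pp.cpm(m)
    assert (out.values[:, 0] == 0).all()
    np.testing.assert_allclose(out.values[:, 1].sum(), 1e6)


def test_cpm_rejects_negative_input():
    em = pp.ExpressionMatrix(np.array([[-1.0]]), ["g1"], ["c1"])
    with pytest.raises(ValueError, match="nonnegative"):
        pp.cpm(em)


def test_row_mean_center_closed_form():
    m = pp.ExpressionMatrix(np.array([[1.0, 2.0, 3.0]]), ["g1"], ["a", "b", "c"])
    np.testing.assert_allclose(pp.row_mean_center(m).values, [[-1, 0, 1]])


def test_log2cpm_is_log2_of_cpm_plus_pseudocount(rng):
    m = _random_counts(rng, n_genes=10, n_cells=4)
    np.testing.assert_allclose(
        pp.log2cpm(m).values, np.log2(pp.cpm(m).values + 1.0)
    )


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_normalization_invariants(seed):
    """CPM columns sum to 1e6 (nonzero columns); centered rows have mean 0."""
    rng = np.random.default_rng(seed)
    m = _random_counts(rng, n_genes=12, n_cells=6, lam=1.5)
    c = pp.cpm(m)
    colsums = m.values.sum(axis=0)
    np.testing.assert_allclose(c.values.sum(axis=0)[colsums > 0], 1e6, atol=1e-6)
    centered = pp.row_mean_center(pp.log2cpm(m))
    np.testing.assert_allclose(centered.values.mean(axis=1), 0, atol=1e-9)
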