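"""Expression matrix handling: max-reduction, top-percentile filter, bins."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fracres.expression import (
    BinScheme,
    ExpressionTable,
    assign_bins,
    filter_top_percent,
    log_transform,
    max_expression,
    read_expression,
)


def write_expr(tmp_path, text):
    path = tmp_path / "expr.tsv"
    path.write_text(text)
    return path


class TestReadExpression:
    def test_toy_matrix(self, tmp_path):
        path = write_expr(tmp_path, "gene_id\tt1\tt2\tt3\ng1\t0\t5\t2\ng2\t1\t1\t1\n")
        table = read_expression(path)
        assert table.values.shape == (2, 3)
        assert list(table.conditions) == ["t1", "t2", "t3"]

    def test_negative_cell_rejected(self, tmp_path):
        path = write_expr(tmp_path, "gene_id\tt1\ng1\t-3\n")
        with pytest.raises(ValueError, match="negative"):
            read_expression(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = write_expr(tmp_path, "gene_id\tt1\tt2\ng1\t1\tlow\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_expression(path)

    def test_duplicate_gene_row_rejected(self, tmp_path):
        path = write_expr(tmp_path, "gene_id\tt1\ng1\t1\ng1\t2\n")
        with pytest.raises(ValueError, match="duplicate gene"):
            read_expression(path)

    def test_column_means_match_recomputation(self, tmp_path):
        rng = np.random.default_rng(3)
        values = rng.gamma(2.0, 5.0, size=(100, 4))
        lines = ["gene_id\t" + "\t".join(f"c{j}" for j in range(4))]
        for i, row in enumerate(values):
            lines.append(f"g{i}\t" + "\t".join(f"{v:.6f}" for v in row))
        path = write_expr(tmp_path, "\n".join(lines) + "\n")
        table = read_expression(path)
        expected = np.round(values, 6).mean(axis=0)
        assert np.allclose(table.values.mean(axis=0).to_numpy(), expected)


class TestMaxExpression:
    def test_examples(self):
        table = ExpressionTable(
            pd.DataFrame({"t1": [0.0, 0.0], "t2": [5.0, 0.0], "t3": [2.0, 0.0]},
                         index=["g1", "g2"])
        )
        pgm = max_expression(table)
        assert pgm["g1"] == 5.0
        assert pgm["g2"] == 0.0

    def test_matches_row_scan(self):
        rng = np.random.default_rng(4)
        values = rng.gamma(2.0, 5.0, size=(500, 6))
        table = ExpressionTable(
            pd.DataFrame(values, index=[f"g{i}" for i in range(500)])
        )
        pgm = max_expression(table)
        for i in range(500):
            assert pgm[f"g{i}"] == max(values[i])


class TestFilterTopPercent:
    def test_removes_exactly_top_two_of_200_distinct(self):
        values = pd.Series(np.arange(1.0, 201.0), index=[f"g{i}" for i in range(200)])
        retained, threshold = filter_top_percent(values, 1.0)
        assert len(retained) == 198
        assert threshold == 198.0
        assert set(values.index) - set(retained) == {"g198", "g199"}

    def test_full_ties_remove_nothing(self):
        values = pd.Series(7.0, index=[f"g{i}" for i in range(500)])
        retained, _ = filter_top_percent(values, 1.0)
        assert len(retained) == 500

    def test_nearest_rank_at_fifty_percent(self):
        values = pd.Series(np.arange(1.0, 11.0), index=[f"g{i}" for i in range(10)])
        retained, threshold = filter_top_percent(values, 50.0)
        assert threshold == 5.0
        assert sorted(values[retained]) == [1, 2, 3, 4, 5]

    def test_too_few_genes_warns_and_keeps_all(self):
        values = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="no resolution"):
            retained, _ = filter_top_percent(values, 1.0)
        assert len(retained) == 10

    @given(
        st.lists(st.floats(min_value=0, max_value=1e4), min_size=100, max_size=300),
        st.floats(min_value=0.5, max_value=20.0),
    )
    def test_removal_bound(self, values, percent):
        series = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
        if len(series) < 100.0 / percent:
            return
        retained, _ = filter_top_percent(series, percent)
        removed = len(series) - len(retained)
        assert removed <= math.ceil(percent / 100.0 * len(series))

    def test_commutes_with_max_reduction(self):
        # filtering the per-gene maxima = reducing then filtering: the filter
        # only ever sees maxima, so the pipeline order cannot matter
        rng = np.random.default_rng(5)
        table = ExpressionTable(
            pd.DataFrame(rng.gamma(2.0, 5.0, size=(200, 3)),
                         index=[f"g{i}" for i in range(200)])
        )
        retained, thr = filter_top_percent(table.per_gene_max)
        sub = ExpressionTable(table.values.loc[retained])
        assert (sub.per_gene_max <= thr).all()
        assert sub.per_gene_max.equals(table.per_gene_max.loc[retained])


class TestBinScheme:
    def test_half_open_rule(self):
        scheme = BinScheme(edges=(0.0, 1.0, 2.0, 3.0))
        assert scheme.assign([1.5])[0] == 1
        assert scheme.assign([1.0])[0] == 1
        assert scheme.assign([0.0])[0] == 0

    def test_last_edge_closed(self):
        scheme = BinScheme(edges=(0.0, 1.0, 2.0, 3.0))
        assert scheme.assign([3.0])[0] == 2

    def test_outside_edges_is_error(self):
        scheme = BinScheme(edges=(0.0, 1.0))
        with pytest.raises(ValueError, match="outside"):
            scheme.assign([1.5])

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            BinScheme(edges=(0.0, 0.0, 1.0))

    def test_degenerate_range_gets_single_usable_bin(self):
        scheme = BinScheme.from_data([2.0, 2.0, 2.0], n_bins=4)
        assert scheme.assign([2.0])[0] == 0

    def test_zero_expression_lands_in_bin_zero(self):
        log_vals = log_transform(pd.Series([0.0, 10.0, 100.0]))
        scheme = BinScheme.from_data(log_vals, n_bins=8)
        assert scheme.assign([log_vals.iloc[0]])[0] == 0

    def test_counts_match_bruteforce_interval_test(self):
        rng = np.random.default_rng(6)
        values = rng.normal(2.0, 1.0, size=1000)
        scheme = BinScheme.from_data(values, n_bins=8)
        assigned = assign_bins(
            pd.Series(values, index=[f"g{i}" for i in range(1000)]), scheme
        )
        edges = scheme.edges
        for b in range(scheme.n_bins):
            if b < scheme.n_bins - 1:
                expected = np.sum((values >= edges[b]) & (values < edges[b + 1]))
            else:
                expected = np.sum((values >= edges[b]) & (values <= edges[b + 1]))
            assert (assigned == b).sum() == expected
        assert assigned.value_counts().sum() == 1000
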