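"""Hit counts, normalized proportions, expression profiles and trend tests."""

import numpy as np
import pandas as pd
import pytest

from fracres.expression import BinScheme
from fracres.go_annotation import GoDag, GoTerm, annotate_sets
from fracres.homology import HomologySet, compute_all_F, gene_index
from fracres.stats import (
    ALL_GENES,
    adjust_benjamini_hochberg,
    expression_profile,
    expression_trend_test,
    functional_trend_test,
    gene_table,
    hit_counts,
    hit_table,
    normalized_proportions,
)

ROOT, CAT_A, CAT_B = "GO:0000001", "GO:0000002", "GO:0000003"
LEAF_A, LEAF_B = "GO:0000004", "GO:0000005"


@pytest.fixture()
def dag():
    def term(tid, name, *parents):
        return GoTerm(tid, name, "biological_process",
                      tuple(("is_a", p) for p in parents))

    return GoDag(
        {
            ROOT: term(ROOT, "root"),
            CAT_A: term(CAT_A, "class A", ROOT),
            CAT_B: term(CAT_B, "class B", ROOT),
            LEAF_A: term(LEAF_A, "leaf a", CAT_A),
            LEAF_B: term(LEAF_B, "leaf b", CAT_B),
        }
    )


def make_sets(spec):
    """spec: list of (copies per 2 species, {gene: leaf hits})."""
    sets, hits = [], {}
    for i, (copies, gene_hits) in enumerate(spec):
        members = {}
        g = 0
        for s, c in enumerate(copies):
            ids = []
            for _ in range(c):
                ids.append(f"g{i}_{g}")
                g += 1
            members[f"s{s}"] = ids
        sets.append(HomologySet(f"h{i}", members))
        for idx, terms in gene_hits.items():
            hits[f"g{i}_{idx}"] = set(terms)
    compute_all_F(sets)
    return sets, hits


class TestHitCounts:
    def test_single_set(self, dag):
        sets, hits = make_sets([((2, 1), {0: [LEAF_A]})])
        amap = annotate_sets(sets, hits, dag)
        assert hit_counts(sets, amap, dag, CAT_A) == {2: 1}

    def test_two_genes_same_category_count_once(self, dag):
        sets, hits = make_sets([((2, 1), {0: [LEAF_A], 1: [LEAF_A]})])
        amap = annotate_sets(sets, hits, dag)
        assert hit_counts(sets, amap, dag, CAT_A) == {2: 1}

    def test_unknown_category_raises(self, dag):
        sets, hits = make_sets([((1, 1), {0: [LEAF_A]})])
        amap = annotate_sets(sets, hits, dag)
        with pytest.raises(KeyError):
            hit_counts(sets, amap, dag, "GO:9999999")

    def test_unannotated_sets_do_not_dilute(self, dag):
        sets, hits = make_sets([((2, 2), {0: [LEAF_A]}), ((2, 2), {})])
        amap = annotate_sets(sets, hits, dag)
        table = hit_table(sets, amap, dag, "biological_process")
        assert table.loc[3].sum() == 1  # the unannotated set is excluded


class TestNormalizedProportions:
    def test_single_category_normalizes_to_one(self, dag):
        sets, hits = make_sets([((1, 1), {0: [LEAF_A]}), ((2, 2), {0: [LEAF_A]})])
        amap = annotate_sets(sets, hits, dag)
        table = hit_table(sets, amap, dag, "biological_process")
        props = normalized_proportions(table[[CAT_A]])
        assert (props[CAT_A] == 1.0).all()

    def test_equal_hits_split_evenly(self, dag):
        sets, hits = make_sets(
            [((1, 1), {0: [LEAF_A]}), ((1, 1), {0: [LEAF_B]})]
        )
        amap = annotate_sets(sets, hits, dag)
        table = hit_table(sets, amap, dag, "biological_process")
        props = normalized_proportions(table[[CAT_A, CAT_B]])
        assert props.loc[1, CAT_A] == 0.5 and props.loc[1, CAT_B] == 0.5

    def test_empty_stratum_is_missing_not_zero(self):
        table = pd.DataFrame({"a": [2, 0], "b": [2, 0]}, index=[1, 2])
        props = normalized_proportions(table)
        assert np.isnan(props.loc[2, "a"])

    def test_scale_invariance_under_replication(self, dag):
        spec = [
            ((2, 1), {0: [LEAF_A]}),
            ((1, 1), {0: [LEAF_B]}),
            ((2, 2), {0: [LEAF_A], 1: [LEAF_B]}),
        ]
        sets1, hits1 = make_sets(spec)
        sets3, hits3 = make_sets(spec * 3)
        amap1 = annotate_sets(sets1, hits1, dag)
        amap3 = annotate_sets(sets3, hits3, dag)
        p1 = normalized_proportions(hit_table(sets1, amap1, dag, "biological_process"))
        p3 = normalized_proportions(hit_table(sets3, amap3, dag, "biological_process"))
        pd.testing.assert_frame_equal(p1, p3)


def make_gene_df(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "set_id", "F", "max_rpkm"])
    df["species_id"] = "s0"
    df["log_max"] = np.log10(df["max_rpkm"] + 1.0)
    return df


class TestExpressionProfile:
    scheme = BinScheme(edges=(0.0, 1.0, 2.0, 3.0))

    def test_single_gene_stratum(self):
        df = make_gene_df([("g1", "h1", 2, 7.0)])
        prof = expression_profile(df, self.scheme)
        assert prof.mean_by_F == {2: 7.0}
        assert prof.category == ALL_GENES

    def test_simple_average(self):
        df = make_gene_df([("g1", "h1", 1, 2.0), ("g2", "h1", 1, 4.0)])
        prof = expression_profile(df, self.scheme)
        assert prof.mean_by_F == {1: 3.0}

    def test_empty_stratum_absent(self):
        df = make_gene_df([("g1", "h1", 3, 5.0)])
        prof = expression_profile(df, self.scheme)
        assert set(prof.mean_by_F) == {3}

    def test_bin_proportions_sum_to_one(self):
        df = make_gene_df(
            [(f"g{i}", "h1", 1 + i % 3, float(i)) for i in range(30)]
        )
        prof = expression_profile(df, self.scheme)
        for f, props in prof.bin_props_by_F.items():
            assert props.sum() == pytest.approx(1.0, abs=1e-9)
            assert len(props) == self.scheme.n_bins


class TestFunctionalTrend:
    def test_membership_increasing_with_F_is_resistant(self, dag):
        spec = []
        for f_target, n in ((1, 40), (2, 40), (3, 40)):
            copies = (2,) * (f_target - 1) + (1,) * (3 - f_target)
            member_prob = {1: 0.1, 2: 0.5, 3: 0.9}[f_target]
            rng = np.random.default_rng(f_target)
            for _ in range(n):
                leaf = LEAF_A if rng.random() < member_prob else LEAF_B
                spec.append((copies, {0: [leaf]}))
        sets, hits = make_sets(spec)
        amap = annotate_sets(sets, hits, dag)
        res = functional_trend_test(sets, amap, dag, CAT_A)
        assert res.slope > 0 and res.verdict == "resistant"
        res_b = functional_trend_test(sets, amap, dag, CAT_B)
        assert res_b.slope < 0 and res_b.verdict == "prone"

    def test_constant_membership_not_significant(self, dag):
        sets, hits = make_sets(
            [((1, 1), {0: [LEAF_A]}), ((2, 2), {0: [LEAF_A]})] * 5
        )
        amap = annotate_sets(sets, hits, dag)
        res = functional_trend_test(sets, amap, dag, CAT_A)
        assert res.p_value == 1.0 and res.verdict == "not_significant"


class TestExpressionTrend:
    def test_expression_increasing_with_F(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(300):
            f = 1 + i % 3
            rows.append((f"g{i}", f"h{i}", f, float(10 ** (0.3 * f) + rng.random())))
        res = expression_trend_test(make_gene_df(rows))
        assert res.slope > 0 and res.verdict == "resistant"

    def test_constant_F_not_significant(self):
        df = make_gene_df([(f"g{i}", "h1", 2, float(i)) for i in range(10)])
        res = expression_trend_test(df)
        assert res.verdict == "not_significant" and res.p_value == 1.0

    def test_category_filter_requires_annotation_map(self):
        df = make_gene_df([("g1", "h1", 1, 1.0)])
        with pytest.raises(ValueError):
            expression_trend_test(df, category=CAT_A)


def test_benjamini_hochberg_never_decreases_p(dag):
    sets, hits = make_sets(
        [((2, 1), {0: [LEAF_A]}), ((1, 1), {0: [LEAF_B]}), ((2, 2), {0: [LEAF_A]})]
    )
    amap = annotate_sets(sets, hits, dag)
    raw = [functional_trend_test(sets, amap, dag, c) for c in (CAT_A, CAT_B)]
    adj = adjust_benjamini_hochberg(raw)
    for r, a in zip(raw, adj):
        assert a.p_value >= r.p_value - 1e-12
        assert a.category == r.category


def test_gene_table_inherits_F_and_filters(dag):
    sets, hits = make_sets([((2, 1), {0: [LEAF_A]})])
    records = gene_index(sets)
    pgm = pd.Series([5.0, 10.0, 99.0], index=["g0_0", "g0_1", "g0_2"])
    retained = pd.Index(["g0_0", "g0_1"])
    df = gene_table(records, {hs.set_id: hs for hs in sets}, pgm, retained)
    assert set(df["gene_id"]) == {"g0_0", "g0_1"}
    assert (df["F"] == 2).all()
    assert df.loc[df["gene_id"] == "g0_1", "log_max"].iloc[0] == pytest.approx(
        np.log10(11.0)
    )
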