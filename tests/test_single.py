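"""single_methylome: correlation, ordinal association, grouping, metagene."""

import numpy as np
import pandas as pd
import pytest

from methget import (
    DataError,
    ExpressionTable,
    assign_expression_groups,
    correlate,
    grouping_statistics,
    metagene_region,
    metagene_site,
    ordinal_association,
)
from methget.io import GeneModel

from conftest import make_meth_table, make_record


def expr_of(mapping):
    return ExpressionTable.from_mapping(mapping)


class TestCorrelate:
    def test_perfect_anticorrelation(self):
        meth = make_meth_table({"a": 0.0, "b": 0.5, "c": 1.0})
        expr = expr_of({"a": 10.0, "b": 5.0, "c": 0.0})
        res = correlate(meth, expr, "CG", "genebody")
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.spearman_rho == pytest.approx(-1.0)
        assert res.n_genes == 3

    def test_zero_variance_reported_missing(self):
        meth = make_meth_table({"a": 0.3, "b": 0.3, "c": 0.3})
        expr = expr_of({"a": 1.0, "b": 2.0, "c": 3.0})
        res = correlate(meth, expr, "CG", "genebody")
        assert res.pearson_r is None
        assert "zero variance" in res.message

    def test_too_few_genes(self):
        meth = make_meth_table({"a": 0.1, "b": 0.9})
        expr = expr_of({"a": 1.0, "b": 2.0})
        with pytest.raises(DataError, match=">=3"):
            correlate(meth, expr, "CG", "genebody")

    def test_missing_genes_excluded_and_counted(self):
        meth = make_meth_table({"a": 0.1, "b": 0.5, "c": 0.9, "d": 0.2})
        expr = expr_of({"a": 1.0, "b": 2.0, "c": 3.0, "e": 4.0})
        res = correlate(meth, expr, "CG", "genebody")
        assert res.n_genes == 3
        assert res.n_excluded == 2  # d (no expr) + e (no meth)

    def test_pearson_invariant_under_affine_expression_rescale(self):
        rng = np.random.default_rng(0)
        levels = rng.random(30)
        ex = rng.random(30) * 10
        meth = make_meth_table({f"g{i}": levels[i] for i in range(30)})
        r1 = correlate(meth, expr_of({f"g{i}": ex[i] for i in range(30)}),
                       "CG", "genebody").pearson_r
        r2 = correlate(meth, expr_of({f"g{i}": 3 * ex[i] + 2 for i in range(30)}),
                       "CG", "genebody").pearson_r
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        levels = rng.random(30)
        ex = rng.random(30) * 10
        meth = make_meth_table({f"g{i}": levels[i] for i in range(30)})
        s1 = correlate(meth, expr_of({f"g{i}": ex[i] for i in range(30)}),
                       "CG", "genebody").spearman_rho
        s2 = correlate(meth, expr_of({f"g{i}": np.expm1(ex[i]) for i in range(30)}),
                       "CG", "genebody").spearman_rho
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_pvalue_matches_t_formula(self):
        rng = np.random.default_rng(2)
        n = 50
        levels = rng.random(n)
        ex = levels * 2 + rng.normal(0, 0.5, n)
        meth = make_meth_table({f"g{i}": levels[i] for i in range(n)})
        res = correlate(meth, expr_of({f"g{i}": abs(ex[i]) for i in range(n)}),
                        "CG", "genebody")
        from scipy import stats

        r = res.pearson_r
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert res.pearson_p == pytest.approx(p, rel=1e-9)


class TestOrdinal:
    def test_boundary_index(self):
        meth = make_meth_table({g: 0.5 for g in "abcde"})
        expr = expr_of({"a": 0.0, "b": 0.0, "c": 1.0, "d": 2.0, "e": 3.0})
        res = ordinal_association(meth, expr, "CG", "genebody", ma_window=2)
        assert res.boundary_index == 2

    def test_constant_methylation_constant_curve(self):
        meth = make_meth_table({f"g{i}": 0.4 for i in range(20)})
        expr = expr_of({f"g{i}": float(i) for i in range(20)})
        res = ordinal_association(meth, expr, "CG", "genebody")
        assert np.allclose(res.curve, 0.4)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(3)
        meth = make_meth_table({f"g{i}": rng.random() for i in range(15)})
        expr = expr_of({f"g{i}": float(i) for i in range(15)})
        res = ordinal_association(meth, expr, "CG", "genebody", ma_window=1)
        assert np.array_equal(res.curve, res.table["level"].to_numpy())

    def test_ties_broken_by_gene_name(self):
        meth = make_meth_table({"b": 0.1, "a": 0.9, "c": 0.5})
        expr = expr_of({"a": 1.0, "b": 1.0, "c": 1.0})
        res = ordinal_association(meth, expr, "CG", "genebody", ma_window=1)
        assert res.table["gene"].tolist() == ["a", "b", "c"]


class TestGrouping:
    def test_quantile_bins_of_equal_size(self):
        meth = make_meth_table({f"g{i:02d}": 0.5 for i in range(10)})
        expr = expr_of({f"g{i:02d}": float(i + 1) for i in range(10)})
        res = grouping_statistics(meth, expr, "CG", "genebody", n_quantiles=5)
        assert res.table["n"].tolist() == [2, 2, 2, 2, 2]
        # 1st quantile holds the lowest-expressed genes
        g1 = res.membership[res.membership == 1].index.tolist()
        assert sorted(g1) == ["g00", "g01"]

    def test_group_sizes_differ_by_at_most_one(self):
        meth = make_meth_table({f"g{i:02d}": 0.5 for i in range(13)})
        expr = expr_of({f"g{i:02d}": float(i + 1) for i in range(13)})
        res = grouping_statistics(meth, expr, "CG", "genebody", n_quantiles=5)
        sizes = res.table["n"]
        assert sizes.max() - sizes.min() <= 1

    def test_monotone_methylation_gives_monotone_group_means(self):
        n = 50
        meth_map = {f"g{i:02d}": 1.0 - i / n for i in range(n)}
        expr_map = {f"g{i:02d}": float(i + 1) for i in range(n)}
        res = grouping_statistics(make_meth_table(meth_map), expr_of(expr_map),
                                  "CG", "genebody", n_quantiles=5)
        # brute-force expected means from the construction
        means = res.table.set_index("group")["mean"]
        expected = [np.mean([1.0 - i / n for i in range(10 * k, 10 * k + 10)])
                    for k in range(5)]
        assert np.allclose(means.loc[[1, 2, 3, 4, 5]], expected)
        assert all(np.diff(means.loc[[1, 2, 3, 4, 5]]) < 0)

    def test_group_zero_holds_unexpressed(self):
        meth = make_meth_table({f"g{i}": 0.5 for i in range(12)})
        emap = {f"g{i}": float(i) for i in range(12)}  # g0 -> 0.0
        res = grouping_statistics(make_meth_table({f"g{i}": 0.5 for i in range(12)}),
                                  expr_of(emap), "CG", "genebody", n_quantiles=5)
        assert res.membership["g0"] == 0

    def test_exclude_unexpressed(self):
        emap = {f"g{i}": float(i) for i in range(12)}
        res = grouping_statistics(make_meth_table({f"g{i}": 0.5 for i in range(12)}),
                                  expr_of(emap), "CG", "genebody", n_quantiles=5,
                                  include_unexpressed=False)
        assert 0 not in res.membership.values
        assert res.n_zero_excluded == 1

    def test_membership_is_permutation_of_analyzed_genes(self):
        rng = np.random.default_rng(4)
        n = 37
        meth = make_meth_table({f"g{i:02d}": rng.random() for i in range(n)})
        expr = expr_of({f"g{i:02d}": float(rng.integers(0, 50)) for i in range(n)})
        res = grouping_statistics(meth, expr, "CG", "genebody", n_quantiles=4)
        assert sorted(res.membership.index) == [f"g{i:02d}" for i in range(n)]
        assert not res.membership.index.has_duplicates

    def test_too_few_expressed_genes(self):
        meth = make_meth_table({"a": 0.1, "b": 0.2, "c": 0.3})
        expr = expr_of({"a": 1.0, "b": 2.0, "c": 0.0})
        with pytest.raises(DataError, match="bins"):
            grouping_statistics(meth, expr, "CG", "genebody", n_quantiles=5)


def _uniform_records(chrom, lo, hi, level=0.6, step=10, context="CG", total=10):
    meth = int(round(level * total))
    return [make_record(chrom, pos, "+", context, meth, total)
            for pos in range(lo, hi + 1, step)]


class TestMetageneRegion:
    def test_constant_field_gives_constant_profile(self):
        genes = [GeneModel(f"g{i}", "Chr1", "+", 10000 + 20000 * i,
                           10000 + 20000 * i + 2999,
                           exons=((10000 + 20000 * i, 10000 + 20000 * i + 2999),))
                 for i in range(4)]
        records = []
        for g in genes:
            records += _uniform_records("Chr1", g.start - 1500, g.end + 1500)
        expr = expr_of({g.gene_id: float(i + 1) for i, g in enumerate(genes)})
        prof = metagene_region(records, genes, expr, "CG", n_groups=2)
        assert np.allclose(prof.matrix.to_numpy(), 0.6)
        assert prof.matrix.shape == (2, 60)  # 15 + 30 + 15

    def test_strand_flip_mirror_profiles_identical(self):
        # one + and one - gene with mirror-image methylation gradients
        gp = GeneModel("gp", "Chr1", "+", 10000, 12999, exons=((10000, 12999),))
        gm = GeneModel("gm", "Chr2", "-", 10000, 12999, exons=((10000, 12999),))
        records = []
        span = range(10000 - 1500, 12999 + 1500 + 1, 25)
        for pos in span:
            frac = (pos - (10000 - 1500)) / (12999 + 1500 - (10000 - 1500))
            meth = int(round(frac * 10))
            records.append(make_record("Chr1", pos, "+", "CG", meth, 10))
        for pos in span:
            # mirrored within the same span: methylation decreasing genomically
            mirror = (10000 - 1500) + (12999 + 1500) - pos
            frac = (mirror - (10000 - 1500)) / (12999 + 1500 - (10000 - 1500))
            meth = int(round(frac * 10))
            records.append(make_record("Chr2", pos, "+", "CG", meth, 10))
        expr = expr_of({"gp": 1.0, "gm": 2.0})
        prof = metagene_region(records, [gp, gm], expr, "CG", n_groups=2)
        row_p = prof.matrix.loc[1].to_numpy()  # gp alone in group 1
        row_m = prof.matrix.loc[2].to_numpy()
        np.testing.assert_allclose(row_p, row_m, rtol=1e-12)

    def test_short_genes_excluded(self):
        short = GeneModel("s", "Chr1", "+", 100, 110, exons=((100, 110),))
        ok = [GeneModel(f"g{i}", "Chr1", "+", 10000 * (i + 1), 10000 * (i + 1) + 2999,
                        exons=((10000 * (i + 1), 10000 * (i + 1) + 2999),))
              for i in range(2)]
        records = []
        for g in ok:
            records += _uniform_records("Chr1", g.start, g.end)
        expr = expr_of({"s": 1.0, "g0": 2.0, "g1": 3.0})
        prof = metagene_region(records, [short] + ok, expr, "CG", n_groups=2)
        assert prof.n_excluded_short == 1

    def test_no_qualifying_genes_fatal(self):
        g = GeneModel("s", "Chr1", "+", 100, 110, exons=((100, 110),))
        with pytest.raises(DataError, match="length filter"):
            metagene_region([make_record(pos=105)], [g],
                            expr_of({"s": 1.0}), "CG")

    def test_body_window_mean_matches_site_mean_level(self):
        # uniform sites, body length divisible by 30: mean of the 30 body
        # windows equals the gene-body site_mean level exactly
        g = GeneModel("g", "Chr1", "+", 3001, 6000, exons=((3001, 6000),))
        g2 = GeneModel("g2", "Chr1", "+", 30001, 33000, exons=((30001, 33000),))
        rng = np.random.default_rng(5)
        records = []
        for gg in (g, g2):
            for pos in range(gg.start, gg.end + 1, 10):
                records.append(make_record("Chr1", pos, "+", "CG",
                                           int(rng.integers(0, 11)), 10))
        expr = expr_of({"g": 1.0, "g2": 2.0})
        prof = metagene_region(records, [g, g2], expr, "CG", n_groups=2,
                               estimator="site_mean")
        body = prof.matrix.loc[1, [f"b{i + 1}" for i in range(30)]].to_numpy()
        site_levels = [r.level for r in records
                       if r.chrom == "Chr1" and g.start <= r.pos <= g.end]
        assert np.mean(body) == pytest.approx(np.mean(site_levels), rel=1e-12)


class TestMetageneSite:
    def test_window_count_and_width(self):
        g = GeneModel("g", "Chr1", "+", 10000, 12999, exons=((10000, 12999),))
        g2 = GeneModel("g2", "Chr1", "+", 50000, 52999, exons=((50000, 52999),))
        records = (_uniform_records("Chr1", 8000, 12000)
                   + _uniform_records("Chr1", 48000, 52000))
        expr = expr_of({"g": 1.0, "g2": 2.0})
        prof = metagene_site(records, [g, g2], expr, "CG", flank_bp=2000,
                             n_windows=10, n_groups=2)
        assert prof.matrix.shape[1] == 20

    def test_single_base_resolution_reproduces_site_levels(self):
        g = GeneModel("g", "Chr1", "+", 1000, 1999, exons=((1000, 1999),))
        g2 = GeneModel("g2", "Chr1", "+", 5000, 5999, exons=((5000, 5999),))
        records = [make_record("Chr1", 990, "+", "CG", 3, 10),
                   make_record("Chr1", 1005, "+", "CG", 7, 10),
                   make_record("Chr1", 4990, "+", "CG", 2, 10),
                   make_record("Chr1", 5005, "+", "CG", 9, 10)]
        expr = expr_of({"g": 1.0, "g2": 2.0})
        prof = metagene_site(records, [g, g2], expr, "CG", flank_bp=50,
                             n_windows=50, n_groups=2, estimator="site_mean")
        row = prof.matrix.loc[1].to_numpy()
        # offsets: 990 - 1000 = -10 -> window 40; 1005 - 1000 = +5 -> window 55
        assert row[40] == pytest.approx(0.3)
        assert row[55] == pytest.approx(0.7)
        assert np.isnan(np.delete(row, [40, 55])).all()

    def test_minus_strand_downstream_maps_upstream(self):
        # same genomic records; minus-strand gene reverses the oriented axis
        gp = GeneModel("gp", "Chr1", "+", 1000, 1999, exons=((1000, 1999),))
        gm = GeneModel("gm", "Chr1", "-", 1, 1000, exons=((1, 1000),))
        # gm TSS = 1000 (high coordinate); gp TSS = 1000 as well
        records = [make_record("Chr1", 1100, "+", "CG", 8, 10)]
        expr = expr_of({"gp": 1.0, "gm": 2.0})
        prof = metagene_site(records, [gp, gm], expr, "CG", flank_bp=200,
                             n_windows=4, n_groups=2)
        row_p = prof.matrix.loc[1].to_numpy()
        row_m = prof.matrix.loc[2].to_numpy()
        # offset +100 for gp -> downstream half; offset -100 for gm -> upstream
        assert not np.isnan(row_p[6])
        assert not np.isnan(row_m[2])
        assert np.isnan(row_m[6])

    def test_tes_anchor(self):
        g = GeneModel("g", "Chr1", "+", 1000, 1999, exons=((1000, 1999),))
        g2 = GeneModel("g2", "Chr1", "+", 5000, 5999, exons=((5000, 5999),))
        records = [make_record("Chr1", 1995, "+", "CG", 5, 10),
                   make_record("Chr1", 5995, "+", "CG", 5, 10)]
        expr = expr_of({"g": 1.0, "g2": 2.0})
        prof = metagene_site(records, [g, g2], expr, "CG", anchor="TES",
                             flank_bp=100, n_windows=2, n_groups=2)
        assert np.nansum(prof.matrix.to_numpy()) > 0

    def test_bad_anchor(self):
        with pytest.raises(DataError, match="anchor"):
            metagene_site([], [], expr_of({"a": 1.0}), "CG", anchor="MIDDLE")


class TestAssignGroups:
    def test_concatenation_is_permutation(self):
        rng = np.random.default_rng(6)
        expr = pd.Series(rng.integers(0, 30, 40).astype(float),
                         index=[f"g{i:02d}" for i in range(40)])
        groups = assign_expression_groups(expr, n_groups=5)
        assert sorted(groups.index) == sorted(expr.index)
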