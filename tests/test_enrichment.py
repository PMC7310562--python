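import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from devtraj import core, enrichment as enr, simulate
from devtraj.benchmarks import exact_tail_pvalue


def _stage(values, ids_prefix, scale="log2"):
    values = np.asarray(values, dtype=float)
    samples = [
        core.SampleMeta(f"{ids_prefix}{i}", "human", "V1C", 50.0 + i)
        for i in range(values.shape[1])
    ]
    return core.ExpressionDataset(
        values=values,
        gene_ids=[f"g{j}" for j in range(values.shape[0])],
        samples=samples,
        scale=scale,
    )


class TestBHAdjust:
    def test_hand_computed_example(self):
        out = enr.bh_adjust(np.array([0.01, 0.04, 0.03, 0.005]))
        np.testing.assert_allclose(out, [0.02, 0.04, 0.04, 0.02])

    def test_all_equal(self):
        np.testing.assert_allclose(enr.bh_adjust(np.full(5, 0.2)), np.full(5, 0.2))

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(enr.bh_adjust(np.array([0.3])), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(core.DataError):
            enr.bh_adjust(np.array([0.5, 1.2]))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_properties_vs_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        ours = enr.bh_adjust(p)
        assert np.all(ours >= p - 1e-12)  # adjusted >= raw
        assert np.all(ours <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(ours[order]) >= -1e-12)  # monotone in p
        reference = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, reference, atol=1e-12)


class TestDifferentialExpression:
    def test_closed_form_t_oracle(self):
        rng = np.random.default_rng(0)
        e = 1.0 + rng.normal(0, 0.1, size=(1, 10))
        l = 2.0 + rng.normal(0, 0.1, size=(1, 10))
        result = enr.differential_expression(_stage(e, "e"), _stage(l, "l"))
        row = result.table.iloc[0]
        # Welch statistic computed directly
        se = np.sqrt(e.var(ddof=1) / 10 + l.var(ddof=1) / 10)
        t = (l.mean() - e.mean()) / se
        from scipy import stats

        nu = (e.var(ddof=1) / 10 + l.var(ddof=1) / 10) ** 2 / (
            (e.var(ddof=1) / 10) ** 2 / 9 + (l.var(ddof=1) / 10) ** 2 / 9
        )
        expected_p = 2 * stats.t.sf(abs(t), nu)
        assert row.pvalue == pytest.approx(expected_p, rel=1e-9)
        assert row.log2fc == pytest.approx(l.mean() - e.mean())
        assert row.direction == "up_late"

    def test_identical_groups_not_significant(self):
        vals = np.tile(np.arange(8.0), (3, 1))
        result = enr.differential_expression(_stage(vals, "e"), _stage(vals, "l"))
        assert (result.table.direction == "ns").all()
        assert (result.table.pvalue > 0.9).all()

    def test_fold_change_gate(self):
        """A tiny but ultra-consistent difference fails the FC > 1.5 gate."""
        rng = np.random.default_rng(1)
        e = rng.normal(0, 0.01, size=(1, 12))
        l = 0.3 + rng.normal(0, 0.01, size=(1, 12))  # FC = 2^0.3 ~ 1.23
        result = enr.differential_expression(_stage(e, "e"), _stage(l, "l"))
        row = result.table.iloc[0]
        assert row.fdr < 0.05
        assert row.direction == "ns"

    def test_linear_scale_rejected(self):
        ds = _stage(np.ones((2, 4)), "e", scale="linear")
        with pytest.raises(core.DataError, match="log2"):
            enr.differential_expression(ds, ds)

    def test_direction_invariant(self, small_config):
        ds_h, *_ = simulate.generate(small_config)
        early, late = core.split_by_age(
            core.log2_transform(ds_h), small_config.transition_age_human
        )
        result = enr.differential_expression(early, late)
        t = result.table
        called = t.direction != "ns"
        assert (
            called
            == ((t.fdr < result.fdr_cut) & (t.fold_change.abs() > result.fc_cut))
        ).all()


class TestSelectMarkers:
    def _means(self, matrix):
        return simulate.CellTypeMeans(
            values=np.asarray(matrix, dtype=float),
            cell_types=["neuron", "glia", "micro"],
            gene_ids=["g1", "g2", "g3"],
        )

    def test_five_fold_rule(self):
        means = self._means([[10.0, 10.0, 5.0], [2.0, 3.0, 0.0], [1.0, 2.9, 0.0]])
        sets = enr.select_markers(means, fold=5.0)
        # g1: 10 >= 5*2 -> neuron marker; g2: 10 < 5*3 -> none;
        # g3: expressed only in neuron -> marker
        assert sets.sets == {"neuron": ["g1", "g3"]}

    def test_all_zero_gene_not_marker(self):
        means = simulate.CellTypeMeans(
            values=np.zeros((3, 1)), cell_types=["a", "b", "c"], gene_ids=["g"]
        )
        assert enr.select_markers(means).sets == {}

    def test_single_cell_type_rejected(self):
        means = simulate.CellTypeMeans(
            values=np.ones((1, 2)), cell_types=["a"], gene_ids=["g1", "g2"]
        )
        with pytest.raises(core.DataError):
            enr.select_markers(means)

    def test_planted_markers_recovered(self, small_config):
        _, _, truth, cell_means = simulate.generate(small_config)
        sets = enr.select_markers(cell_means, fold=small_config.marker_fold)
        for cell_type, genes in truth.markers.items():
            assert set(genes) <= set(sets.sets[cell_type])


class TestFisherEnrichment:
    @given(
        n_universe=st.integers(2, 200),
        data=st.data(),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_pvalue_matches_exact_tail(self, n_universe, data):
        n_set = data.draw(st.integers(1, n_universe))
        n_query = data.draw(st.integers(1, n_universe))
        k_lo = max(0, n_query + n_set - n_universe)
        k = data.draw(st.integers(k_lo, min(n_query, n_set)))
        p = enr.overrep_pvalue(k, n_query, n_set, n_universe)
        assert p == pytest.approx(exact_tail_pvalue(k, n_query, n_set, n_universe), abs=1e-12)

    def test_disjoint_set_pvalue_one(self):
        sets = core.GeneSetCollection(sets={"s": ["g8", "g9"]})
        universe = [f"g{i}" for i in range(10)]
        result = enr.fisher_enrichment(["g0", "g1"], sets, universe)
        assert result.table.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_query_equals_set_is_extreme(self):
        universe = [f"g{i}" for i in range(30)]
        sets = core.GeneSetCollection(sets={"s": universe[:5]})
        result = enr.fisher_enrichment(universe[:5], sets, universe)
        assert result.table.loc["s", "pvalue"] == pytest.approx(
            exact_tail_pvalue(5, 5, 5, 30), abs=1e-12
        )
        assert np.isfinite(result.table.loc["s", "odds_ratio"])  # Haldane-corrected

    def test_query_outside_universe_rejected(self):
        sets = core.GeneSetCollection(sets={"s": ["g1"]})
        with pytest.raises(core.DataError):
            enr.fisher_enrichment(["not_there"], sets, ["g1", "g2"])

    def test_planted_marker_sets_enriched(self, small_config):
        """A planted marker set is strongly over-represented in itself when
        run through the full enrichment interface."""
        _, _, truth, cell_means = simulate.generate(small_config)
        markers = enr.select_markers(cell_means, fold=small_config.marker_fold)
        universe = list(cell_means.gene_ids)
        first = next(iter(markers.sets))
        result = enr.fisher_enrichment(markers.sets[first], markers, universe)
        assert result.table.loc[first, "fdr"] < 1e-6
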