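import dataclasses

import networkx as nx
import numpy as np
import pytest

from devtraj import core, network as net, simulate
from devtraj.benchmarks import (
    _planted_block_data,
    adjusted_rand_index,
    naive_neighborhood_sizes,
    naive_tom,
)


class TestTopologicalOverlap:
    def test_triangle_all_ones(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = net.topological_overlap(a)
        np.testing.assert_allclose(tom, np.ones((3, 3)))

    def test_zero_adjacency(self):
        tom = net.topological_overlap(np.zeros((4, 4)))
        np.testing.assert_allclose(tom, np.eye(4))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(4, 10))
            a = rng.uniform(size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            assert np.max(np.abs(net.topological_overlap(a) - naive_tom(a))) < 1e-12

    def test_asymmetric_rejected(self):
        a = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(core.DataError, match="symmetric"):
            net.topological_overlap(a)


class TestDetectModules:
    def test_two_planted_blocks(self):
        rng = np.random.default_rng(1)
        expr, labels = _planted_block_data(rng, [50, 50], 0.7, 100, 40)
        genes = [f"g{i}" for i in range(expr.shape[0])]
        adj = np.abs(np.corrcoef(expr)) ** 6
        np.fill_diagonal(adj, 0.0)
        modules = net.detect_modules(net.topological_overlap(adj), genes)
        pred = [modules.assignment[g] for g in genes]
        assert len(modules.modules()) == 2
        assert adjusted_rand_index(labels, pred) >= 0.9

    def test_pure_noise_gives_no_modules(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(size=(80, 40))
        genes = [f"g{i}" for i in range(80)]
        adj = np.abs(np.corrcoef(expr)) ** 6
        np.fill_diagonal(adj, 0.0)
        modules = net.detect_modules(net.topological_overlap(adj), genes)
        assert modules.modules() == {}

    def test_min_size_filter(self):
        rng = np.random.default_rng(3)
        expr, _ = _planted_block_data(rng, [60, 40, 20], 0.7, 0, 40)
        genes = [f"g{i}" for i in range(expr.shape[0])]
        adj = np.abs(np.corrcoef(expr)) ** 6
        np.fill_diagonal(adj, 0.0)
        modules = net.detect_modules(
            net.topological_overlap(adj), genes, min_module_size=30
        )
        sizes = sorted(len(g) for g in modules.modules().values())
        assert len(sizes) == 2  # the 20-gene block is dissolved
        assert sizes[-1] >= 55 and sizes[0] >= 35


class TestSoftPower:
    def test_deterministic(self):
        rng = np.random.default_rng(4)
        expr, _ = _planted_block_data(rng, [40, 40], 0.7, 40, 40)
        assert net.pick_soft_power(expr) == net.pick_soft_power(expr)

    def test_uncorrelated_data_falls_back_with_warning(self):
        rng = np.random.default_rng(5)
        expr = rng.normal(size=(30, 200))
        with pytest.warns(UserWarning, match="scale-free"):
            p = net.pick_soft_power(expr, target_r2=0.999)
        assert 1 <= p <= 20


class TestMDC:
    def _stages(self, seed, rho_early, rho_late, n=40, size=20):
        rng = np.random.default_rng(seed)
        e, _ = _planted_block_data(rng, [size], rho_early, 0, n)
        l, _ = _planted_block_data(rng, [size], rho_late, 0, n)
        genes = [f"g{i}" for i in range(size)]

        def ds(vals, prefix):
            samples = [
                core.SampleMeta(f"{prefix}{i}", "human", "V1C", 50.0 + i)
                for i in range(vals.shape[1])
            ]
            return core.ExpressionDataset(
                values=vals, gene_ids=genes, samples=samples, scale="log2z"
            )

        return ds(e, "e"), ds(l, "l"), genes

    def test_gain_detected(self):
        early, late, genes = self._stages(0, 0.8, 0.1)
        value, klass = net.mdc(genes, early, late, soft_power=6)
        assert value > 0.5
        assert klass == "gain"

    def test_identical_stages_class_none(self):
        early, _, genes = self._stages(1, 0.5, 0.5)
        value, klass = net.mdc(genes, early, early, soft_power=6)
        assert value == 0.0
        assert klass == "none"

    def test_antisymmetry_exact(self):
        early, late, genes = self._stages(2, 0.7, 0.2)
        v1, _ = net.mdc(genes, early, late, soft_power=6)
        v2, _ = net.mdc(genes, late, early, soft_power=6)
        assert v1 == -v2

    def test_planted_classes_recovered(self, small_config):
        cfg = dataclasses.replace(
            small_config, n_modules=3, module_size=20, n_switch=20, replicates_per_age=3
        )
        ds_h, _, truth, _ = simulate.generate(cfg)
        z = core.log2_z_transform(ds_h)
        early, late = core.split_by_age(z, cfg.transition_age_human)
        ok = 0
        for name, (genes, klass) in truth.module_blocks.items():
            _, got = net.mdc(genes, early, late, soft_power=6, seed=0)
            ok += got == klass
        assert ok >= 2

    def test_module_too_small_rejected(self):
        early, late, genes = self._stages(3, 0.7, 0.2)
        with pytest.raises(core.DataError):
            net.mdc(genes[:2], early, late)


class TestMINetwork:
    def test_gaussian_mi_estimator_accuracy(self):
        rng = np.random.default_rng(6)
        rho = 0.6
        errs = []
        for _ in range(10):
            x = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=500).T
            errs.append(net._copula_mi_matrix(x)[0, 1] - (-0.5 * np.log(1 - rho**2)))
        assert abs(float(np.mean(errs))) < 0.05

    def test_chain_indirect_edge_removed_by_dpi(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        y = x + rng.normal(0, 0.5, 100)
        z = y + rng.normal(0, 0.5, 100)
        result = net.mi_network(np.vstack([x, y, z]), ["X", "Y", "Z"], seed=0)
        edges = {tuple(sorted(e[:2])) for e in result.edges}
        assert edges == {("X", "Y"), ("Y", "Z")}

    def test_independent_genes_no_edges(self):
        rng = np.random.default_rng(8)
        expr = rng.normal(size=(12, 60))
        result = net.mi_network(expr, [f"g{i}" for i in range(12)], seed=0)
        assert result.graph.number_of_edges() == 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(core.DataError):
            net.mi_network(np.random.default_rng(0).normal(size=(4, 5)), list("abcd"))


class TestKeyDrivers:
    def _net_from_graph(self, graph):
        return net.MINetwork(graph=graph, nodes=list(graph.nodes))

    def test_star_center_unique_hub(self):
        star = nx.relabel_nodes(nx.star_graph(10), {i: f"n{i}" for i in range(11)})
        hubs = net.key_drivers(self._net_from_graph(star), hops=1)
        assert hubs == ["n0"]

    def test_ring_has_no_hubs(self):
        ring = nx.relabel_nodes(nx.cycle_graph(12), {i: f"n{i}" for i in range(12)})
        assert net.key_drivers(self._net_from_graph(ring), hops=2) == []

    def test_neighborhood_sizes_match_bfs_oracle(self):
        rng = np.random.default_rng(9)
        graph = nx.gnp_random_graph(30, 0.15, seed=3)
        graph = nx.relabel_nodes(graph, {i: f"n{i}" for i in range(30)})
        wrapped = self._net_from_graph(graph)
        ours = net.neighborhood_sizes(wrapped, hops=2)
        oracle = naive_neighborhood_sizes(
            [(u, v) for u, v in graph.edges], list(graph.nodes), hops=2
        )
        assert ours == oracle

    def test_early_specific_hubs_set_difference(self):
        star = nx.relabel_nodes(nx.star_graph(10), {i: f"n{i}" for i in range(11)})
        ring = nx.relabel_nodes(nx.cycle_graph(11), {i: f"n{i}" for i in range(11)})
        early = self._net_from_graph(star)
        late = self._net_from_graph(ring)
        assert net.early_specific_hubs(early, late, hops=1) == ["n0"]
        identical = net.early_specific_hubs(
            self._net_from_graph(star), self._net_from_graph(star.copy()), hops=1
        )
        assert identical == []

    def test_planted_regulator_is_early_hub(self, small_config):
        ds_h, _, truth, _ = simulate.generate(small_config)
        z = core.log2_z_transform(ds_h)
        early, late = core.split_by_age(z, small_config.transition_age_human)
        name, (genes, _) = next(iter(truth.module_blocks.items()))
        regulator = truth.module_regulators[name]
        e_net = net.mi_network(early.subset_genes(genes).values, genes, seed=0)
        sizes = net.neighborhood_sizes(e_net, hops=2)
        top = sorted(sizes.values(), reverse=True)[max(1, len(genes) // 20) - 1]
        assert sizes[regulator] >= top


class TestCovariates:
    def test_residualization_removes_covariate_signal(self):
        rng = np.random.default_rng(10)
        cov = rng.normal(size=(30, 1))
        expr = 2.0 + 3.0 * cov[:, 0][None, :] + rng.normal(0, 0.1, size=(5, 30))
        samples = [
            core.SampleMeta(f"s{i}", "human", "V1C", 50.0 + i) for i in range(30)
        ]
        ds = core.ExpressionDataset(
            values=expr, gene_ids=[f"g{i}" for i in range(5)], samples=samples
        )
        out = net.regress_out_covariates(ds, cov)
        for row in out.values:
            assert abs(np.corrcoef(row, cov[:, 0])[0, 1]) < 0.05
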