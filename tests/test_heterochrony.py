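import numpy as np
import pytest

from devtraj import core, heterochrony as het, simulate


class TestLog2Age:
    def test_values(self):
        np.testing.assert_allclose(
            het.log2_age(np.array([56.0, 1.0, 128.0])),
            [np.log2(56.0), 0.0, 7.0],
        )
        assert het.log2_age(np.array([56.0]))[0] == pytest.approx(5.807, abs=1e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(core.DataError):
            het.log2_age(np.array([0.0]))


class TestAgeRelatedTest:
    def test_exact_quadratic(self):
        u = np.linspace(4, 8, 20)
        expr = 1.0 + 0.5 * u - 0.3 * u**2
        p, degree, adj = het.age_related_test(expr, u)
        assert degree == 2
        assert p < 1e-100
        assert adj > 0.999

    def test_linear_with_small_noise_prefers_degree_one(self):
        rng = np.random.default_rng(0)
        u = np.linspace(4, 8, 30)
        wins = 0
        for _ in range(20):
            expr = 2.0 + 0.8 * u + rng.normal(0, 0.2, u.size)
            _, degree, _ = het.age_related_test(expr, u)
            wins += degree == 1
        assert wins > 10  # the adjusted-r2 penalty picks the true degree in a majority

    def test_null_uniformity(self):
        rng = np.random.default_rng(1)
        u = np.linspace(4, 8, 25)
        pvals = [
            het.age_related_test(rng.normal(size=u.size), u)[0] for _ in range(400)
        ]
        frac = np.mean(np.array(pvals) < 0.05)
        assert frac < 0.12  # ~5% nominal, slack for degree selection

    def test_too_few_ages(self):
        with pytest.raises(core.DataError):
            het.age_related_test(np.array([1.0, 2.0]), np.array([4.0, 5.0]))


class TestSpeciesDivergence:
    def _ages(self, n):
        return np.linspace(4, 8, n)

    def test_identical_trajectories_not_significant(self):
        u = self._ages(20)
        rng = np.random.default_rng(2)
        f = 1 + 0.5 * u - 0.2 * u**2
        p = het.species_divergence_test(
            f + rng.normal(0, 0.3, 20), u, f + rng.normal(0, 0.3, 20), u, 2
        )
        assert p > 0.05

    def test_vertical_offset_detected(self):
        u = self._ages(20)
        rng = np.random.default_rng(3)
        f = 1 + 0.5 * u
        p = het.species_divergence_test(
            f + 1.0 + rng.normal(0, 0.2, 20), u, f + rng.normal(0, 0.2, 20), u, 1
        )
        assert p < 1e-4

    def test_time_shift_detected_via_interaction(self):
        u = self._ages(20)
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(10):
            f = lambda x: 0.8 * (x - 6.0) ** 2
            p = het.species_divergence_test(
                f(u - 1.0) + rng.normal(0, 0.3, 20), u, f(u) + rng.normal(0, 0.3, 20), u, 2
            )
            hits += p < 0.05
        assert hits >= 8


class TestDtwShift:
    def _dense(self, fn, lo=4.0, hi=9.0, n=60):
        u = np.linspace(lo, hi, n)
        return fn(u), 2.0**u

    def test_identical_curves_zero_shift(self):
        f = lambda u: 0.5 * (u - 6.5) ** 2
        eh, ah = self._dense(f)
        em, am = self._dense(f)
        shift = het.dtw_shift(eh, ah, em, am, degree=2)
        assert abs(shift) < 0.05

    def test_planted_displacement_recovered(self):
        f = lambda u: 0.5 * (u - 6.5) ** 2
        eh, ah = self._dense(lambda u: f(u - 0.8))
        em, am = self._dense(f)
        shift = het.dtw_shift(eh, ah, em, am, degree=2)
        assert shift == pytest.approx(0.8, abs=0.1)

    def test_antisymmetry(self):
        f = lambda u: 0.5 * (u - 6.5) ** 2
        eh, ah = self._dense(lambda u: f(u - 0.6))
        em, am = self._dense(f)
        fwd = het.dtw_shift(eh, ah, em, am, degree=2)
        rev = het.dtw_shift(em, am, eh, ah, degree=2)
        grid_tol = 2 * (np.log2(ah.max()) - np.log2(ah.min())) / 49
        assert abs(fwd + rev) <= grid_tol

    def test_flat_curve_undefined(self):
        eh, ah = self._dense(lambda u: np.full_like(u, 3.0))
        em, am = self._dense(lambda u: 0.1 * u)
        assert het.dtw_shift(eh, ah, em, am, degree=1) is None

    def test_non_overlapping_ranges_rejected(self):
        eh, ah = self._dense(lambda u: u, lo=2.0, hi=4.0)
        em, am = self._dense(lambda u: u, lo=5.0, hi=7.0)
        with pytest.raises(core.DataError, match="overlap"):
            het.dtw_shift(eh, ah, em, am, degree=1)


class TestShiftSignificance:
    def test_zero_shift_large_pvalue(self):
        rng = np.random.default_rng(5)
        u = np.linspace(4, 9, 25)
        f = 0.5 * (u - 6.5) ** 2
        eh = f + rng.normal(0, 0.3, 25)
        em = f + rng.normal(0, 0.3, 25)
        p = het.shift_significance(eh, 2.0**u, em, 2.0**u, 2, 0.0, n_sims=200, seed=0)
        assert p > 0.5

    def test_planted_shift_detected(self, small_config):
        ds_h, ds_m, truth, _ = simulate.generate(small_config)
        h, m = core.log2_transform(ds_h), core.log2_transform(ds_m)
        gene = next(iter(truth.shifts))
        eh = h.values[h.gene_ids.index(gene)]
        em = m.values[m.gene_ids.index(gene)]
        u = np.concatenate([het.log2_age(h.ages), het.log2_age(m.ages)])
        _, degree, _ = het.age_related_test(np.concatenate([eh, em]), u)
        shift = het.dtw_shift(eh, h.ages, em, m.ages, degree)
        p = het.shift_significance(
            eh, h.ages, em, m.ages, degree, shift, n_sims=500, seed=1
        )
        assert p < 0.05

    def test_too_few_sims_rejected(self):
        with pytest.raises(core.DataError, match="n_sims"):
            het.shift_significance(
                np.ones(5), np.arange(1, 6.0), np.ones(5), np.arange(1, 6.0), 1, 0.5,
                n_sims=10,
            )


class TestClassify:
    @pytest.mark.parametrize(
        "shift,p,expected",
        [
            (0.8, 0.01, "neoteny"),
            (-0.8, 0.01, "acceleration"),
            (0.8, 0.2, "none"),
            (-0.8, 0.05, "none"),  # boundary p not < alpha
            (0.0, 0.001, "none"),
            (None, 0.001, "none"),
        ],
    )
    def test_mapping(self, shift, p, expected):
        assert het.classify(shift, p) == expected


class TestScreenInvariant:
    def test_passes_is_pure_function_of_pvalues(self):
        r = het.GeneScreenResult("g", 0.01, 2, 0.5, 0.04)
        assert r.passes
        assert not het.GeneScreenResult("g", 0.06, 2, 0.5, 0.01).passes
        assert not het.GeneScreenResult("g", 0.01, 2, 0.5, 0.05).passes


def test_call_heterochrony_classes_match_planted_ratio(small_config):
    """Among significant calls on planted genes, the neoteny:acceleration
    split matches the planted ratio within a generous binomial band."""
    ds_h, ds_m, truth, _ = simulate.generate(small_config)
    h, m = core.log2_transform(ds_h), core.log2_transform(ds_m)
    genes = list(truth.shifts)
    _, calls = het.call_heterochrony(
        h, m, n_sims=200, seed=0, genes=genes, screen=False
    )
    neo = sum(c.klass == "neoteny" for c in calls)
    acc = sum(c.klass == "acceleration" for c in calls)
    assert neo + acc >= len(genes) * 0.6
    planted_neo = sum(s > 0 for s in truth.shifts.values())
    expected = planted_neo / len(genes)
    assert abs(neo / (neo + acc) - expected) < 0.25
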