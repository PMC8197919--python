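"""Burden / variance-component association machinery."""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from chordsift.burden import (
    BurdenInput,
    run_burden_suite,
    score_statistics,
    skato_test,
    variant_weights,
)
from chordsift.errors import InputError
from chordsift.simulate import SimulationConfig, simulate_cohort, synthetic_panel


def _input(G, y, n=None):
    G = np.asarray(G, dtype=float)
    n = n or G.shape[0]
    mafs = np.minimum(G.sum(axis=0) / (2 * n), 0.5)
    w = variant_weights(mafs, n_samples=n)
    return BurdenInput(G=G, y=np.asarray(y, dtype=float), weights=w)


class TestWeights:
    def test_flat_scheme(self):
        assert np.all(variant_weights(np.array([0.001, 0.01]), scheme="flat") == 1.0)

    def test_beta_weights_decrease_with_maf(self):
        mafs = np.linspace(0.0005, 0.5, 50)
        w = variant_weights(mafs)
        assert np.all(np.diff(w) < 0)

    def test_weight_ratio_matches_beta_density(self):
        """Closed-form oracle: Beta(1,25) density ratio (1-f)^24 terms."""
        w = variant_weights(np.array([0.001, 0.01]))
        expected = (25 * (1 - 0.001) ** 24) / (25 * (1 - 0.01) ** 24)
        assert w[0] / w[1] == pytest.approx(expected, rel=1e-12)
        assert w[0] == pytest.approx(beta_dist.pdf(0.001, 1, 25), rel=1e-12)

    def test_zero_maf_uses_pseudocount(self):
        w = variant_weights(np.array([0.0, 0.001]), n_samples=100)
        assert w[0] == pytest.approx(beta_dist.pdf(0.5 / 201, 1, 25), rel=1e-12)
        with pytest.raises(InputError):
            variant_weights(np.array([0.0]))

    def test_maf_above_half_rejected(self):
        with pytest.raises(InputError):
            variant_weights(np.array([0.6]))


class TestScoreStatistics:
    @pytest.fixture()
    def inp(self, small_assoc_instance):
        G, y = small_assoc_instance
        return _input(G, y)

    def test_rho_endpoints(self, inp):
        """rho=1 is the burden statistic, rho=0 the kernel statistic."""
        res = skato_test(inp)
        assert score_statistics(inp, 1.0) == pytest.approx(res.q_burden)
        assert score_statistics(inp, 0.0) == pytest.approx(res.q_skat)

    def test_single_variant_constant_in_rho(self, small_assoc_instance):
        G, y = small_assoc_instance
        single = _input(G[:, :1], y)
        qs = [score_statistics(single, rho) for rho in (0.0, 0.3, 0.7, 1.0)]
        assert all(q == pytest.approx(qs[0]) for q in qs)

    def test_rho_outside_unit_interval_rejected(self, inp):
        with pytest.raises(InputError):
            score_statistics(inp, 1.5)

    def test_constant_phenotype_rejected(self, small_assoc_instance):
        G, _ = small_assoc_instance
        with pytest.raises(InputError):
            _input(G, np.ones(G.shape[0]))


class TestSkato:
    def test_analytic_close_to_permutation(self, small_assoc_instance):
        G, y = small_assoc_instance
        res = skato_test(_input(G, y), n_permutations=10_000, seed=3)
        se = np.sqrt(res.p_permutation * (1 - res.p_permutation) / 10_000)
        assert abs(res.p_skato - res.p_permutation) < 3 * se

    def test_permutation_requires_seed(self, small_assoc_instance):
        G, y = small_assoc_instance
        with pytest.raises(InputError, match="seed"):
            skato_test(_input(G, y), n_permutations=100)

    def test_permutation_reproducible_and_reorder_invariant(self, small_assoc_instance):
        G, y = small_assoc_instance
        a = skato_test(_input(G, y), n_permutations=500, seed=11)
        b = skato_test(_input(G, y), n_permutations=500, seed=11)
        assert a.p_permutation == b.p_permutation
        order = np.random.default_rng(1).permutation(G.shape[0])
        c = skato_test(_input(G[order], y[order]), n_permutations=500, seed=11)
        assert c.p_permutation == pytest.approx(a.p_permutation, abs=0.02)

    def test_combination_bound(self, small_assoc_instance):
        """p_skato never beats the best grid point and never exceeds its
        Bonferroni bound over the grid."""
        G, y = small_assoc_instance
        res = skato_test(_input(G, y))
        t = min(res.p_per_rho)
        assert t <= res.p_skato <= min(1.0, len(res.rho_grid) * t) + 1e-12

    def test_degenerate_all_zero_genotypes(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        G = np.zeros((4, 3))
        inp = BurdenInput(G=G, y=y, weights=np.ones(3))
        with pytest.warns(UserWarning, match="no genotype variance"):
            res = skato_test(inp)
        assert res.p_skato == 1.0

    def test_enrichment_shifts_p_distribution(self):
        """Paired simulation: planted carrier enrichment (odds ratio 5) gives
        systematically smaller p than matched null replicates."""
        rng = np.random.default_rng(99)
        n, n_case, m = 400, 100, 5
        null_p, enr_p = [], []
        for _ in range(120):
            maf = rng.uniform(0.01, 0.03, m)
            y = np.zeros(n)
            y[:n_case] = 1.0
            G0 = rng.binomial(2, maf, size=(n, m)).astype(float)
            null_p.append(skato_test(_input(G0, y)).p_skato)
            q0 = 1 - (1 - maf) ** 2
            odds = 5 * q0 / (1 - q0)
            q1 = odds / (1 + odds)
            G1 = G0.copy()
            G1[:n_case] = (rng.random((n_case, m)) < q1).astype(float)
            enr_p.append(skato_test(_input(G1, y)).p_skato)
        assert np.median(enr_p) < np.median(null_p)


class TestSuite:
    @pytest.fixture(scope="class")
    def sim(self):
        cfg = SimulationConfig(panel=synthetic_panel(12), seed=21, maf_range=(1e-3, 1e-2))
        return simulate_cohort(cfg)

    def test_pathogenic_only_is_column_subset(self, sim):
        from chordsift.pathogenicity import classify

        classifications = [
            classify(r, a) for r, a in zip(sim.cohort.variant_index, sim.annotations)
        ]
        all_rare = run_burden_suite(sim.cohort, sim.config.panel, mode="all_rare")
        patho = run_burden_suite(
            sim.cohort, sim.config.panel, classifications, mode="pathogenic_only"
        )
        m_all = {r.unit_id: r.m_variants for r in all_rare}
        for r in patho:
            assert r.m_variants <= m_all[r.unit_id]

    def test_bonferroni_caps_at_one(self, sim):
        results = run_burden_suite(sim.cohort, sim.config.panel, mode="all_rare")
        k = len(results)
        for r in results:
            assert r.adj_p == pytest.approx(min(1.0, r.p_skato * k))

    def test_pathway_mode_yields_category_units(self, sim):
        results = run_burden_suite(sim.cohort, sim.config.panel, mode="pathway")
        labels = {r.unit_id for r in results}
        assert labels <= {
            "super_enhancer_essential", "notochord", "mesoderm_commitment",
            "swi_snf", "pi3k_akt_mtor", "sonic_hedgehog", "driver",
        }
        assert all(r.mode == "pathway" for r in results)

    def test_unknown_mode_rejected(self, sim):
        with pytest.raises(InputError):
            run_burden_suite(sim.cohort, sim.config.panel, mode="everything")
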