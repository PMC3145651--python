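"""Hub-dilution and hub-substitution experiments with paired Fisher comparison."""

import numpy as np
import pytest

import plsnet as P
from plsnet.datasets import GeneSet
from plsnet.perturbation import (
    addition_experiment,
    compare_performance,
    substitution_experiment,
)


def nonhub_pool(ds, truth):
    return GeneSet("pool", tuple(g for g in ds.gene_ids if g not in set(truth.hub_genes)))


class TestComparePerformance:
    def test_identical_outcomes_give_p_one(self):
        ok = np.array([True] * 40 + [False] * 10)
        assert compare_performance(ok, ok) == pytest.approx(1.0)

    def test_extreme_difference(self):
        a = np.ones(50, dtype=bool)
        b = np.zeros(50, dtype=bool)
        assert compare_performance(a, b) < 1e-20

    def test_matches_hypergeometric_enumeration(self):
        from scipy.stats import hypergeom

        a = np.array([True] * 40 + [False] * 10)
        b = np.array([True] * 30 + [False] * 20)
        # enumerate the margin-fixed support of the 2x2 table
        n_a, n_b, k = 50, 50, 70  # row sums and first-column (correct) sum
        rv = hypergeom(n_a + n_b, n_a, k)
        probs = {x: rv.pmf(x) for x in range(max(0, k - n_b), min(k, n_a) + 1)}
        p_obs = probs[40]
        expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))
        assert compare_performance(a, b) == pytest.approx(expected, rel=1e-7)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compare_performance([], [True])


class TestAddition:
    def test_zero_added_reproduces_baseline_protocol(self, paperlike):
        ds, _, truth = paperlike
        pool = nonhub_pool(ds, truth)
        res = addition_experiment(ds, truth.hub_genes, pool,
                                  added_counts=(0, 2), n_repeats=10, seed=3)
        base = res.baseline
        summary = P.repeated_split_eval(ds, truth.hub_genes, n_repeats=10, seed=3)
        np.testing.assert_allclose(base.aucs, summary.aucs)
        np.testing.assert_allclose(base.accuracies, summary.accuracies)

    def test_same_seed_identical_tables(self, paperlike):
        ds, _, truth = paperlike
        pool = nonhub_pool(ds, truth)
        a = addition_experiment(ds, truth.hub_genes, pool, added_counts=(1, 4),
                                n_repeats=10, seed=5).to_frame()
        b = addition_experiment(ds, truth.hub_genes, pool, added_counts=(1, 4),
                                n_repeats=10, seed=5).to_frame()
        assert a.equals(b)

    def test_noise_dilution_does_not_degrade_significantly(self, paperlike):
        ds, _, truth = paperlike
        pool = nonhub_pool(ds, truth)  # pure-noise non-hubs
        res = addition_experiment(ds, truth.hub_genes, pool, n_repeats=50, seed=1)
        base = res.baseline
        for c in res.configs:
            assert abs(c.auc_mean - base.auc_mean) <= max(2 * c.auc_sd, 0.02)

    def test_pool_too_small_errors(self, paperlike):
        ds, _, truth = paperlike
        with pytest.raises(ValueError, match="pool"):
            addition_experiment(ds, truth.hub_genes, GeneSet("p", ("G001",)),
                                added_counts=(4,), n_repeats=2, seed=0)

    def test_overlapping_pool_errors(self, paperlike):
        ds, _, truth = paperlike
        with pytest.raises(ValueError, match="overlaps"):
            addition_experiment(ds, truth.hub_genes, truth.hub_genes,
                                added_counts=(1,), n_repeats=2, seed=0)


class TestSubstitution:
    def test_full_hub_count_is_baseline_with_p_one(self, paperlike):
        ds, _, truth = paperlike
        pool = nonhub_pool(ds, truth)
        res = substitution_experiment(ds, truth.hub_genes, pool,
                                      hub_counts=(7, 3), n_repeats=10, seed=2)
        assert res.baseline.hub_count == 7
        assert res.baseline.p_vs_baseline == 1.0

    def test_performance_collapses_without_hubs(self, paperlike):
        ds, _, truth = paperlike
        pool = nonhub_pool(ds, truth)
        res = substitution_experiment(ds, truth.hub_genes, pool,
                                      hub_counts=(7, 3, 0), n_repeats=50, seed=4)
        by_count = {c.hub_count: c for c in res.configs}
        assert by_count[7].auc_mean > by_count[3].auc_mean > by_count[0].auc_mean
        assert by_count[3].p_vs_baseline < 0.05
        # all-noise signature behaves like a coin flip
        assert abs(by_count[0].auc_mean - 0.5) <= 0.1

    def test_flat_when_signal_not_hub_concentrated(self):
        # negative control: non-hubs carry the same effect as hubs, so
        # swapping them must not change performance beyond noise
        cfg = P.SimulationConfig(
            n_genes=150, n_case=29, n_control=17, n_hubs=7, hub_min_degree=31,
            hub_effect=1.5, nonhub_de_fraction=1.0, nonhub_effect=1.5,
            neighbor_correlation=0.0, seed=8,
        )
        ds, _, truth = P.simulate(cfg)
        pool = nonhub_pool(ds, truth)
        res = substitution_experiment(ds, truth.hub_genes, pool,
                                      hub_counts=(7, 5, 3, 1, 0),
                                      n_repeats=50, seed=8)
        aucs = [c.auc_mean for c in res.configs]
        assert max(aucs) - min(aucs) < 0.05
        assert all(c.p_vs_baseline > 0.01 for c in res.configs)

    def test_results_invariant_to_config_order(self, paperlike):
        ds, _, truth = paperlike
        pool = nonhub_pool(ds, truth)
        a = substitution_experiment(ds, truth.hub_genes, pool, hub_counts=(7, 4, 1),
                                    n_repeats=10, seed=6)
        b = substitution_experiment(ds, truth.hub_genes, pool, hub_counts=(1, 7, 4),
                                    n_repeats=10, seed=6)
        fa = a.to_frame().sort_values("hub_count").reset_index(drop=True)
        fb = b.to_frame().sort_values("hub_count").reset_index(drop=True)
        assert fa.equals(fb)

    def test_per_repeat_values_in_range(self, paperlike):
        ds, _, truth = paperlike
        pool = nonhub_pool(ds, truth)
        res = substitution_experiment(ds, truth.hub_genes, pool,
                                      hub_counts=(7, 2), n_repeats=10, seed=9)
        for c in res.configs:
            assert np.all((0 <= c.aucs) & (c.aucs <= 1))
            assert np.all((0 <= c.accuracies) & (c.accuracies <= 1))

    def test_signature_size_exceeding_hubs_errors(self, paperlike):
        ds, _, truth = paperlike
        pool = nonhub_pool(ds, truth)
        with pytest.raises(ValueError):
            substitution_experiment(ds, truth.hub_genes, pool, signature_size=10,
                                    n_repeats=2, seed=0)
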