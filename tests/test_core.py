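"""Averaging, the test statistics, p-value helpers and the bootstrap test."""

import numpy as np
import pytest

from anocva import (
    PopulationSet,
    anocva_statistics,
    anocva_test,
    average_dissimilarity,
    bonferroni_adjust,
    generate_population_set,
    pvalue_from_replicates,
    robustness_filter,
    silhouette_per_item,
    SyntheticSpec,
)

from conftest import oracle_silhouette, random_dissimilarity


def two_group_pop(mats_g1, mats_g2):
    mats = list(mats_g1) + list(mats_g2)
    groups = ["a"] * len(mats_g1) + ["b"] * len(mats_g2)
    return PopulationSet.from_matrices(mats, groups)


class TestAveraging:
    def test_identical_subjects_average_to_themselves(self, rng):
        D = random_dissimilarity(rng, 5)
        avg = average_dissimilarity(two_group_pop([D, D], [D, D, D]))
        np.testing.assert_allclose(avg.A_bar_j[0], D)
        np.testing.assert_allclose(avg.A_bar_j[1], D)
        np.testing.assert_allclose(avg.A_doublebar, D)

    def test_equal_sizes_give_plain_mean(self, rng):
        D1, D2 = random_dissimilarity(rng, 4), random_dissimilarity(rng, 4)
        avg = average_dissimilarity(two_group_pop([D1, D1], [D2, D2]))
        np.testing.assert_allclose(avg.A_doublebar, (D1 + D2) / 2)

    def test_weighted_mean_equals_mean_over_all_subjects(self, rng):
        D1, D2 = random_dissimilarity(rng, 4), random_dissimilarity(rng, 4)
        avg = average_dissimilarity(two_group_pop([D1, D1, D1], [D2]))
        np.testing.assert_allclose(avg.A_doublebar, (3 * D1 + D2) / 4, atol=1e-12)

    def test_pooling_commutes_with_weighted_averaging(self, rng):
        mats = [random_dissimilarity(rng, 6) for _ in range(7)]
        pop = two_group_pop(mats[:5], mats[5:])
        avg = average_dissimilarity(pop)
        np.testing.assert_allclose(avg.A_doublebar, np.mean(mats, axis=0), atol=1e-12)

    def test_mismatched_dimensions_rejected(self, rng):
        with pytest.raises(ValueError, match="same number of items"):
            two_group_pop([random_dissimilarity(rng, 4)], [random_dissimilarity(rng, 5)])


class TestStatistics:
    def test_identical_groups_give_zero_statistics(self, rng):
        D = random_dissimilarity(rng, 6)
        avg = average_dissimilarity(two_group_pop([D], [D]))
        dS, ds, S, S_j = anocva_statistics(avg, np.array([1, 1, 2, 2, 3, 3]))
        assert dS == 0.0
        np.testing.assert_array_equal(ds, np.zeros(6))

    def test_toy_instance_composes_silhouette_oracle(self):
        D1 = np.array(
            [[0, 0.2, 0.9, 0.8], [0.2, 0, 0.7, 0.9], [0.9, 0.7, 0, 0.3], [0.8, 0.9, 0.3, 0]]
        )
        D2 = np.array(
            [[0, 0.6, 0.5, 0.4], [0.6, 0, 0.8, 0.3], [0.5, 0.8, 0, 0.6], [0.4, 0.3, 0.6, 0]]
        )
        labels = np.array([1, 1, 2, 2])
        avg = average_dissimilarity(two_group_pop([D1], [D2]))
        dS, ds, S, S_j = anocva_statistics(avg, labels)
        S_o = oracle_silhouette((D1 + D2) / 2, labels)
        S1_o, S2_o = oracle_silhouette(D1, labels), oracle_silhouette(D2, labels)
        want_dS = np.sum((S_o - S1_o) ** 2) + np.sum((S_o - S2_o) ** 2)
        want_ds = (S_o - (S1_o + S2_o) / 2) ** 2
        assert dS == pytest.approx(want_dS, abs=1e-12)
        np.testing.assert_allclose(ds, want_ds, atol=1e-12)

    def test_global_statistic_is_sum_of_squared_deviations(self, rng):
        mats = [random_dissimilarity(rng, 8) for _ in range(6)]
        avg = average_dissimilarity(two_group_pop(mats[:3], mats[3:]))
        labels = np.array([1, 1, 2, 2, 3, 3, 3, 1])
        dS, ds, S, S_j = anocva_statistics(avg, labels)
        assert dS == pytest.approx(((S[None, :] - S_j) ** 2).sum(), abs=1e-12)
        assert dS >= 0 and np.all(ds >= 0)

    def test_invariant_to_cluster_relabeling(self, rng):
        mats = [random_dissimilarity(rng, 6) for _ in range(4)]
        avg = average_dissimilarity(two_group_pop(mats[:2], mats[2:]))
        labels = np.array([1, 1, 2, 2, 3, 3])
        relabeled = np.array([3, 3, 1, 1, 2, 2])  # same partition, new ids
        dS_a, ds_a, _, _ = anocva_statistics(avg, labels)
        dS_b, ds_b, _, _ = anocva_statistics(avg, relabeled)
        assert dS_a == pytest.approx(dS_b, abs=1e-12)
        np.testing.assert_allclose(ds_a, ds_b, atol=1e-12)


class TestPvalueHelpers:
    def test_observed_zero_gives_p_one(self):
        assert pvalue_from_replicates(0.0, [0.1, 0.0, 2.0]) == 1.0

    def test_observed_above_all_replicates(self):
        assert pvalue_from_replicates(5.0, [1.0, 2.0, 3.0, 4.0]) == 0.0
        assert pvalue_from_replicates(5.0, [1.0, 2.0, 3.0, 4.0], add_one=True) == 1 / 5

    def test_ties_count_toward_numerator(self):
        assert pvalue_from_replicates(2.0, [1.0, 2.0, 3.0, 0.5]) == 0.5

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            pvalue_from_replicates(1.0, [])

    def test_bonferroni(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01, 0.5]), [0.02, 1.0])
        np.testing.assert_allclose(bonferroni_adjust([0.0, 0.0]), [0.0, 0.0])
        np.testing.assert_allclose(bonferroni_adjust([0.3]), [0.3])
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5, 1.2])

    def test_robustness_filter(self):
        np.testing.assert_array_equal(robustness_filter([0.01], [0.10]), [False])
        np.testing.assert_array_equal(robustness_filter([0.2, 0.8], [0.2, 0.8]), [True, True])
        np.testing.assert_array_equal(
            robustness_filter([0.02, 0.5], [0.06, 0.58]), [True, False]
        )
        with pytest.raises(ValueError):
            robustness_filter([0.1], [0.1, 0.2])


class TestBootstrapTest:
    def test_degenerate_null_gives_p_one(self, rng):
        D = random_dissimilarity(rng, 6)
        pop = two_group_pop([D] * 3, [D] * 2)
        res = anocva_test(pop, k_clusters=2, n_bootstrap=50, seed=1)
        assert res.delta_S == pytest.approx(0.0, abs=1e-24)
        np.testing.assert_allclose(res.delta_s, np.zeros(6), atol=1e-24)
        assert res.p_global == 1.0

    def test_fixed_seed_is_bit_identical(self):
        pop = generate_population_set(SyntheticSpec(seed=5))
        r1 = anocva_test(pop, k_clusters=3, n_bootstrap=60, seed=17)
        r2 = anocva_test(pop, k_clusters=3, n_bootstrap=60, seed=17)
        assert r1.p_global == r2.p_global
        np.testing.assert_array_equal(r1.p_items, r2.p_items)
        np.testing.assert_array_equal(r1.delta_s, r2.delta_s)

    def test_subject_order_does_not_change_observed_statistics(self, rng):
        mats = [random_dissimilarity(rng, 8) for _ in range(6)]
        pop_a = two_group_pop(mats[:3], mats[3:])
        pop_b = two_group_pop(mats[:3][::-1], mats[3:][::-1])
        labels = np.array([1, 1, 2, 2, 3, 3, 1, 2])
        dS_a, ds_a, _, _ = anocva_statistics(average_dissimilarity(pop_a), labels)
        dS_b, ds_b, _, _ = anocva_statistics(average_dissimilarity(pop_b), labels)
        assert dS_a == pytest.approx(dS_b, abs=1e-12)
        np.testing.assert_allclose(ds_a, ds_b, atol=1e-12)

    def test_auto_k_matches_planted_structure(self):
        pop = generate_population_set(SyntheticSpec(noise_sd=0.02, seed=3))
        res = anocva_test(pop, k_clusters="auto", n_bootstrap=20, seed=4, k_max=6)
        assert res.k_clusters == 3
        assert res.options["k_fixed_during_bootstrap"]

    def test_no_reclustering_variant_runs(self):
        pop = generate_population_set(SyntheticSpec(seed=6))
        res = anocva_test(pop, k_clusters=3, n_bootstrap=40, seed=7, recluster_bootstrap=False)
        assert 0.0 <= res.p_global <= 1.0

    def test_power_monotone_in_number_of_perturbed_items(self):
        # expected observed DeltaS grows with the size of the perturbed set
        mean_dS = []
        for n_eff in (0, 2, 5):
            effect = tuple(range(1, n_eff + 1))
            vals = []
            for rep in range(12):
                spec = SyntheticSpec(planted_k=5, effect_items=effect, seed=500 + rep)
                pop = generate_population_set(spec)
                avg = average_dissimilarity(pop)
                from anocva import spectral_clustering

                labels = spectral_clustering(avg.A_doublebar, 5, validate=False)
                dS, *_ = anocva_statistics(avg, labels, validate=False)
                vals.append(dS)
            mean_dS.append(np.mean(vals))
        assert mean_dS[0] < mean_dS[1] < mean_dS[2]

    def test_invalid_inputs_rejected(self, rng):
        D = random_dissimilarity(rng, 6)
        pop = two_group_pop([D], [D])
        with pytest.raises(ValueError):
            anocva_test(pop, k_clusters=2, n_bootstrap=0)
        small = two_group_pop([random_dissimilarity(rng, 2)], [random_dissimilarity(rng, 2)])
        with pytest.raises(ValueError):
            anocva_test(small, k_clusters=2, n_bootstrap=10)
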