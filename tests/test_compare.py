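import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from shotmapbench import (
    SampleMatrix,
    family_association_tests,
    pathway_enrichment,
    pca_profiles,
    permanova,
    prevalence_filter,
    storey_qvalues,
)
from shotmapbench.compare import attach_qvalues, estimate_pi0
from shotmapbench.synthetic import make_sample_matrix


def _matrix(values, groups=None, depth=None):
    values = pd.DataFrame(values)
    meta = pd.DataFrame(index=values.columns)
    if groups is not None:
        meta["group"] = groups
    if depth is not None:
        meta["depth"] = depth
    return SampleMatrix(values, meta)


class TestPrevalenceFilter:
    def test_fully_observed_drops_partially_observed_family(self):
        values = {f"s{i}": [1.0, 1.0 if i < 9 else 0.0] for i in range(10)}
        matrix = SampleMatrix(
            pd.DataFrame(values, index=["keep", "drop"]),
            pd.DataFrame(index=list(values)),
        )
        filtered = prevalence_filter(matrix)
        assert list(filtered.values.index) == ["keep"]

    def test_zero_fraction_is_identity(self):
        matrix = make_sample_matrix(n_families=6, n_samples=4, seed=1)
        filtered = prevalence_filter(matrix, mode="min_fraction", min_fraction=0.0)
        assert filtered.values.equals(matrix.values)

    def test_fully_observed_equals_min_fraction_one(self):
        matrix = make_sample_matrix(n_families=6, n_samples=4, seed=2)
        matrix.values.iloc[0, 0] = 0.0
        a = prevalence_filter(matrix, mode="fully_observed")
        b = prevalence_filter(matrix, mode="min_fraction", min_fraction=1.0)
        assert list(a.values.index) == list(b.values.index)

    def test_empty_result_warns_not_errors(self):
        matrix = _matrix({"s1": [0.0], "s2": [0.0]})
        with pytest.warns(UserWarning):
            filtered = prevalence_filter(matrix)
        assert len(filtered.values) == 0


class TestAssociationTests:
    def test_separated_groups_exact_p(self):
        # {1,2,3} vs {10,11,12}: 2 of C(6,3)=20 assignments are as extreme
        matrix = _matrix(
            {f"s{i}": [v] for i, v in enumerate([1, 2, 3, 10, 11, 12])},
            groups=["a", "a", "a", "b", "b", "b"],
        )
        [result] = family_association_tests(matrix, "group")
        assert result.p == pytest.approx(0.1)

    def test_constant_family_p_one(self):
        matrix = _matrix(
            {f"s{i}": [5.0, float(i)] for i in range(6)},
            groups=["a", "a", "a", "b", "b", "b"],
        )
        results = family_association_tests(matrix, "group")
        assert results[0].p == 1.0 and results[0].statistic == 0.0

    def test_monotone_continuous_association_tau_one(self):
        matrix = _matrix(
            {f"s{i}": [float(i + 1)] for i in range(5)},
            depth=[1.0, 2.0, 3.0, 4.0, 5.0],
        )
        [result] = family_association_tests(matrix, "depth")
        assert result.statistic == pytest.approx(1.0)
        assert result.p < 0.05

    def test_exact_kruskal_matches_exhaustive_enumeration(self):
        # independent oracle: scipy's H over all distinct label orderings
        rng = np.random.default_rng(3)
        values = rng.normal(size=8)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        matrix = _matrix(
            {f"s{i}": [values[i]] for i in range(8)},
            groups=[f"g{l}" for l in labels],
        )
        [result] = family_association_tests(matrix, "group")

        h_obs = stats.kruskal(values[labels == 0], values[labels == 1]).statistic
        perms = set(itertools.permutations(labels))
        extreme = sum(
            stats.kruskal(
                values[np.array(p) == 0], values[np.array(p) == 1]
            ).statistic >= h_obs - 1e-12
            for p in perms
        )
        assert result.p == pytest.approx(extreme / len(perms))

    def test_asymptotic_mode_used_for_larger_cohorts(self):
        matrix = make_sample_matrix(n_families=5, n_samples=24, seed=4)
        results = family_association_tests(matrix, "group")
        assert len(results) == 5
        assert all(0 <= r.p <= 1 for r in results)

    def test_type_one_error_calibrated_on_null(self):
        # null matrices: rejection rate at alpha=0.05 within binomial error
        n_tests, alpha = 600, 0.05
        matrix = make_sample_matrix(n_families=n_tests, n_samples=30, seed=5)
        results = family_association_tests(matrix, "group")
        rate = np.mean([r.p <= alpha for r in results])
        se = math.sqrt(alpha * (1 - alpha) / n_tests)
        assert abs(rate - alpha) < 4 * se

    def test_missing_covariate_rejected(self):
        matrix = make_sample_matrix(n_families=3, n_samples=6, seed=6)
        with pytest.raises(KeyError):
            family_association_tests(matrix, "nope")


class TestStoreyQvalues:
    def test_bh_hand_example(self):
        q = storey_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_identical_pvalues(self):
        q = storey_qvalues([0.5, 0.5, 0.5], pi0=1.0)
        assert q == pytest.approx([0.5, 0.5, 0.5])

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        q = storey_qvalues(p, pi0=1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_pi0_one_equals_benjamini_hochberg(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(5, 60))
            ours = storey_qvalues(p, pi0=1.0)
            _, bh, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(ours, bh, atol=1e-12)

    def test_estimated_pi0_shrinks_q_under_signal(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(0, 0.001, 50), rng.uniform(size=50)])
        pi0 = estimate_pi0(p)
        assert 0 < pi0 < 1.0
        q_storey = storey_qvalues(p)
        q_bh = storey_qvalues(p, pi0=1.0)
        assert np.all(q_storey <= q_bh + 1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.1, 1.5])

    def test_attach_qvalues_round_trip(self):
        from shotmapbench.compare import TestResult as TR

        results = [TR("F1", 1.0, 0.01), TR("F2", 0.5, 0.8)]
        with_q = attach_qvalues(results, pi0=1.0)
        assert with_q[0].q <= with_q[1].q


class TestPathwayEnrichment:
    def test_perfect_overlap_hypergeometric_tail(self):
        universe = {f"F{i}" for i in range(100)}
        sig = {f"F{i}" for i in range(10)}
        table = pathway_enrichment(sig, universe, {"p1": set(sig)})
        assert table.loc["p1", "p"] == pytest.approx(1.0 / math.comb(100, 10))

    def test_empty_significant_set_gives_p_one(self):
        universe = {f"F{i}" for i in range(20)}
        table = pathway_enrichment(set(), universe, {"p1": {"F0", "F1"}})
        assert table.loc["p1", "p"] == pytest.approx(1.0)

    def test_matches_brute_force_hypergeometric_sum(self):
        # table (a=5, b=5, c=0, d=90): P(X >= 5) with X ~ Hypergeom
        universe = {f"F{i}" for i in range(100)}
        sig = {f"F{i}" for i in range(10)}
        path = {f"F{i}" for i in range(5)}  # all 5 members significant
        table = pathway_enrichment(sig, universe, {"p1": path})
        n_sig, n_path = len(sig), len(path)
        brute = sum(
            math.comb(n_path, k) * math.comb(100 - n_path, n_sig - k)
            for k in range(5, n_path + 1)
        ) / math.comb(100, n_sig)
        assert table.loc["p1", "p"] == pytest.approx(brute)

    def test_pathway_outside_universe_skipped(self):
        universe = {"F1", "F2"}
        table = pathway_enrichment({"F1"}, universe, {"ghost": {"X1", "X2"}})
        assert len(table) == 0

    def test_significant_must_be_subset(self):
        with pytest.raises(ValueError):
            pathway_enrichment({"F99"}, {"F1"}, {"p": {"F1"}})


class TestPermanova:
    @staticmethod
    def _clustered_dm(n_per=4, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        points = np.vstack([
            rng.normal(0, 1, size=(n_per, 2)),
            rng.normal(sep, 1, size=(n_per, 2)),
        ])
        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        groups = ["a"] * n_per + ["b"] * n_per
        return d, groups

    def test_separated_clusters_minimum_p(self):
        # groups big enough that a permutation recreating the exact
        # partition (the only way to tie the observed F) is unlikely
        d, groups = self._clustered_dm(n_per=10)
        f, p = permanova(d, groups, n_perm=200, seed=1)
        assert p == pytest.approx(1 / 201)
        assert f > 1

    def test_deterministic_given_seed(self):
        d, groups = self._clustered_dm(sep=1.0)
        assert permanova(d, groups, n_perm=99, seed=3) == permanova(
            d, groups, n_perm=99, seed=3
        )

    def test_matches_skbio_pseudo_f(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        d, groups = self._clustered_dm(sep=2.0, seed=5)
        f, _ = permanova(d, groups, n_perm=10, seed=0)
        result = skbio_permanova(DistanceMatrix(d), groups, permutations=10)
        assert f == pytest.approx(result["test statistic"])

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        for i in range(120):
            points = rng.normal(size=(12, 3))
            d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
            groups = ["a"] * 6 + ["b"] * 6
            _, p = permanova(d, groups, n_perm=60, seed=i)
            pvals.append(p)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_group_of_one_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            permanova(d, ["a", "b", "b"], n_perm=10, seed=0)


class TestPCA:
    def test_duplicated_sample_identical_scores(self):
        matrix = make_sample_matrix(n_families=8, n_samples=5, seed=12)
        matrix.values["s_dup"] = matrix.values["s0"]
        matrix.sample_meta.loc["s_dup"] = matrix.sample_meta.loc["s0"]
        scores, _ = pca_profiles(matrix)
        np.testing.assert_allclose(
            scores.loc["s0"].to_numpy(), scores.loc["s_dup"].to_numpy(), atol=1e-9
        )

    def test_explained_variance_non_increasing_and_bounded(self):
        matrix = make_sample_matrix(n_families=10, n_samples=8, seed=13)
        _, ratios = pca_profiles(matrix)
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1 + 1e-9

    def test_two_cluster_structure_separated_on_pc1(self):
        from sklearn.metrics import silhouette_score

        matrix = make_sample_matrix(
            n_families=30, n_samples=16, n_affected=15, effect_size=6.0, seed=14
        )
        scores, _ = pca_profiles(matrix)
        labels = matrix.sample_meta.loc[scores.index, "group"]
        sil = silhouette_score(scores[["PC1"]].to_numpy(), labels)
        assert sil > 0

    def test_constant_families_dropped(self):
        matrix = make_sample_matrix(n_families=5, n_samples=6, seed=15)
        matrix.values.iloc[0] = 3.14
        scores, _ = pca_profiles(matrix)
        assert scores.shape[0] == 6
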