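"""Imputation algorithms: classification rule, the five methods, tuning and
masking-based evaluation."""

import numpy as np
import pandas as pd
import pytest

import halfsibgs as h
from halfsibgs.genotypes import GenotypeError
from halfsibgs.imputation import KnnFamImputer


def _gm(values, families=None):
    values = np.asarray(values, dtype=float)
    return h.GenotypeMatrix(
        values,
        [f"i{k}" for k in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        families,
    )


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.4, 0.0), (0.51, 1.0), (-0.5, 0.0), (0.5, 0.0), (-0.51, -1.0),
         (1.7, 1.0), (0.0, 0.0)],
    )
    def test_nearest_centroid_with_tie_toward_het(self, value, expected):
        assert h.classify_genotypes(np.array([value]))[0] == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            h.classify_genotypes(np.array([np.nan]))


class TestMeanImputation:
    def test_locus_mean_fill(self):
        gm = _gm([[-1, 1], [1, 1], [np.nan, np.nan]])
        res = h.impute_mean(gm)
        assert res.completed_values[2, 0] == pytest.approx(0.0)
        assert res.completed_values[2, 1] == pytest.approx(1.0)
        assert res.completed.values[2, 0] == 0.0
        assert res.completed.values[2, 1] == 1.0

    def test_identity_when_complete(self):
        gm = _gm([[-1, 0], [1, 0]])
        res = h.impute_mean(gm)
        np.testing.assert_array_equal(res.completed.values, gm.values)

    def test_fully_missing_locus_errors(self):
        gm = _gm([[np.nan], [np.nan]])
        with pytest.raises(GenotypeError, match="no observed calls"):
            h.impute_mean(gm)


class TestSVD:
    def test_rank_one_masked_entry_recovered(self):
        rng = np.random.default_rng(0)
        u = rng.integers(0, 2, 12) * 2.0 - 1.0  # +-1 column
        v = np.ones(8)
        x = np.outer(u, v)  # rank-1 matrix of +-1
        masked = x.copy()
        masked[3, 4] = np.nan
        gm = _gm(masked)
        res = h.impute_svd(gm, n_eigenvectors=1, n_iterations=60)
        assert abs(res.completed_values[3, 4] - x[3, 4]) < 1e-6

    def test_zero_iterations_equals_classified_mean_imputation(self, small_trial):
        gm = small_trial["masked"]
        svd0 = h.impute_svd(gm, n_eigenvectors=3, n_iterations=0)
        mi = h.impute_mean(gm)
        np.testing.assert_array_equal(svd0.completed.values, mi.completed.values)

    def test_rank_too_large_rejected(self):
        gm = _gm(np.zeros((3, 4)))
        gm.values[0, 0] = np.nan
        gm.values[1, :] = 1.0
        with pytest.raises(ValueError, match="rank"):
            h.impute_svd(gm, n_eigenvectors=3, n_iterations=1)


class TestKNN:
    def test_duplicate_column_wins(self):
        # s0 and s2 identical where both observed; distance 0 dominates
        gm = _gm([[1, -1, 1], [0, 1, 0], [-1, 0, -1], [np.nan, 1, 1]])
        res = h.impute_knn(gm, k=2)
        assert res.completed.values[3, 0] == 1.0

    def test_weighted_average_matches_hand_computation(self):
        # columns: target s0 with one hole; neighbours s1, s2 complete
        values = np.array(
            [
                [1.0, 1.0, -1.0],
                [0.0, 1.0, 0.0],
                [-1.0, -1.0, 0.0],
                [np.nan, 1.0, 0.0],
            ]
        )
        gm = _gm(values)
        n = 4
        # pairwise-complete distances to s0 over rows 0..2, scaled by n/3
        d1 = np.sqrt((0 + 1 + 0) * n / 3)
        d2 = np.sqrt((4 + 0 + 1) * n / 3)
        expect = (1.0 / d1 * 1.0 + 1.0 / d2 * 0.0) / (1.0 / d1 + 1.0 / d2)
        res = h.impute_knn(gm, k=2)
        assert res.completed_values[3, 0] == pytest.approx(expect)

    def test_k_larger_than_neighbours_warns_and_uses_all(self, caplog):
        gm = _gm([[1.0, 1.0], [0.0, 1.0], [np.nan, -1.0]])
        with caplog.at_level("WARNING", logger="halfsibgs"):
            res = h.impute_knn(gm, k=10)
        assert "using all available" in caplog.text
        assert res.completed.missing_fraction == 0.0


class TestEM:
    def test_no_missing_returns_input(self):
        gm = _gm([[1, 0], [-1, 1], [0, 0]])
        res = h.impute_em(gm)
        assert res.iterations_run == 0
        np.testing.assert_array_equal(res.completed.values, gm.values)

    def test_perfectly_correlated_partner_locus(self):
        rng = np.random.default_rng(1)
        col = rng.integers(-1, 2, 40).astype(float)
        x = np.column_stack([col, col])
        x[5, 0] = np.nan
        res = h.impute_em(_gm(x), tol=0.001, n_factors=1, max_iter=200)
        assert abs(res.completed_values[5, 0] - col[5]) < 0.05
        assert res.completed.values[5, 0] == col[5]

    def test_observed_entries_untouched(self, small_trial):
        gm = small_trial["masked"]
        res = h.impute_em(gm, max_iter=3)
        obs = ~gm.missing_mask
        np.testing.assert_array_equal(res.completed.values[obs], gm.values[obs])


class TestKnnFam:
    def test_mode_of_neighbour_codes(self):
        # 6 individuals, fam A has an obvious modal genotype at s1
        values = np.array(
            [
                [1.0, np.nan],
                [1.0, 1.0],
                [1.0, 1.0],
                [0.0, 0.0],
                [-1.0, 1.0],
                [0.0, 0.0],
            ]
        )
        fams = ["A", "A", "A", "B", "B", "B"]
        res = h.impute_knn_fam(_gm(values, fams), K1=2, K2=3)
        assert res.completed.values[0, 1] == 1.0

    def test_k1_zero_is_panelwide_rule(self, small_trial):
        gm = small_trial["masked"]
        res = h.impute_knn_fam(gm, K1=0, K2=10)
        assert res.completed.missing_fraction == 0.0

    def test_singleton_family_falls_back_with_warning(self, caplog):
        values = np.array([[1.0, np.nan], [1.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        fams = ["lonely", "B", "B", "B"]
        with caplog.at_level("WARNING", logger="halfsibgs"):
            res = h.impute_knn_fam(_gm(values, fams), K1=2, K2=2)
        assert "no within-family neighbors" in caplog.text
        assert res.completed.values[0, 1] == 1.0

    def test_invalid_neighbourhood(self, toy_genotypes):
        with pytest.raises(ValueError):
            h.impute_knn_fam(toy_genotypes, K1=0, K2=0)

    def test_observed_entries_untouched_and_classified(self, small_trial):
        gm = small_trial["masked"]
        res = h.impute_knn_fam(gm)
        obs = ~gm.missing_mask
        np.testing.assert_array_equal(res.completed.values[obs], gm.values[obs])
        assert set(np.unique(res.completed.values)) <= {-1.0, 0.0, 1.0}


class TestTuning:
    def test_duplicate_panel_perfect_at_single_neighbour(self):
        rng = np.random.default_rng(3)
        base = rng.integers(-1, 2, (10, 60)).astype(float)
        values = np.vstack([base, base])  # every individual duplicated
        fams = [f"f{k % 5}" for k in range(10)] * 2
        gm = _gm(values, fams)
        # mask cells only in the first copy; the duplicate row stays observed
        mask = np.zeros_like(values, dtype=bool)
        mask[:10][rng.random((10, 60)) < 0.2] = True
        masked = gm.copy()
        masked.values[mask] = np.nan
        res = h.impute_knn_fam(masked, K1=1, K2=0)
        ev = h.evaluate_imputation(gm, mask, res.completed)
        assert ev.accuracy == 1.0

    def test_grid_reproducible_under_seed(self, small_trial):
        gm = small_trial["masked"]
        r1 = h.tune_knn_fam(gm, n_mask=300, seed=9, K1_grid=(1, 5), K2_grid=(5, 10))
        r2 = h.tune_knn_fam(gm, n_mask=300, seed=9, K1_grid=(1, 5), K2_grid=(5, 10))
        assert r1[0] == r2[0] and r1[1] == r2[1]
        pd.testing.assert_frame_equal(r1[2], r2[2])

    def test_mask_budget_checked(self, toy_genotypes):
        with pytest.raises(ValueError, match="n_mask"):
            h.tune_knn_fam(toy_genotypes, n_mask=10_000)


class TestEvaluation:
    def test_perfect_completion(self, small_trial):
        ev = h.evaluate_imputation(
            small_trial["genotypes"], small_trial["mask"], small_trial["genotypes"]
        )
        assert ev.accuracy == 1.0
        assert ev.n_correct == ev.n_masked == int(small_trial["mask"].sum())

    def test_constant_zero_matrix_scores_fraction_of_hets(self):
        rng = np.random.default_rng(4)
        truth = rng.integers(-1, 2, (20, 30)).astype(float)
        gm = _gm(truth)
        mask = rng.random((20, 30)) < 0.3
        zeros = _gm(np.zeros_like(truth))
        ev = h.evaluate_imputation(gm, mask, zeros)
        assert ev.accuracy == pytest.approx((truth[mask] == 0).mean())

    def test_unmaskable_position_rejected(self, toy_genotypes):
        mask = np.zeros(toy_genotypes.values.shape, dtype=bool)
        mask[0, 3] = True  # originally missing -> no truth there
        with pytest.raises(ValueError, match="no known original"):
            h.evaluate_imputation(toy_genotypes, mask, toy_genotypes)

    def test_family_aware_beats_mean_on_structured_panel(self):
        wins = 0
        for seed in range(3):
            cfg = h.SimConfig(n_families=10, n_sites=1, n_offspring_per_family_site=20,
                              n_snps=800, n_qtl=80, seed=40 + seed, missing_rate=0.3)
            ped, geno, masked, mask, pheno, truth = h.simulate_trial(cfg)
            mi = h.evaluate_imputation(geno, mask, h.impute_mean(masked).completed)
            kf = h.evaluate_imputation(
                geno, mask, h.impute_knn_fam(masked, K1=10, K2=10).completed
            )
            wins += kf.accuracy >= mi.accuracy
        assert wins >= 2

    def test_per_family_table(self, small_trial):
        res = h.impute_mean(small_trial["masked"])
        ev = h.evaluate_imputation(
            small_trial["genotypes"], small_trial["mask"], res.completed
        )
        assert ev.per_family_accuracy is not None
        assert ev.per_family_accuracy["n"].sum() == ev.n_masked
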