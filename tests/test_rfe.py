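"""Linear SVM fits and the recursive elimination schedule."""

import math
import warnings

import numpy as np
import pytest

from vbmlearn import (
    RFEConfig,
    ScreeningConfig,
    fit_linear_svm,
    generate_cohort,
    rfe_rank,
    screen,
    select_features,
    to_matrix,
)
from vbmlearn.rfe import elimination_schedule
from conftest import brute_force_rfe_order, matrix_cohort


class TestLinearSVM:
    def test_symmetric_separable_boundary_at_zero(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        fit = fit_linear_svm(X, y, C=1e6)
        assert abs(fit.bias) < 1e-6
        assert np.array_equal(fit.predict(X), y)

    def test_dual_to_primal_reconstruction(self, rng):
        # w == sum_i alpha_i y_i x_i over the support vectors, every fit
        for _ in range(5):
            X = rng.normal(size=(20, 6))
            y = np.where(rng.random(20) > 0.5, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            fit = fit_linear_svm(X, y, C=1.0)
            recon = fit.dual_coef @ fit.support_vectors
            np.testing.assert_allclose(fit.weights, recon, atol=1e-6)

    def test_dual_coefficients_sum_to_zero(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.where(rng.random(30) > 0.5, 1, -1)
        fit = fit_linear_svm(X, y, C=1.0)
        assert abs(fit.dual_coef.sum()) < 1e-8  # sum alpha_i y_i = 0

    def test_informative_feature_outweighs_noise(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.repeat([1, -1], 20)
            X = np.column_stack([y + 0.1 * rng.normal(size=40), rng.normal(size=40)])
            fit = fit_linear_svm(X, y, C=1.0)
            wins += abs(fit.weights[0]) > abs(fit.weights[1])
        assert wins >= 99

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_linear_svm(np.ones((4, 2)), [1, 1, 1, 1])

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ValueError, match="C"):
            fit_linear_svm(np.eye(4), [1, 1, -1, -1], C=0.0)

    def test_deterministic(self, rng):
        X = rng.normal(size=(24, 8))
        y = np.repeat([1, -1], 12)
        a = fit_linear_svm(X, y)
        b = fit_linear_svm(X, y)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.bias == b.bias


class TestRFERank:
    def test_single_feature_full_retention_is_noop(self):
        y = np.repeat([1, -1], 5)
        X = (y + 0.01 * np.arange(10)).reshape(-1, 1)
        ranking = rfe_rank(X, y, RFEConfig(retain_fraction=1.0))
        assert ranking.retained.tolist() == [0]
        assert ranking.rank.tolist() == [1]
        assert ranking.rounds == []

    def test_matches_one_at_a_time_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.repeat([1, -1], 15)
            signal = np.outer(y, rng.normal(size=3))
            X = np.hstack([signal, rng.normal(size=(30, 7))])
            config = RFEConfig(elim_fraction=0.01, retain_fraction=0.1)  # 1/round
            ranking = rfe_rank(X, y, config)
            oracle = brute_force_rfe_order(X, y, C=1.0)
            got_order = [int(r.removed[0]) for r in ranking.rounds]
            assert got_order == oracle[: len(got_order)]
            assert ranking.retained.tolist() == [oracle[-1]]

    def test_matches_sklearn_rfe_ranking(self):
        from sklearn.feature_selection import RFE
        from sklearn.svm import SVC

        rng = np.random.default_rng(11)
        y = np.repeat([1, -1], 12)
        X = np.hstack([np.outer(y, [1.0, 0.5]), rng.normal(size=(24, 6))])
        ranking = rfe_rank(X, y, RFEConfig(elim_fraction=0.01, retain_fraction=1 / 8))
        ref = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=1, step=1).fit(X, y)
        # same elimination order <=> identical rank vectors
        assert ranking.rank.tolist() == ref.ranking_.tolist()

    def test_schedule_arithmetic_matches_direct_simulation(self):
        got = elimination_schedule(100, 0.05, 0.40)
        remaining, expected = 100, []
        while remaining > 40:
            k = min(max(1, math.ceil(0.05 * remaining)), remaining - 40)
            expected.append(k)
            remaining -= k
        assert got == expected
        assert 100 - sum(got) == 40

    @pytest.mark.parametrize("n, elim, retain", [(10, 0.3, 0.5), (37, 0.05, 0.14), (5, 0.9, 0.2)])
    def test_retained_count_is_ceil_of_fraction(self, n, elim, retain, rng):
        y = np.repeat([1, -1], 10)
        X = rng.normal(size=(20, n)) + 0.3 * y[:, None]
        ranking = rfe_rank(X, y, RFEConfig(elim_fraction=elim, retain_fraction=retain))
        assert ranking.retained.size == math.ceil(retain * n)
        # rank is a permutation of 1..n
        assert sorted(ranking.rank.tolist()) == list(range(1, n + 1))

    def test_scale_equivariance_with_rescaled_penalty(self, rng):
        y = np.repeat([1, -1], 10)
        X = rng.normal(size=(20, 8)) + 0.2 * y[:, None]
        s = 7.0
        r1 = rfe_rank(X, y, RFEConfig(C=1.0, elim_fraction=0.01, retain_fraction=0.25))
        r2 = rfe_rank(s * X, y, RFEConfig(C=1.0 / s**2, elim_fraction=0.01, retain_fraction=0.25))
        assert r1.rank.tolist() == r2.rank.tolist()
        assert r1.retained.tolist() == r2.retained.tolist()

    def test_standardize_makes_order_scale_invariant(self, rng):
        y = np.repeat([1, -1], 12)
        X = rng.normal(size=(24, 6)) + 0.3 * y[:, None]
        scales = np.array([1.0, 10.0, 0.1, 5.0, 0.5, 2.0])
        cfg = RFEConfig(elim_fraction=0.01, retain_fraction=0.34, standardize=True)
        r1 = rfe_rank(X, y, cfg)
        r2 = rfe_rank(X * scales, y, cfg)
        assert r1.rank.tolist() == r2.rank.tolist()

    def test_signal_features_survive_when_capacity_allows(self):
        # separable data with k informative features, retain_fraction*n >= k
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.repeat([1, -1], 20)
            k = 3
            X = np.hstack([np.outer(y, rng.uniform(1, 2, size=k)),
                           0.1 * rng.normal(size=(40, 17))])
            ranking = rfe_rank(X, y, RFEConfig(retain_fraction=0.2))  # retain 4 >= k
            assert set(range(k)) <= set(ranking.retained.tolist())

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            rfe_rank(np.empty((4, 0)), [1, 1, -1, -1])

    def test_config_validation(self):
        with pytest.raises(ValueError, match="elim_fraction"):
            RFEConfig(elim_fraction=0.0)
        with pytest.raises(ValueError, match="retain_fraction"):
            RFEConfig(retain_fraction=1.5)


class TestSelectFeatures:
    def test_full_retention_returns_input_matrix(self, rng):
        X = rng.normal(size=(12, 27)) + 0.5 * np.repeat([1, -1], 6)[:, None]
        cohort = matrix_cohort(X, np.repeat([1, -1], 6))
        res = screen(cohort, ScreeningConfig(alpha=0.999, min_cluster=1))
        reduced, ranking, prov = select_features(cohort, res, RFEConfig(retain_fraction=1.0))
        np.testing.assert_array_equal(reduced.X, cohort.X[:, res.selected_columns])
        assert prov["n_retained"] == res.n_selected

    def test_retained_count_arithmetic(self, blob_cohort_spec):
        volumes, labels, _ = generate_cohort(blob_cohort_spec)
        cohort = to_matrix(volumes, labels)
        res = screen(cohort, ScreeningConfig(alpha=0.05, min_cluster=10))
        reduced, _, prov = select_features(cohort, res, RFEConfig(retain_fraction=0.4))
        assert reduced.n_voxels == math.ceil(0.4 * res.n_selected)
        assert prov["n_surviving"] == res.n_selected

    def test_empty_surviving_set_instructive_error(self, rng):
        X = rng.normal(size=(8, 30))
        cohort = matrix_cohort(X, np.repeat([1, -1], 4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = screen(cohort, ScreeningConfig(alpha=1e-6, min_cluster=30))
        with pytest.raises(ValueError, match="alpha"):
            select_features(cohort, res)
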