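"""Scaling, PCA, OPLS-DA and its validation statistics."""

import numpy as np
import pytest

from sleepmet.chemometrics import (
    ChemometricsError,
    cv_anova,
    fit_opls,
    fit_pca,
    pca_outlier_flag,
    pcorr_loadings,
    permutation_test,
    q2_cross_validation,
    scale_matrix,
    select_n_orthogonal,
)


class TestScaling:
    def test_center(self):
        s = scale_matrix(np.array([[1.0], [2.0], [3.0]]), "center")
        assert np.allclose(s.X.ravel(), [-1, 0, 1])

    def test_pareto_halves_sd_of_sd4_column(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(200)
        col = (col - col.mean()) / col.std(ddof=1) * 4.0
        s = scale_matrix(col[:, None], "pareto")
        assert s.X.std(ddof=1) == pytest.approx(2.0, abs=1e-9)

    def test_uv_gives_unit_sd(self):
        X = np.random.default_rng(1).standard_normal((50, 4)) * [1, 5, 0.1, 100]
        s = scale_matrix(X, "uv")
        assert np.allclose(s.X.std(axis=0, ddof=1), 1.0)

    def test_zero_variance_column_centered_only(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            s = scale_matrix(X, "uv")
        assert np.allclose(s.X[:, 0], 0.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ChemometricsError):
            scale_matrix(np.empty((0, 0)), "uv")


class TestPca:
    def test_perfect_correlation_is_rank_one(self):
        x = np.arange(10.0)
        X = scale_matrix(np.column_stack([x, 2 * x]), "uv").X
        m = fit_pca(X, 1)
        assert m.r2x_cum == pytest.approx(1.0, abs=1e-12)

    def test_full_decomposition_explains_everything(self):
        X = scale_matrix(np.random.default_rng(2).standard_normal((10, 4)), "center").X
        assert fit_pca(X, 4).r2x_cum == pytest.approx(1.0, abs=1e-12)

    def test_eigenvalues_match_covariance_oracle(self):
        X = scale_matrix(np.random.default_rng(3).standard_normal((30, 5)), "center").X
        m = fit_pca(X, 5)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert np.allclose(m.explained_variance, eig, atol=1e-10)

    def test_loadings_orthonormal_variance_nonincreasing(self):
        X = scale_matrix(np.random.default_rng(4).standard_normal((20, 6)), "uv").X
        m = fit_pca(X, 4)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(4), atol=1e-10)
        assert (np.diff(m.explained_variance) <= 1e-12).all()

    def test_identical_samples_not_flagged(self):
        # zero spread: every score identical, nothing can exceed the limit
        from sleepmet.chemometrics import PcaModel

        pm = PcaModel(np.ones((8, 1)), np.ones((3, 1)) / np.sqrt(3), np.array([0.0]), 1.0, 8)
        assert pca_outlier_flag(pm, list(range(8)), 0.99) == []

    def test_gaussian_false_flag_rate_near_nominal(self):
        flags = 0
        for seed in range(30):
            X = scale_matrix(np.random.default_rng(seed).standard_normal((100, 5)), "uv").X
            m = fit_pca(X, 2)
            flags += len(pca_outlier_flag(m, list(range(100)), 0.99))
        # ~1 expected per set of 100 at the 99% limit
        assert flags / 30 <= 4

    def test_rank_violation_rejected(self):
        X = np.random.default_rng(5).standard_normal((4, 10))
        with pytest.raises(ChemometricsError):
            fit_pca(X, 5)


class TestOpls:
    def test_zero_orth_equals_pls1_oracle(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(6)
        X = scale_matrix(rng.standard_normal((25, 7)), "uv").X
        y = rng.integers(0, 2, 25).astype(float)
        m = fit_opls(X, y, 0)
        oracle = PLSRegression(n_components=1, scale=False).fit(X, y - y.mean())
        assert np.abs(m.predict(X) - (oracle.predict(X).ravel() + y.mean())).max() < 1e-8

    def test_recovers_planted_predictive_score(self):
        rng = np.random.default_rng(7)
        n = 30
        y = np.repeat([0.0, 1.0], n // 2)
        t = y - y.mean()
        t_o = rng.standard_normal(n)
        t_o -= t_o @ t / (t @ t) * t  # orthogonalize
        p, p_o = rng.standard_normal(6), rng.standard_normal(6)
        X = np.outer(t, p) + np.outer(t_o, p_o)
        m = fit_opls(X, y, 1)
        r = np.corrcoef(m.t, y)[0, 1]
        assert abs(r) > 0.999

    def test_predictive_score_orthogonal_to_orthogonal_scores(self):
        rng = np.random.default_rng(8)
        X = scale_matrix(rng.standard_normal((24, 10)), "uv").X
        y = np.repeat([0, 1], 12)
        m = fit_opls(X, y, 3)
        assert np.abs(m.T_o.T @ m.t).max() < 1e-8

    def test_r2y_never_drops_when_filtering_orthogonal_variation(self):
        rng = np.random.default_rng(9)
        X = scale_matrix(rng.standard_normal((24, 10)), "uv").X
        y = np.repeat([0, 1], 12)
        r2 = [fit_opls(X, y, k).r2y for k in range(4)]
        assert all(b >= a - 1e-10 for a, b in zip(r2, r2[1:]))

    def test_constant_y_rejected(self):
        X = np.random.default_rng(10).standard_normal((10, 3))
        with pytest.raises(ChemometricsError):
            fit_opls(X, np.ones(10), 0)


class TestPcorr:
    def test_column_equal_to_score_is_one(self):
        rng = np.random.default_rng(11)
        X = scale_matrix(rng.standard_normal((20, 4)), "uv").X
        y = np.repeat([0, 1], 10)
        m = fit_opls(X, y, 0)
        Xa = np.column_stack([X, m.t, -m.t])
        pc = pcorr_loadings(m, Xa)
        assert pc[-2] == pytest.approx(1.0)
        assert pc[-1] == pytest.approx(-1.0)
        assert (np.abs(pc) <= 1.0).all()


class TestQ2:
    def test_perfect_signal(self):
        # center scaling keeps the tiny nuisance columns tiny (uv would
        # inflate them to unit variance and dilute the predictive weight)
        rng = np.random.default_rng(12)
        y = np.tile([0.0, 1.0], 20)
        X = np.column_stack([y - 0.5, rng.standard_normal((40, 3)) * 0.01])
        assert q2_cross_validation(scale_matrix(X, "center").X, y, 0) > 0.99

    def test_null_data_nonpositive(self):
        rng = np.random.default_rng(13)
        X = scale_matrix(rng.standard_normal((40, 10)), "uv").X
        y = np.tile([0, 1], 20)
        assert q2_cross_validation(X, y, 0) <= 0

    def test_q2_below_r2y(self):
        rng = np.random.default_rng(14)
        X = scale_matrix(rng.standard_normal((28, 8)), "uv").X
        y = np.repeat([0, 1], 14)
        for k in (0, 1, 2):
            assert q2_cross_validation(X, y, k) <= fit_opls(X, y, k).r2y + 1e-12


class TestComponentSelection:
    def test_planted_orthogonal_confounder_detected(self):
        rng = np.random.default_rng(15)
        n = 40
        y = np.tile([0.0, 1.0], n // 2)
        t = y - y.mean()
        conf = rng.standard_normal(n)
        conf -= conf @ t / (t @ t) * t
        X = np.outer(t, rng.standard_normal(8)) + 8 * np.outer(conf, rng.standard_normal(8))
        X += 0.05 * rng.standard_normal(X.shape)
        assert select_n_orthogonal(scale_matrix(X, "uv").X, y, 4) >= 1

    def test_pure_predictive_structure_returns_zero(self):
        rng = np.random.default_rng(16)
        y = np.tile([0.0, 1.0], 20)
        X = np.outer(y - 0.5, rng.standard_normal(6)) + 0.05 * rng.standard_normal((40, 6))
        assert select_n_orthogonal(scale_matrix(X, "uv").X, y, 4) == 0

    def test_never_exceeds_max(self):
        rng = np.random.default_rng(17)
        X = scale_matrix(rng.standard_normal((30, 10)), "uv").X
        y = np.tile([0, 1], 15)
        assert select_n_orthogonal(X, y, 2) <= 2


class TestCvAnova:
    def test_overwhelming_signal_significant(self):
        rng = np.random.default_rng(18)
        y = np.tile([0.0, 1.0], 15)
        X = np.column_stack([y - 0.5 + 0.01 * rng.standard_normal(30), rng.standard_normal((30, 2))])
        assert cv_anova(scale_matrix(X, "uv").X, y, 0) < 1e-3

    def test_probability_range(self):
        rng = np.random.default_rng(19)
        for seed in range(10):
            X = scale_matrix(np.random.default_rng(seed).standard_normal((20, 5)), "uv").X
            y = np.tile([0, 1], 10)
            assert 0.0 <= cv_anova(X, y, 0) <= 1.0


class TestPermutation:
    def test_strong_effect_hits_add_one_floor(self):
        rng = np.random.default_rng(20)
        y = np.repeat([0, 1], 10)
        X = np.column_stack([y * 3.0 + 0.05 * rng.standard_normal(20), rng.standard_normal((20, 4))])
        p, null, q2 = permutation_test(scale_matrix(X, "uv").X, y, 999, seed=21)
        assert p == pytest.approx(1 / 1000)
        assert p >= 1 / (999 + 1)

    def test_minimum_pvalue_bound(self):
        rng = np.random.default_rng(22)
        X = scale_matrix(rng.standard_normal((16, 4)), "uv").X
        y = np.tile([0, 1], 8)
        p, _, _ = permutation_test(X, y, 99, seed=23)
        assert p >= 1 / 100
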