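import inspect

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from oracles import osc_pls_scores_loadings, planted_two_direction_instance
from longomix.opls import (
    cross_validate_q2,
    fit_opls_da,
    permutation_test,
    significant_loadings,
)


def labels_of(y):
    return np.where(y > 0, "test", "control")


class TestFit:
    def test_pure_signal_limit(self, rng):
        # X exactly rank one along a class-aligned direction
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        v = rng.normal(size=8)
        X = np.outer(y, v)
        model, diags = fit_opls_da(X, labels_of(y), n_ortho=0)
        assert diags.r2x_pred == pytest.approx(1.0, abs=1e-10)
        assert diags.r2y == pytest.approx(1.0, abs=1e-10)
        # requesting orthogonal components finds nothing informative
        model2, diags2 = fit_opls_da(X, labels_of(y), n_ortho=2)
        assert sum(diags2.r2x_ortho) < 1e-10

    def test_reduces_to_pls1_without_orthogonal_components(self, rng):
        X, y = planted_two_direction_instance(rng, 20, 15)
        model, _ = fit_opls_da(X, labels_of(y), n_ortho=0)
        pls = PLSRegression(n_components=1, scale=False).fit(X, y)
        assert np.allclose(model.predict_response(X), np.ravel(pls.predict(X)),
                           atol=1e-10)
        sgn = np.sign(pls.x_scores_[:, 0] @ model.t_pred)
        assert np.allclose(model.t_pred, sgn * pls.x_scores_[:, 0], atol=1e-10)

    def test_matches_osc_pls_oracle(self, rng):
        X, y = planted_two_direction_instance(rng, 18, 25)
        model, _ = fit_opls_da(X, labels_of(y), n_ortho=1)
        t_ref, p_ref = osc_pls_scores_loadings(X, y, 1)
        sgn = np.sign(t_ref @ model.t_pred)
        assert np.allclose(model.t_pred, sgn * t_ref, atol=1e-6)
        assert np.allclose(model.p_pred, sgn * p_ref, atol=1e-6)

    def test_model_invariants(self, rng):
        X, y = planted_two_direction_instance(rng, 16, 12)
        model, _ = fit_opls_da(X, labels_of(y), n_ortho=2)
        assert np.linalg.norm(model.w) == pytest.approx(1.0)
        for k in range(model.n_ortho):
            assert np.linalg.norm(model.W_ortho[:, k]) == pytest.approx(1.0)
            assert abs(model.w @ model.W_ortho[:, k]) < 1e-8
            assert abs(model.t_pred @ model.T_ortho[:, k]) < 1e-8

    def test_variance_conservation(self, rng):
        for _ in range(20):
            n, p = int(rng.integers(8, 30)), int(rng.integers(5, 50))
            X = rng.normal(size=(n, p))
            labels = np.where(np.arange(n) % 2 == 0, "test", "control")
            _, d = fit_opls_da(X, labels, n_ortho=int(rng.integers(0, 4)))
            total = d.r2x_pred + sum(d.r2x_ortho) + d.r2x_residual
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_sign_invariance_under_label_encoding(self, rng):
        X, y = planted_two_direction_instance(rng, 16, 20)
        m1, d1 = fit_opls_da(X, labels_of(y), n_ortho=1, positive_label="test")
        m2, d2 = fit_opls_da(X, labels_of(y), n_ortho=1, positive_label="control")
        assert np.allclose(m1.t_pred, -m2.t_pred, atol=1e-10)
        assert np.allclose(m1.p_pred, -m2.p_pred, atol=1e-10)
        assert d1.r2y == pytest.approx(d2.r2y)
        assert d1.q2 == pytest.approx(d2.q2)
        assert significant_loadings(m1) == significant_loadings(m2)

    def test_rejects_single_class(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError):
            fit_opls_da(X, ["test"] * 6, n_ortho=0)

    def test_rejects_zero_variance(self):
        X = np.zeros((6, 4))
        labels = ["test"] * 3 + ["control"] * 3
        with pytest.raises(ValueError):
            fit_opls_da(X, labels, n_ortho=0)

    def test_q2_never_exceeds_r2y(self, rng):
        X, y = planted_two_direction_instance(rng, 20, 10, noise=0.5)
        _, d = fit_opls_da(X, labels_of(y), n_ortho=1)
        assert d.q2 <= d.r2y + 1e-8


class TestCrossValidation:
    def test_default_folds_is_seven(self):
        assert inspect.signature(cross_validate_q2).parameters["folds"].default == 7

    def test_strong_signal_q2(self, rng):
        X, y = planted_two_direction_instance(rng, 28, 30)
        q2 = cross_validate_q2(X, labels_of(y), 1, folds=7)
        assert q2 > 0.9

    def test_noise_only_q2_near_or_below_zero(self):
        # labels independent of X: mean Q2 over seeded runs below 0.05
        vals = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            X = r.normal(size=(24, 30))
            labels = np.array(["test"] * 12 + ["control"] * 12)
            vals.append(cross_validate_q2(X, labels, 1, folds=7))
        assert np.mean(vals) < 0.05

    def test_rejects_folds_exceeding_class_size(self, rng):
        X, y = planted_two_direction_instance(rng, 12, 8)
        with pytest.raises(ValueError, match="class"):
            cross_validate_q2(X, labels_of(y), 1, folds=7)

    def test_scaler_refit_inside_folds_changes_result(self, rng):
        X = rng.lognormal(size=(28, 15))
        y = np.concatenate([np.ones(14), -np.ones(14)])
        X[:14] *= 1.5
        q_inside = cross_validate_q2(X, labels_of(y), 0, folds=7, scaler="pareto")
        from longomix.preprocess import pareto_scale
        q_global = cross_validate_q2(pareto_scale(X), labels_of(y), 0, folds=7)
        assert q_inside != pytest.approx(q_global, abs=1e-12)


class TestPermutation:
    def test_default_n_perm_is_200(self):
        assert inspect.signature(permutation_test).parameters["n_perm"].default == 200

    def test_separable_data_minimal_p(self, rng):
        X, y = planted_two_direction_instance(rng, 24, 30)
        res = permutation_test(X, labels_of(y), 1, n_perm=200, seed=5, folds=7)
        assert res.p_value == pytest.approx(1 / 201)
        assert res.n_perm == 200
        assert len(res.permuted_q2) == 200

    def test_noise_only_large_p(self):
        r = np.random.default_rng(99)
        X = r.normal(size=(24, 30))
        labels = np.array(["test"] * 12 + ["control"] * 12)
        res = permutation_test(X, labels, 1, n_perm=100, seed=7, folds=7)
        assert res.p_value > 0.05

    def test_reproducible_by_seed(self, rng):
        X, y = planted_two_direction_instance(rng, 16, 10, noise=1.0)
        a = permutation_test(X, labels_of(y), 1, n_perm=20, seed=3)
        b = permutation_test(X, labels_of(y), 1, n_perm=20, seed=3)
        assert a.permuted_q2 == b.permuted_q2

    def test_rejects_zero_permutations(self, rng):
        X, y = planted_two_direction_instance(rng, 12, 6)
        with pytest.raises(ValueError):
            permutation_test(X, labels_of(y), 1, n_perm=0)


class TestSignificantLoadings:
    @staticmethod
    def _model_with_loadings(p):
        from longomix.opls import OplsModel
        p = np.asarray(p, dtype=float)
        return OplsModel(
            w=np.zeros_like(p), p_pred=p, t_pred=np.zeros(3),
            W_ortho=np.empty((p.size, 0)), P_ortho=np.empty((p.size, 0)),
            T_ortho=np.empty((3, 0)), b=1.0, y_mean=0.0,
            class_map={"test": 1.0, "control": -1.0},
        )

    def test_single_outlier_flagged(self):
        # sd of [3.0] + 99 x [0.1] is ~0.29 by hand; only the outlier exceeds it
        p = np.array([3.0] + [0.1] * 99)
        assert float(p.std(ddof=1)) == pytest.approx(0.29, abs=0.001)
        model = self._model_with_loadings(p)
        assert significant_loadings(model) == {0}

    def test_all_equal_nonzero_all_flagged(self):
        model = self._model_with_loadings([0.5] * 10)
        assert significant_loadings(model) == set(range(10))

    def test_all_zero_empty(self):
        model = self._model_with_loadings([0.0] * 10)
        assert significant_loadings(model) == set()

    def test_feature_id_mapping(self):
        model = self._model_with_loadings([3.0] + [0.1] * 99)
        ids = [f"F{i}" for i in range(100)]
        assert significant_loadings(model, ids) == {"F0"}


class TestAutoOrtho:
    def test_auto_finds_planted_orthogonal_component(self, rng):
        X, y = planted_two_direction_instance(rng, 28, 30)
        model, diags = fit_opls_da(X, labels_of(y), n_ortho="auto")
        assert model.n_ortho >= 1
        assert diags.q2 > 0.9
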