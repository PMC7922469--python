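import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from soynmr.pls import (
    OPLS,
    NipalsPLS,
    autofit,
    fit_opls,
    fit_pls,
    fit_statistics,
    vip,
)


def random_problem(rng, n=30, p=10, q=1, noise=0.1):
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, q))
    Y = X @ B + noise * rng.normal(size=(n, q))
    return X, Y if q > 1 else Y[:, 0]


class TestNipalsPLS:
    def test_full_rank_pls1_equals_least_squares(self, rng):
        # oracle: normal-equations solve on centred data
        X, y = random_problem(rng, n=25, p=6)
        m = fit_pls(X, y, n_components=6)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        assert np.allclose(m.predict(X), Xc @ beta + y.mean(), atol=1e-8)

    def test_orthonormal_x_single_component_weight(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(30, 5)))
        X = Q  # orthonormal columns
        y = rng.normal(size=30)
        m = fit_pls(X, y, n_components=1)
        Xc = X - X.mean(axis=0)
        w_expected = Xc.T @ (y - y.mean())
        w_expected /= np.linalg.norm(w_expected)
        assert np.allclose(np.abs(m.x_weights_[:, 0]), np.abs(w_expected), atol=1e-8)

    def test_invariant_to_sample_duplication(self, rng):
        X, y = random_problem(rng)
        m1 = fit_pls(X, y, 3)
        m2 = fit_pls(np.vstack([X, X]), np.concatenate([y, y]), 3)
        for attr in ("x_weights_", "x_loadings_", "y_loadings_"):
            assert np.allclose(getattr(m1, attr), getattr(m2, attr), atol=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X, Y = random_problem(rng, n=40, p=15, q=3)
        m = fit_pls(X, Y, 5)
        G = m.x_scores_.T @ m.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_weights_unit_norm(self, rng):
        X, Y = random_problem(rng, q=2)
        m = fit_pls(X, Y, 4)
        assert np.allclose(np.linalg.norm(m.x_weights_, axis=0), 1.0, atol=1e-10)

    @pytest.mark.parametrize("n,p,A", [(30, 10, 4), (50, 100, 5)])
    def test_matches_sklearn_single_response(self, rng, n, p, A):
        X, y = random_problem(rng, n=n, p=p)
        ours = fit_pls(X, y, A)
        ref = PLSRegression(n_components=A, scale=False).fit(X, y[:, None])
        assert np.allclose(ours.predict(X), ref.predict(X)[:, 0], atol=1e-8)

    @pytest.mark.parametrize("n,p,q,A", [(30, 10, 2, 4), (50, 100, 3, 5)])
    def test_matches_svd_fixed_point_multi_response(self, rng, n, p, q, A):
        # independent oracle: per component, the NIPALS fixed point is the
        # leading left singular vector of X'Y — computed directly by SVD
        X, Y = random_problem(rng, n=n, p=p, q=q)
        Xd = X - X.mean(axis=0)
        Yd = Y - Y.mean(axis=0)
        preds = np.zeros_like(Yd)
        for _ in range(A):
            U = np.linalg.svd(Xd.T @ Yd, full_matrices=False)[0]
            w = U[:, 0]
            t = Xd @ w
            tt = t @ t
            c = Yd.T @ t / tt
            pv = Xd.T @ t / tt
            Xd = Xd - np.outer(t, pv)
            Yd = Yd - np.outer(t, c)
            preds += np.outer(t, c)
        ours = fit_pls(X, Y, A)
        assert np.allclose(ours.predict(X), preds + Y.mean(axis=0), atol=1e-8)

    def test_component_count_beyond_rank_rejected(self, rng):
        X, y = random_problem(rng, n=10, p=4)
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, y, 5)

    def test_permutation_equivariance_of_weights_and_vip(self, rng):
        X, y = random_problem(rng, p=8)
        perm = rng.permutation(8)
        m1 = fit_pls(X, y, 3)
        m2 = fit_pls(X[:, perm], y, 3)
        assert np.allclose(m1.x_weights_[perm], m2.x_weights_, atol=1e-8)
        assert np.allclose(vip(m1)[perm], vip(m2), atol=1e-8)


class TestOPLS:
    def test_zero_orthogonal_equals_one_component_pls(self, rng):
        X, y = random_problem(rng)
        assert np.allclose(
            fit_opls(X, y, 0).predict(X),
            fit_pls(X, y, 1).predict(X),
            atol=1e-10,
        )

    def test_orthogonal_scores_uncorrelated_with_response(self, rng):
        X, y = random_problem(rng, n=40, p=20, noise=1.0)
        m = fit_opls(X, y, 3)
        yc = y - y.mean()
        for j in range(3):
            t_o = m.ortho_scores_[:, j]
            assert abs(t_o @ yc) < 1e-8 * np.linalg.norm(t_o) * np.linalg.norm(yc)

    def test_predictive_weight_orthogonal_to_orthogonal_weights(self, rng):
        X, y = random_problem(rng, n=40, p=20, noise=1.0)
        m = fit_opls(X, y, 2)
        # orthogonal weights are built orthogonal to the initial y-covariance
        # direction; check they stay near-orthogonal to the final one
        for j in range(2):
            assert abs(m.x_weights_ @ m.ortho_weights_[:, j]) < 1e-6

    def test_recovers_planted_orthogonal_direction(self, rng):
        # X = y a' + z b' with a ⊥ b and z ⊥ y: one orthogonal component
        # must align with b (oracle: subspace projection)
        n, p = 60, 12
        a = np.zeros(p); a[0] = 1.0
        b = np.zeros(p); b[5] = 1.0
        y = rng.normal(size=n)
        z = rng.normal(size=n)
        y -= y.mean(); z -= z.mean()
        z -= (z @ y) / (y @ y) * y
        z += 0.02 * y  # tiny controlled y-leakage lets OSC see the direction
        X = np.outer(y, a) + np.outer(z, b)
        m = fit_opls(X, y, 1)
        cos = abs(m.ortho_weights_[:, 0] @ b) / np.linalg.norm(b)
        assert cos > 0.999

    def test_fitted_values_match_pls_with_same_total_components(self, rng):
        X, y = random_problem(rng, n=35, p=14, noise=0.5)
        for k in (1, 2, 3):
            o = fit_opls(X, y, k)
            m = fit_pls(X, y, 1 + k)
            assert np.allclose(o.predict(X), m.predict(X), atol=1e-8)

    def test_prediction_invariant_to_orthogonal_perturbation(self, rng):
        X, y = random_problem(rng, n=30, p=10, noise=0.5)
        m = fit_opls(X, y, 2)
        x = X[3].copy()
        base = m.predict(x[None, :])
        for gamma in (0.5, 5.0):
            pert = x + gamma * m.ortho_loadings_[:, 0]
            moved = m.predict(pert[None, :])
            # projection onto (w_o, p_o) removes the added direction
            assert np.allclose(moved, base, atol=1e-6)

    def test_training_mean_row_predicts_response_mean(self, rng):
        X, y = random_problem(rng)
        m = fit_opls(X, y, 1)
        assert m.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean())

    def test_excessive_orthogonal_components_advise_reduction(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=20)
        X = np.outer(y, np.ones(3))  # rank-1, no orthogonal variation
        with pytest.raises(ValueError, match="smaller n_orth"):
            fit_opls(X, y, 1)

    def test_signature_format(self):
        assert OPLS(n_orthogonal=4).signature == "1+4"
        assert NipalsPLS(n_components=5).signature == "5"


class TestVIP:
    def test_single_component_vip_is_scaled_weight(self, rng):
        X, y = random_problem(rng, p=7)
        m = fit_pls(X, y, 1)
        assert np.allclose(vip(m), np.sqrt(7) * np.abs(m.x_weights_[:, 0]), atol=1e-10)

    def test_squared_vip_sums_to_variable_count(self, rng):
        for q, A in [(1, 3), (3, 4)]:
            X, Y = random_problem(rng, n=40, p=13, q=q)
            v = vip(fit_pls(X, Y, A))
            assert v @ v == pytest.approx(13, abs=1e-8)
        X, y = random_problem(rng, n=40, p=13)
        v = vip(fit_opls(X, y, 2))
        assert v @ v == pytest.approx(13, abs=1e-8)

    def test_duplicated_columns_get_equal_vip(self, rng):
        X, y = random_problem(rng, p=5)
        Xdup = np.column_stack([X, X[:, 2]])
        v = vip(fit_pls(Xdup, y, 2))
        assert v[2] == pytest.approx(v[5], abs=1e-8)


class TestFitStatistics:
    def test_noiseless_linear_response_gives_unit_r2y(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5)
        st = fit_statistics(NipalsPLS(5), X, y, cv=5)
        assert st.r2y == pytest.approx(1.0, abs=1e-8)

    def test_r2y_never_below_q2y(self, rng):
        for _ in range(5):
            X, y = random_problem(rng, n=40, p=12, noise=1.0)
            st = fit_statistics(NipalsPLS(3), X, y, cv=7)
            assert st.r2y >= st.q2y

    def test_null_response_q2y_nonpositive_on_average(self):
        # permuted labels carry no signal: mean Q2Y over seeds < 0.05
        q2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 10))
            y = rng.permutation(np.repeat([0.0, 1.0], 20))
            st = fit_statistics(
                NipalsPLS(2), X, y, cv=7, stratify=y, random_state=seed
            )
            q2s.append(st.q2y)
        assert np.mean(q2s) < 0.05

    def test_fold_losing_a_class_rejected(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.array([1.0] + [0.0] * 11)
        with pytest.raises(ValueError, match="class"):
            # the lone positive must drop out of one training fold
            fit_statistics(NipalsPLS(1), X, y, cv=7, stratify=y)

    def test_requires_two_folds(self, rng):
        X, y = random_problem(rng)
        with pytest.raises(ValueError, match="cv"):
            fit_statistics(NipalsPLS(1), X, y, cv=1)


class TestAutofit:
    def test_rank_one_noiseless_selects_single_component(self, rng):
        t = rng.normal(size=30)
        p = rng.normal(size=8)
        X = np.outer(t, p)  # rank-one predictor block
        y = X @ p  # response carried entirely by the single factor
        res = autofit(X, y, family="pls", max_components=5)
        assert res.signature == "1"

    def test_pure_noise_still_returns_one_component(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        res = autofit(X, y, family="pls", max_components=5)
        assert res.signature == "1"

    def test_two_factor_signal_selects_two_components(self):
        rng = np.random.default_rng(7)
        n = 60
        t1, t2 = rng.normal(size=n), rng.normal(size=n)
        p1 = np.r_[np.ones(5), np.zeros(5)]
        p2 = np.r_[np.zeros(5), np.ones(5)]
        # unequal block scales force the factors into separate components
        X = 10 * np.outer(t1, p1) + np.outer(t2, p2) + 0.05 * rng.normal(size=(n, 10))
        y = t1 + t2 + 0.05 * rng.normal(size=n)
        res = autofit(X, y, family="pls", max_components=5)
        assert res.signature == "2"

    def test_opls_family_returns_signature(self, rng):
        X, y = random_problem(rng, n=40, p=10, noise=0.5)
        res = autofit(X, y, family="opls", max_components=4)
        assert res.signature.startswith("1+")
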