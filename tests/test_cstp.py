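"""CSTP filter learning: covariances, alternating optimization, features."""

import numpy as np
import pytest
from scipy import linalg, optimize

from p300sttc.cstp import CSTP, class_covariances, extract_features, fit_cstp, pca_project, project


def _angle_deg(a, b):
    a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
    return np.degrees(np.arccos(min(abs(float(a @ b)), 1.0)))


class TestClassCovariances:
    def test_single_trial_unit_trace(self, rng):
        X = rng.standard_normal((2, 3, 8))
        y = np.array([0, 1])
        with pytest.raises(ValueError):  # <2 trials per class
            class_covariances(X, y)
        X4 = np.concatenate([X, X])
        s1, s2 = class_covariances(X4, np.array([0, 1, 0, 1]))
        assert np.trace(s1) == pytest.approx(1.0)
        assert np.trace(s2) == pytest.approx(1.0)

    def test_duplicated_trials_equal_single(self, rng):
        x = rng.standard_normal((1, 4, 10))
        X = np.concatenate([x, x, x, x])
        s1, s2 = class_covariances(X, np.array([0, 0, 1, 1]))
        expected = x[0] @ x[0].T / np.trace(x[0] @ x[0].T)
        assert np.allclose(s1, expected)
        assert np.allclose(s2, expected)

    def test_matches_explicit_loop(self, rng):
        X = rng.standard_normal((6, 3, 12))
        y = np.array([0, 0, 0, 1, 1, 1])
        V = rng.standard_normal((12, 4))
        s1, _ = class_covariances(X, y, projector=V, kind="spatial")
        acc = np.zeros((3, 3))
        for trial in X[:3]:
            Z = trial @ V
            acc += Z @ Z.T / np.trace(Z @ Z.T)
        assert np.allclose(s1, acc / 3)

    def test_temporal_kind_matches_loop(self, rng):
        X = rng.standard_normal((4, 3, 6))
        y = np.array([0, 0, 1, 1])
        W = rng.standard_normal((3, 2))
        _, r2 = class_covariances(X, y, projector=W, kind="temporal")
        acc = np.zeros((6, 6))
        for trial in X[2:]:
            U = W.T @ trial
            acc += U.T @ U / np.trace(U.T @ U)
        assert np.allclose(r2, acc / 2)

    def test_zero_trial_rejected(self):
        X = np.zeros((4, 2, 5))
        with pytest.raises(ValueError, match="zero"):
            class_covariances(X, np.array([0, 0, 1, 1]))


class TestFitCSTP:
    def test_null_classes_give_unit_objective(self, rng):
        base = rng.standard_normal((8, 3, 40))
        X = np.concatenate([base, base])  # identical trial sets in both classes
        y = np.repeat([0, 1], 8)
        m = CSTP(m_filters=2, k_filters=2).fit(X, y)
        assert m.objective_trace_[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(m.spatial_eigvals_, 0.5, atol=1e-4)

    def test_objective_trace_monotone(self, rng):
        for seed in range(4):
            r = np.random.default_rng(seed)
            X = r.standard_normal((20, 4, 30))
            X[:10] += 0.5 * r.standard_normal((4, 1))  # class-1 spatial offset
            y = np.repeat([0, 1], 10)
            m = CSTP(m_filters=2, k_filters=2).fit(X, y)
            assert np.all(np.diff(m.objective_trace_) >= -1e-9)

    def test_planted_spatial_direction_recovered(self, rng):
        theta = np.deg2rad(30)
        u = np.array([np.cos(theta), np.sin(theta)])
        X = rng.standard_normal((100, 2, 50))
        # class 1: strong extra variance along u
        X[:50] += 5.0 * u[:, None] * rng.standard_normal((50, 1, 50))
        y = np.repeat([0, 1], 50)
        m = CSTP(m_filters=2, k_filters=2).fit(X, y)
        # classes_[0]=0 is "class 1"; its variance-maximizing filter is W_[:, 0].
        # CSP filters live in the whitened metric; compare the corresponding
        # spatial pattern A = (S1+S2) W (inverse-transpose image of W).
        pattern = (m.sigma1_ + m.sigma2_) @ m.W_[:, 0]
        assert _angle_deg(pattern, u) < 5.0

    def test_matches_grid_search_oracle_on_toy(self):
        """M=K=1 on a 2-channel / 4-sample instance: the alternating fit's
        objective agrees with an exhaustive+refined search over unit (w, v)."""
        r = np.random.default_rng(7)
        u = np.array([0.8, 0.6])
        g = np.array([0.2, 0.9, -0.4, 0.1])
        X = 0.3 * r.standard_normal((8, 2, 4))
        X[:4] += 1.5 * u[:, None] * g[None, :]  # planted spatiotemporal component
        y = np.repeat([0, 1], 4)

        m = CSTP(m_filters=1, k_filters=1, max_iter=50, tol=1e-10).fit(X, y)
        J_fit = m.objective_trace_[-1]

        Xn = X / np.sqrt((X**2).sum(axis=(1, 2), keepdims=True))

        def neg_J(v_angles):
            a, b, c = v_angles
            v = np.array([np.cos(a), np.sin(a) * np.cos(b),
                          np.sin(a) * np.sin(b) * np.cos(c),
                          np.sin(a) * np.sin(b) * np.sin(c)])
            Yv = Xn @ v  # trials x channels
            S1 = (Yv[:4, :, None] * Yv[:4, None, :]).mean(axis=0)
            S2 = (Yv[4:, :, None] * Yv[4:, None, :]).mean(axis=0)
            lam = linalg.eigh(S1, S1 + S2, eigvals_only=True)[-1]
            return -lam / (1 - lam)

        grid = optimize.brute(neg_J, [(0, np.pi)] * 2 + [(0, 2 * np.pi)],
                              Ns=25, finish=None)
        best = optimize.minimize(neg_J, grid, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12})
        J_oracle = -best.fun
        assert J_fit == pytest.approx(J_oracle, rel=1e-3)

    def test_class_swap_reciprocity(self, rng):
        X = rng.standard_normal((12, 3, 16))
        X[:6] += 0.8 * rng.standard_normal((3, 1))
        y = np.repeat([0, 1], 6)
        m_fwd = CSTP(m_filters=2, k_filters=2).fit(X, y)
        m_rev = CSTP(m_filters=2, k_filters=2).fit(X, 1 - y)
        # two-ended selection: the top filter of one problem matches the
        # bottom filter of the other (up to sign)
        assert _angle_deg(m_fwd.W_[:, 0], m_rev.W_[:, 1]) < 1.0
        assert _angle_deg(m_fwd.W_[:, 1], m_rev.W_[:, 0]) < 1.0

    def test_shape_validation(self, rng):
        X = rng.standard_normal((6, 3, 10))
        y = np.repeat([0, 1], 3)
        with pytest.raises(ValueError):
            CSTP(m_filters=9).fit(X, y)
        with pytest.raises(ValueError):
            CSTP(k_filters=99).fit(X, y)


class TestProjectAndFeatures:
    def _manual_model(self, W, V):
        m = CSTP(m_filters=W.shape[1], k_filters=V.shape[1])
        m.W_, m.V_ = W, V
        return m

    def test_identity_projection(self, rng):
        X = rng.standard_normal((3, 4, 4))
        m = self._manual_model(np.eye(4), np.eye(4))
        assert np.allclose(project(m, X), X)

    def test_rank_one_projection_is_scalar(self, rng):
        X = rng.standard_normal((5, 3, 7))
        w, v = rng.standard_normal(3), rng.standard_normal(7)
        m = self._manual_model(w[:, None], v[:, None])
        Z = project(m, X)
        assert Z.shape == (5, 1, 1)
        for i in range(5):
            assert Z[i, 0, 0] == pytest.approx(w @ X[i] @ v)

    def test_bilinearity(self, rng):
        X1, X2 = rng.standard_normal((2, 4, 3, 7))
        m = self._manual_model(rng.standard_normal((3, 2)), rng.standard_normal((7, 2)))
        assert np.allclose(project(m, X1 + X2), project(m, X1) + project(m, X2))

    def test_feature_normalization_identity(self, rng):
        X = rng.standard_normal((10, 4, 30))
        y = np.repeat([0, 1], 5)
        m = fit_cstp(X, y, m_filters=2, k_filters=3)
        F = extract_features(m, X)
        assert F.shape == (10, 5)
        assert np.all(F <= 0)
        assert np.allclose(np.exp(F[:, :2]).sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(np.exp(F[:, 2:]).sum(axis=1), 1.0, atol=1e-8)

    def test_equal_row_variances_give_log_half(self, rng):
        m = self._manual_model(np.eye(2), np.eye(8))
        z = rng.standard_normal(8)
        X = np.stack([np.stack([z, z[::-1]])])  # two rows, identical variance
        F = m.transform(X)
        assert F[0, 0] == pytest.approx(np.log(0.5))
        assert F[0, 1] == pytest.approx(np.log(0.5))

    def test_features_match_loop(self, rng):
        X = rng.standard_normal((4, 3, 12))
        W = rng.standard_normal((3, 2))
        V = rng.standard_normal((12, 2))
        F = self._manual_model(W, V).transform(X)
        for i in range(4):
            Z = W.T @ X[i] @ V
            vs = Z.var(axis=1)
            vt = Z.var(axis=0)
            expected = np.concatenate([np.log(vs / vs.sum()), np.log(vt / vt.sum())])
            assert np.allclose(F[i], expected)


class TestPCA:
    def test_isotropic_gaussian_splits_variance(self):
        r = np.random.default_rng(0)
        X = r.standard_normal((4000, 2))
        _, evr = pca_project(X, 2)
        assert evr[0] == pytest.approx(0.5, abs=0.05)
        assert evr[1] == pytest.approx(0.5, abs=0.05)

    def test_collinear_data(self, rng):
        base = rng.standard_normal(50)
        X = np.c_[base, 2 * base, -base]
        scores, evr = pca_project(X, 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)
        assert scores.shape == (50, 2)

    def test_ratios_non_increasing_and_bounded(self, rng):
        X = rng.standard_normal((40, 6))
        _, evr = pca_project(X, 6)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_excess_components_truncated_with_warning(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.warns(RuntimeWarning):
            scores, _ = pca_project(X, 10)
        assert scores.shape[1] == 3

    def test_full_rank_scores_preserve_distances(self, rng):
        X = rng.standard_normal((20, 4))
        scores, _ = pca_project(X, 4)
        d0 = np.linalg.norm(X[:, None] - X[None], axis=2)
        d1 = np.linalg.norm(scores[:, None] - scores[None], axis=2)
        assert np.allclose(d0, d1)
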