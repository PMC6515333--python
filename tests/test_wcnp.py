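"""Kernel machinery: KPCA, within-class graph, geometry transform,
C-SVC and multi-output epsilon-SVR, with independent reference oracles."""

import numpy as np
import pytest
from sklearn.datasets import make_moons
from sklearn.svm import SVC

from myodetect.wcnp import (
    GeometryTransform,
    KernelSpec,
    center_gram,
    csvc_decision,
    csvc_fit,
    geometry_transform,
    gram,
    kpca_fit,
    msvr_fit,
    msvr_predict,
    wcnp_scatter,
    within_class_adjacency,
)


def reference_msvr(K, Z, C, eps, max_iter=500, tol=1e-12):
    """Independent standard multi-output epsilon-SVR (IRWLS, dual form).

    Works directly on the kernel matrix with the classical linear system
    over the active set; no KPCA embedding, no geometry transform.
    """
    N, q = Z.shape
    beta = np.zeros((N, q))
    b = Z.mean(axis=0)

    def objective(beta, b):
        E = Z - K @ beta - b
        u = np.sqrt((E**2).sum(1))
        loss = np.where(u > eps, (u - eps) ** 2, 0.0)
        return 0.5 * np.trace(beta.T @ K @ beta) + C * loss.sum()

    obj = objective(beta, b)
    for _ in range(max_iter):
        E = Z - K @ beta - b
        u = np.sqrt((E**2).sum(1))
        act = u > eps
        if not act.any():
            break
        a = np.zeros(N)
        a[act] = 2 * C * (u[act] - eps) / u[act]
        idx = np.where(act)[0]
        Ka = K[np.ix_(idx, idx)]
        n_a = idx.size
        lhs = np.zeros((n_a + 1, n_a + 1))
        lhs[:n_a, :n_a] = Ka + np.diag(1.0 / a[idx])
        lhs[:n_a, n_a] = 1.0
        lhs[n_a, :n_a] = a[idx] @ Ka
        lhs[n_a, n_a] = a[idx].sum()
        rhs = np.vstack([Z[idx], a[idx] @ Z[idx]])
        sol = np.linalg.solve(lhs, rhs)
        beta_new = np.zeros((N, q))
        beta_new[idx] = sol[:n_a]
        b_new = sol[n_a]
        step = 1.0
        for _ in range(30):
            bt = beta + step * (beta_new - beta)
            bb = b + step * (b_new - b)
            o = objective(bt, bb)
            if o <= obj:
                break
            step *= 0.5
        if o > obj - tol * max(obj, 1.0):
            beta, b, obj = bt, bb, o
            break
        beta, b, obj = bt, bb, o
    return beta, b


class TestGram:
    def test_unit_diagonal_symmetric_range(self, rng):
        X = rng.normal(size=(12, 3))
        K = gram(X, X, KernelSpec(r=2.0))
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)
        assert K.min() > 0 and K.max() <= 1.0

    def test_matches_loop_evaluation(self, rng):
        X = rng.normal(size=(5, 4))
        K = gram(X, X, KernelSpec(r=0.7))
        for i in range(5):
            for j in range(5):
                expected = np.exp(-0.7 * np.sum((X[i] - X[j]) ** 2))
                assert K[i, j] == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_r(self):
        with pytest.raises(ValueError):
            KernelSpec(r=0.0)


class TestCenterGram:
    def test_row_and_column_sums_vanish(self, rng):
        X = rng.normal(size=(9, 2))
        Kc = center_gram(gram(X, X))
        assert np.abs(Kc.sum(axis=0)).max() < 1e-10
        assert np.abs(Kc.sum(axis=1)).max() < 1e-10

    def test_idempotent(self, rng):
        Kc = center_gram(gram(*(rng.normal(size=(7, 3)),) * 2))
        assert np.allclose(center_gram(Kc), Kc, atol=1e-12)

    def test_equals_hkh(self, rng):
        X = rng.normal(size=(8, 3))
        K = gram(X, X)
        H = np.eye(8) - np.ones((8, 8)) / 8
        assert np.allclose(center_gram(K), H @ K @ H, atol=1e-12)


class TestKPCA:
    def test_gram_reconstruction(self, rng):
        """Projections keep all information: P P^T = centered Gram."""
        X = rng.normal(size=(15, 4))
        proj = kpca_fit(X)
        Kc = center_gram(proj.K_train)
        assert np.abs(proj.P @ proj.P.T - Kc).max() < 1e-8

    def test_transform_consistent_with_training_coordinates(self, rng):
        X = rng.normal(size=(12, 3))
        proj = kpca_fit(X)
        assert np.allclose(proj.transform(X), proj.P, atol=1e-8)

    def test_eigenvalues_descending(self, rng):
        proj = kpca_fit(rng.normal(size=(10, 3)))
        assert np.all(np.diff(proj.eigvals) <= 1e-12)

    def test_mean_point_projects_to_zero(self, rng):
        # centering sends the mean kernel row to the origin
        X = rng.normal(size=(10, 3))
        proj = kpca_fit(X)
        assert np.abs(proj.P.mean(axis=0)).max() < 1e-8


class TestWithinClassGraph:
    def test_no_cross_class_weights(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0] * 10 + [1] * 10)
        g = within_class_adjacency(gram(X, X), y, t=3)
        assert np.all(g.A[:10, 10:] == 0)
        assert np.all(g.A[10:, :10] == 0)

    def test_duplicate_points_get_unit_raw_weight(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1, 1], [2, 2], [3, 3]])
        K = gram(X, X, KernelSpec(r=1.0))
        g = within_class_adjacency(K, np.zeros(5, dtype=int), t=2)
        # the raw (pre-normalization) weight of the duplicate pair is exp(0)=1,
        # the largest in its row
        row = g.A[0]
        assert row.argmax() == 1

    def test_brute_force_neighbor_agreement(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.array([0] * 11 + [1] * 9)
        K = gram(X, X)
        g = within_class_adjacency(K, y, t=4)
        # brute force: for every i, its 4 nearest same-class others
        d2 = np.sum((X[:, None] - X[None]) ** 2, axis=-1)
        for i in range(20):
            same = [j for j in range(20) if y[j] == y[i] and j != i]
            nbrs = sorted(same, key=lambda j: d2[i, j])[:4]
            for j in nbrs:
                assert g.A[i, j] > 0
            far = [j for j in same if j not in nbrs]
            # non-neighbors may only be nonzero through the mutual condition:
            # i must be among j's own t nearest same-class neighbors
            for j in far:
                if g.A[i, j] > 0:
                    same_j = [q for q in range(20) if y[q] == y[j] and q != j]
                    assert i in sorted(same_j, key=lambda q: d2[j, q])[:4]

    def test_t_too_large_rejected(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.array([0] * 4 + [1] * 4)
        with pytest.raises(ValueError):
            within_class_adjacency(gram(X, X), y, t=4)


class TestScatterAndGeometry:
    def test_scatter_psd_and_zero_graph_reduction(self, rng):
        X = rng.normal(size=(15, 3))
        proj = kpca_fit(X)
        g = within_class_adjacency(proj.K_train, np.zeros(15, dtype=int), t=3)
        Sw = wcnp_scatter(proj, g)
        assert np.linalg.eigvalsh(Sw).min() > -1e-8
        g.A = np.zeros_like(g.A)
        Sw0 = wcnp_scatter(proj, g)
        assert np.allclose(Sw0, proj.P.T @ proj.P, atol=1e-8)

    def test_eta_zero_gives_identity(self, rng):
        Sw = np.diag(rng.uniform(1, 5, 4))
        geo = geometry_transform(Sw, eta=0.0, N=10)
        assert np.allclose(geo.S_half, np.eye(4))
        assert np.allclose(geo.S_neg_half, np.eye(4))

    def test_half_powers_round_trip(self, rng):
        A = rng.normal(size=(6, 6))
        Sw = A @ A.T
        geo = geometry_transform(Sw, eta=3.0, N=12)
        assert np.abs(geo.S_half @ geo.S_half - geo.S).max() < 1e-8
        assert np.abs(geo.S_neg_half @ geo.S @ geo.S_neg_half - np.eye(6)).max() < 1e-8

    def test_condition_number_grows_with_eta(self, rng):
        A = rng.normal(size=(5, 5))
        Sw = A @ A.T
        conds = [np.linalg.cond(geometry_transform(Sw, eta, 10).S) for eta in (0.5, 2, 8)]
        assert conds[0] <= conds[1] <= conds[2]


class TestCSVC:
    def test_eta_zero_matches_reference_rbf_svm(self):
        """eta=0 degrades exactly to the Gaussian-kernel C-SVM."""
        X, y = make_moons(200, noise=0.2, random_state=1)
        ypm = np.where(y == 1, 1, -1)
        model = csvc_fit(X, ypm, C=0.5, kernel=KernelSpec(r=2.0), eta=0.0, t=7)
        ref = SVC(kernel="rbf", gamma=2.0, C=0.5).fit(X, ypm)
        Xt, _ = make_moons(150, noise=0.2, random_state=2)
        s, _ = csvc_decision(model, Xt)
        assert (np.sign(s) == ref.predict(Xt)).mean() == 1.0

    def test_dual_constraints(self):
        X, y = make_moons(80, noise=0.15, random_state=0)
        ypm = np.where(y == 1, 1, -1)
        model = csvc_fit(X, ypm, C=0.5, eta=2.0, t=7)
        a = np.abs(model.alpha_y)
        assert a.min() >= -1e-9 and a.max() <= 0.5 + 1e-9
        assert abs(model.alpha_y.sum()) < 1e-6

    def test_route_equivalence(self):
        """Kernel-expansion decision equals transformed-linear decision."""
        X, y = make_moons(100, noise=0.2, random_state=3)
        ypm = np.where(y == 1, 1, -1)
        model = csvc_fit(X, ypm, C=0.5, eta=2.0, t=7)
        s_lin, _ = csvc_decision(model, X)
        s_ker = model.decision_kernel_route(X)
        assert np.abs(s_lin - s_ker).max() < 1e-8

    def test_separable_margin_kkt(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
        ypm = np.array([-1] * 30 + [1] * 30)
        model = csvc_fit(X, ypm, C=5.0, kernel=KernelSpec(r=0.5), eta=2.0, t=7)
        s, _ = csvc_decision(model, X)
        assert (np.sign(s) == ypm).all()
        non_support = np.setdiff1d(np.arange(60), model.support)
        assert (ypm[non_support] * s[non_support] >= 1 - 1e-6).all()

    def test_probability_range_and_continuity(self, rng):
        X, y = make_moons(60, noise=0.15, random_state=4)
        ypm = np.where(y == 1, 1, -1)
        model = csvc_fit(X, ypm, C=0.5, eta=2.0, t=7)
        s1, p1 = csvc_decision(model, X[:5])
        s2, p2 = csvc_decision(model, X[:5] + 1e-6)
        assert ((p1 >= 0) & (p1 <= 1)).all()
        assert np.abs(s1 - s2).max() < 1e-3

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError):
            csvc_fit(X, np.ones(20), C=0.5)


class TestMSVR:
    def _fixture(self, rng, n=60):
        X = rng.normal(0, 1, (n, 5))
        B = rng.normal(0, 0.5, (5, 4))
        Z = X @ B
        return X, Z

    def test_eta_zero_matches_reference_standard_msvr(self, rng):
        """eta=0 degrades to the standard MSVR on the same Gaussian kernel."""
        X, Z = self._fixture(rng)
        Z = Z + rng.normal(0, 0.05, Z.shape)
        C, eps, r = 5.0, 0.2, 0.5
        model = msvr_fit(X, Z, C=C, epsilon=eps, kernel=KernelSpec(r=r), eta=0.0,
                         t=7, max_iter=1000, tol=1e-14)
        K = gram(X, X, KernelSpec(r=r))
        beta_ref, b_ref = reference_msvr(K, Z, C, eps, max_iter=1000)
        pred_ref = K @ beta_ref + b_ref
        pred = msvr_predict(model, X)
        assert np.abs(pred - pred_ref).max() < 1e-4

    def test_constructive_recovery(self, rng):
        """Targets achievable within the tube are recovered for >=95% of
        training samples."""
        X, Z = self._fixture(rng, n=80)
        Z = Z + rng.normal(0, 0.01, Z.shape)
        model = msvr_fit(X, Z, C=100.0, epsilon=0.1, kernel=KernelSpec(r=0.5),
                         eta=2.0, t=7)
        pred = msvr_predict(model, X)
        u = np.sqrt(((Z - pred) ** 2).sum(1))
        assert (u <= 0.1 + 1e-6).mean() >= 0.95

    def test_dead_zone_returns_mean_correction(self, rng):
        X, Z = self._fixture(rng)
        model = msvr_fit(X, Z, C=1.0, epsilon=1e3)
        assert np.abs(model.Wmat).max() == 0.0
        assert np.allclose(model.bias, Z.mean(axis=0))
        assert np.allclose(msvr_predict(model, X[:3]), Z.mean(axis=0))

    def test_objective_monotone(self, rng):
        X, Z = self._fixture(rng)
        Z = Z + rng.normal(0, 0.1, Z.shape)
        model = msvr_fit(X, Z, C=5.0, epsilon=0.2, kernel=KernelSpec(r=0.5))
        tr = model.objective_trace
        assert all(a >= b - 1e-9 for a, b in zip(tr, tr[1:]))

    def test_route_equivalence(self, rng):
        X, Z = self._fixture(rng)
        Z = Z + rng.normal(0, 0.05, Z.shape)
        model = msvr_fit(X, Z, C=5.0, epsilon=0.2, kernel=KernelSpec(r=0.5), eta=2.0)
        pred = msvr_predict(model, X)
        pred_k = model.predict_kernel_route(X)
        assert np.abs(pred - pred_k).max() < 1e-8

    def test_input_validation(self, rng):
        X = rng.normal(size=(4, 3))
        with pytest.raises(ValueError):
            msvr_fit(X, np.ones((4, 4)))
        X = rng.normal(size=(10, 3))
        Z = np.ones((10, 4))
        Z[0, 0] = np.inf
        with pytest.raises(ValueError):
            msvr_fit(X, Z)
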