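"""Within-class neighborhood preserved (WCNP) kernel classifier/regressor.

The idea: before fitting a max-margin classifier, re-shape the kernel
feature space so that directions along which same-class neighbors spread are
shrunk. Concretely:

1. Kernel PCA on the centered Gaussian Gram matrix gives every sample an
   exact finite-dimensional coordinate vector (no information loss when all
   positive-eigenvalue components are kept).
2. A within-class t-nearest-neighbor graph with locally scaled weights
   A_ij = exp(-d_ij^2 / (sigma_i sigma_j)) (sigma_i = distance to the t-th
   within-class neighbor), row-normalized and symmetrized, defines the
   within-class neighborhood preserving scatter
   S_w = P^T (I-A)^T (I-A) P over the KPCA coordinates P.
3. The geometry transform S = I + eta/(2N) S_w whitens that scatter:
   training samples become x_bar = S^(-1/2) P_i, and a standard linear
   soft-margin C-SVM (or the multi-output epsilon-SVR below) is fitted in
   the transformed space. eta = 0 recovers the plain Gaussian-kernel C-SVM.

The MIMO epsilon-SVR couples all four box-regression outputs through an
epsilon-insensitive loss on the joint residual norm, solved by iteratively
reweighted least squares (IRWLS) with step halving.

Decision values can be evaluated by two algebraically equivalent routes —
the transformed-linear form <w_bar, x_bar> + b and the kernel expansion
sum_i alpha_i y_i k_c(x_i)^T W S^{-1} W^T k_c(x) + b — which the test suite
uses to validate the S-matrix algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn import svm

__all__ = [
    "KernelSpec",
    "gram",
    "center_gram",
    "KPCAProjection",
    "kpca_fit",
    "WithinClassGraph",
    "within_class_adjacency",
    "wcnp_scatter",
    "GeometryTransform",
    "geometry_transform",
    "WCNPClassifier",
    "csvc_fit",
    "csvc_decision",
    "WCNPRegressor",
    "msvr_fit",
    "msvr_predict",
]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel exp(-r ||u - v||^2); r > 0."""

    r: float = 2.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("kernel width r must be positive")


def gram(Xa: np.ndarray, Xb: np.ndarray, kernel: KernelSpec = KernelSpec()) -> np.ndarray:
    """Gaussian Gram matrix K_ij = exp(-r ||a_i - b_j||^2)."""
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("feature dimensions differ")
    d2 = cdist(Xa, Xb, metric="sqeuclidean")
    return np.exp(-kernel.r * d2)


def center_gram(K: np.ndarray) -> np.ndarray:
    """Double-center a square Gram matrix: H K H with H = I - 11^T/N.

    Output rows and columns sum to zero; centering is idempotent.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    row = K.mean(axis=0, keepdims=True)
    col = K.mean(axis=1, keepdims=True)
    return K - row - col + K.mean()


@dataclass
class KPCAProjection:
    """Kernel-PCA coordinates of a training set.

    ``W`` has columns mu_i scaled so each feature-space component has unit
    norm; components with eigenvalue <= floor * max are dropped.
    ``P = K_centered @ W`` are the training coordinates; the pairwise inner
    products of P reproduce the centered Gram exactly when no component is
    dropped.
    """

    X_train: np.ndarray
    kernel: KernelSpec
    W: np.ndarray  # (N, m)
    eigvals: np.ndarray  # (m,), descending
    K_train: np.ndarray  # uncentered (N, N)
    row_means: np.ndarray  # per-column means of K_train (N,)
    all_mean: float
    P: np.ndarray = field(init=False)  # training coordinates (N, m)

    def __post_init__(self) -> None:
        self.P = center_gram(self.K_train) @ self.W

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new samples: consistently centered kernel rows times W."""
        k = gram(np.atleast_2d(X), self.X_train, self.kernel)  # (n, N)
        kc = k - k.mean(axis=1, keepdims=True) - self.row_means[None, :] + self.all_mean
        return kc @ self.W

    def centered_kernel_rows(self, X: np.ndarray) -> np.ndarray:
        k = gram(np.atleast_2d(X), self.X_train, self.kernel)
        return k - k.mean(axis=1, keepdims=True) - self.row_means[None, :] + self.all_mean


def kpca_fit(
    X: np.ndarray,
    kernel: KernelSpec = KernelSpec(),
    eig_floor: float = 1e-10,
) -> KPCAProjection:
    """Eigendecompose the centered Gram and keep positive components.

    Eigenvector coefficients are scaled by 1/sqrt(eigenvalue) so retained
    components are orthonormal in feature space.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = gram(X, X, kernel)
    Kc = center_gram(K)
    w, V = np.linalg.eigh(Kc)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > eig_floor * max(w.max(), 0.0)
    if not keep.any():
        raise ValueError("all eigenvalues at or below the floor — degenerate kernel matrix")
    w, V = w[keep], V[:, keep]
    W = V / np.sqrt(w)[None, :]
    return KPCAProjection(
        X_train=X,
        kernel=kernel,
        W=W,
        eigvals=w,
        K_train=K,
        row_means=K.mean(axis=0),
        all_mean=float(K.mean()),
    )


@dataclass
class WithinClassGraph:
    """Row-normalized, symmetrized within-class t-NN affinity matrix."""

    A: np.ndarray  # (N, N) symmetric, zero across classes
    t: int
    labels: np.ndarray


def within_class_adjacency(
    K: np.ndarray,
    labels: np.ndarray | None,
    t: int = 7,
) -> WithinClassGraph:
    """Locally-scaled within-class t-NN affinities in kernel space.

    Kernel-space squared distances d^2_ij = K_ii + K_jj - 2 K_ij. For pairs
    (i, j) of the same class where one is among the other's t nearest
    within-class neighbors, the raw weight is
    exp(-d^2_ij / (sigma_i sigma_j)) with sigma_i the distance (not squared)
    to the i-th sample's t-th within-class neighbor. Rows are normalized by
    their sums and the result symmetrized as (A + A^T)/2.

    ``labels=None`` treats all samples as a single class (the regressor's
    setting, where every training sample is a positive).
    """
    K = np.asarray(K, dtype=float)
    N = K.shape[0]
    labels = np.zeros(N, dtype=int) if labels is None else np.asarray(labels)
    diag = np.diag(K)
    d2 = np.maximum(diag[:, None] + diag[None, :] - 2 * K, 0.0)

    A = np.zeros((N, N))
    sigma = np.zeros(N)
    neighbor_sets: list[np.ndarray] = [np.empty(0, dtype=int)] * N
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        if t >= idx.size:
            raise ValueError(f"t={t} must be smaller than class size {idx.size}")
        sub = d2[np.ix_(idx, idx)]
        order = np.argsort(sub, axis=1, kind="stable")
        for a, i in enumerate(idx):
            nbr = idx[order[a, 1 : t + 1]]  # skip self (distance 0 first)
            neighbor_sets[i] = nbr
            sigma[i] = np.sqrt(sub[a, order[a, t]])

    sigma = np.maximum(sigma, 1e-12)
    for i in range(N):
        for j in neighbor_sets[i]:
            w = np.exp(-d2[i, j] / (sigma[i] * sigma[j]))
            A[i, j] = w
            A[j, i] = max(A[j, i], w)  # mutual-neighbor condition (either side)

    row_sums = A.sum(axis=1, keepdims=True)
    nz = row_sums[:, 0] > 0
    A[nz] = A[nz] / row_sums[nz]
    A = 0.5 * (A + A.T)
    return WithinClassGraph(A=A, t=t, labels=labels)


def wcnp_scatter(proj: KPCAProjection, graph: WithinClassGraph) -> np.ndarray:
    """Within-class neighborhood preserving scatter over KPCA coordinates:

    S_w = P^T (I - A)^T (I - A) P, symmetric positive semidefinite (m x m).
    """
    P = proj.P
    IA = np.eye(P.shape[0]) - graph.A
    M = IA @ P
    Sw = M.T @ M
    return 0.5 * (Sw + Sw.T)


@dataclass
class GeometryTransform:
    """S = I + eta/(2N) S_w and its symmetric powers."""

    S: np.ndarray
    S_half: np.ndarray
    S_neg_half: np.ndarray
    S_inv: np.ndarray
    eta: float


def geometry_transform(Sw: np.ndarray, eta: float, N: int) -> GeometryTransform:
    """Form S = I + eta/(2N) S_w and compute S^{1/2}, S^{-1/2}, S^{-1}
    through the symmetric eigendecomposition (S is SPD by construction)."""
    if eta < 0:
        raise ValueError("eta must be non-negative")
    m = Sw.shape[0]
    S = np.eye(m) + (eta / (2.0 * N)) * Sw
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, 1e-15)
    S_half = (V * np.sqrt(w)) @ V.T
    S_neg_half = (V / np.sqrt(w)) @ V.T
    S_inv = (V / w) @ V.T
    return GeometryTransform(S=S, S_half=S_half, S_neg_half=S_neg_half, S_inv=S_inv, eta=eta)


def _wcnp_embed(
    X: np.ndarray,
    labels: np.ndarray | None,
    kernel: KernelSpec,
    eta: float,
    t: int,
) -> tuple[KPCAProjection, GeometryTransform, np.ndarray]:
    """Shared front end: KPCA + graph + geometry transform + embedded
    training coordinates X_bar = P S^{-1/2}."""
    proj = kpca_fit(X, kernel)
    graph = within_class_adjacency(proj.K_train, labels, t)
    Sw = wcnp_scatter(proj, graph)
    geo = geometry_transform(Sw, eta, X.shape[0])
    Xbar = proj.P @ geo.S_neg_half
    return proj, geo, Xbar


@dataclass
class WCNPClassifier:
    """Fitted WCNP C-SVC: embedded geometry + linear SVM solution."""

    proj: KPCAProjection
    geo: GeometryTransform
    Xbar: np.ndarray
    alpha_y: np.ndarray  # alpha_i^* y_i on support vectors, embedded order
    support: np.ndarray  # indices of support vectors
    intercept: float
    C: float
    platt_ab: tuple[float, float]  # probability map sigmoid(a*score + b)
    w_bar: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.w_bar = self.alpha_y @ self.Xbar[self.support]

    def decision_kernel_route(self, X: np.ndarray) -> np.ndarray:
        """Kernel-expansion decision: sum_i alpha_i y_i k_c(x_i)^T W S^{-1}
        W^T k_c(x) + b — the representer form of the same hyperplane."""
        kc = self.proj.centered_kernel_rows(X)  # (n, N)
        right = self.geo.S_inv @ (self.proj.W.T @ kc.T)  # (m, n)
        left = self.proj.P[self.support]  # (n_sv, m)
        return self.alpha_y @ (left @ right) + self.intercept


def _platt_fit(scores: np.ndarray, y01: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood sigmoid calibration p = 1/(1+exp(a*s+b))
    parameterized here as sigmoid(a*s + b) for the positive class."""
    from scipy.optimize import minimize

    s = np.asarray(scores, dtype=float)
    yy = np.asarray(y01, dtype=float)

    def nll(ab):
        z = ab[0] * s + ab[1]
        # log(1+exp(-z)) stable
        return np.sum(np.logaddexp(0.0, -z) * yy + np.logaddexp(0.0, z) * (1 - yy))

    res = minimize(nll, x0=np.array([1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    return float(res.x[0]), float(res.x[1])


def csvc_fit(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 0.5,
    kernel: KernelSpec = KernelSpec(r=2.0),
    eta: float = 2.0,
    t: int = 7,
) -> WCNPClassifier:
    """Fit the WCNP C-SVC.

    Embeds samples as x_bar = S^{-1/2} W^T k_c(x), then solves the standard
    soft-margin linear C-SVM in the embedded space (the kernel nonlinearity
    already lives in the KPCA map). With eta = 0 this is exactly a
    Gaussian-kernel C-SVM. A Platt sigmoid fitted on the training decision
    values supplies class probabilities for downstream ranking.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("csvc_fit requires exactly two classes")
    ypm = np.where(y == classes.max(), 1, -1)

    proj, geo, Xbar = _wcnp_embed(X, ypm, kernel, eta, t)
    clf = svm.SVC(kernel="linear", C=C)
    clf.fit(Xbar, ypm)
    alpha_y = clf.dual_coef_[0].copy()
    support = clf.support_.copy()
    intercept = float(clf.intercept_[0])

    model = WCNPClassifier(
        proj=proj, geo=geo, Xbar=Xbar, alpha_y=alpha_y, support=support,
        intercept=intercept, C=C, platt_ab=(1.0, 0.0),
    )
    train_scores = Xbar @ model.w_bar + intercept
    model.platt_ab = _platt_fit(train_scores, (ypm > 0).astype(float))
    return model


def csvc_decision(model: WCNPClassifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed decision values and calibrated positive-class probabilities.

    Evaluated in the transformed-linear form <w_bar, x_bar> + b; the
    kernel-expansion route is available as
    :meth:`WCNPClassifier.decision_kernel_route`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    from scipy.special import expit

    xbar = model.proj.transform(X) @ model.geo.S_neg_half
    scores = xbar @ model.w_bar + model.intercept
    a, b = model.platt_ab
    return scores, expit(a * scores + b)


@dataclass
class WCNPRegressor:
    """Fitted MIMO epsilon-SVR in the WCNP-embedded space."""

    proj: KPCAProjection
    geo: GeometryTransform
    Xbar: np.ndarray
    Wmat: np.ndarray  # (m, 4) primal weights in embedded space
    bias: np.ndarray  # (4,)
    beta: np.ndarray  # (N, 4) representer coefficients a_i * e_i
    epsilon: float
    C: float
    objective_trace: list[float] = field(default_factory=list)

    def predict_kernel_route(self, X: np.ndarray) -> np.ndarray:
        """Representer-form prediction sum_i beta_ij <x_bar_i, x_bar> + b_j."""
        kc = self.proj.centered_kernel_rows(X)
        emb = (kc @ self.proj.W) @ self.geo.S_neg_half  # (n, m)
        return (emb @ self.Xbar.T) @ self.beta + self.bias


def _msvr_objective(Wmat, bias, Xbar, Z, C, eps):
    E = Z - Xbar @ Wmat - bias
    u = np.sqrt(np.sum(E**2, axis=1))
    loss = np.where(u > eps, (u - eps) ** 2, 0.0)
    return 0.5 * np.sum(Wmat**2) + C * np.sum(loss)


def msvr_fit(
    X: np.ndarray,
    Z: np.ndarray,
    C: float = 0.5,
    epsilon: float = 1.5,
    kernel: KernelSpec = KernelSpec(r=2.0),
    eta: float = 2.0,
    t: int = 7,
    labels: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> WCNPRegressor:
    """Fit the MIMO epsilon-SVR by IRWLS in the embedded space.

    The epsilon-insensitive loss acts on the joint residual norm
    u_i = ||z_i - W^T x_bar_i - b||: samples inside the epsilon tube carry
    zero weight, others the quasi-Newton weight a_i = 2C (u_i - eps)/u_i.
    Each sweep solves the weighted regularized least-squares problem on the
    active set and applies step halving whenever the full step would
    increase the true objective; iteration stops when the relative objective
    change falls below ``tol``. With no labels the neighborhood graph treats
    all samples as one class.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[0] != Z.shape[0]:
        raise ValueError("X and Z row counts differ")
    if X.shape[0] < 5:
        raise ValueError("need at least 5 samples")
    if not np.all(np.isfinite(Z)):
        raise ValueError("targets must be finite")
    N, q = Z.shape

    proj, geo, Xbar = _wcnp_embed(X, labels, kernel, eta, t)
    m = Xbar.shape[1]
    Wmat = np.zeros((m, q))
    # bias starts at the target means: the dead-zone solution is then the
    # mean correction rather than the zero vector
    bias = Z.mean(axis=0)
    obj = _msvr_objective(Wmat, bias, Xbar, Z, C, epsilon)
    trace = [obj]

    for it in range(max_iter):
        E = Z - Xbar @ Wmat - bias
        u = np.sqrt(np.sum(E**2, axis=1))
        active = u > epsilon
        if not active.any():
            break
        a = np.zeros(N)
        a[active] = 2.0 * C * (u[active] - epsilon) / u[active]

        Xs = Xbar[active]
        Zs = Z[active]
        asel = a[active]
        XtA = Xs.T * asel
        lhs = np.zeros((m + 1, m + 1))
        lhs[:m, :m] = XtA @ Xs + np.eye(m)
        lhs[:m, m] = XtA.sum(axis=1)
        lhs[m, :m] = lhs[:m, m]
        lhs[m, m] = asel.sum()
        rhs = np.vstack([XtA @ Zs, asel @ Zs])
        sol = np.linalg.solve(lhs, rhs)
        W_new, b_new = sol[:m], sol[m]

        # step halving toward the IRWLS solution
        step = 1.0
        improved = False
        for _ in range(25):
            W_try = Wmat + step * (W_new - Wmat)
            b_try = bias + step * (b_new - bias)
            obj_try = _msvr_objective(W_try, b_try, Xbar, Z, C, epsilon)
            if obj_try <= obj:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        rel = (obj - obj_try) / max(obj, 1e-30)
        Wmat, bias, obj = W_try, b_try, obj_try
        trace.append(obj)
        if rel < tol:
            break
    else:
        raise RuntimeError(
            f"MSVR did not converge in {max_iter} iterations; objective trace tail "
            f"{trace[-3:]}"
        )

    # exact representer conversion W = Xbar^T beta (minimum-norm solution);
    # at the IRWLS fixed point this coincides with the KKT form a_i * e_i
    beta = np.linalg.lstsq(Xbar.T, Wmat, rcond=None)[0]
    return WCNPRegressor(
        proj=proj, geo=geo, Xbar=Xbar, Wmat=Wmat, bias=bias, beta=beta,
        epsilon=epsilon, C=C, objective_trace=trace,
    )


def msvr_predict(model: WCNPRegressor, X: np.ndarray) -> np.ndarray:
    """Predict the 4-vector targets for new samples (transformed-linear
    route; see :meth:`WCNPRegressor.predict_kernel_route` for the kernel
    form)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    emb = model.proj.transform(X) @ model.geo.S_neg_half
    out = emb @ model.Wmat + model.bias
    return out[0] if out.shape[0] == 1 else out
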