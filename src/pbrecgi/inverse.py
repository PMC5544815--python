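"""Per-instant inverse solvers: Tikhonov baseline and sparse basis
reconstruction.

Tikhonov regularization solves, at each time instant,

    min_x ||A x - b||^2 + lambda ||R x||^2

with R the identity (order 0), a length-scaled edge-difference operator
(order 1) or the umbrella graph Laplacian (order 2); lambda multiplies the
squared seminorm. The weight is selected per instant by the L-curve corner.

The physiology-based solver expresses the solution in a truncated spatial
basis U_k and imposes an L1 budget on the coefficients,

    min_beta ||A U_k beta - b||^2   s.t.  ||beta||_1 <= lambda,

solved exactly along the LARS/lasso homotopy path (the path is piecewise
linear in the coefficients, so the budget-constrained solution is an exact
interpolation between path knots). The budget is chosen per instant by
cross-validation over electrodes, minimizing held-out mean squared error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.linear_model import lars_path
from sklearn.model_selection import KFold

from .basis import SpatialBasis
from .mesh import TriSurfaceMesh
from .transfer import BodyPotentials, TransferMatrix


class SingularityError(np.linalg.LinAlgError):
    pass


# ---------------------------------------------------------------------------
# Regularization operators
# ---------------------------------------------------------------------------

@dataclass
class RegularizationOperator:
    """Matrix R of the Tikhonov seminorm ||R x||; orders 1 and 2 annihilate
    spatially constant potentials."""

    R: np.ndarray | sparse.spmatrix
    order: int

    def as_dense(self) -> np.ndarray:
        return self.R.toarray() if sparse.issparse(self.R) else np.asarray(self.R)


def build_regularization_operator(mesh: TriSurfaceMesh | int,
                                  order: int = 0) -> RegularizationOperator:
    """Order 0: identity. Order 1: per-edge differences scaled by 1/length.
    Order 2: umbrella (graph) Laplacian. A mesh is only required for orders
    1 and 2; order 0 accepts a plain node count."""
    if order == 0:
        n = mesh if isinstance(mesh, int) else mesh.n_vertices
        return RegularizationOperator(sparse.eye(n, format="csr"), 0)
    if isinstance(mesh, int):
        raise ValueError("orders 1 and 2 need a mesh")
    n = mesh.n_vertices
    if order == 1:
        e = mesh.edges()
        w = 1.0 / mesh.edge_lengths()
        rows = np.repeat(np.arange(len(e)), 2)
        cols = e.ravel()
        vals = np.column_stack([w, -w]).ravel()
        R = sparse.csr_matrix((vals, (rows, cols)), shape=(len(e), n))
    elif order == 2:
        adj = mesh.adjacency()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        R = (sparse.diags(deg) - adj).tocsr()
        from scipy.sparse.csgraph import connected_components
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp > 1:
            warnings.warn(f"mesh has {n_comp} connected components",
                          stacklevel=2)
    else:
        raise ValueError("order must be 0, 1 or 2")
    return RegularizationOperator(R, order)


# ---------------------------------------------------------------------------
# Tikhonov
# ---------------------------------------------------------------------------

@dataclass
class TikhonovSolution:
    """Reconstructed potentials with the per-instant weight and diagnostics."""

    phi_H_hat: np.ndarray  # (n_nodes, n_t), mV
    lambda_t: np.ndarray  # (n_t,)
    residual_t: np.ndarray  # ||A x - b|| per instant
    seminorm_t: np.ndarray  # ||R x|| per instant
    method: str = "tikhonov"


@dataclass
class PBRSolution:
    """Sparse-basis reconstruction: phi_H_hat = U_k @ beta_t."""

    beta_t: np.ndarray  # (k, n_t)
    phi_H_hat: np.ndarray  # (n_nodes, n_t), mV
    lambda_t: np.ndarray  # L1 budget per instant
    nonzero_t: np.ndarray  # active coefficients per instant
    method: str = "pbr"


def _as_matrix(A) -> np.ndarray:
    return A.A if isinstance(A, TransferMatrix) else np.asarray(A, float)


def tikhonov_solve(A, phi_B_t: np.ndarray, R: RegularizationOperator,
                   lam: float) -> np.ndarray:
    """Unique minimizer (A^T A + lam R^T R)^{-1} A^T b of the Tikhonov
    functional (lam multiplies the squared seminorm)."""
    A = _as_matrix(A)
    b = np.asarray(phi_B_t, float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    Rd = R.as_dense()
    M = A.T @ A + lam * (Rd.T @ Rd)
    try:
        # solve via Cholesky; fails on the semidefinite rank-deficient case
        c, low = _cho_factor(M)
        d = np.abs(np.diag(c))
        if d.min() == 0 or (d.min() / d.max()) ** 2 < 1e-12:
            raise np.linalg.LinAlgError("effectively singular")
        x = _cho_solve((c, low), A.T @ b)
        if not np.all(np.isfinite(x)):
            raise np.linalg.LinAlgError("non-finite solution")
        return x
    except np.linalg.LinAlgError as exc:
        raise SingularityError(
            "normal equations singular (rank-deficient A with lam=0?)"
        ) from exc


def _cho_factor(M):
    from scipy.linalg import cho_factor
    try:
        return cho_factor(M)
    except Exception as exc:
        raise np.linalg.LinAlgError(str(exc)) from exc


def _cho_solve(cf, y):
    from scipy.linalg import cho_solve
    return cho_solve(cf, y)


def default_lambda_grid(A, n: int = 40) -> np.ndarray:
    """40 log-spaced weights spanning [1e-8, 1e2] * sigma_1(A)^2, covering
    the under- to over-regularized regimes."""
    A = _as_matrix(A)
    s1 = np.linalg.norm(A, 2)
    return np.logspace(-8, 2, n) * s1 ** 2


def lcurve_select_lambda(A, phi_B_t: np.ndarray, R: RegularizationOperator,
                         lambda_grid: np.ndarray | None = None) -> float:
    """Weight at the corner (maximum curvature) of the L-curve
    (log residual norm vs log solution seminorm) over a grid."""
    A = _as_matrix(A)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(A)
    grid = np.sort(np.asarray(lambda_grid, float))
    if len(grid) < 10 or np.any(grid <= 0):
        raise ValueError("need a grid of >= 10 positive weights")
    b = np.asarray(phi_B_t, float)
    if R.order == 0:
        # filter-factor evaluation, identical to the whole-series fast path
        rho, eta = _order0_lcurve_norms(A, b[:, None], grid)
        rho, eta = rho[:, 0], eta[:, 0]
    else:
        rho = np.empty(len(grid))
        eta = np.empty(len(grid))
        Rd = R.as_dense()
        AtA, Atb, RtR = A.T @ A, A.T @ b, Rd.T @ Rd
        for i, lam in enumerate(grid):
            x = np.linalg.solve(AtA + lam * RtR, Atb)
            rho[i] = np.linalg.norm(A @ x - b)
            eta[i] = np.linalg.norm(Rd @ x)
    if np.allclose(rho, rho[0]) and np.allclose(eta, eta[0]):
        warnings.warn("flat L-curve; falling back to smallest weight",
                      stacklevel=2)
        return float(grid[0])
    idx = _lcurve_corner_indices(np.log(np.maximum(rho, 1e-300))[:, None],
                                 np.log(np.maximum(eta, 1e-300))[:, None])
    return float(grid[int(idx[0])])


#: a log-log L-curve corner is scale-free; curvature of order one marks a
#: distinct corner, featureless (noise-only or consistent) curves stay far
#: below this
_CORNER_CURVATURE_MIN = 0.2


def _lcurve_corner_indices(lx: np.ndarray, ly: np.ndarray) -> np.ndarray:
    """Grid index of the L-curve corner for each column of (log rho, log
    eta): the maximum-curvature point when a distinct corner exists, else
    the minimum-product (Reginska) point, which degrades gracefully to heavy
    regularization on noise-only data and to light regularization on
    consistent data."""
    dx, dy = np.gradient(lx, axis=0), np.gradient(ly, axis=0)
    ddx, ddy = np.gradient(dx, axis=0), np.gradient(dy, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dx * ddy - dy * ddx) / (dx ** 2 + dy ** 2) ** 1.5
    kappa = np.where(np.isfinite(kappa), kappa, 0.0)
    best = np.argmax(kappa, axis=0)
    weak = kappa.max(axis=0) <= _CORNER_CURVATURE_MIN
    if np.any(weak):
        product = np.argmin(lx + ly, axis=0)
        best = np.where(weak, product, best)
    return best


# ---------------------------------------------------------------------------
# Sparse basis reconstruction (budget-form lasso)
# ---------------------------------------------------------------------------

def _lasso_budget_path(X: np.ndarray, y: np.ndarray):
    """LARS/lasso path as (l1_norms, coefs) with coefs of shape (k, n_knots);
    the L1 norm is non-decreasing along the path."""
    _, _, coefs = lars_path(X, y, method="lasso")
    l1 = np.abs(coefs).sum(axis=0)
    return l1, coefs


def _coef_at_budget(l1: np.ndarray, coefs: np.ndarray,
                    budget: float) -> np.ndarray:
    """Exact budget-constrained solution by linear interpolation between
    path knots (signs are constant within a knot interval, so the L1 norm is
    linear there)."""
    if budget <= 0:
        return np.zeros(coefs.shape[0])
    if budget >= l1[-1]:
        return coefs[:, -1].copy()
    j = int(np.searchsorted(l1, budget))
    if l1[j] == l1[j - 1]:
        return coefs[:, j].copy()
    t = (budget - l1[j - 1]) / (l1[j] - l1[j - 1])
    return (1 - t) * coefs[:, j - 1] + t * coefs[:, j]


def project_l1_ball(v: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection onto the L1 ball of the given radius
    (soft-threshold with the water-filling threshold of Duchi et al.)."""
    if radius <= 0:
        return np.zeros_like(v)
    a = np.abs(v)
    if a.sum() <= radius:
        return v.copy()
    u = np.sort(a)[::-1]
    cum = np.cumsum(u)
    rho = np.max(np.flatnonzero(u > (cum - radius) / np.arange(1, len(u) + 1)))
    theta = (cum[rho] - radius) / (rho + 1.0)
    return np.sign(v) * np.maximum(a - theta, 0.0)


def _fista_polish(X: np.ndarray, y: np.ndarray, beta0: np.ndarray,
                  lam: float, tol: float = 1e-12,
                  max_iter: int = 5000) -> np.ndarray:
    """Accelerated projected gradient on ||X b - y||^2 over the L1 ball.

    Warm-started from the homotopy-path solution this converges in a handful
    of iterations; it also resolves degenerate inputs (exactly collinear or
    tied columns) where the one-at-a-time LARS path is ambiguous.
    """
    L = 2.0 * np.linalg.norm(X, 2) ** 2
    if L == 0:
        return beta0
    step = 1.0 / L
    b = project_l1_ball(beta0, lam)
    z, t = b.copy(), 1.0
    f_prev = np.inf
    for _ in range(max_iter):
        g = 2.0 * (X.T @ (X @ z - y))
        b_new = project_l1_ball(z - step * g, lam)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = b_new + (t - 1.0) / t_new * (b_new - b)
        b, t = b_new, t_new
        r = X @ b - y
        f = r @ r
        if abs(f_prev - f) <= tol * max(f, 1.0):
            break
        f_prev = f
    return b


def pbr_solve(A, U_k: SpatialBasis | np.ndarray, phi_B_t: np.ndarray,
              lam: float) -> np.ndarray:
    """Coefficients beta minimizing ||A U_k beta - b||^2 subject to
    ||beta||_1 <= lam (smaller lam = stronger regularization).

    Solved along the LARS/lasso homotopy path and polished by a projected
    accelerated gradient pass, which guarantees the constrained optimum even
    for degenerate (tied-column) designs."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    A = _as_matrix(A)
    U = U_k.U_k if isinstance(U_k, SpatialBasis) else np.asarray(U_k, float)
    X = A @ U
    y = np.asarray(phi_B_t, float)
    if lam == 0:
        return np.zeros(U.shape[1])
    l1, coefs = _lasso_budget_path(X, y)
    beta = _coef_at_budget(l1, coefs, lam)
    return _fista_polish(X, y, beta, lam)


def select_lasso_lambda(A, U_k: SpatialBasis | np.ndarray,
                        phi_B_t: np.ndarray, folds: int = 5, seed: int = 0,
                        grid_size: int = 30) -> float:
    """L1 budget minimizing K-fold cross-validated mean squared error across
    electrodes (rows of A U_k), on a log grid up to the least-squares L1
    norm. Ties go to the smallest budget. Deterministic per seed."""
    A = _as_matrix(A)
    U = U_k.U_k if isinstance(U_k, SpatialBasis) else np.asarray(U_k, float)
    X = A @ U
    y = np.asarray(phi_B_t, float)
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError("more folds than electrodes")
    l1_full, _ = _lasso_budget_path(X, y)
    l1_max = l1_full[-1]
    if l1_max == 0:
        return 0.0
    budgets = np.concatenate([[0.0],
                              np.geomspace(1e-3, 1.0, grid_size) * l1_max])
    mse = np.zeros(len(budgets))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(X):
        l1, coefs = _lasso_budget_path(X[tr], y[tr])
        for i, budget in enumerate(budgets):
            beta = _coef_at_budget(l1, coefs, budget)
            r = X[te] @ beta - y[te]
            mse[i] += r @ r / len(te)
    mse /= folds
    # smallest budget within numerical tolerance of the minimum
    best = np.min(mse)
    tol = 1e-9 * max(best, 1e-30) + 1e-30
    return float(budgets[int(np.argmax(mse <= best + tol))])


# ---------------------------------------------------------------------------
# Whole-series reconstruction
# ---------------------------------------------------------------------------

def rereference(phi_B: np.ndarray) -> np.ndarray:
    """Remove the spatial mean across electrodes per instant (the constant
    is unobservable: A maps constants to constants, and electrograms are
    zero-referenced)."""
    return phi_B - phi_B.mean(axis=0, keepdims=True)


def reconstruct_series(A, basis_or_R, phi_B: BodyPotentials | np.ndarray,
                       method: str = "tikhonov", *,
                       rereference_body: bool = True,
                       lambda_grid: np.ndarray | None = None,
                       lam: float | None = None,
                       cv_folds: int = 5, seed: int = 0):
    """Solve the inverse problem independently at every time instant.

    method='tikhonov': ``basis_or_R`` is a RegularizationOperator; the
    weight is chosen per instant by the L-curve unless ``lam`` is given.
    method='pbr': ``basis_or_R`` is a SpatialBasis; the L1 budget is chosen
    per instant by electrode cross-validation unless ``lam`` is given.
    """
    Amat = _as_matrix(A)
    B = phi_B.phi_B if isinstance(phi_B, BodyPotentials) else np.atleast_2d(
        np.asarray(phi_B, float))
    if rereference_body:
        B = rereference(B)
    n_t = B.shape[1]

    if method == "tikhonov":
        R = basis_or_R
        if not isinstance(R, RegularizationOperator):
            raise TypeError("tikhonov needs a RegularizationOperator")
        grid = (default_lambda_grid(Amat) if lambda_grid is None
                else np.asarray(lambda_grid, float))
        if R.order == 0 and lam is None:
            return _tikhonov_series_svd(Amat, B, np.sort(grid))
        Rd = R.as_dense()
        n_nodes = Amat.shape[1]
        out = np.empty((n_nodes, n_t))
        lams = np.empty(n_t)
        res = np.empty(n_t)
        semi = np.empty(n_t)
        for t in range(n_t):
            b = B[:, t]
            lam_t = lam if lam is not None else lcurve_select_lambda(
                Amat, b, R, grid)
            x = tikhonov_solve(Amat, b, R, lam_t)
            out[:, t] = x
            lams[t] = lam_t
            res[t] = np.linalg.norm(Amat @ x - b)
            semi[t] = np.linalg.norm(Rd @ x)
        return TikhonovSolution(phi_H_hat=out, lambda_t=lams, residual_t=res,
                                seminorm_t=semi)

    if method == "pbr":
        basis = basis_or_R
        if not isinstance(basis, SpatialBasis):
            raise TypeError("pbr needs a SpatialBasis")
        U = basis.U_k
        X = Amat @ U
        k = U.shape[1]
        betas = np.empty((k, n_t))
        lams = np.empty(n_t)
        for t in range(n_t):
            y = B[:, t]
            if lam is not None:
                budget = lam
            else:
                budget = select_lasso_lambda(Amat, basis, y, folds=cv_folds,
                                             seed=seed)
            l1, coefs = _lasso_budget_path(X, y)
            betas[:, t] = _coef_at_budget(l1, coefs, budget)
            lams[t] = budget
        phi = U @ betas
        return PBRSolution(beta_t=betas, phi_H_hat=phi, lambda_t=lams,
                           nonzero_t=(np.abs(betas) > 1e-12).sum(axis=0))

    raise ValueError("method must be 'tikhonov' or 'pbr'")


def _order0_lcurve_norms(A: np.ndarray, B: np.ndarray, grid: np.ndarray):
    """Residual and solution norms of order-0 Tikhonov on a weight grid via
    SVD filter factors: (n_grid, n_t) arrays for a series B."""
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    beta = U.T @ B
    perp2 = np.maximum((B ** 2).sum(axis=0) - (beta ** 2).sum(axis=0), 0.0)
    s2 = s ** 2
    rho = np.empty((len(grid), B.shape[1]))
    eta = np.empty_like(rho)
    for i, lam_i in enumerate(grid):
        f_res = lam_i / (s2 + lam_i)  # residual filter
        f_sol = s / (s2 + lam_i)  # solution filter
        rho[i] = np.sqrt(((f_res[:, None] * beta) ** 2).sum(axis=0) + perp2)
        eta[i] = np.sqrt(((f_sol[:, None] * beta) ** 2).sum(axis=0))
    return rho, eta


def _tikhonov_series_svd(A: np.ndarray, B: np.ndarray,
                         grid: np.ndarray) -> TikhonovSolution:
    """Order-0 Tikhonov over a whole series with per-instant L-curve
    selection, using the SVD of A so that residual and solution norms on the
    weight grid come from filter factors instead of per-weight solves.
    Identical (to rounding) to the per-instant generic path."""
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    beta = U.T @ B  # (r, n_t)
    s2 = s ** 2
    n_t = B.shape[1]
    rho, eta = _order0_lcurve_norms(A, B, grid)
    best = _lcurve_corner_indices(np.log(np.maximum(rho, 1e-300)),
                                  np.log(np.maximum(eta, 1e-300)))
    lams = grid[best]
    out = np.empty((A.shape[1], n_t))
    for t in range(n_t):
        f = s / (s2 + lams[t])
        out[:, t] = Vt.T @ (f * beta[:, t])
    res = rho[best, np.arange(n_t)]
    semi = eta[best, np.arange(n_t)]
    return TikhonovSolution(phi_H_hat=out, lambda_t=lams, residual_t=res,
                            seminorm_t=semi)
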