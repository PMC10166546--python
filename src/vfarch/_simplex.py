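"""Simplex-constrained least-squares primitives.

The two subproblems of the alternating archetype fit — expressing each field
as a convex combination of archetypes, and each archetype as a convex
combination of fields — are least-squares problems with the coefficient rows
constrained to the probability simplex.  They are solved here by accelerated
projected gradient descent (FISTA with a monotone safeguard: the best iterate
seen is kept, and momentum restarts whenever the objective rises), followed by
an exact KKT solve on the identified support.  The projection onto the simplex
is the standard O(k log k) sort-and-threshold algorithm.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def project_rows_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of ``V`` onto the probability simplex."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n, k = V.shape
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = U - css / ind > 0
    # rho = largest index where cond holds (cond[:, 0] is always True)
    rho = k - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(n), rho] / (rho + 1)
    W = np.maximum(V - theta[:, None], 0.0)
    W /= W.sum(axis=1, keepdims=True)
    return W


def condition_guard(
    gram: np.ndarray, max_kappa: float = 1000.0
) -> tuple[np.ndarray, float]:
    """Bound the condition number of a symmetric PSD system matrix.

    If the condition number (ratio of extreme eigenvalues) exceeds
    ``max_kappa``, the smallest diagonal ridge bringing it to exactly
    ``max_kappa`` is added; otherwise the matrix is returned unchanged.
    For a tall design ``A`` pass its Gram matrix ``A.T @ A``.

    Returns ``(adjusted_matrix, ridge)``.
    """
    gram = np.asarray(gram, dtype=float)
    if gram.ndim != 2 or gram.shape[0] != gram.shape[1]:
        raise ValueError("condition_guard expects a square (Gram) matrix")
    if not np.allclose(gram, gram.T, rtol=1e-10, atol=1e-12):
        raise ValueError("condition_guard expects a symmetric matrix")
    if max_kappa <= 1:
        raise ValueError("max_kappa must exceed 1")
    eigvals = scipy.linalg.eigvalsh(gram)
    lmax = float(eigvals[-1])
    lmin = float(max(eigvals[0], 0.0))
    if lmax <= 0.0:  # zero matrix: condition number is undefined; leave as is
        return gram, 0.0
    if lmin > 0.0 and lmax / lmin <= max_kappa:
        return gram, 0.0
    ridge = (lmax - max_kappa * lmin) / (max_kappa - 1.0)
    return gram + ridge * np.eye(gram.shape[0]), ridge


def _fista(grad, obj, W0, lipschitz, max_iter, tol):
    """Monotone FISTA on the product of row simplices."""
    W = project_rows_simplex(W0)
    Y = W.copy()
    t = 1.0
    f_best = obj(W)
    W_best = W.copy()
    step = 1.0 / max(lipschitz, np.finfo(float).tiny)
    for _ in range(max_iter):
        W_new = project_rows_simplex(Y - step * grad(Y))
        f_new = obj(W_new)
        if f_new > f_best:  # momentum overshoot: restart from the best point
            Y = W_best.copy()
            t = 1.0
            W_new = project_rows_simplex(Y - step * grad(Y))
            f_new = obj(W_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Y = W_new + ((t - 1.0) / t_new) * (W_new - W)
        delta = np.abs(W_new - W).max()
        W, t = W_new, t_new
        if f_new < f_best:
            f_best, W_best = f_new, W_new.copy()
        if delta < tol:
            break
    return W_best


def _polish_rows(
    X: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
    max_kappa: float = 1000.0,
    support_eps: float = 1e-9,
) -> tuple[np.ndarray, list[float]]:
    """Exact KKT solve of each row's problem on its active support.

    A row's support is the set of coordinates the projected-gradient solution
    left positive; on that support the equality-constrained least-squares
    problem is solved exactly (Gram system guarded by ``condition_guard``).
    The polished row is accepted only if feasible and at least as good.
    """
    G = Z @ Z.T
    C = X @ Z.T
    W = W.copy()
    ridges: list[float] = []
    for i in range(W.shape[0]):
        w = W[i]
        support = np.flatnonzero(w > support_eps)
        if support.size == 0:
            support = np.array([int(np.argmax(w))])
        if support.size == 1:
            w_new = np.zeros_like(w)
            w_new[support[0]] = 1.0
        else:
            m = support.size
            Gs, ridge = condition_guard(G[np.ix_(support, support)], max_kappa)
            if ridge > 0:
                ridges.append(ridge)
            kkt = np.zeros((m + 1, m + 1))
            kkt[:m, :m] = Gs
            kkt[:m, m] = 1.0
            kkt[m, :m] = 1.0
            rhs = np.concatenate([C[i, support], [1.0]])
            try:
                sol = scipy.linalg.solve(kkt, rhs, assume_a="sym")
            except scipy.linalg.LinAlgError:  # pragma: no cover - degenerate
                continue
            ws = sol[:m]
            if ws.min() < -1e-10:
                continue  # active set was wrong; keep the PG solution
            ws = np.maximum(ws, 0.0)
            ws /= ws.sum()
            w_new = np.zeros_like(w)
            w_new[support] = ws
        old = X[i] - w @ Z
        new = X[i] - w_new @ Z
        if new @ new <= old @ old + 1e-15:
            W[i] = w_new
    return W, ridges


def simplex_coefficients(
    X: np.ndarray,
    Z: np.ndarray,
    W0: np.ndarray | None = None,
    max_iter: int = 400,
    tol: float = 1e-12,
    polish: bool = True,
    max_kappa: float = 1000.0,
) -> tuple[np.ndarray, list[float]]:
    """Solve ``min ||X - W Z||_F^2`` with every row of ``W`` on the simplex.

    Returns the coefficient matrix and the list of condition-guard ridges
    applied during polishing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, d = X.shape
    k = Z.shape[0]
    if Z.shape[1] != d:
        raise ValueError(f"shape mismatch: X has {d} columns, Z has {Z.shape[1]}")
    G = Z @ Z.T
    lipschitz = float(scipy.linalg.eigvalsh(G)[-1])
    C = X @ Z.T
    if W0 is None:
        W0 = np.full((n, k), 1.0 / k)
    W = _fista(
        grad=lambda Y: Y @ G - C,
        obj=lambda W_: 0.5 * float(np.einsum("ij,ij->", W_ @ Z - X, W_ @ Z - X)),
        W0=W0,
        lipschitz=lipschitz,
        max_iter=max_iter,
        tol=tol,
    )
    ridges: list[float] = []
    if polish:
        W, ridges = _polish_rows(X, Z, W, max_kappa=max_kappa)
    return W, ridges


def update_generators(
    X: np.ndarray,
    A: np.ndarray,
    B0: np.ndarray,
    XXt: np.ndarray | None = None,
    max_iter: int = 150,
    tol: float = 1e-12,
) -> np.ndarray:
    """Projected-gradient update of the generator matrix ``B``.

    Minimises the true reconstruction objective ``||X - A B X||_F^2`` over
    rows of ``B`` on the simplex (warm-started from ``B0``), so each update
    never increases the model RSS beyond solver tolerance.
    """
    X = np.asarray(X, dtype=float)
    A = np.asarray(A, dtype=float)
    if XXt is None:
        XXt = X @ X.T
    AtA = A.T @ A
    AtXXt = A.T @ XXt
    lipschitz = float(scipy.linalg.eigvalsh(AtA)[-1]) * float(
        scipy.linalg.eigvalsh(XXt)[-1]
    )

    def obj(B):
        R = X - A @ (B @ X)
        return 0.5 * float(np.einsum("ij,ij->", R, R))

    return _fista(
        grad=lambda B: AtA @ (B @ XXt) - AtXXt,
        obj=obj,
        W0=B0,
        lipschitz=lipschitz,
        max_iter=max_iter,
        tol=tol,
    )
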