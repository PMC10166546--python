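"""Archetypal analysis of total-deviation matrices.

The model is the convex matrix factorisation ``X ~ A Z`` with ``Z = B X``:
every field is a convex combination (rows of ``A`` on the simplex) of ``k``
archetypes, and every archetype is itself a convex combination (rows of ``B``
on the simplex) of observed fields, so archetypes are extreme but realisable
patterns on the data's convex hull.  Fitting alternates two exact
simplex-constrained least-squares updates:

* the coefficient step solves each field's projection onto the current
  archetype set (rows of ``A``);
* the generator step takes a monotone accelerated projected-gradient step on
  the true objective ``||X - A B X||^2`` over the rows of ``B``.

Both steps decrease the residual sum of squares, so the recorded RSS path is
non-increasing.  The fit restarts from several random initialisations (each
archetype initialised at a distinct observed field) and keeps the best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._simplex import (
    condition_guard,
    simplex_coefficients,
    update_generators,
)

__all__ = [
    "ArchetypalAnalysis",
    "FitOptions",
    "fit_archetypes",
    "compute_rss",
    "condition_guard",
]

_SQRT_EPS = float(np.sqrt(np.finfo(float).eps))


def compute_rss(X: np.ndarray, A: np.ndarray, Z: np.ndarray) -> float:
    """Residual sum of squared errors ``sum((X - A Z)**2)``."""
    X = np.asarray(X, dtype=float)
    A = np.asarray(A, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if A.shape[0] != X.shape[0] or A.shape[1] != Z.shape[0] or Z.shape[1] != X.shape[1]:
        raise ValueError(
            f"shape mismatch: X{X.shape}, A{A.shape}, Z{Z.shape}"
        )
    R = X - A @ Z
    return float(np.einsum("ij,ij->", R, R))


def normalized_rss(X: np.ndarray, A: np.ndarray, Z: np.ndarray) -> float:
    """RSS per matrix entry, ``RSS / (n * d)``, for cross-cohort comparison."""
    return compute_rss(X, A, Z) / (X.shape[0] * X.shape[1])


class ArchetypalAnalysis(TransformerMixin, BaseEstimator):
    """Archetypal analysis estimator.

    Parameters
    ----------
    n_archetypes : int
        Number of archetypes ``k``.
    max_iter : int, default 100
        Maximum alternating iterations per restart.
    tol : float, default sqrt(machine eps)
        Relative RSS improvement below which a restart stops.
    max_kappa : float, default 1000
        Condition-number bound for the exact KKT solves; worse-conditioned
        systems receive the smallest diagonal ridge bringing them to the
        bound (recorded in ``ridge_events_``).
    penalty_weight : float, default 200
        Sum-to-one penalty constant of the classical penalty-row formulation.
        Retained (and validated) for compatibility with that device; the
        default solver enforces the simplex exactly by projection and does
        not use it.
    n_restarts : int, default 5
        Random restarts; the lowest-RSS fit wins, ties (within 1e-12) going
        to the lowest restart index.
    random_state : int or numpy Generator, optional
        Seeds the restart initialisations.
    weights : None
        Reserved.  Per-observation weights are not implemented; any
        non-uniform value is rejected.
    init_rows : sequence of int, optional
        Explicit training-row indices initialising the archetypes (one
        restart, overriding ``n_restarts``); useful for reproducibility
        studies.

    Attributes
    ----------
    archetypes_ : ndarray of shape (k, d)
        Archetype vectors, in descending relative-weight order.
    coefficients_ : ndarray of shape (n, k)
        Simplex weights of each training field over the archetypes.
    generators_ : ndarray of shape (k, n)
        Simplex weights of each archetype over the training fields
        (``archetypes_ = generators_ @ X``).
    relative_weights_ : ndarray of shape (k,)
        Mean percent weight of each archetype over the training set (sums to
        100).
    average_td_ : ndarray of shape (k,)
        Unweighted mean of each archetype vector (dB for TD data).
    rss_, rss_path_, n_iter_, restart_index_, ridge_events_, normal_index_
        Fit diagnostics; ``normal_index_`` is the (0-based) archetype with
        the highest average TD, taken as the normal pattern.
    """

    def __init__(
        self,
        n_archetypes: int = 14,
        max_iter: int = 100,
        tol: float = _SQRT_EPS,
        max_kappa: float = 1000.0,
        penalty_weight: float = 200.0,
        n_restarts: int = 5,
        random_state: int | np.random.Generator | None = None,
        weights: np.ndarray | None = None,
        init_rows: tuple[int, ...] | None = None,
        solver_max_iter: int = 200,
    ):
        self.n_archetypes = n_archetypes
        self.max_iter = max_iter
        self.tol = tol
        self.max_kappa = max_kappa
        self.penalty_weight = penalty_weight
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.weights = weights
        self.init_rows = init_rows
        self.solver_max_iter = solver_max_iter

    # ------------------------------------------------------------------
    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix of fields x locations")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        k = self.n_archetypes
        if k < 1:
            raise ValueError("n_archetypes must be >= 1")
        if X.shape[0] < k:
            raise ValueError(
                f"need at least k={k} fields, got n={X.shape[0]}"
            )
        if not np.any(X):
            raise ValueError("X has rank 0 (all zeros); nothing to fit")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("max_iter and n_restarts must be >= 1")
        if self.penalty_weight <= 0:
            raise ValueError("penalty_weight must be positive")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (X.shape[0],) or not np.allclose(w, w.flat[0]):
                raise NotImplementedError(
                    "per-observation weights are reserved; only uniform "
                    "weights are accepted"
                )
        return X

    def _run_restart(self, X: np.ndarray, rows: np.ndarray):
        n = X.shape[0]
        k = self.n_archetypes
        XXt = X @ X.T
        B = np.zeros((k, n))
        B[np.arange(k), rows] = 1.0
        Z = B @ X
        ridge_events: list[float] = []
        A, _ = simplex_coefficients(
            X, Z, max_iter=self.solver_max_iter, polish=False
        )
        rss = compute_rss(X, A, Z)
        path = [rss]
        best = {"A": A, "B": B, "Z": Z, "rss": rss}
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            B = update_generators(X, A, B, XXt=XXt, max_iter=self.solver_max_iter)
            Z = B @ X
            # the KKT polish is deferred to the end of the restart: the
            # projected-gradient step is accurate enough to drive descent
            A, _ = simplex_coefficients(
                X, Z, W0=A, max_iter=self.solver_max_iter, polish=False
            )
            rss_new = compute_rss(X, A, Z)
            path.append(rss_new)
            if rss_new <= best["rss"]:
                best = {"A": A, "B": B, "Z": Z, "rss": rss_new}
            if rss_new > rss * (1 + 1e-9):
                warnings.warn(
                    "RSS stalled (non-improving step); terminating restart",
                    RuntimeWarning,
                )
                break
            if rss > 0 and (rss - rss_new) / rss < self.tol:
                rss = rss_new
                break
            rss = rss_new
        # final exact polish of the coefficient rows on their supports
        from ._simplex import _polish_rows

        A_pol, ridges = _polish_rows(
            X, best["Z"], best["A"], max_kappa=self.max_kappa
        )
        ridge_events.extend(ridges)
        rss_pol = compute_rss(X, A_pol, best["Z"])
        if rss_pol <= best["rss"]:
            best = {"A": A_pol, "B": best["B"], "Z": best["Z"], "rss": rss_pol}
            path.append(rss_pol)
        best.update(path=path, n_iter=n_iter, ridges=ridge_events)
        return best

    def fit(self, X: np.ndarray, y=None) -> "ArchetypalAnalysis":
        X = self._validate(X)
        n = X.shape[0]
        k = self.n_archetypes
        if isinstance(self.random_state, np.random.Generator):
            rng = self.random_state
        else:
            rng = np.random.default_rng(self.random_state)
        if self.init_rows is not None:
            inits = [np.asarray(self.init_rows, dtype=int)]
            if inits[0].shape != (k,) or len(set(inits[0].tolist())) != k:
                raise ValueError("init_rows must be k distinct row indices")
        else:
            inits = [rng.choice(n, size=k, replace=False) for _ in range(self.n_restarts)]
        best = None
        best_idx = -1
        for idx, rows in enumerate(inits):
            result = self._run_restart(X, rows)
            if best is None or result["rss"] < best["rss"] - 1e-12:
                best, best_idx = result, idx
        A, B, Z = best["A"], best["B"], best["Z"]
        rw = 100.0 * A.mean(axis=0)
        order = np.argsort(-rw, kind="stable")
        self.archetypes_ = Z[order]
        self.coefficients_ = A[:, order]
        self.generators_ = B[order]
        self.relative_weights_ = rw[order]
        self.average_td_ = self.archetypes_.mean(axis=1)
        self.rss_ = best["rss"]
        self.rss_path_ = best["path"]
        self.n_iter_ = best["n_iter"]
        self.restart_index_ = best_idx
        self.ridge_events_ = best["ridges"]
        self.normal_index_ = int(np.argmax(self.average_td_))
        if self.normal_index_ != 0:
            warnings.warn(
                "the highest-average-TD archetype is not the highest-RW "
                "archetype; check the normal-pattern designation",
                RuntimeWarning,
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Decompose fields onto the frozen archetypes: simplex weights."""
        if not hasattr(self, "archetypes_"):
            raise RuntimeError("estimator is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.archetypes_.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} locations, model expects "
                f"{self.archetypes_.shape[1]}"
            )
        W, _ = simplex_coefficients(
            X, self.archetypes_, max_iter=800, max_kappa=self.max_kappa
        )
        return W

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.archetypes_

    def score(self, X: np.ndarray, y=None) -> float:
        """Negative normalized RSS of held-out fields (higher is better)."""
        W = self.transform(X)
        return -normalized_rss(X, W, self.archetypes_)


@dataclass
class FitOptions:
    """Options bundle for the functional interface (mirrors the estimator)."""

    k: int
    max_iterations: int = 100
    min_improvement: float = _SQRT_EPS
    max_kappa: float = 1000.0
    penalty_weight: float = 200.0
    n_restarts: int = 5
    seed: int | None = 0
    init_rows: tuple[int, ...] | None = None
    solver_max_iter: int = 200

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.penalty_weight <= 0:
            raise ValueError("penalty_weight must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def estimator(self) -> ArchetypalAnalysis:
        return ArchetypalAnalysis(
            n_archetypes=self.k,
            max_iter=self.max_iterations,
            tol=self.min_improvement,
            max_kappa=self.max_kappa,
            penalty_weight=self.penalty_weight,
            n_restarts=self.n_restarts,
            random_state=self.seed,
            init_rows=self.init_rows,
            solver_max_iter=self.solver_max_iter,
        )


def fit_archetypes(X: np.ndarray, opts: FitOptions):
    """Fit an archetype model to a TD matrix; returns an ArchetypeModel."""
    from .model import ArchetypeModel

    est = opts.estimator().fit(X)
    return ArchetypeModel.from_estimator(est, opts=opts)
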