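"""Unit and property tests for the archetypal-analysis core."""

import warnings

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vfarch import ArchetypalAnalysis, FitOptions, compute_rss, condition_guard, fit_archetypes
from vfarch.aa import normalized_rss


def fit_quiet(est, X):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return est.fit(X)


# ------------------------------------------------------------------- rss
def test_rss_zero_for_exact_reconstruction(rng):
    Z = rng.normal(size=(3, 52))
    A = rng.dirichlet(np.ones(3), size=10)
    X = A @ Z
    assert compute_rss(X, A, Z) == 0.0


def test_rss_hand_arithmetic():
    X = np.array([[1.0, 0.0], [0.0, 1.0]])
    A = np.eye(2)
    Z = np.zeros((2, 2))
    assert compute_rss(X, A, Z) == pytest.approx(2.0)


def test_rss_quadratic_homogeneity(rng):
    X = rng.normal(size=(6, 4))
    A = rng.dirichlet(np.ones(2), size=6)
    Z = rng.normal(size=(2, 4))
    base = compute_rss(X, A, Z)
    doubled = compute_rss(2 * X - A @ Z, A, Z)  # doubles every residual
    assert doubled == pytest.approx(4 * base, rel=1e-12)


def test_rss_shape_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        compute_rss(rng.normal(size=(5, 4)), rng.normal(size=(5, 3)), rng.normal(size=(2, 4)))


def test_normalized_rss_scales_by_entries(rng):
    X = rng.normal(size=(5, 4))
    A = rng.dirichlet(np.ones(2), size=5)
    Z = rng.normal(size=(2, 4))
    assert normalized_rss(X, A, Z) == pytest.approx(compute_rss(X, A, Z) / 20)


# --------------------------------------------------------------- cond guard
def test_condition_guard_leaves_well_conditioned_unchanged():
    G = np.eye(3)
    out, ridge = condition_guard(G, 1000)
    assert ridge == 0.0
    np.testing.assert_array_equal(out, G)


def test_condition_guard_ridges_rank_deficient_to_bound():
    G = np.array([[1.0, 1.0], [1.0, 1.0]])
    out, ridge = condition_guard(G, 1000)
    assert ridge > 0
    ev = np.linalg.eigvalsh(out)
    assert ev[-1] / ev[0] == pytest.approx(1000.0, rel=1e-9)


def test_condition_guard_boundary_kappa_unchanged():
    G = np.diag([1000.0, 1.0])  # condition number exactly at the bound
    out, ridge = condition_guard(G, 1000)
    assert ridge == 0.0
    np.testing.assert_array_equal(out, G)


# ------------------------------------------------------------ analytic fits
def test_single_archetype_is_sample_mean(rng):
    X = rng.normal(0, 5, size=(25, 52))
    est = fit_quiet(ArchetypalAnalysis(n_archetypes=1, n_restarts=2, random_state=0), X)
    assert np.abs(est.archetypes_[0] - X.mean(axis=0)).max() < 1e-6


def test_n_equals_k_reconstructs_exactly(rng):
    X = rng.normal(0, 5, size=(4, 52))
    est = fit_quiet(ArchetypalAnalysis(n_archetypes=4, n_restarts=2, random_state=0), X)
    assert est.rss_ < 1e-10


def test_triangle_vertices_recovered(rng):
    V = np.zeros((3, 52))
    V[0, 0], V[1, 1] = 10.0, 10.0
    V[2, 0] = V[2, 1] = -5.0
    X = np.vstack([V, rng.dirichlet(np.ones(3), size=50) @ V])
    est = fit_quiet(ArchetypalAnalysis(n_archetypes=3, n_restarts=10, random_state=0), X)
    dist = np.linalg.norm(V[:, None, :] - est.archetypes_[None], axis=2)
    r, c = scipy.optimize.linear_sum_assignment(dist)
    assert est.rss_ < 1e-6
    assert dist[r, c].max() < 1e-3


# ------------------------------------------------------- invariants on fits
def test_monotone_descent_and_simplex_feasibility(rng):
    X = rng.normal(-5, 6, size=(60, 52))
    est = fit_quiet(
        ArchetypalAnalysis(n_archetypes=4, n_restarts=2, max_iter=40, random_state=3), X
    )
    path = est.rss_path_
    assert all(path[i + 1] <= path[i] * (1 + 1e-9) for i in range(len(path) - 1))
    for M in (est.coefficients_, est.generators_):
        assert M.min() >= 0
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-8)
    # archetypes are convex combinations of the training rows
    np.testing.assert_allclose(est.archetypes_, est.generators_ @ X, atol=1e-10)


def test_archetypes_ordered_by_descending_rw(recovery_fit):
    rw = recovery_fit.relative_weights_
    assert np.all(np.diff(rw) <= 1e-12)
    assert rw.sum() == pytest.approx(100.0, abs=0.1)


def test_permutation_invariance_with_mapped_init(rng):
    X = rng.normal(0, 4, size=(30, 52))
    init = (3, 11, 25)
    est1 = fit_quiet(ArchetypalAnalysis(n_archetypes=3, init_rows=init, max_iter=30), X)
    perm = rng.permutation(30)
    inv = np.argsort(perm)
    est2 = fit_quiet(
        ArchetypalAnalysis(
            n_archetypes=3, init_rows=tuple(int(inv[i]) for i in init), max_iter=30
        ),
        X[perm],
    )
    d = np.linalg.norm(est1.archetypes_[:, None] - est2.archetypes_[None], axis=2)
    r, c = scipy.optimize.linear_sum_assignment(d)
    assert d[r, c].max() < 1e-6


def test_restart_als_not_worse_than_brute_force_grid(rng):
    """On tiny 2-D instances the ALS fit must match a dense simplex grid
    search over the generator matrix (step 0.05) to within 1e-3."""
    for seed in (5, 6):
        local = np.random.default_rng(seed)
        X = local.normal(0, 3, size=(4, 2))
        grid = []
        for a in range(21):
            for b in range(21 - a):
                for c in range(21 - a - b):
                    grid.append((a / 20, b / 20, c / 20, (20 - a - b - c) / 20))
        Zc = np.array(grid) @ X  # every candidate archetype location
        best = np.inf
        for i in range(len(Zc)):
            z1 = Zc[i]
            d21 = Zc - z1
            denom = (d21 * d21).sum(axis=1)
            Xm = X - z1
            num = Xm @ d21.T
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.nan_to_num(np.clip(num / denom, 0.0, 1.0))
            rss = ((Xm**2).sum(axis=1)[:, None] - 2 * t * num + t**2 * denom).sum(axis=0)
            best = min(best, float(rss.min()))
        est = fit_quiet(ArchetypalAnalysis(n_archetypes=2, n_restarts=4, random_state=0), X)
        assert est.rss_ <= best + 1e-3


@settings(max_examples=10)
@given(
    X=arrays(
        np.float64,
        (12, 6),
        elements=st.floats(min_value=-10, max_value=10, allow_nan=False),
    )
)
def test_simplex_feasibility_property(X):
    if np.linalg.matrix_rank(X) == 0:
        return
    est = fit_quiet(
        ArchetypalAnalysis(n_archetypes=2, n_restarts=1, max_iter=15, random_state=0), X
    )
    for M in (est.coefficients_, est.generators_):
        assert M.min() >= 0
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-8)


# -------------------------------------------------------------- validation
def test_fit_parameter_errors(rng):
    X = rng.normal(size=(3, 52))
    with pytest.raises(ValueError):
        ArchetypalAnalysis(n_archetypes=4).fit(X)  # n < k
    with pytest.raises(ValueError):
        ArchetypalAnalysis(n_archetypes=2).fit(np.zeros((10, 52)))  # rank 0
    with pytest.raises(ValueError):
        ArchetypalAnalysis(n_archetypes=2, penalty_weight=0.0).fit(rng.normal(size=(9, 52)))


def test_non_uniform_weights_rejected(rng):
    X = rng.normal(size=(10, 52))
    w = np.ones(10)
    fit_quiet(ArchetypalAnalysis(n_archetypes=2, weights=w, n_restarts=1, max_iter=5), X)
    w2 = w.copy()
    w2[0] = 2.0
    with pytest.raises(NotImplementedError):
        ArchetypalAnalysis(n_archetypes=2, weights=w2).fit(X)


def test_fit_options_validation_and_wrapper(rng):
    with pytest.raises(ValueError):
        FitOptions(k=0)
    with pytest.raises(ValueError):
        FitOptions(k=2, penalty_weight=-1)
    X = rng.normal(0, 3, size=(15, 52))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = fit_archetypes(X, FitOptions(k=2, n_restarts=1, max_iterations=10, seed=0))
    assert model.k == 2
    assert model.metadata["seed"] == 0


def test_transform_deterministic(recovery_fit, rng):
    x = rng.normal(-3, 4, size=(3, 52))
    W1 = recovery_fit.transform(x)
    W2 = recovery_fit.transform(x)
    np.testing.assert_array_equal(W1, W2)
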