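import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from gflseg import (
    PenaltyConfig,
    build_surrogate,
    fit_gfl,
    objective,
    solve_tridiagonal,
    surrogate_value,
)
from gflseg.gfl_solver import SurrogateSystem
from .conftest import make_signal


def smoothed_minimum(data, cfg, x0):
    """Independent minimizer of the smoothed objective (L-BFGS-B, analytic grad)."""
    M, N = data.values.shape
    lam1 = cfg.per_row("lambda1", M)
    lam2 = cfg.per_row("lambda2", M)
    lam3 = cfg.per_row("lambda3", M)
    eps = cfg.epsilon

    def fg(b):
        b = b.reshape(M, N)
        f = objective(b, data, cfg, smoothed=True)
        g = -(data.mask * (np.where(data.mask, data.values, 0.0) - b))
        g = g + lam1[:, None] * b / np.sqrt(b**2 + eps)
        d = np.diff(b, axis=1)
        t2 = lam2[:, None] * d / np.sqrt(d**2 + eps)
        s = np.sqrt(np.sum((lam3[:, None] * d) ** 2, axis=0) + eps)
        t3 = lam3[:, None] ** 2 * d / s[None, :]
        g[:, 1:] += t2 + t3
        g[:, :-1] -= t2 + t3
        return f, g.ravel()

    opt = minimize(
        fg,
        np.asarray(x0, dtype=float).ravel(),
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=50_000, maxfun=100_000, ftol=1e-16, gtol=1e-10),
    )
    return opt.fun


class TestObjective:
    def test_perfect_fit_no_penalty_is_zero(self, rng):
        y = rng.normal(size=(2, 8))
        data = make_signal(y)
        assert objective(y, data, PenaltyConfig()) == 0.0

    def test_hand_computed_value(self):
        # y=(0,2), beta=(1,1): data 1/2*(1+1), lasso 1*(1+1), fusion 0
        data = make_signal([[0.0, 2.0]])
        cfg = PenaltyConfig(lambda1=1.0, lambda2=1.0, lambda3=0.0)
        val = objective(np.array([[1.0, 1.0]]), data, cfg, smoothed=False)
        assert val == pytest.approx(3.0)

    def test_smoothed_dominates_exact(self, rng):
        y = rng.normal(size=(3, 12))
        data = make_signal(y)
        cfg = PenaltyConfig(lambda1=0.3, lambda2=0.7, lambda3=0.5, epsilon=1e-4)
        for _ in range(10):
            b = rng.normal(size=(3, 12))
            assert objective(b, data, cfg, smoothed=True) >= objective(
                b, data, cfg, smoothed=False
            )

    def test_shape_mismatch_rejected(self, rng):
        data = make_signal(rng.normal(size=(2, 5)))
        with pytest.raises(ValueError):
            objective(np.zeros((2, 6)), data, PenaltyConfig())


class TestSurrogate:
    def test_pure_lasso_is_diagonal(self, rng):
        data = make_signal(rng.normal(size=(2, 10)))
        cfg = PenaltyConfig(lambda1=0.5)
        sys = build_surrogate(rng.normal(size=(2, 10)), data, cfg)
        assert np.all(sys.offdiag == 0)

    def test_tangency(self, rng):
        y = rng.normal(size=(2, 15))
        data = make_signal(y)
        cfg = PenaltyConfig(lambda1=0.2, lambda2=0.8, lambda3=0.6)
        for _ in range(10):
            b0 = rng.normal(size=(2, 15))
            sys = build_surrogate(b0, data, cfg)
            gap = surrogate_value(sys, b0) - objective(b0, data, cfg, smoothed=True)
            assert abs(gap) <= 1e-10 * max(1.0, abs(surrogate_value(sys, b0)))

    def test_majorizes_everywhere(self, rng):
        y = rng.normal(size=(3, 10))
        data = make_signal(y)
        cfg = PenaltyConfig(lambda1=0.2, lambda2=0.8, lambda3=0.6)
        b0 = rng.normal(size=(3, 10))
        sys = build_surrogate(b0, data, cfg)
        for _ in range(100):
            b = rng.normal(scale=2.0, size=(3, 10))
            assert surrogate_value(sys, b) >= objective(
                b, data, cfg, smoothed=True
            ) - 1e-9


class TestTridiagonalSolve:
    def test_identity_returns_rhs(self, rng):
        rhs = rng.normal(size=(3, 7))
        sys = SurrogateSystem(
            diag=np.ones((3, 7)), offdiag=np.zeros((3, 6)), rhs=rhs
        )
        assert np.allclose(solve_tridiagonal(sys), rhs)

    def test_two_by_two_hand_solve(self):
        sys = SurrogateSystem(
            diag=np.array([[2.0, 2.0]]),
            offdiag=np.array([[1.0]]),
            rhs=np.array([[1.0, 1.0]]),
        )
        assert np.allclose(solve_tridiagonal(sys), [[1 / 3, 1 / 3]])

    def test_matches_dense_solver(self, rng):
        N = 50
        off = rng.normal(size=N - 1)
        diag = np.abs(rng.normal(size=N)) + 2 * np.abs(off).max() + 1  # diag dominant
        rhs = rng.normal(size=N)
        sys = SurrogateSystem(diag=diag[None], offdiag=off[None], rhs=rhs[None])
        A = np.diag(diag) + np.diag(off, 1) + np.diag(off, -1)
        expected = np.linalg.solve(A, rhs)
        got = solve_tridiagonal(sys)[0]
        assert np.max(np.abs(got - expected)) <= 1e-10 * np.max(np.abs(expected))

    def test_nonfinite_coefficients_flagged_with_row(self):
        sys = SurrogateSystem(
            diag=np.array([[1.0, 1.0], [np.nan, 1.0]]),
            offdiag=np.array([[0.0], [0.0]]),
            rhs=np.ones((2, 2)),
        )
        with pytest.raises(FloatingPointError, match="row 1"):
            solve_tridiagonal(sys)


class TestFitGfl:
    def test_unpenalized_returns_data_exactly(self, rng):
        y = rng.normal(size=(2, 30))
        res = fit_gfl(make_signal(y), PenaltyConfig())
        assert np.array_equal(res.beta, y)
        assert res.n_iter == 1 and res.converged

    def test_dominant_lasso_drives_to_zero(self, rng):
        y = rng.normal(size=(1, 20))
        lam = 10 * np.abs(y).max() * 20
        res = fit_gfl(make_signal(y), PenaltyConfig(lambda1=lam, tol=1e-12, max_iter=2000))
        assert np.abs(res.beta).max() <= 1e-4

    def test_dominant_fusion_flattens_to_mean(self, rng):
        y = rng.normal(size=(1, 40))
        y[0, 20:] += 3.0
        res = fit_gfl(
            make_signal(y), PenaltyConfig(lambda2=1e6, tol=1e-12, max_iter=5000)
        )
        assert np.max(np.abs(res.beta - y.mean())) <= 1e-4

    def test_objective_trace_non_increasing(self, rng):
        y = rng.normal(size=(3, 40))
        y[:, 15:25] += 2.0
        cfg = PenaltyConfig(lambda1=0.1, lambda2=1.0, lambda3=1.0)
        res = fit_gfl(make_signal(y), cfg)
        tr = res.objective_trace
        assert np.all(np.diff(tr) <= 1e-9 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_matches_generic_minimizer(self, rng):
        y = rng.normal(size=(2, 20))
        y[:, 8:14] += 2.0
        data = make_signal(y)
        cfg = PenaltyConfig(
            lambda1=0.1, lambda2=1.0, lambda3=1.0, tol=1e-10, max_iter=2000
        )
        res = fit_gfl(data, cfg)
        oracle = smoothed_minimum(data, cfg, y)
        assert res.objective_trace[-1] == pytest.approx(oracle, rel=1e-4)

    def test_row_permutation_equivariance(self, rng):
        y = rng.normal(size=(3, 25))
        cfg = PenaltyConfig(lambda1=0.1, lambda2=0.7, lambda3=0.9, tol=1e-10, max_iter=2000)
        base = fit_gfl(make_signal(y), cfg).beta
        perm = [2, 0, 1]
        permuted = fit_gfl(make_signal(y[perm]), cfg).beta
        assert np.max(np.abs(permuted - base[perm])) <= 1e-8

    def test_masked_entries_sandwiched_by_neighbors(self, rng):
        mask = np.ones((2, 30), dtype=bool)
        mask[0, 10:15] = False
        y = rng.normal(size=(2, 30))
        data = make_signal(np.where(mask, y, np.nan), mask=mask)
        res = fit_gfl(data, PenaltyConfig(lambda2=0.5, lambda3=0.5, tol=1e-10, max_iter=2000))
        b = res.beta[0]
        assert np.all(np.isfinite(res.beta))
        lo, hi = min(b[9], b[15]), max(b[9], b[15])
        assert np.all(b[10:15] >= lo - 1e-8) and np.all(b[10:15] <= hi + 1e-8)

    def test_scale_equivariance(self, rng):
        # scaling y and every lambda by s (and eps by s^2) scales the fit by
        # s: exactly when the group term is off (all norm arguments share the
        # signal's units), and up to the O(sqrt(eps)) smoothing bias when it
        # is on (the group norm's argument carries units lambda*signal, so a
        # single eps cannot track both scalings)
        y = rng.normal(size=(2, 20))
        s = 3.7
        eps = 1e-8
        kw = dict(tol=1e-15, max_iter=80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for lam3, tol in ((0.0, 1e-9), (0.9, 10 * np.sqrt(eps))):
                a = fit_gfl(
                    make_signal(y),
                    PenaltyConfig(lambda1=0.1, lambda2=0.7, lambda3=lam3,
                                  epsilon=eps, **kw),
                ).beta
                b = fit_gfl(
                    make_signal(s * y),
                    PenaltyConfig(lambda1=0.1 * s, lambda2=0.7 * s,
                                  lambda3=lam3 * s, epsilon=eps * s * s, **kw),
                ).beta
                assert np.max(np.abs(b - s * a)) <= tol * s

    def test_nonconvergence_warns_not_raises(self, rng):
        y = rng.normal(size=(1, 50))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = fit_gfl(make_signal(y), PenaltyConfig(lambda2=5.0, tol=1e-15, max_iter=3))
        assert not res.converged

    def test_per_iteration_cost_roughly_linear(self):
        import time

        times = {}
        for N in (1_000, 100_000):
            y = np.random.default_rng(0).normal(size=(1, N))
            data = make_signal(y)
            cfg = PenaltyConfig(lambda1=0.1, lambda2=1.0)
            sys = build_surrogate(y, data, cfg)
            t0 = time.perf_counter()
            for _ in range(3):
                build_surrogate(y, data, cfg)
                solve_tridiagonal(sys)
            times[N] = (time.perf_counter() - t0) / 3
        # 100x problem size: allow generous slack over the linear 100x
        assert times[100_000] / times[1_000] < 500


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        PenaltyConfig(epsilon=0.0)
    with pytest.raises(ValueError):
        PenaltyConfig(lambda1=-1.0)
    with pytest.raises(ValueError):
        PenaltyConfig(max_iter=0)
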