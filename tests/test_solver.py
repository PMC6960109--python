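"""Stage-1 BPDN solver and compressive-sensing recovery."""

import numpy as np
import pytest
from scipy.optimize import linprog

from dsnn.solver import SolverConfig, bpdn_solve, recover_stage1
from dsnn.transforms import (
    DCTBasisPair,
    ObservationMask,
    build_sensing_operator,
    inverse_2d,
)

from conftest import DenseMatrixOperator, materialize_sensing_matrix

RNG = np.random.default_rng(7)


def min_l1_lp(A: np.ndarray, y: np.ndarray) -> float:
    """Linear-programming oracle for min ||z||_1 s.t. A z = y
    (split z = p - q with p, q >= 0)."""
    n = A.shape[1]
    res = linprog(
        c=np.ones(2 * n),
        A_eq=np.hstack([A, -A]),
        b_eq=y,
        bounds=[(0, None)] * 2 * n,
        method="highs",
    )
    assert res.success
    return float(res.fun)


class TestBpdnSolve:
    def test_identity_system_interpolates(self):
        op = DenseMatrixOperator(np.eye(4))
        y = np.array([1.0, -2.0, 0.0, 3.0])
        Z = bpdn_solve(op, y, SolverConfig(sigma=0.0, opt_tol=1e-6, dec_tol=1e-6))
        np.testing.assert_allclose(Z.ravel(), y, atol=1e-4)

    def test_large_sigma_gives_zero(self):
        op = DenseMatrixOperator(np.eye(4))
        y = np.array([1.0, -2.0, 0.0, 3.0])
        Z = bpdn_solve(op, y, SolverConfig(sigma=np.linalg.norm(y) + 0.1))
        np.testing.assert_array_equal(Z, 0.0)

    def test_minimal_l1_on_2x3_system(self):
        # solutions form a = b = 1 - c; |a|+|b|+|c| is minimized at c = 1
        A = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        y = np.array([1.0, 1.0])
        Z = bpdn_solve(
            DenseMatrixOperator(A), y, SolverConfig(opt_tol=1e-6, dec_tol=1e-6)
        )
        np.testing.assert_allclose(Z.ravel(), [0.0, 0.0, 1.0], atol=1e-3)
        assert np.abs(Z).sum() == pytest.approx(1.0, abs=1e-3)

    def test_matches_lp_oracle_on_masked_dct_systems(self):
        cfg = SolverConfig(opt_tol=1e-6, dec_tol=1e-7, spg_iters=2000)
        for trial in range(10):
            rng = np.random.default_rng(100 + trial)
            m, n = rng.integers(2, 5, size=2)
            mask_arr = (rng.random((m, n)) < 0.7).astype(np.uint8)
            mask_arr[rng.integers(m), :] = 1
            mask = ObservationMask(mask_arr)
            basis = DCTBasisPair(int(m), int(n))
            op = build_sensing_operator(mask, basis)
            y = rng.standard_normal(op.n_measurements)
            Z = bpdn_solve(op, y, cfg)
            dense = materialize_sensing_matrix(mask, basis)
            expected = min_l1_lp(dense, y)
            assert np.abs(Z).sum() == pytest.approx(expected, abs=1e-4)

    def test_nonconvergence_warns(self):
        A = RNG.standard_normal((3, 8))
        y = RNG.standard_normal(3)
        cfg = SolverConfig(max_iters=1, spg_iters=1, opt_tol=1e-12, dec_tol=1e-12)
        with pytest.warns(RuntimeWarning):
            bpdn_solve(DenseMatrixOperator(A), y, cfg)


class TestRecoverStage1:
    def test_fully_observed_interpolates(self):
        Y = RNG.standard_normal((8, 6)) + 5.0
        mask = ObservationMask(np.ones_like(Y))
        res = recover_stage1(Y, mask, SolverConfig())
        rel = np.linalg.norm(res.X_tilde - Y) / np.linalg.norm(Y)
        assert rel < 1e-6
        assert res.converged

    def test_zero_data_gives_zero(self):
        mask_arr = (RNG.random((6, 6)) < 0.5).astype(np.uint8)
        mask_arr[0, :] = 1
        res = recover_stage1(np.zeros((6, 6)), ObservationMask(mask_arr), SolverConfig())
        np.testing.assert_array_equal(res.X_tilde, 0.0)

    def test_exact_recovery_of_sparse_ground_truth(self):
        # 25 nonzero DCT coefficients in a 32×32 matrix, 60% observed
        rng = np.random.default_rng(11)
        m = n = 32
        basis = DCTBasisPair(m, n)
        Z_true = np.zeros((m, n))
        support = rng.choice(m * n, size=25, replace=False)
        Z_true.ravel()[support] = rng.standard_normal(25) * 3.0
        X_true = inverse_2d(Z_true, basis)
        mask_arr = np.zeros(m * n, dtype=np.uint8)
        mask_arr[rng.choice(m * n, size=int(0.6 * m * n), replace=False)] = 1
        mask = ObservationMask(mask_arr.reshape(m, n))
        Y = np.where(mask.as_bool(), X_true, 0.0)
        res = recover_stage1(Y, mask, SolverConfig())
        rel = np.linalg.norm(res.X_tilde - X_true) / np.linalg.norm(X_true)
        assert rel < 1e-3

    def test_observed_misfit_bound(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((10, 12))
        mask_arr = (rng.random((10, 12)) < 0.6).astype(np.uint8)
        mask_arr[0, :] = 1
        mask = ObservationMask(mask_arr)
        cfg = SolverConfig()
        res = recover_stage1(np.where(mask.as_bool(), Y, 0.0), mask, cfg)
        obs = mask.as_bool()
        misfit = np.linalg.norm((res.X_tilde - Y)[obs])
        ynorm = np.linalg.norm(Y[obs])
        assert misfit <= cfg.sigma + 2 * cfg.opt_tol * max(1.0, ynorm)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((8, 8))
        mask_arr = (rng.random((8, 8)) < 0.7).astype(np.uint8)
        mask_arr[0, :] = 1
        mask = ObservationMask(mask_arr)
        cfg = SolverConfig(opt_tol=1e-6, dec_tol=1e-6)
        base = recover_stage1(np.where(mask.as_bool(), Y, 0.0), mask, cfg).X_tilde
        scaled = recover_stage1(np.where(mask.as_bool(), 3.0 * Y, 0.0), mask, cfg).X_tilde
        # near-optimal iterates of the two runs may differ slightly even
        # though the exact minimizers scale exactly
        rel = np.linalg.norm(scaled - 3.0 * base) / np.linalg.norm(3.0 * base)
        assert rel < 1e-2

    def test_coefficient_consistency(self):
        rng = np.random.default_rng(9)
        Y = rng.standard_normal((6, 6))
        mask_arr = (rng.random((6, 6)) < 0.8).astype(np.uint8)
        mask_arr[0, :] = 1
        mask = ObservationMask(mask_arr)
        res = recover_stage1(np.where(mask.as_bool(), Y, 0.0), mask, SolverConfig())
        basis = DCTBasisPair(6, 6)
        np.testing.assert_allclose(
            res.X_tilde, inverse_2d(res.Z, basis), atol=1e-10
        )

    def test_recovery_error_improves_with_observability(self):
        rng = np.random.default_rng(21)
        m = n = 24
        basis = DCTBasisPair(m, n)
        Z_true = np.zeros((m, n))
        Z_true.ravel()[rng.choice(m * n, 30, replace=False)] = rng.standard_normal(30)
        X_true = inverse_2d(Z_true, basis)
        errors = []
        for frac in (0.3, 0.6, 0.9):
            errs = []
            for rep in range(2):
                r2 = np.random.default_rng(500 + rep)
                mask_arr = np.zeros(m * n, dtype=np.uint8)
                mask_arr[r2.choice(m * n, int(frac * m * n), replace=False)] = 1
                mask = ObservationMask(mask_arr.reshape(m, n))
                res = recover_stage1(
                    np.where(mask.as_bool(), X_true, 0.0), mask, SolverConfig()
                )
                errs.append(np.linalg.norm(res.X_tilde - X_true))
            errors.append(np.mean(errs))
        assert errors[0] >= errors[1] >= errors[2]
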