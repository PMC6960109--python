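"""Stage-2: outlier zeroing, SVT, and the Split-Bregman loop."""

import numpy as np
import pytest

from dsnn.denoise import (
    DenoiseConfig,
    init_estimate,
    make_state,
    split_bregman_denoise,
    svt,
    zero_outliers,
)
from dsnn.io import ExpressionMatrix
from dsnn.transforms import ObservationMask

RNG = np.random.default_rng(77)


def _col_matrix(values):
    """m×1 ExpressionMatrix + full mask from a list of column values."""
    arr = np.asarray(values, float).reshape(-1, 1)
    m = ExpressionMatrix(
        arr, sample_ids=tuple(f"s{i}" for i in range(arr.shape[0])),
        gene_ids=("g",), allow_negative=True,
    )
    return m, ObservationMask(np.ones_like(arr))


class TestZeroOutliers:
    def test_infinite_band_keeps_everything(self):
        Y, mask = _col_matrix([1.0, 2.0, 3.0])
        X_tilde = np.array([[1.1], [2.2], [3.3]])
        X_rec, X_inv = zero_outliers(X_tilde, Y, mask, np.inf)
        np.testing.assert_array_equal(X_rec, X_tilde)
        assert X_inv.sum() == 0

    def test_band_zeroes_only_deviant_entry(self):
        # observed column [1,2,3]: mean 2, sample std 1; band half-width 0.2
        Y, mask = _col_matrix([1.0, 2.0, 3.0])
        X_tilde = np.array([[2.1], [1.5], [2.05]])
        X_rec, X_inv = zero_outliers(X_tilde, Y, mask, 0.2)
        np.testing.assert_allclose(X_rec, [[2.1], [0.0], [2.05]])
        np.testing.assert_array_equal(X_inv, [[0], [1], [0]])

    def test_constant_column_left_untouched(self):
        Y, mask = _col_matrix([4.0, 4.0, 4.0])
        X_tilde = np.array([[9.0], [4.0], [-3.0]])
        X_rec, X_inv = zero_outliers(X_tilde, Y, mask, 0.2)
        np.testing.assert_array_equal(X_rec, X_tilde)
        assert X_inv.sum() == 0

    def test_stats_use_observed_entries_only(self):
        # 4th value is masked out and must not influence mean/std
        arr = np.array([[1.0], [2.0], [3.0], [999.0]])
        Y = ExpressionMatrix(
            arr, sample_ids=("a", "b", "c", "d"), gene_ids=("g",)
        )
        mask = ObservationMask([[1], [1], [1], [0]])
        X_tilde = np.array([[2.1], [1.5], [2.05], [2.0]])
        X_rec, _ = zero_outliers(X_tilde, Y, mask, 0.2)
        np.testing.assert_allclose(X_rec[:3], [[2.1], [0.0], [2.05]])

    def test_column_without_observations_errors(self):
        arr = np.zeros((2, 2))
        Y = ExpressionMatrix(arr, sample_ids=("a", "b"), gene_ids=("g1", "g2"))
        mask = ObservationMask([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="no observed"):
            zero_outliers(arr, Y, mask, 0.2)


class TestInitEstimate:
    def test_no_zeroed_entries_is_exact(self):
        X_rec = RNG.standard_normal((4, 4)) + 10.0
        X0 = init_estimate(X_rec, np.zeros_like(X_rec), seed=1)
        np.testing.assert_array_equal(X0, X_rec)

    def test_seeded_determinism_and_range(self):
        X_rec = np.zeros((5, 5))
        X_inv = np.ones((5, 5))
        a = init_estimate(X_rec, X_inv, seed=9)
        b = init_estimate(X_rec, X_inv, seed=9)
        np.testing.assert_array_equal(a, b)
        assert ((a >= 0) & (a < 1)).all()


class TestSvt:
    def test_zero_threshold_is_identity(self):
        V = RNG.standard_normal((6, 4))
        np.testing.assert_allclose(svt(V, 0.0), V, atol=1e-10)

    def test_threshold_above_spectrum_gives_zero(self):
        V = RNG.standard_normal((5, 5))
        tau = np.linalg.svd(V, compute_uv=False)[0] + 1.0
        np.testing.assert_array_equal(svt(V, tau), 0.0)

    def test_diagonal_closed_form(self):
        V = np.diag([3.0, 1.0])
        np.testing.assert_allclose(svt(V, 1.0), np.diag([2.0, 0.0]), atol=1e-12)

    def test_non_expansive(self):
        for _ in range(20):
            A = RNG.standard_normal((6, 5))
            B = RNG.standard_normal((6, 5))
            tau = float(RNG.random() * 3)
            assert (
                np.linalg.norm(svt(A, tau) - svt(B, tau))
                <= np.linalg.norm(A - B) + 1e-10
            )

    def test_shrinks_nuclear_norm_and_rank(self):
        V = RNG.standard_normal((8, 6))
        out = svt(V, 1.0)
        s_in = np.linalg.svd(V, compute_uv=False)
        s_out = np.linalg.svd(out, compute_uv=False)
        assert s_out.sum() <= s_in.sum()
        assert (s_out > 1e-10).sum() <= (s_in > 1e-10).sum()


class TestSplitBregman:
    def test_fixed_point_when_nothing_zeroed(self):
        X_rec = RNG.standard_normal((5, 5)) + 5.0
        state = make_state(X_rec, np.zeros_like(X_rec), X_obs=X_rec, seed=0)
        out = split_bregman_denoise(state, DenoiseConfig())
        np.testing.assert_array_equal(out, X_rec)
        assert state.k == 1 and state.converged

    def test_retained_entries_pass_through(self):
        X_tilde = RNG.standard_normal((10, 8)) * 50 + 300
        X_inv = (RNG.random((10, 8)) < 0.3).astype(np.uint8)
        X_rec = np.where(X_inv == 1, 0.0, X_tilde)
        X_inv = (X_rec == 0).astype(np.uint8)
        state = make_state(X_rec, X_inv, X_obs=X_rec, seed=3)
        out = split_bregman_denoise(state, DenoiseConfig(max_iters=500))
        retained = X_inv == 0
        np.testing.assert_array_equal(out[retained], X_rec[retained])

    def test_zeroed_entries_better_than_random_init(self):
        # rank-2 ground truth; ~20% of entries zeroed and re-estimated
        rng = np.random.default_rng(12)
        truth = np.outer(rng.random(40) * 20 + 100, rng.random(40) + 0.5)
        X_inv = (rng.random((40, 40)) < 0.2).astype(np.uint8)
        X_rec = np.where(X_inv == 1, 0.0, truth)
        X_inv = (X_rec == 0).astype(np.uint8)
        state = make_state(X_rec, X_inv, X_obs=X_rec, seed=4)
        init_err = np.linalg.norm((state.X_hat - truth)[X_inv == 1])
        out = split_bregman_denoise(state, DenoiseConfig(max_iters=2000))
        final_err = np.linalg.norm((out - truth)[X_inv == 1])
        assert final_err < init_err

    def test_deterministic_given_seed(self):
        X_tilde = RNG.standard_normal((6, 6)) * 10 + 50
        X_inv = (RNG.random((6, 6)) < 0.4).astype(np.uint8)
        X_rec = np.where(X_inv == 1, 0.0, X_tilde)
        X_inv = (X_rec == 0).astype(np.uint8)
        outs = []
        for _ in range(2):
            state = make_state(X_rec, X_inv, X_obs=X_rec, seed=42)
            outs.append(split_bregman_denoise(state, DenoiseConfig(max_iters=200)))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_tau_zero_converges_immediately(self):
        X_rec = np.where(RNG.random((5, 5)) < 0.5, 0.0, 3.0)
        X_inv = (X_rec == 0).astype(np.uint8)
        state = make_state(X_rec, X_inv, X_obs=X_rec, seed=0)
        split_bregman_denoise(state, DenoiseConfig(tau=0.0))
        assert state.k <= 2 and state.converged

    def test_state_indicator_validation(self):
        with pytest.raises(ValueError):
            make_state(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)))
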