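"""Solver tests: half-step least-squares correctness against a dense
pseudoinverse oracle, fusing-step algebra, fixed points, exact recovery,
and the failure of pure alternation."""

import numpy as np
import pytest

import splitfuse as sf
from splitfuse.solver import NumericalError

from conftest import dense_sensing_matrix


class TestHalfStep:
    def test_zero_observations_give_zero(self, small_masks, small_signal):
        b = sf.solve_half_step(small_signal, np.zeros((8, 3)), small_masks)
        assert np.linalg.norm(b) < 1e-10 * np.linalg.norm(small_signal)

    def test_matches_dense_pseudoinverse(self, rng):
        m = sf.sample_masks(8, 3, seed=31)
        x = rng.uniform(0.1, 1.0, size=8)
        Y = sf.forward_intensity(x, m)
        b = sf.solve_half_step(x, Y, m)
        Ha = dense_sensing_matrix(x, m)
        assert np.linalg.matrix_rank(Ha) == 8  # unique minimizer
        b_dense, *_ = np.linalg.lstsq(Ha, Y.T.ravel(), rcond=None)
        np.testing.assert_allclose(b, b_dense, rtol=1e-8)

    def test_truth_anchor_recovers_truth(self, rng):
        # x is the exact zero-residual solution when anchored at x
        x = rng.normal(size=16)
        m = sf.sample_masks(16, 2, seed=37)
        Y = sf.forward_intensity(x, m)
        b = sf.solve_half_step(x, Y, m)
        assert np.linalg.norm(b - x) / np.linalg.norm(x) < 1e-6

    def test_zero_anchor_raises(self, small_masks):
        with pytest.raises(NumericalError):
            sf.solve_half_step(np.zeros(8), np.ones((8, 3)), small_masks)


class TestRecombine:
    def test_fixed_point(self, rng):
        v = rng.normal(size=12)
        np.testing.assert_array_equal(sf.recombine(v, v), v)

    def test_symmetric_cancellation(self, rng):
        # opposing resting positions x+d and x-d fuse back to x
        x, d = rng.normal(size=(2, 12))
        np.testing.assert_allclose(sf.recombine(x + d, x - d), x, atol=1e-14)

    def test_arithmetic(self):
        np.testing.assert_array_equal(
            sf.recombine(np.array([1.0, 0.0]), np.array([0.0, 1.0])),
            np.array([0.5, 0.5]),
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sf.recombine(np.ones(3), np.ones(4))


class TestRun:
    def test_truth_init_is_fixed_point(self, rng):
        x = rng.uniform(0.1, 1.0, size=32)
        m = sf.sample_masks(32, 3, seed=41)
        Y = sf.forward_intensity(x, m)
        res = sf.run(Y, m, x.copy(), ground_truth=x)
        assert res.converged
        assert res.n_iters <= 2
        assert res.final_error < 1e-12

    def test_noise_free_recovery_from_random_init(self):
        # 64-length uniform signal, K=4: exact recovery expected
        x = np.random.default_rng(5).uniform(size=64)
        m = sf.sample_masks(64, 4, seed=6)
        Y = sf.forward_intensity(x, m)
        init = sf.random_positive_init(Y, m, seed=7)
        res = sf.run(Y, m, init, ground_truth=x)
        assert res.final_error < 1e-6
        assert res.converged

    def test_gaussian_k2_fails(self):
        # 32x32 zero-mean signal with only 2 masks: no recovery from any
        # positive init (too little information for a general real signal)
        x = np.random.default_rng(8).standard_normal((32, 32))
        m = sf.sample_masks((32, 32), 2, seed=9)
        Y = sf.forward_intensity(x, m)
        init = sf.random_positive_init(Y, m, seed=10)
        res = sf.run(Y, m, init, sf.SolverConfig(max_outer=400),
                     ground_truth=x)
        assert res.final_error >= 1e-5

    def test_err_trace_length_matches_iterations(self, rng):
        x = rng.uniform(0.1, 1.0, size=32)
        m = sf.sample_masks(32, 4, seed=43)
        Y = sf.forward_intensity(x, m)
        init = sf.random_positive_init(Y, m, seed=3)
        res = sf.run(Y, m, init, ground_truth=x)
        assert len(res.err_trace) == res.n_iters
        assert len(res.step_delta) == res.n_iters

    def test_no_ground_truth_no_trace(self, rng):
        x = rng.uniform(0.1, 1.0, size=16)
        m = sf.sample_masks(16, 3, seed=47)
        Y = sf.forward_intensity(x, m)
        res = sf.run(Y, m, sf.random_positive_init(Y, m, seed=1))
        assert res.err_trace is None

    def test_zero_init_rejected(self, small_masks):
        with pytest.raises(ValueError):
            sf.run(np.ones((8, 3)), small_masks, np.zeros(8))

    def test_noise_monotonicity(self):
        # final error non-increasing in SNR at fixed masks and noise seed
        x = sf.phantom_image((16, 16))
        m = sf.sample_masks((16, 16), 8, seed=51)
        Y = sf.forward_intensity(x, m)
        errs = []
        for snr in (10.0, 20.0, 30.0, np.inf):
            noisy = sf.add_awgn(Y, snr, seed=4)
            init = sf.random_positive_init(noisy, m, seed=5)
            res = sf.run(noisy, m, init, ground_truth=x)
            errs.append(res.final_error)
        assert all(errs[i] >= errs[i + 1] - 1e-12 for i in range(3))


class TestPureAlternation:
    def test_alternation_stalls_where_fusing_succeeds(self):
        # dropping the fusing step leaves the split variables on opposing
        # sides of the solution; the same seeds succeed with fusing on
        stalls = successes = 0
        for t in range(3):
            x = np.random.default_rng(60 + t).uniform(size=64)
            m = sf.sample_masks(64, 4, seed=70 + t)
            Y = sf.forward_intensity(x, m)
            init = sf.random_positive_init(Y, m, seed=80 + t)
            off = sf.run(Y, m, init, sf.SolverConfig(fuse=False, max_outer=600),
                         ground_truth=x)
            on = sf.run(Y, m, init, ground_truth=x)
            stalls += off.final_error > 1e-3
            successes += on.final_error < 1e-6
        assert stalls >= 2
        assert successes == 3
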