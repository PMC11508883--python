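"""Forward-model tests: mask statistics, Parseval conservation, dense-oracle
equivalence of the matrix-free operators, and AWGN calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import splitfuse as sf
from splitfuse.forward import ALPHABETS, realized_snr_db

from conftest import dense_H, dense_sensing_matrix


class TestSampleMasks:
    def test_alphabet_membership_and_unit_modulus(self):
        m = sf.sample_masks(4, 1, seed=0)
        assert m.masks.shape == (1, 4)
        flat = m.masks.ravel()
        assert np.allclose(np.abs(flat), 1.0)
        for w in flat:
            assert np.any(np.isclose(w, ALPHABETS["quaternary"]))

    def test_mask_moments(self):
        # first and second moments vanish; |w|^2 is exactly one
        m = sf.sample_masks(100_000, 1, seed=7)
        w = m.masks.ravel()
        assert abs(w.mean()) < 0.02
        assert abs((w**2).mean()) < 0.02
        assert np.mean(np.abs(w) ** 2) == 1.0

    def test_reproducible_and_distinct_seeds(self):
        a = sf.sample_masks((4, 4), 2, seed=5)
        b = sf.sample_masks((4, 4), 2, seed=5)
        c = sf.sample_masks((4, 4), 2, seed=6)
        assert np.array_equal(a.masks, b.masks)
        assert not np.array_equal(a.masks, c.masks)

    @pytest.mark.parametrize("alphabet", ["binary", "imaginary"])
    def test_variant_alphabets(self, alphabet):
        m = sf.sample_masks(16, 2, seed=1, alphabet=alphabet)
        for w in m.masks.ravel():
            assert np.any(np.isclose(w, ALPHABETS[alphabet]))

    @pytest.mark.parametrize("bad", [(1, 1), (0, 2), (8, 0)])
    def test_invalid_sizes_rejected(self, bad):
        N, K = bad
        with pytest.raises(ValueError):
            sf.sample_masks(N, K)

    def test_npz_roundtrip(self, tmp_path, small_masks):
        p = tmp_path / "masks.npz"
        small_masks.save_npz(p)
        loaded = sf.MaskSet.load_npz(p)
        assert np.array_equal(loaded.masks, small_masks.masks)
        assert loaded.seed == small_masks.seed

    def test_hdf5_roundtrip(self, tmp_path, small_masks):
        p = tmp_path / "masks.h5"
        small_masks.save_hdf5(p)
        loaded = sf.MaskSet.load_hdf5(p)
        assert np.array_equal(loaded.masks, small_masks.masks)


class TestForwardIntensity:
    def test_zero_signal_gives_zero(self, small_masks):
        Y = sf.forward_intensity(np.zeros(8), small_masks)
        assert np.all(Y == 0)

    def test_nonnegative(self, small_masks, small_signal):
        assert np.all(sf.forward_intensity(small_signal, small_masks) >= 0)

    def test_parseval_per_mask(self, small_masks, small_signal):
        Y = sf.forward_intensity(small_signal, small_masks)
        expected = 8 * np.dot(small_signal, small_signal)
        assert np.allclose(Y.sum(axis=0), expected, rtol=1e-12)

    def test_matches_dense_dft(self, rng):
        m = sf.sample_masks(4, 2, seed=11)
        x = rng.normal(size=4)
        Y = sf.forward_intensity(x, m)
        H = dense_H(m)
        dense = np.array([[x @ H[i, j] @ x for j in range(2)] for i in range(4)])
        np.testing.assert_allclose(Y, dense, rtol=1e-9, atol=1e-12)

    def test_2d_layout_parseval(self, rng):
        x = rng.uniform(size=(4, 4))
        m = sf.sample_masks((4, 4), 2, seed=3)
        Y = sf.forward_intensity(x, m)
        assert Y.shape == (16, 2)
        assert np.allclose(Y.sum(axis=0), 16 * np.sum(x**2))

    def test_size_mismatch_rejected(self, small_masks):
        with pytest.raises(ValueError):
            sf.forward_intensity(np.ones(9), small_masks)


class TestBilinear:
    def test_diagonal_case_reproduces_forward(self, small_masks, small_signal):
        B = sf.bilinear_intensity(small_signal, small_signal, small_masks)
        Y = sf.forward_intensity(small_signal, small_masks)
        np.testing.assert_allclose(B, Y, rtol=1e-12)

    def test_symmetry(self, small_masks, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        np.testing.assert_allclose(
            sf.bilinear_intensity(a, b, small_masks),
            sf.bilinear_intensity(b, a, small_masks),
            rtol=1e-12,
        )

    def test_matches_dense_oracle(self, rng):
        m = sf.sample_masks(4, 2, seed=13)
        a, b = rng.normal(size=4), rng.normal(size=4)
        B = sf.bilinear_intensity(a, b, m)
        H = dense_H(m)
        dense = np.array([[a @ H[i, j] @ b for j in range(2)] for i in range(4)])
        np.testing.assert_allclose(B, dense, rtol=1e-9, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_bilinearity_by_superposition(self, seed):
        rng = np.random.default_rng(seed)
        m = sf.sample_masks(8, 2, seed=99)
        a, b1, b2 = rng.normal(size=(3, 8))
        alpha = float(rng.normal())
        lhs = sf.bilinear_intensity(a, b1 + alpha * b2, m)
        rhs = sf.bilinear_intensity(a, b1, m) + alpha * sf.bilinear_intensity(
            a, b2, m
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)


class TestAdjoint:
    def test_zero_residual(self, small_masks, small_signal):
        op = sf.BilinearOperator(small_signal, small_masks)
        out = op.adjoint(np.zeros((8, 3)))
        assert np.all(out == 0)

    def test_inner_product_identity(self, rng, small_masks):
        a, v = rng.normal(size=(2, 8))
        r = rng.normal(size=(8, 3))
        op = sf.BilinearOperator(a, small_masks)
        lhs = float(np.sum(op.apply(v) * r))
        rhs = float(np.dot(v, op.adjoint(r)))
        assert abs(lhs - rhs) <= 1e-9 * max(abs(lhs), 1.0)

    def test_matches_dense_oracle(self, rng):
        m = sf.sample_masks(4, 2, seed=17)
        a = rng.normal(size=4)
        r = rng.normal(size=(4, 2))
        op = sf.BilinearOperator(a, m)
        H = dense_H(m)
        dense = sum(r[i, j] * (H[i, j] @ a) for j in range(2) for i in range(4))
        np.testing.assert_allclose(op.adjoint(r), dense, rtol=1e-9, atol=1e-12)

    def test_apply_matches_dense_rows(self, rng):
        m = sf.sample_masks(4, 2, seed=19)
        a, v = rng.normal(size=(2, 4))
        op = sf.BilinearOperator(a, m)
        Ha = dense_sensing_matrix(a, m)
        np.testing.assert_allclose(
            op.apply(v).T.ravel(), Ha @ v, rtol=1e-9, atol=1e-12
        )

    def test_anchor_reproduces_forward(self, small_masks, small_signal):
        op = sf.BilinearOperator(small_signal, small_masks)
        np.testing.assert_allclose(
            op.apply(small_signal),
            sf.forward_intensity(small_signal, small_masks),
            rtol=1e-12,
        )


class TestAWGN:
    def test_infinite_snr_identity(self, small_masks, small_signal):
        Y = sf.forward_intensity(small_signal, small_masks)
        assert np.array_equal(sf.add_awgn(Y, np.inf), Y)

    def test_realized_snr_close_to_nominal(self, rng):
        x = rng.uniform(size=(64, 64))
        m = sf.sample_masks((64, 64), 4, seed=23)
        Y = sf.forward_intensity(x, m)
        noisy = sf.add_awgn(Y, 20.0, seed=5)
        assert abs(realized_snr_db(Y, noisy) - 20.0) < 0.2

    def test_deterministic_given_seed(self, small_masks, small_signal):
        Y = sf.forward_intensity(small_signal, small_masks)
        a = sf.add_awgn(Y, 15.0, seed=3)
        b = sf.add_awgn(Y, 15.0, seed=3)
        assert np.array_equal(a, b)

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(ValueError):
            sf.add_awgn(np.ones((4, 1)), 0.0)
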