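"""Delay embedding, SVD decomposition and truncated reconstruction."""

import numpy as np
import pytest

from eoflux import (
    DelayEmbeddedMatrix,
    ParameterError,
    SpaceTimeField,
    ValidationError,
    de_embed,
    delay_embed,
    reconstruct,
    select_components,
    svd_decompose,
)


def _field(values):
    values = np.asarray(values, dtype=float)
    return SpaceTimeField(values, np.zeros_like(values, dtype=bool),
                          grid_shape=(values.shape[0], 1),
                          times=np.arange(values.shape[1], dtype=float))


class TestDelayEmbed:
    def test_single_pixel_hankel_block(self):
        emb = delay_embed(_field([[1, 2, 3, 4]]), W=2)
        np.testing.assert_array_equal(emb.data, [[1, 2, 3], [2, 3, 4]])

    def test_w1_is_identity(self, small_field):
        emb = delay_embed(small_field, W=1)
        np.testing.assert_array_equal(emb.data, small_field.values)

    def test_shape_formula(self, rng):
        values = rng.normal(size=(100, 46))
        emb = delay_embed(values, W=4)
        assert emb.data.shape == (400, 43)

    def test_hankel_constraint_within_blocks(self, rng):
        P, N, W = 5, 11, 3
        values = rng.normal(size=(P, N))
        emb = delay_embed(values, W)
        blocks = emb.data.reshape(P, W, N - W + 1)
        for w in range(W):
            for j in range(N - W + 1):
                np.testing.assert_array_equal(blocks[:, w, j], values[:, j + w])

    def test_window_too_large_and_masked_input(self, small_field):
        with pytest.raises(ParameterError):
            delay_embed(small_field, W=small_field.n_times + 1)
        gappy = small_field.copy()
        gappy.mask[0, 0] = True
        with pytest.raises(ValidationError):
            delay_embed(gappy, W=2)
        # W=1 tolerates gaps
        assert delay_embed(gappy, W=1).data.shape == gappy.values.shape


class TestDeEmbed:
    def test_inverse_of_embed(self, rng):
        values = rng.normal(size=(7, 20))
        for W in (1, 2, 4):
            emb = delay_embed(values, W)
            np.testing.assert_allclose(de_embed(emb), values, atol=1e-12)

    def test_antidiagonal_averaging_by_hand(self):
        # inconsistent Hankel block: time 2 is represented by entries 3 and 2.5
        data = np.array([[1.0, 2.0, 3.0], [2.5, 3.0, 4.0]])
        emb = DelayEmbeddedMatrix(data=data, W=2, P=1, N=4)
        np.testing.assert_allclose(de_embed(emb), [[1.0, 2.25, 3.0, 4.0]])

    def test_inconsistent_metadata_rejected(self):
        with pytest.raises(ValidationError):
            DelayEmbeddedMatrix(data=np.zeros((4, 3)), W=2, P=1, N=4)


class TestSVDDecompose:
    def test_rank1_matrix(self, rng):
        u = rng.normal(size=6)
        v = rng.normal(size=9)
        v -= v.mean()  # zero-mean rows survive mean removal intact
        d = svd_decompose(np.outer(u, v))
        assert np.sum(d.S > 1e-10) == 1
        assert d.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_reconstruction_identity(self, rng):
        X = rng.normal(size=(8, 12))
        d = svd_decompose(X)
        full = reconstruct(d, range(d.n_modes))
        np.testing.assert_allclose(full, X, rtol=1e-8, atol=1e-10)

    def test_orthonormal_columns_and_variance_sums(self, rng):
        X = rng.normal(size=(10, 7))
        d = svd_decompose(X)
        np.testing.assert_allclose(d.Z.T @ d.Z, np.eye(d.n_modes), atol=1e-8)
        np.testing.assert_allclose(d.H.T @ d.H, np.eye(d.n_modes), atol=1e-8)
        assert np.all(np.diff(d.S) <= 1e-12)
        assert d.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_squared_singular_values_match_eigensolver(self, rng):
        X = rng.normal(size=(5, 7))
        C = X - X.mean(axis=1, keepdims=True)
        d = svd_decompose(X)
        eigs = np.sort(np.linalg.eigvalsh(C.T @ C))[::-1]
        np.testing.assert_allclose(d.S**2, np.clip(eigs[:d.n_modes], 0, None),
                                   rtol=1e-8, atol=1e-8)

    def test_energy_conservation(self, rng):
        X = rng.normal(size=(9, 14))
        C = X - X.mean(axis=1, keepdims=True)
        d = svd_decompose(X)
        assert np.sum(d.S**2) == pytest.approx(np.sum(C**2), rel=1e-8)

    def test_non_finite_rejected(self):
        from eoflux import NumericError
        with pytest.raises(NumericError):
            svd_decompose(np.array([[1.0, np.nan], [0.0, 1.0]]))

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(6, 8))
        d = svd_decompose(X)
        lead = np.argmax(np.abs(d.Z), axis=0)
        assert np.all(d.Z[lead, np.arange(d.n_modes)] >= 0)


class TestSelectComponents:
    def test_cumulative_threshold(self):
        d = svd_decompose(np.zeros((4, 4)))
        d.S = np.sqrt(np.array([0.5, 0.3, 0.1, 0.1]))
        d.variance_fraction = np.array([0.5, 0.3, 0.1, 0.1])
        assert select_components(d, 0.8) == 2
        assert select_components(d, 0.81) == 3
        assert select_components(d, 1.0) == 4

    def test_threshold_range_validated(self, rng):
        d = svd_decompose(rng.normal(size=(4, 5)))
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(ParameterError):
                select_components(d, bad)


class TestReconstruct:
    def test_empty_set_gives_mean_field(self, rng):
        X = rng.normal(size=(6, 9))
        d = svd_decompose(X)
        np.testing.assert_allclose(reconstruct(d, []),
                                   np.tile(X.mean(axis=1)[:, None], (1, 9)))

    def test_exact_rank2_recovered_by_two_modes(self, rng):
        u = rng.normal(size=(7, 2))
        v = rng.normal(size=(10, 2))
        X = 5.0 + u @ v.T
        d = svd_decompose(X)
        np.testing.assert_allclose(reconstruct(d, [0, 1]), X, rtol=1e-6, atol=1e-8)

    def test_out_of_range_index_rejected(self, rng):
        d = svd_decompose(rng.normal(size=(4, 5)))
        with pytest.raises(ParameterError):
            reconstruct(d, [99])

    def test_error_monotone_in_k(self, rng):
        X = rng.normal(size=(10, 12))
        d = svd_decompose(X)
        errs = [np.linalg.norm(X - reconstruct(d, range(k)))
                for k in range(d.n_modes + 1)]
        assert np.all(np.diff(errs) <= 1e-9)


class TestEndToEnd:
    def test_w1_pipeline_equals_plain_eof(self, small_field):
        """Embed(W=1) -> decompose -> full reconstruct -> de-embed matches plain EOF."""
        plain = reconstruct(svd_decompose(small_field.values),
                            range(min(small_field.values.shape)))
        emb = delay_embed(small_field, W=1)
        d = svd_decompose(emb)
        emb.data = reconstruct(d, range(d.n_modes))
        np.testing.assert_allclose(de_embed(emb), plain, atol=1e-10)

    def test_truncated_reconstruction_matches_eigendecomposition_oracle(self, rng):
        """Truncated SVD reconstructions agree with a brute-force eigensolver route."""
        for _ in range(50):
            m, n = rng.integers(2, 7), rng.integers(2, 9)
            X = rng.integers(-3, 4, size=(m, n)).astype(float)
            C = X - X.mean(axis=1, keepdims=True)
            d = svd_decompose(X)
            # oracle: eigendecomposition of C Cᵀ, project C onto leading eigenvectors
            w, V = np.linalg.eigh(C @ C.T)
            order = np.argsort(w)[::-1]
            V = V[:, order]
            for k in range(1, min(m, n) + 1):
                ours = reconstruct(d, range(k), include_mean=False)
                oracle = V[:, :k] @ (V[:, :k].T @ C)
                denom = max(np.linalg.norm(C), 1e-12)
                # both are the best rank-k approximation; compare via error norms
                assert abs(np.linalg.norm(C - ours) - np.linalg.norm(C - oracle)) \
                    / denom < 1e-8
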