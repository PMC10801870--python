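"""Reservoir readout, dimensionality and kernel-variance machinery."""

import numpy as np
import pytest

from hetsnn.params import DisorderSpec, default_truncation
from hetsnn.reservoir import (OnsetProtocol, collect_responses, fit_readout,
                              kernel_variance, make_target,
                              participation_ratio, predict, response_kernel,
                              test_mse)


def _orthonormal_rows(n, T, scale=None):
    """Rows of sines: orthogonal, zero-mean, unit norm."""
    t = np.arange(T)
    X = np.stack([np.sin(2 * np.pi * (k + 1) * (t + 0.5) / T) for k in range(n)])
    X /= np.linalg.norm(X, axis=1, keepdims=True)
    if scale is not None:
        X = np.asarray(scale)[:, None] * X
    return X


class TestTargets:
    def test_product_sines_zeros(self):
        t = np.arange(0.0, 250.0)
        y = make_target("product_sines", t)
        assert y[0] == 0.0
        # at 25 ms the 20 Hz factor is sin(pi) = 0
        assert y[25] == pytest.approx(0.0, abs=1e-12)

    def test_smoothed_delta_peak_and_mass(self):
        t = np.arange(0.0, 300.0)
        y = make_target("smoothed_delta", t)
        assert np.argmax(y) == 150
        assert np.trapezoid(y, t) == pytest.approx(1.0, abs=1e-3)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            make_target("chirp", np.arange(10.0))


class TestRidgeReadout:
    def test_identity_features_reproduce_target(self):
        X = np.eye(6)
        y = np.arange(6.0)
        model = fit_readout(X, y, gamma=0.0)
        assert np.allclose(model.w, y, atol=1e-12)
        assert test_mse(model, [X], y) < 1e-24

    def test_shrinkage_with_growing_gamma(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 40))
        y = rng.normal(size=40)
        norms = [np.linalg.norm(fit_readout(X, y, g).w)
                 for g in (1e-3, 1.0, 1e3)]
        assert norms[0] > norms[1] > norms[2]

    def test_matches_explicit_solve(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 8))
        y = rng.normal(size=8)
        gamma = 0.1
        model = fit_readout(X, y, gamma)
        w_direct = np.linalg.solve(X @ X.T + gamma * np.eye(5), X @ y)
        assert np.allclose(model.w, w_direct, atol=1e-10)

    def test_matches_sklearn_ridge(self):
        """Independent cross-check against scikit-learn's ridge solver."""
        from sklearn.linear_model import Ridge
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 50))
        y = rng.normal(size=50)
        gamma = 0.37
        model = fit_readout(X, y, gamma)
        ref = Ridge(alpha=gamma, fit_intercept=False, solver="cholesky")
        ref.fit(X.T, y)
        assert np.allclose(model.w, ref.coef_, atol=1e-8)

    def test_trial_concatenation_tiles_target(self):
        X = np.eye(3)
        y = np.array([1.0, 2.0, 3.0])
        model = fit_readout([X, X], y, gamma=0.0)
        assert np.allclose(model.w, y, atol=1e-10)

    def test_singular_gram_advises_regularization(self):
        X = np.ones((4, 3))
        with pytest.raises(np.linalg.LinAlgError, match="gamma"):
            fit_readout(X, np.ones(3), gamma=0.0)


class TestMse:
    def test_exact_reconstruction_is_zero(self):
        X = np.eye(4)
        y = np.ones(4)
        model = fit_readout(X, y, 0.0)
        assert test_mse(model, [X], y) == pytest.approx(0.0, abs=1e-20)

    def test_null_predictor_gives_target_power(self):
        from hetsnn.reservoir import ReadoutModel
        y = np.array([1.0, -2.0, 3.0])
        model = ReadoutModel(w=np.zeros(2), gamma=0.0)
        assert test_mse(model, [np.zeros((2, 3))], y) == pytest.approx(np.mean(y ** 2))

    def test_hand_computed_two_trials(self):
        from hetsnn.reservoir import ReadoutModel
        model = ReadoutModel(w=np.array([1.0]), gamma=0.0)
        y = np.array([0.0, 1.0])
        X1 = np.array([[0.0, 1.0]])   # errors 0, 0
        X2 = np.array([[1.0, 1.0]])   # errors 1, 0
        assert test_mse(model, [X1, X2], y) == pytest.approx(0.25)


class TestParticipationRatio:
    def test_isotropic_covariance_gives_dimension(self):
        X = _orthonormal_rows(4, 200)
        assert participation_ratio(X) == pytest.approx(4.0, abs=1e-6)

    def test_known_spectrum(self):
        X = _orthonormal_rows(3, 300, scale=[np.sqrt(2.0), 1.0, 1.0])
        assert participation_ratio(X) == pytest.approx(16.0 / 6.0, abs=1e-6)

    def test_rank_one_gives_one(self):
        base = _orthonormal_rows(1, 100)[0]
        X = np.stack([base, 2 * base, -base])
        assert participation_ratio(X) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            participation_ratio(np.ones((3, 10)))

    def test_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            X = rng.normal(size=(6, 30))
            d = participation_ratio(X)
            assert 1.0 <= d <= 6.0


class TestResponseKernel:
    def test_projector_for_orthonormal_span(self):
        X = _orthonormal_rows(5, 5)  # full rank, square
        K = response_kernel(X, X, gamma=0.0)
        y = np.arange(5.0)
        assert np.allclose(y @ K, y, atol=1e-8)

    def test_shrinks_with_gamma(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4, 6))
        small = np.abs(response_kernel(X, X, 1e-3)).sum()
        large = np.abs(response_kernel(X, X, 1e3)).sum()
        assert large < small

    def test_toy_matches_explicit_arithmetic(self):
        rng = np.random.default_rng(6)
        Xc = rng.normal(size=(3, 8))
        Xa = rng.normal(size=(3, 4))
        gamma = 0.2
        K = response_kernel(Xa, Xc, gamma)
        K_direct = Xa.T @ np.linalg.inv(Xc @ Xc.T + gamma * np.eye(3)) @ Xa
        assert np.allclose(K, K_direct, atol=1e-10)

    def test_readout_and_kernel_consistent(self):
        """y K equals the readout prediction when the trial is the
        training concatenation."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 20))
        y = rng.normal(size=20)
        gamma = 0.5
        model = fit_readout(X, y, gamma)
        K = response_kernel(X, X, gamma)
        assert np.allclose(predict(model, X), y @ K, atol=1e-10)


class TestKernelVariance:
    def test_identical_kernels_give_zero(self):
        K = np.arange(9.0).reshape(3, 3)
        Q, q = kernel_variance([K, K.copy(), K.copy()])
        assert np.all(Q == 0.0) and q == 0.0

    def test_unit_difference_pair(self):
        K = np.zeros((4, 4))
        Q, q = kernel_variance([K, K + 1.0])
        assert np.all(Q == 1.0)
        assert q == pytest.approx(16.0)

    def test_three_trials_average_over_pairs(self):
        c = 0.6
        K = np.zeros((2, 2))
        Q, q = kernel_variance([K, K, K + c])  # pairwise diffs {0, c, c}
        assert np.allclose(Q, 2 * c / 3)
        assert q == pytest.approx(4 * (2 * c / 3) ** 2)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            kernel_variance([np.zeros((2, 2))])


@pytest.fixture(scope="module")
def tiny_proto():
    return OnsetProtocol(n_onsets=4, n_train=3, n_test=1, burn_in=300.0,
                         post_onset=80.0, onset_span=80.0, n_neurons=80)


class TestCollectResponses:
    def test_deterministic_given_seed(self, rs_adapt, tiny_proto):
        low, high = default_truncation(rs_adapt)
        spec = DisorderSpec("lorentzian", -40.0, 0.5, low, high)
        a = collect_responses(rs_adapt, spec, tiny_proto, 55.0, seed=1)
        b = collect_responses(rs_adapt, spec, tiny_proto, 55.0, seed=1)
        for Xa, Xb in zip(a.X, b.X):
            assert np.array_equal(Xa, Xb)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_shapes_and_split(self, rs_adapt, tiny_proto):
        low, high = default_truncation(rs_adapt)
        spec = DisorderSpec("lorentzian", -40.0, 0.5, low, high)
        rset = collect_responses(rs_adapt, spec, tiny_proto, 55.0, seed=2)
        assert len(rset.X) == 4
        assert all(X.shape == (80, 80) for X in rset.X)
        assert len(rset.train_idx) == 3 and len(rset.test_idx) == 1
        assert set(rset.train_idx) | set(rset.test_idx) == set(range(4))

    def test_mismatched_split_rejected(self):
        with pytest.raises(ValueError):
            OnsetProtocol(n_onsets=10, n_train=8, n_test=3)
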