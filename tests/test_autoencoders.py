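import numpy as np
import pytest

from mkelm import (
    KernelSpec,
    encode,
    fit_elm_ae,
    fit_kelm_ae,
    fit_rekelm_ae,
    fit_rkelm_ae,
    make_random_layer,
    random_map,
    reconstruct,
    reduced_kernel_matrix,
)
from mkelm.autoencoders import EncoderModel, hidden_representation
from mkelm.kernels import ReferenceSet

from _oracles import kernel_loop, map_loop, ridge_lstsq


@pytest.fixture
def X20(rng):
    return rng.normal(size=(20, 3))


class TestElmAe:
    def test_oracle_equivalence(self, X20):
        layer = make_random_layer(3, 12, "gaussian01", "sigmoid", seed=4)
        model = fit_elm_ae(X20, layer, C=10.0)
        H = map_loop(layer.weights, layer.biases, X20)
        assert np.allclose(model.gamma, ridge_lstsq(H, X20, 10.0), atol=1e-6)

    def test_repeated_rows_reconstruct_identically(self):
        X = np.tile(np.array([[0.3, -0.7]]), (6, 1))
        layer = make_random_layer(2, 5, seed=0)
        model = fit_elm_ae(X, layer, C=100.0)
        rec = reconstruct(model, X)
        assert np.isfinite(model.gamma).all()
        assert np.allclose(rec, rec[0])


class TestKelmAe:
    def test_matches_dense_solve_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        spec = KernelSpec("rbf", 1.1)
        model = fit_kelm_ae(X, spec, C=10.0)
        omega = kernel_loop("rbf", 1.1, X, X)
        expected = np.linalg.solve(np.eye(5) / 10.0 + omega, X)
        assert np.allclose(model.gamma, expected, atol=1e-8)

    def test_gamma_shape_is_full_n(self, rng):
        X = rng.normal(size=(9, 4))
        model = fit_kelm_ae(X, KernelSpec("rbf"), C=1.0)
        assert model.gamma.shape == (9, 4)


class TestRkelmAe:
    def test_full_reference_set_recovers_full_kernel(self, rng):
        X = rng.normal(size=(10, 3))
        spec = KernelSpec("rbf", 0.8)
        model = fit_rkelm_ae(X, spec, n_refs=10, C=5.0, seed=1)
        omega_hat = reduced_kernel_matrix(spec, X, model.references)
        full = kernel_loop("rbf", 0.8, X, X)
        # same matrix up to the reference (column) permutation
        assert np.allclose(omega_hat, full[:, model.references.source_indices])

    def test_matches_ridge_oracle(self, rng):
        X = rng.normal(size=(30, 4))
        spec = KernelSpec("rbf", 1.0)
        model = fit_rkelm_ae(X, spec, n_refs=5, C=8.0, seed=3)
        omega_hat = kernel_loop("rbf", 1.0, X, model.references.points)
        assert np.allclose(model.gamma, ridge_lstsq(omega_hat, X, 8.0), atol=1e-6)

    def test_solved_system_is_reference_sized(self, rng):
        model = fit_rkelm_ae(rng.normal(size=(40, 3)), KernelSpec("rbf"), 6, 1.0, 0)
        assert model.gamma.shape == (6, 3)


class TestRekelmAe:
    def test_shape_contract(self, rng):
        X = rng.normal(size=(50, 6))
        model = fit_rekelm_ae(X, L1=60, n_refs=10, kernel=KernelSpec("rbf"), C=1.0, seed=0)
        assert model.random_layer.weights.shape == (60, 6)
        assert model.references.points.shape == (10, 60)
        assert model.gamma.shape == (10, 6)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(25, 4))
        a = fit_rekelm_ae(X, 20, 5, KernelSpec("manhattan"), 2.0, seed=9)
        b = fit_rekelm_ae(X, 20, 5, KernelSpec("manhattan"), 2.0, seed=9)
        assert np.array_equal(a.gamma, b.gamma)

    def test_step_by_step_oracle(self, rng):
        X = rng.normal(size=(25, 4))
        model = fit_rekelm_ae(X, 12, 6, KernelSpec("rbf"), C=4.0, seed=2)
        layer = model.random_layer
        H = map_loop(layer.weights, layer.biases, X)
        omega_hat = kernel_loop("rbf", model.kernel.sigma, H, model.references.points)
        assert np.allclose(model.gamma, ridge_lstsq(omega_hat, X, 4.0), atol=1e-8)

    def test_layer_drawn_from_standard_normal(self, rng):
        model = fit_rekelm_ae(rng.normal(size=(30, 5)), 400, 5, KernelSpec("rbf"), 1.0, 0)
        w = model.random_layer.weights.ravel()
        assert model.random_layer.weight_distribution == "gaussian01"
        assert abs(w.mean()) < 0.1 and abs(w.std() - 1.0) < 0.1


class TestEncodeReconstruct:
    def test_identity_gamma_is_identity_encoding(self):
        model = EncoderModel("elm_ae", np.eye(3), 1.0, 3,
                             random_layer=make_random_layer(3, 3, seed=0))
        X = np.arange(12, dtype=float).reshape(4, 3)
        assert np.array_equal(encode(model, X), X)

    def test_single_row_encoding_length(self, rng):
        X = rng.normal(size=(30, 6))
        model = fit_rekelm_ae(X, 20, 10, KernelSpec("rbf"), 1.0, 0)
        assert encode(model, X[:1]).shape == (1, 10)

    def test_encode_equals_dot_product_loop(self, rng):
        X = rng.normal(size=(8, 3))
        model = fit_rkelm_ae(X, KernelSpec("manhattan"), 4, 1.0, 0)
        enc = encode(model, X)
        manual = np.array([[float(x @ g) for g in model.gamma] for x in X])
        assert np.allclose(enc, manual, atol=1e-12)

    def test_via_kernel_encoding_is_hidden_representation(self, rng):
        X = rng.normal(size=(10, 3))
        model = fit_rkelm_ae(X, KernelSpec("rbf"), 4, 1.0, 0)
        assert np.array_equal(encode(model, X, via_kernel=True),
                              hidden_representation(model, X))

    def test_interpolation_limit_large_c(self, rng):
        X = rng.normal(size=(12, 3))
        model = fit_rkelm_ae(X, KernelSpec("rbf", 1.0), n_refs=12, C=1e9, seed=0)
        rel = np.linalg.norm(reconstruct(model, X) - X) / np.linalg.norm(X)
        assert rel < 1e-3

    def test_full_shrinkage_limit_small_c(self, rng):
        X = rng.normal(size=(12, 3))
        model = fit_rkelm_ae(X, KernelSpec("rbf", 1.0), n_refs=6, C=1e-12, seed=0)
        assert np.linalg.norm(reconstruct(model, X)) < 1e-6

    def test_reconstruction_error_nonincreasing_in_c(self, rng):
        X = rng.normal(size=(30, 4))
        errs = []
        for c in 2.0 ** np.arange(-6, 13, 2):
            model = fit_rekelm_ae(X, 20, 8, KernelSpec("rbf"), float(c), seed=5)
            errs.append(np.linalg.norm(reconstruct(model, X) - X))
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_reference_permutation_permutes_encoding_columns(self, rng):
        X = rng.normal(size=(15, 3))
        model = fit_rkelm_ae(X, KernelSpec("rbf", 1.0), 5, 2.0, seed=1)
        perm = np.array([3, 0, 4, 1, 2])
        refs = model.references
        permuted = EncoderModel(
            model.variant,
            model.gamma,  # gamma rows follow references; permute both
            model.regularization,
            model.input_dim,
            kernel=model.kernel,
            references=ReferenceSet(refs.points[perm], refs.source_indices[perm], refs.seed),
        )
        # hidden (kernel) representation columns permute with the references
        base = hidden_representation(model, X)
        assert np.allclose(hidden_representation(permuted, X), base[:, perm])
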