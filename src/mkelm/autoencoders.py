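"""Kernel and random-map autoencoders solved in closed form.

Four variants, all of which reconstruct the raw input X from some hidden
representation Phi(X) by one ridge solve for the output weights Gamma:

==============  ==========================================  ============
variant         hidden representation Phi(X)                Gamma shape
==============  ==========================================  ============
``elm_ae``      random map H = act(XW^T + b)                L x d
``kelm_ae``     full kernel matrix Omega (N x N)            N x d
``rkelm_ae``    reduced kernel matrix vs N-hat refs         N-hat x d
``rekelm_ae``   reduced kernel matrix of the random map     N-hat x d
==============  ==========================================  ============

``rekelm_ae`` is the reduced *expectation*-kernel autoencoder: inputs
are first expanded through a random hidden layer of L1 nodes (drawn
from N(0,1), sigmoid activation), then similarities to N-hat reference
rows of that mapped matrix are computed with a standard kernel.
Applying a kernel to randomly mapped inputs is a finite-sample
realization of an expectation kernel, so the variant combines random
mapping and similarity mapping in one encoder while keeping the
solved system at N-hat x N-hat.

Encoding of new samples uses X Gamma^T on raw features; an alternative
that uses the sample's kernel row as its feature vector is available via
``encode(..., via_kernel=True)`` but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .errors import DataError, InvalidArgumentError, ShapeError
from .kernels import (
    KernelSpec,
    ReferenceSet,
    reduced_kernel_matrix,
    select_references,
)
from .linalg import RandomLayer, derive_subseeds, make_random_layer, random_map, ridge_solve

VARIANTS = ("elm_ae", "kelm_ae", "rkelm_ae", "rekelm_ae")


@dataclass(frozen=True)
class EncoderModel:
    """One fitted autoencoder: its hidden map and output weights Gamma."""

    variant: str
    gamma: np.ndarray
    regularization: float
    input_dim: int
    random_layer: Optional[RandomLayer] = None
    kernel: Optional[KernelSpec] = None
    references: Optional[ReferenceSet] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InvalidArgumentError(f"unknown variant {self.variant!r}")
        if self.gamma.shape[1] != self.input_dim:
            raise ShapeError("gamma must have one column per input feature")

    @property
    def hidden_dim(self) -> int:
        return self.gamma.shape[0]


def fit_elm_ae(X: np.ndarray, layer: RandomLayer, C: float) -> EncoderModel:
    """Random-map autoencoder: Gamma = ridge solution of H Gamma = X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    H = random_map(layer, X)
    gamma = ridge_solve(H, X, C, form="auto").coefficients
    return EncoderModel(
        variant="elm_ae",
        gamma=gamma,
        regularization=float(C),
        input_dim=X.shape[1],
        random_layer=layer,
        seed=layer.seed,
    )


def fit_kelm_ae(X: np.ndarray, kernel: KernelSpec, C: float) -> EncoderModel:
    """Full kernel autoencoder: Gamma = (I/C + Omega)^{-1} X.

    The full N x N kernel matrix of the training set against itself is
    solved directly, costing O(N^3); the reduced variants below exist
    precisely to avoid this.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise InvalidArgumentError("kelm_ae requires at least 2 samples")
    if C <= 0:
        raise InvalidArgumentError(f"C must be > 0, got {C}")
    kernel = kernel.resolved(X)
    refs = ReferenceSet(X.copy(), np.arange(X.shape[0]), seed=-1)
    omega = reduced_kernel_matrix(kernel, X, refs)
    if not np.isfinite(omega).all():
        raise DataError("non-finite kernel entries")
    G = omega.copy()
    G[np.diag_indices_from(G)] += 1.0 / C
    gamma = scipy.linalg.solve(G, X)
    return EncoderModel(
        variant="kelm_ae",
        gamma=gamma,
        regularization=float(C),
        input_dim=X.shape[1],
        kernel=kernel,
        references=refs,
    )


def fit_rkelm_ae(
    X: np.ndarray, kernel: KernelSpec, n_refs: int, C: float, seed: int
) -> EncoderModel:
    """Reduced kernel autoencoder against N-hat random reference rows of X.

    Gamma = (I/C + Omega-hat^T Omega-hat)^{-1} Omega-hat^T X: the solved
    system is N-hat x N-hat regardless of N.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    refs = select_references(X, n_refs, seed)
    kernel = kernel.resolved(X)
    omega = reduced_kernel_matrix(kernel, X, refs)
    gamma = ridge_solve(omega, X, C, form="gram_p").coefficients
    return EncoderModel(
        variant="rkelm_ae",
        gamma=gamma,
        regularization=float(C),
        input_dim=X.shape[1],
        kernel=kernel,
        references=refs,
        seed=int(seed),
    )


def fit_rekelm_ae(
    X: np.ndarray,
    L1: int,
    n_refs: int,
    kernel: KernelSpec,
    C: float,
    seed: int,
    activation: str = "sigmoid",
) -> EncoderModel:
    """Reduced expectation-kernel autoencoder.

    Steps (deterministic given ``seed``; sub-seed 0 draws the layer,
    sub-seed 1 draws the references):

    1. draw a random layer of L1 nodes from N(0, 1);
    2. map X through it: H (N x L1);
    3. choose N-hat distinct reference rows of H;
    4. build the reduced kernel matrix Omega-hat of H vs the references
       (RBF bandwidth resolved by the median heuristic on H);
    5. Gamma = ridge solution of Omega-hat Gamma = X (gram_p form).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if L1 < 1:
        raise InvalidArgumentError(f"L1 must be >= 1, got {L1}")
    layer_seed, ref_seed = derive_subseeds(seed, 2)
    layer = make_random_layer(
        X.shape[1], L1, distribution="gaussian01", activation=activation, seed=layer_seed
    )
    H = random_map(layer, X)
    refs = select_references(H, n_refs, ref_seed)
    kernel = kernel.resolved(H)
    omega = reduced_kernel_matrix(kernel, H, refs)
    gamma = ridge_solve(omega, X, C, form="gram_p").coefficients
    return EncoderModel(
        variant="rekelm_ae",
        gamma=gamma,
        regularization=float(C),
        input_dim=X.shape[1],
        random_layer=layer,
        kernel=kernel,
        references=refs,
        seed=int(seed),
    )


def hidden_representation(model: EncoderModel, X: np.ndarray) -> np.ndarray:
    """Recompute Phi(X) through the model's stored layer/references."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ShapeError(
            f"X has {X.shape[1]} columns but model expects {model.input_dim}"
        )
    if model.variant == "elm_ae":
        return random_map(model.random_layer, X)
    if model.variant in ("kelm_ae", "rkelm_ae"):
        return reduced_kernel_matrix(model.kernel, X, model.references)
    H = random_map(model.random_layer, X)
    return reduced_kernel_matrix(model.kernel, H, model.references)


def encode(model: EncoderModel, X: np.ndarray, via_kernel: bool = False) -> np.ndarray:
    """Abstract features of X: X Gamma^T (default) or Phi(X) directly.

    The default follows the linear read-out X Gamma^T, applied
    identically to training and unseen rows.  ``via_kernel=True``
    instead returns the sample's hidden (kernel/map) representation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if via_kernel:
        return hidden_representation(model, X)
    if X.shape[1] != model.input_dim:
        raise ShapeError(
            f"X has {X.shape[1]} columns but model expects {model.input_dim}"
        )
    return X @ model.gamma.T


def reconstruct(model: EncoderModel, X: np.ndarray) -> np.ndarray:
    """Reconstruction Phi(X) Gamma, an N x d approximation of X."""
    return hidden_representation(model, X) @ model.gamma
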