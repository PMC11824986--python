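"""Random feature maps and regularized least-squares solving.

Every model in the package reduces to the same two primitives: a fixed
random hidden layer ``h(x) = act(Wx + b)`` and a ridge solve of
``H beta = T`` with regularization ``C``.  The ridge solution has two
algebraically identical closed forms,

    beta = H^T (I/C + H H^T)^{-1} T        (gram over samples, N x N)
    beta = (I/C + H^T H)^{-1} H^T T        (gram over features, p x p)

and the cheaper one is picked automatically based on which Gram matrix
is smaller.  The ``I/C`` convention (identity divided by C, added to the
Gram matrix) is used throughout: larger C means less shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg

from .errors import DataError, InvalidArgumentError, ShapeError

Activation = Literal["sigmoid", "identity"]
WeightDistribution = Literal["gaussian01", "uniform_pm1"]

ACTIVATIONS = ("sigmoid", "identity")
DISTRIBUTIONS = ("gaussian01", "uniform_pm1")


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically safe logistic function 1/(1+exp(-z)).

    Branches on the sign of ``z`` so that ``exp`` is only ever evaluated
    at non-positive arguments; no overflow for any finite input.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class RandomLayer:
    """A fixed random hidden layer: weights W (L x d), biases b (L,).

    Weights and biases are drawn once from ``weight_distribution`` and
    never trained; the layer is fully reproducible from ``seed``.
    """

    weights: np.ndarray
    biases: np.ndarray
    activation: Activation
    weight_distribution: WeightDistribution
    seed: int

    def __post_init__(self) -> None:
        if self.weights.ndim != 2:
            raise ShapeError("weights must be a 2-d matrix")
        if self.weights.shape[0] != self.biases.shape[0]:
            raise ShapeError(
                f"weights rows ({self.weights.shape[0]}) must equal "
                f"biases length ({self.biases.shape[0]})"
            )
        if self.activation not in ACTIVATIONS:
            raise InvalidArgumentError(f"unknown activation {self.activation!r}")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def input_dim(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class RidgeSolution:
    """Output weights of a ridge solve, with the form that produced them."""

    coefficients: np.ndarray
    regularization: float
    solve_form: Literal["gram_n", "gram_p"]

    def __post_init__(self) -> None:
        if self.regularization <= 0:
            raise InvalidArgumentError("regularization C must be > 0")


def make_random_layer(
    input_dim: int,
    n_nodes: int,
    distribution: WeightDistribution = "uniform_pm1",
    activation: Activation = "sigmoid",
    seed: int = 0,
) -> RandomLayer:
    """Draw a random hidden layer with i.i.d. weights and biases.

    ``gaussian01`` draws from N(0, 1); ``uniform_pm1`` draws uniformly
    from (-1, 1).  Both weights and biases come from the same
    distribution, in that order, from a single ``default_rng(seed)``
    stream, so the layer is bit-reproducible.
    """
    if input_dim < 1 or n_nodes < 1:
        raise InvalidArgumentError(
            f"input_dim and n_nodes must be >= 1, got {input_dim}, {n_nodes}"
        )
    if distribution not in DISTRIBUTIONS:
        raise InvalidArgumentError(f"unknown distribution {distribution!r}")
    rng = np.random.default_rng(seed)
    if distribution == "gaussian01":
        weights = rng.standard_normal((n_nodes, input_dim))
        biases = rng.standard_normal(n_nodes)
    else:
        weights = rng.uniform(-1.0, 1.0, size=(n_nodes, input_dim))
        biases = rng.uniform(-1.0, 1.0, size=n_nodes)
    return RandomLayer(weights, biases, activation, distribution, int(seed))


def random_map(layer: RandomLayer, X: np.ndarray) -> np.ndarray:
    """Map samples through the random layer: row i -> act(W x_i + b)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError("X must be a 2-d matrix (N x d)")
    if X.shape[1] != layer.input_dim:
        raise ShapeError(
            f"X has {X.shape[1]} columns but layer expects {layer.input_dim}"
        )
    Z = X @ layer.weights.T + layer.biases
    if layer.activation == "sigmoid":
        return sigmoid(Z)
    return Z


def ridge_solve(
    H: np.ndarray,
    T: np.ndarray,
    C: float,
    form: Literal["gram_n", "gram_p", "auto"] = "auto",
) -> RidgeSolution:
    """Solve min ||H beta - T||_F^2 + (1/C) ||beta||_F^2 in closed form.

    Parameters
    ----------
    H : (N, p) feature matrix.
    T : (N, m) target matrix.
    C : positive regularization parameter; larger C -> weaker shrinkage.
    form : which Gram matrix to invert.  ``auto`` picks ``gram_n`` (the
        N x N system) when N < p, else ``gram_p`` (p x p); both forms
        agree exactly in infinite precision.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    if H.shape[0] != T.shape[0]:
        raise ShapeError(
            f"H has {H.shape[0]} rows but T has {T.shape[0]}"
        )
    if C <= 0:
        raise InvalidArgumentError(f"C must be > 0, got {C}")
    if not (np.isfinite(H).all() and np.isfinite(T).all()):
        raise DataError("non-finite entries in H or T")
    n, p = H.shape
    if form == "auto":
        form = "gram_n" if n < p else "gram_p"
    if form == "gram_n":
        G = H @ H.T
        G[np.diag_indices_from(G)] += 1.0 / C
        coef = H.T @ scipy.linalg.solve(G, T, assume_a="pos")
    elif form == "gram_p":
        G = H.T @ H
        G[np.diag_indices_from(G)] += 1.0 / C
        coef = scipy.linalg.solve(G, H.T @ T, assume_a="pos")
    else:
        raise InvalidArgumentError(f"unknown form {form!r}")
    return RidgeSolution(coef, float(C), form)


def derive_subseeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent component seeds from one master seed.

    Uses ``np.random.SeedSequence(master_seed).generate_state(n)`` and
    consumes the uint32 words in positional order; every consumer of a
    sub-seed documents its position, so any component of a composite
    model can be regenerated in isolation.
    """
    state = np.random.SeedSequence(int(master_seed)).generate_state(n)
    return [int(s) for s in state]
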