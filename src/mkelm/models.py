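"""ELM classifier and the two multi-kernel architectures.

``MKP`` (multi-kernel parallel): one reduced expectation-kernel
autoencoder per kernel, all fitted on the raw input; the classifier
consumes the column-wise concatenation of the *activated* read-outs
sigmoid(X Gamma_i^T), in kernel order.  Passing the read-out through
the hidden activation follows multilayer-ELM convention; without it
every feature block is a rank-<=d linear map of X and kernel diversity
cannot contribute anything to the classifier.

``MKR`` (multi-kernel residual): the autoencoders are stacked in series
with residual connections.  With Y^(0) = X, block i min-max normalizes
the running stream to a [0, 1] view (bounds learned during training and
stored), fits its encoder on that view, and adds the view's
reconstruction back onto the *raw* stream:

    Y^(i) = Y^(i-1) + reconstruct_i( norm_i(Y^(i-1)) ).

Every Y^(i) keeps the input width d; the final classifier consumes the
[0, 1]-normalized Y^(k).  Normalizing the encoder's view (not the
stream) keeps each block's N(0,1)-weight sigmoid layer in its active
regime while preserving the shrinkage limit exactly: as C -> 0 every
reconstruction vanishes and Y^(k) = X.  The residual sum uses the
encoder's dimension-preserving reconstruction (N x d) rather than its
encoding (N x N-hat), which could not be added to the input unless
N-hat = d.

Both architectures share one master seed; sub-seeds are drawn in
positional order (encoder 0 .. k-1, then the classifier), so refitting
any stage reproduces it bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .autoencoders import EncoderModel, encode, fit_rekelm_ae, reconstruct
from .data import MinMaxBounds, apply_minmax, minmax_normalize
from .errors import DegenerateLabelsError, InvalidArgumentError, ShapeError
from .kernels import KernelSpec, n_refs_from_ratio
from .linalg import (
    RandomLayer,
    derive_subseeds,
    make_random_layer,
    random_map,
    ridge_solve,
    sigmoid,
)

TargetCoding = Literal["plus_minus_one", "zero_one"]


@dataclass(frozen=True)
class ELMClassifier:
    """Single-hidden-layer ELM with ridge-solved output weights."""

    hidden_layer: RandomLayer
    beta: np.ndarray
    classes: np.ndarray
    target_coding: TargetCoding
    regularization: float

    def __post_init__(self) -> None:
        if self.beta.shape[0] != self.hidden_layer.n_nodes:
            raise ShapeError("beta rows must equal hidden node count")
        if self.beta.shape[1] != self.classes.shape[0]:
            raise ShapeError("beta columns must equal number of classes")


@dataclass(frozen=True)
class MultiKernelModel:
    """A fitted MKP or MKR model: encoders plus final classifier.

    ``stage_bounds`` (MKR only) holds the per-block [0, 1] view bounds;
    ``final_bounds`` (MKR only) the classifier-input bounds.
    """

    architecture: Literal["mkp", "mkr"]
    encoders: tuple[EncoderModel, ...]
    classifier: ELMClassifier
    r1: float
    r2: float
    seed: int
    stage_bounds: tuple[MinMaxBounds, ...] = field(default_factory=tuple)
    final_bounds: Optional[MinMaxBounds] = None

    @property
    def input_dim(self) -> int:
        return self.encoders[0].input_dim


def one_hot_targets(
    labels: np.ndarray, classes: np.ndarray, coding: TargetCoding
) -> np.ndarray:
    """One-hot target matrix: +1/-1 (default) or 1/0 per class column."""
    idx = np.searchsorted(classes, labels)
    if not np.array_equal(classes[idx], labels):
        raise InvalidArgumentError("labels contain values outside the class list")
    T = np.full(
        (labels.shape[0], classes.shape[0]),
        -1.0 if coding == "plus_minus_one" else 0.0,
    )
    T[np.arange(labels.shape[0]), idx] = 1.0
    return T


def fit_elm_classifier(
    X: np.ndarray,
    labels: Sequence,
    L: int = 1000,
    C: float = 100.0,
    seed: int = 0,
    target_coding: TargetCoding = "plus_minus_one",
) -> ELMClassifier:
    """Fit an ELM classifier: random sigmoid layer, ridge-solved beta.

    Hidden weights are uniform on (-1, 1), the convention for every
    random layer outside the expectation-kernel encoders.  Defaults
    L=1000, C=100 follow the fixed classifier configuration used in the
    comparative experiments.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.shape[0] < 2:
        raise DegenerateLabelsError("need at least 2 classes to fit a classifier")
    layer = make_random_layer(
        X.shape[1], L, distribution="uniform_pm1", activation="sigmoid", seed=seed
    )
    T = one_hot_targets(labels, classes, target_coding)
    H = random_map(layer, X)
    beta = ridge_solve(H, T, C, form="auto").coefficients
    return ELMClassifier(layer, beta, classes, target_coding, float(C))


def predict_scores(model: ELMClassifier, X: np.ndarray) -> np.ndarray:
    """Raw decision scores f(x) = h(x) beta, one column per class."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return random_map(model.hidden_layer, X) @ model.beta


def predict_labels(model: ELMClassifier, X: np.ndarray) -> np.ndarray:
    """Argmax-of-scores class labels (cost-blind decision)."""
    return model.classes[np.argmax(predict_scores(model, X), axis=1)]


def _sizing(X: np.ndarray, r1: float, r2: float) -> tuple[int, int]:
    if r1 <= 0:
        raise InvalidArgumentError(f"R1 must be > 0, got {r1}")
    L1 = max(1, round(r1 * X.shape[1]))
    n_refs = n_refs_from_ratio(r2, X.shape[0])
    return L1, n_refs


def fit_mkp_elm(
    X: np.ndarray,
    labels: Sequence,
    kernels: Sequence[KernelSpec],
    r1: float = 10.0,
    r2: float = 0.05,
    L: int = 1000,
    C: float = 100.0,
    seed: int = 0,
) -> MultiKernelModel:
    """Fit the parallel multi-kernel model.

    Each kernel gets its own reduced expectation-kernel autoencoder with
    identical sizing (L1 = round(R1 d), N-hat = round(R2 N)); the final
    classifier is trained on the activated concatenation
    [sigmoid(X Gamma_1^T), ..., sigmoid(X Gamma_k^T)].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(kernels) < 1:
        raise InvalidArgumentError("at least one kernel is required")
    L1, n_refs = _sizing(X, r1, r2)
    seeds = derive_subseeds(seed, len(kernels) + 1)
    encoders = tuple(
        fit_rekelm_ae(X, L1, n_refs, k, C, s) for k, s in zip(kernels, seeds[:-1])
    )
    features = np.hstack([sigmoid(encode(e, X)) for e in encoders])
    clf = fit_elm_classifier(features, labels, L=L, C=C, seed=seeds[-1])
    return MultiKernelModel("mkp", encoders, clf, float(r1), float(r2), int(seed))


def fit_mkr_elm(
    X: np.ndarray,
    labels: Sequence,
    kernels: Sequence[KernelSpec],
    r1: float = 10.0,
    r2: float = 0.05,
    L: int = 1000,
    C: float = 100.0,
    seed: int = 0,
) -> MultiKernelModel:
    """Fit the residual multi-kernel model (see module docstring)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(kernels) < 1:
        raise InvalidArgumentError("at least one kernel is required")
    L1, n_refs = _sizing(X, r1, r2)
    seeds = derive_subseeds(seed, len(kernels) + 1)
    Y = X
    encoders: list[EncoderModel] = []
    stage_bounds: list[MinMaxBounds] = []
    for k, s in zip(kernels, seeds[:-1]):
        view, bounds = minmax_normalize(Y)
        enc = fit_rekelm_ae(view, L1, n_refs, k, C, s)
        encoders.append(enc)
        stage_bounds.append(bounds)
        Y = Y + reconstruct(enc, view)
    features, final_bounds = minmax_normalize(Y)
    clf = fit_elm_classifier(features, labels, L=L, C=C, seed=seeds[-1])
    return MultiKernelModel(
        "mkr",
        tuple(encoders),
        clf,
        float(r1),
        float(r2),
        int(seed),
        tuple(stage_bounds),
        final_bounds,
    )


def residual_cascade(model: MultiKernelModel, X: np.ndarray) -> np.ndarray:
    """The raw residual stream Y^(k) of an MKR model for given rows.

    Replays the stored per-stage view bounds; as every encoder's C -> 0
    the reconstructions vanish and this returns X unchanged.
    """
    if model.architecture != "mkr":
        raise InvalidArgumentError("residual_cascade is defined for MKR models only")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ShapeError(
            f"X has {X.shape[1]} columns but model expects {model.input_dim}"
        )
    Y = X
    for enc, bounds in zip(model.encoders, model.stage_bounds):
        view = apply_minmax(Y, bounds)
        Y = Y + reconstruct(enc, view)
    return Y


def transform(model: MultiKernelModel, X: np.ndarray) -> np.ndarray:
    """Reproduce the training-time feature path for (possibly unseen) rows.

    MKP: activated concatenated read-outs; MKR: the residual cascade
    Y^(k) mapped through the stored classifier-input normalization.  On
    the training matrix this equals, bit for bit, the features the
    classifier was fitted on.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ShapeError(
            f"X has {X.shape[1]} columns but model expects {model.input_dim}"
        )
    if model.architecture == "mkp":
        return np.hstack([sigmoid(encode(e, X)) for e in model.encoders])
    return apply_minmax(residual_cascade(model, X), model.final_bounds)


def predict_model_scores(model: MultiKernelModel, X: np.ndarray) -> np.ndarray:
    """Classifier scores through the full multi-kernel feature path."""
    return predict_scores(model.classifier, transform(model, X))


def predict_model_labels(model: MultiKernelModel, X: np.ndarray) -> np.ndarray:
    """Argmax class labels through the full multi-kernel feature path."""
    scores = predict_model_scores(model, X)
    return model.classifier.classes[np.argmax(scores, axis=1)]
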