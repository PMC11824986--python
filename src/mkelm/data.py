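"""Synthetic Gaussian-cluster data and the train/test protocol.

The generator emulates the statistical shape of the tabular benchmark
datasets the models target: m Gaussian clusters in d dimensions with
controllable overlap (via the ratio of center separation to noise
standard deviation) and controllable class imbalance (via a proportion
vector).  Class centers are i.i.d. standard normal vectors rescaled so
their mean pairwise distance equals ``cluster_separation``; samples are
drawn isotropically around their class center with standard deviation
``noise_sd``.

The accompanying protocol helpers implement the evaluation pipeline
used throughout: per-feature min-max normalization to [0, 1] with
bounds learned on training data only, and a uniform random 60/40
train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic classification dataset."""

    n_samples: int = 600
    n_features: int = 8
    n_classes: int = 3
    class_proportions: Optional[tuple[float, ...]] = None
    cluster_separation: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise InvalidArgumentError("need at least 2 classes")
        if self.n_samples < self.n_classes:
            raise InvalidArgumentError("need at least one sample per class")
        if self.cluster_separation <= 0 or self.noise_sd <= 0:
            raise InvalidArgumentError("separation and noise_sd must be > 0")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if p.shape[0] != self.n_classes or (p <= 0).any():
                raise InvalidArgumentError("proportions must be n_classes positive values")
            if abs(p.sum() - 1.0) > 1e-9:
                raise InvalidArgumentError("proportions must sum to 1")

    @property
    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_proportions, dtype=float)


def generate_classification_data(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, y) from the Gaussian-cluster model; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    m, d = spec.n_classes, spec.n_features
    centers = rng.standard_normal((m, d))
    diffs = centers[:, None, :] - centers[None, :, :]
    dists = np.linalg.norm(diffs, axis=-1)
    mean_dist = dists[~np.eye(m, dtype=bool)].mean()
    if mean_dist > 0:
        centers *= spec.cluster_separation / mean_dist
    counts = rng.multinomial(spec.n_samples, spec.proportions)
    # multinomial can zero out a tiny class; guarantee presence
    for i in np.flatnonzero(counts == 0):
        counts[i] += 1
        counts[np.argmax(counts)] -= 1
    y = np.repeat(np.arange(m), counts)
    X = centers[y] + spec.noise_sd * rng.standard_normal((spec.n_samples, d))
    perm = rng.permutation(spec.n_samples)
    return X[perm], y[perm]


@dataclass(frozen=True)
class MinMaxBounds:
    """Per-feature training minima/maxima for [0, 1] normalization."""

    minima: np.ndarray
    maxima: np.ndarray


def minmax_normalize(X: np.ndarray) -> tuple[np.ndarray, MinMaxBounds]:
    """Affinely map each column to [0, 1]; constant columns map to 0.

    Returns the normalized matrix and the bounds, to be reapplied to
    held-out data (whose values may then fall outside [0, 1]).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise InvalidArgumentError("need at least one row")
    lo, hi = X.min(axis=0), X.max(axis=0)
    bounds = MinMaxBounds(lo, hi)
    return apply_minmax(X, bounds), bounds


def apply_minmax(X: np.ndarray, bounds: MinMaxBounds) -> np.ndarray:
    """Apply stored normalization bounds to new rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    span = bounds.maxima - bounds.minima
    out = np.zeros_like(X)
    nz = span != 0
    out[:, nz] = (X[:, nz] - bounds.minima[nz]) / span[nz]
    return out

def invert_minmax(Xn: np.ndarray, bounds: MinMaxBounds) -> np.ndarray:
    """Inverse of :func:`apply_minmax` (constant columns restore the minimum)."""
    Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
    span = bounds.maxima - bounds.minima
    return Xn * span + bounds.minima


def split_train_test(
    X: np.ndarray,
    labels: Sequence,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Uniform random split into (X_train, X_test, y_train, y_test).

    Warns (does not fail) if either side is missing a class.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels)
    n = X.shape[0]
    if not 0 < train_fraction < 1:
        raise InvalidArgumentError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise InvalidArgumentError("both split sides must be nonempty")
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    all_classes = set(np.unique(y).tolist())
    for name, part in (("training", y[tr]), ("test", y[te])):
        missing = all_classes - set(np.unique(part).tolist())
        if missing:
            warnings.warn(f"{name} split is missing classes {sorted(missing)}")
    return X[tr], X[te], y[tr], y[te]
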