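"""Similarity/kernel functions and reduced (rectangular) kernel matrices.

Four families are available, mirroring the fusion design of the
multi-kernel models: a Gaussian RBF, raw squared-Euclidean distance, raw
Manhattan distance, and a cosine similarity.  The distance families are
used directly as similarity features without conversion to a decaying
kernel — the downstream ridge solve is indifferent to monotone
orientation.  The cosine family ships in two variants: the "printed"
form divides by the product of *squared* norms, the "standard" form by
the product of norms; the printed form is the default (see the methods
note for the rationale).

A *reduced* kernel matrix is the rectangular N x N-hat similarity matrix
between all samples and a randomly chosen subset of reference points,
the device that makes kernel autoencoders scale past the O(N^3) full
kernel solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .errors import InvalidArgumentError, ShapeError, UndefinedSimilarityError

KERNEL_FAMILIES = (
    "rbf",
    "euclidean_sq",
    "manhattan",
    "cosine_printed",
    "cosine_standard",
)

#: The default four-kernel configuration, in fusion order K1..K4.
DEFAULT_KERNEL_ORDER = ("rbf", "euclidean_sq", "manhattan", "cosine_printed")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its bandwidth (RBF only).

    ``sigma`` is required and positive iff ``family == "rbf"``; a spec
    with ``sigma=None`` for RBF is allowed as a placeholder and is
    resolved by the median heuristic at fit time.
    """

    family: str
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise InvalidArgumentError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf":
            if self.sigma is not None and self.sigma <= 0:
                raise InvalidArgumentError("rbf sigma must be > 0")
        elif self.sigma is not None:
            raise InvalidArgumentError(f"sigma is only meaningful for rbf, not {self.family}")

    def resolved(self, X: np.ndarray) -> "KernelSpec":
        """Return a spec with sigma fixed (median heuristic) if unset."""
        if self.family == "rbf" and self.sigma is None:
            return KernelSpec("rbf", median_heuristic_sigma(X))
        return self


@dataclass(frozen=True)
class ReferenceSet:
    """Reference points for reduced kernel construction.

    Points are stored by value so a fitted encoder survives
    serialization without the training data; ``source_indices`` records
    where each row came from in the matrix it was drawn from.
    """

    points: np.ndarray
    source_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.points.shape[0] != self.source_indices.shape[0]:
            raise ShapeError("one source index per reference point required")
        if len(set(self.source_indices.tolist())) != self.source_indices.shape[0]:
            raise InvalidArgumentError("source_indices must be distinct")

    @property
    def n_refs(self) -> int:
        return self.points.shape[0]


def median_heuristic_sigma(X: np.ndarray, max_rows: int = 500) -> float:
    """Median pairwise Euclidean distance of the rows of X.

    For matrices with more than ``max_rows`` rows, an evenly spaced
    deterministic subsample is used.  Falls back to 1.0 when the median
    distance is zero (all rows identical).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] > max_rows:
        idx = np.linspace(0, X.shape[0] - 1, max_rows).astype(int)
        X = X[idx]
    if X.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(X)))
    return med if med > 0 else 1.0


def n_refs_from_ratio(r2: float, n: int) -> int:
    """Reference count N-hat = round(R2 * N), clamped to [1, N]."""
    if not 0 < r2 <= 1:
        raise InvalidArgumentError(f"R2 must be in (0, 1], got {r2}")
    return int(min(max(round(r2 * n), 1), n))


def kernel_value(spec: KernelSpec, x: np.ndarray, r: np.ndarray) -> float:
    """Evaluate K(x, r) for a single pair of vectors.

    All families are symmetric in (x, r).  Cosine families raise
    :class:`UndefinedSimilarityError` on a zero vector.
    """
    x = np.asarray(x, dtype=float).ravel()
    r = np.asarray(r, dtype=float).ravel()
    if x.shape != r.shape:
        raise ShapeError(f"x and r must have equal length ({x.shape} vs {r.shape})")
    return float(reduced_kernel_matrix_pointwise(spec, x[None, :], r[None, :])[0, 0])


def reduced_kernel_matrix(
    spec: KernelSpec, X: np.ndarray, refs: ReferenceSet
) -> np.ndarray:
    """Rectangular kernel matrix, entry (i, j) = K(x_i, ref_j)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    R = refs.points
    if X.shape[1] != R.shape[1]:
        raise ShapeError(
            f"X has {X.shape[1]} columns but references have {R.shape[1]}"
        )
    return reduced_kernel_matrix_pointwise(spec, X, R)


def reduced_kernel_matrix_pointwise(
    spec: KernelSpec, X: np.ndarray, R: np.ndarray
) -> np.ndarray:
    """Vectorized kernel matrix between two raw row matrices."""
    if spec.family == "rbf":
        if spec.sigma is None:
            raise InvalidArgumentError("rbf sigma unresolved; call spec.resolved(X)")
        sq = cdist(X, R, metric="sqeuclidean")
        return np.exp(-sq / (2.0 * spec.sigma**2))
    if spec.family == "euclidean_sq":
        return cdist(X, R, metric="sqeuclidean")
    if spec.family == "manhattan":
        return cdist(X, R, metric="cityblock")
    # cosine families
    xn = np.linalg.norm(X, axis=1)
    rn = np.linalg.norm(R, axis=1)
    if np.any(xn == 0) or np.any(rn == 0):
        raise UndefinedSimilarityError("cosine similarity undefined for zero vectors")
    dots = X @ R.T
    if spec.family == "cosine_printed":
        return dots / (xn[:, None] ** 2 * rn[None, :] ** 2)
    return dots / (xn[:, None] * rn[None, :])


def select_references(X: np.ndarray, n_refs: int, seed: int) -> ReferenceSet:
    """Uniformly sample ``n_refs`` distinct rows of X without replacement."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 1 <= n_refs <= n:
        raise InvalidArgumentError(
            f"n_refs must be in [1, {n}], got {n_refs}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_refs, replace=False)
    return ReferenceSet(X[idx].copy(), idx.astype(int), int(seed))
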