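"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: explicit Python loops for maps and kernels, and an
augmented-system least-squares route (SVD-based ``lstsq`` on
[H; I/sqrt(C)]) for every ridge solve — no Gram-matrix inverses, so the
numerical path is disjoint from the package's closed-form solvers.
"""

import math

import numpy as np


def ridge_lstsq(H: np.ndarray, T: np.ndarray, C: float) -> np.ndarray:
    """min ||H b - T||^2 + (1/C)||b||^2 via the augmented system."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    p = H.shape[1]
    A = np.vstack([H, np.eye(p) / math.sqrt(C)])
    B = np.vstack([T, np.zeros((p, T.shape[1]))])
    return np.linalg.lstsq(A, B, rcond=None)[0]


def weighted_ridge_lstsq(
    H: np.ndarray, T: np.ndarray, w: np.ndarray, C: float
) -> np.ndarray:
    """min sum_i w_i ||h_i b - t_i||^2 + (1/C)||b||^2 via sqrt-weight rows."""
    s = np.sqrt(np.asarray(w, dtype=float))[:, None]
    p = H.shape[1]
    A = np.vstack([H * s, np.eye(p) / math.sqrt(C)])
    B = np.vstack([np.asarray(T, dtype=float) * s, np.zeros((p, T.shape[1]))])
    return np.linalg.lstsq(A, B, rcond=None)[0]


def map_loop(weights: np.ndarray, biases: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Scalar-loop sigmoid random map."""
    n, L = X.shape[0], weights.shape[0]
    out = np.empty((n, L))
    for i in range(n):
        for j in range(L):
            z = float(np.dot(weights[j], X[i]) + biases[j])
            out[i, j] = 1.0 / (1.0 + math.exp(-z)) if z >= 0 else math.exp(z) / (1.0 + math.exp(z))
    return out


def kernel_scalar(family: str, sigma, x: np.ndarray, r: np.ndarray) -> float:
    d = x - r
    if family == "rbf":
        return math.exp(-float(d @ d) / (2.0 * sigma**2))
    if family == "euclidean_sq":
        return float(d @ d)
    if family == "manhattan":
        return float(np.abs(d).sum())
    nx, nr = math.sqrt(float(x @ x)), math.sqrt(float(r @ r))
    dot = float(x @ r)
    if family == "cosine_printed":
        return dot / (nx**2 * nr**2)
    if family == "cosine_standard":
        return dot / (nx * nr)
    raise ValueError(family)


def kernel_loop(family: str, sigma, X: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Double-loop kernel matrix."""
    out = np.empty((X.shape[0], R.shape[0]))
    for i in range(X.shape[0]):
        for j in range(R.shape[0]):
            out[i, j] = kernel_scalar(family, sigma, X[i], R[j])
    return out
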