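"""Cost matrices, posterior conversion, minimum-risk decisions, metrics.

The decision layer turns raw classifier scores into class posteriors
(per-class sigmoid, then row normalization) and picks, per sample, the
class j* minimizing the expected misclassification cost
sum_i P(i|x) c_ij over an m x m cost matrix with c_ij the cost of
predicting class j when the truth is class i.  With 0-1 costs this
reduces exactly to the argmax (MAP) rule; with asymmetric costs it
trades raw accuracy for total cost.

Also housed here: the cost/imbalance sample-weighting schemes used by
weighted-ELM baselines, the CELM baseline itself, and the evaluation
metrics (accuracy, total misclassification cost Tc, and relative
performance r = Tc / worst Tc across compared methods).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from sklearn.metrics import confusion_matrix

from .errors import DegenerateLabelsError, InvalidArgumentError, ShapeError
from .linalg import make_random_layer, random_map, sigmoid
from .models import ELMClassifier, one_hot_targets

COST_FAMILIES = ("uniform_range", "type_a", "type_b", "type_c")
WEIGHT_SCHEMES = ("class_balance", "per_sample_cost", "row_sum", "helm")

_POSTERIOR_FLOOR = 1e-12


@dataclass(frozen=True)
class CostMatrix:
    """m x m misclassification costs; c_ij = cost of truth i predicted j."""

    costs: np.ndarray
    class_order: np.ndarray

    def __post_init__(self) -> None:
        c = self.costs
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ShapeError("cost matrix must be square")
        if c.shape[0] != self.class_order.shape[0]:
            raise ShapeError("one class label per cost row required")
        if not np.isfinite(c).all() or (c < 0).any():
            raise InvalidArgumentError("costs must be finite and >= 0")
        off = c[~np.eye(c.shape[0], dtype=bool)]
        if off.size and not (off > 0).any():
            raise InvalidArgumentError("at least one off-diagonal cost must be > 0")

    @property
    def n_classes(self) -> int:
        return self.costs.shape[0]


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts plus the three summary metrics."""

    confusion: np.ndarray
    acc: float
    total_cost: float
    class_order: np.ndarray
    relative_performance: Optional[float] = None


def zero_one_costs(m: int, class_order: Optional[Sequence] = None) -> CostMatrix:
    """The 0-1 cost matrix under which minimum risk equals argmax."""
    order = np.arange(m) if class_order is None else np.asarray(class_order)
    return CostMatrix(np.ones((m, m)) - np.eye(m), order)


def make_cost_matrix(
    m: int,
    family: str = "uniform_range",
    max_cost: float = 20.0,
    seed: int = 0,
    class_counts: Optional[Sequence[int]] = None,
    class_order: Optional[Sequence] = None,
) -> CostMatrix:
    """Generate a random cost matrix with zero diagonal.

    Families
    --------
    uniform_range
        Off-diagonal integers uniform in [1, max_cost] (default 20).
    type_a
        Off-diagonal integers uniform in [1, 10].
    type_b
        Row severity: each true class i draws one integer severity
        s_i in [1, 10] and c_ij = s_i for all j != i.
    type_c
        Imbalance-linked: c_ij proportional to 1/count of class i,
        rescaled so the maximum off-diagonal cost is 10; requires
        ``class_counts``.

    The three typed families are stand-ins for cost-matrix designs whose
    exact construction is not published; see the methods note.
    """
    if m < 2:
        raise InvalidArgumentError(f"need m >= 2 classes, got {m}")
    if family not in COST_FAMILIES:
        raise InvalidArgumentError(f"unknown cost family {family!r}")
    order = np.arange(m) if class_order is None else np.asarray(class_order)
    rng = np.random.default_rng(seed)
    off = ~np.eye(m, dtype=bool)
    costs = np.zeros((m, m))
    if family == "uniform_range":
        costs[off] = rng.integers(1, int(max_cost) + 1, size=off.sum()).astype(float)
    elif family == "type_a":
        costs[off] = rng.integers(1, 11, size=off.sum()).astype(float)
    elif family == "type_b":
        sev = rng.integers(1, 11, size=m).astype(float)
        costs = np.repeat(sev[:, None], m, axis=1)
        np.fill_diagonal(costs, 0.0)
    else:
        if class_counts is None:
            raise InvalidArgumentError("type_c requires class_counts")
        counts = np.asarray(class_counts, dtype=float)
        if counts.shape[0] != m or (counts <= 0).any():
            raise InvalidArgumentError("class_counts must be m positive counts")
        inv = 1.0 / counts
        costs = np.repeat(inv[:, None], m, axis=1) * (10.0 / inv.max())
        np.fill_diagonal(costs, 0.0)
    return CostMatrix(costs, order)


def scores_to_posteriors(scores: np.ndarray) -> np.ndarray:
    """Per-class sigmoid of the scores, row-normalized to sum to 1.

    Probabilities are clamped to [1e-12, 1 - 1e-12] before
    normalization so downstream risks stay finite.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if not np.isfinite(scores).all():
        raise InvalidArgumentError("scores must be finite")
    p = np.clip(sigmoid(scores), _POSTERIOR_FLOOR, 1.0 - _POSTERIOR_FLOOR)
    return p / p.sum(axis=1, keepdims=True)


def min_risk_decide(posteriors: np.ndarray, cost: CostMatrix) -> np.ndarray:
    """Per row, the class minimizing expected cost sum_i P(i|x) c_ij.

    Ties break to the lowest class index (np.argmin convention).
    """
    posteriors = np.atleast_2d(np.asarray(posteriors, dtype=float))
    if posteriors.shape[1] != cost.n_classes:
        raise ShapeError(
            f"posteriors have {posteriors.shape[1]} classes, cost matrix {cost.n_classes}"
        )
    risks = posteriors @ cost.costs
    return cost.class_order[np.argmin(risks, axis=1)]


def compute_cost_weights(
    labels: Sequence, cost: Optional[CostMatrix], scheme: str
) -> np.ndarray:
    """Per-sample positive weights under one of four schemes.

    class_balance
        w_i = N_min / N_{y_i} — inverse class frequency, minority = 1.
    per_sample_cost / row_sum
        w_i = sum_j c_{y_i, j} — the true-class row sum of the cost
        matrix.  The two names coincide here: the per-sample cost c_i of
        the weighted-error formulation is resolved as the row sum, the
        same quantity the later row-sum scheme makes explicit.
    helm
        w_i = 1 / (p + (N_{y_i} - p) N_{y_i} / max_j N_{y_j}) with
        p = N - N_{y_i}; a hierarchical-ELM weighting that interpolates
        between inverse-complement and inverse-own-count (the printed
        formula is ambiguous; this reading is positive for every class
        distribution).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise InvalidArgumentError("labels must be nonempty")
    if scheme not in WEIGHT_SCHEMES:
        raise InvalidArgumentError(f"unknown weighting scheme {scheme!r}")
    classes, counts = np.unique(labels, return_counts=True)
    idx = np.searchsorted(classes, labels)
    if scheme == "class_balance":
        return counts.min() / counts[idx].astype(float)
    if scheme == "helm":
        n = labels.shape[0]
        p = n - counts.astype(float)
        denom = p + (counts - p) * counts / counts.max()
        return (1.0 / denom)[idx]
    if cost is None:
        raise InvalidArgumentError(f"scheme {scheme!r} requires a cost matrix")
    order_idx = np.searchsorted(cost.class_order, classes)
    if not np.array_equal(cost.class_order[order_idx], classes):
        raise InvalidArgumentError("labels contain classes absent from the cost matrix")
    row_sums = cost.costs.sum(axis=1)[order_idx]
    return row_sums[idx]


def fit_celm(
    X: np.ndarray,
    labels: Sequence,
    cost: CostMatrix,
    L: int = 1000,
    C: float = 100.0,
    seed: int = 0,
) -> ELMClassifier:
    """Cost-weighted ELM baseline.

    Solves the weighted ridge system
    beta = (I/C + H^T D H)^{-1} H^T D T with D the diagonal of
    true-class row-sum cost weights, so samples of expensive classes
    contribute more to the squared error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.shape[0] < 2:
        raise DegenerateLabelsError("need at least 2 classes")
    layer = make_random_layer(
        X.shape[1], L, distribution="uniform_pm1", activation="sigmoid", seed=seed
    )
    H = random_map(layer, X)
    T = one_hot_targets(labels, classes, "plus_minus_one")
    w = compute_cost_weights(labels, cost, "row_sum")
    Hw = H * w[:, None]
    G = H.T @ Hw
    G[np.diag_indices_from(G)] += 1.0 / C
    beta = scipy.linalg.solve(G, Hw.T @ T, assume_a="pos")
    return ELMClassifier(layer, beta, classes, "plus_minus_one", float(C))


def evaluate(
    true_labels: Sequence, predicted_labels: Sequence, cost: CostMatrix
) -> EvaluationReport:
    """Confusion counts, accuracy, and total misclassification cost.

    acc = 1 - (# errors)/N;  Tc = sum_ij err_ij c_ij, where err_ij
    counts samples of true class i predicted as class j.
    """
    y = np.asarray(true_labels)
    yhat = np.asarray(predicted_labels)
    if y.shape[0] != yhat.shape[0]:
        raise ShapeError("true and predicted label lengths differ")
    known = np.isin(y, cost.class_order) & np.isin(yhat, cost.class_order)
    if not known.all():
        raise InvalidArgumentError("labels outside the cost matrix class order")
    conf = confusion_matrix(y, yhat, labels=cost.class_order)
    n = conf.sum()
    acc = float(np.trace(conf)) / n
    off = ~np.eye(cost.n_classes, dtype=bool)
    tc = float((conf[off] * cost.costs[off]).sum())
    return EvaluationReport(conf, acc, tc, cost.class_order.copy())


def relative_performance(costs_by_method: Sequence[float]) -> list[float]:
    """Each method's Tc divided by the worst (maximum) Tc; worst = 1."""
    tc = np.asarray(costs_by_method, dtype=float)
    if tc.size == 0 or (tc < 0).any():
        raise InvalidArgumentError("need a nonempty list of nonnegative costs")
    if tc.max() == 0:
        raise InvalidArgumentError("relative performance undefined when every Tc is 0")
    return (tc / tc.max()).tolist()
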