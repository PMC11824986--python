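"""Serialization: model archives, cost matrices, delimited datasets.

Model archives are versioned JSON documents holding every random layer,
reference set, kernel spec, output matrix and seed, so a loaded model
reproduces predictions bit-identically without the training data.  All
writes are atomic: content goes to a temporary file in the destination
directory, then ``os.replace`` moves it into place.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .autoencoders import EncoderModel
from .cost import CostMatrix
from .data import MinMaxBounds
from .errors import ArchiveError, InvalidArgumentError
from .kernels import KernelSpec, ReferenceSet
from .linalg import RandomLayer
from .models import ELMClassifier, MultiKernelModel

ARCHIVE_VERSION = 1
PathLike = Union[str, Path]


def atomic_write_text(path: PathLike, content: str) -> None:
    """Write text to ``path`` via a temp file + rename (atomic on POSIX)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _arr(a: np.ndarray) -> list:
    return np.asarray(a).tolist()


def _layer_to_dict(layer: Optional[RandomLayer]) -> Optional[dict]:
    if layer is None:
        return None
    return {
        "weights": _arr(layer.weights),
        "biases": _arr(layer.biases),
        "activation": layer.activation,
        "weight_distribution": layer.weight_distribution,
        "seed": layer.seed,
    }


def _layer_from_dict(d: Optional[dict]) -> Optional[RandomLayer]:
    if d is None:
        return None
    return RandomLayer(
        np.asarray(d["weights"], dtype=float),
        np.asarray(d["biases"], dtype=float),
        d["activation"],
        d["weight_distribution"],
        int(d["seed"]),
    )


def _refs_to_dict(refs: Optional[ReferenceSet]) -> Optional[dict]:
    if refs is None:
        return None
    return {
        "points": _arr(refs.points),
        "source_indices": _arr(refs.source_indices),
        "seed": refs.seed,
    }


def _refs_from_dict(d: Optional[dict]) -> Optional[ReferenceSet]:
    if d is None:
        return None
    return ReferenceSet(
        np.asarray(d["points"], dtype=float),
        np.asarray(d["source_indices"], dtype=int),
        int(d["seed"]),
    )


def _kernel_to_dict(k: Optional[KernelSpec]) -> Optional[dict]:
    if k is None:
        return None
    return {"family": k.family, "sigma": k.sigma}


def _kernel_from_dict(d: Optional[dict]) -> Optional[KernelSpec]:
    if d is None:
        return None
    return KernelSpec(d["family"], d["sigma"])


def _encoder_to_dict(e: EncoderModel) -> dict:
    return {
        "variant": e.variant,
        "gamma": _arr(e.gamma),
        "regularization": e.regularization,
        "input_dim": e.input_dim,
        "random_layer": _layer_to_dict(e.random_layer),
        "kernel": _kernel_to_dict(e.kernel),
        "references": _refs_to_dict(e.references),
        "seed": e.seed,
    }


def _encoder_from_dict(d: dict) -> EncoderModel:
    return EncoderModel(
        variant=d["variant"],
        gamma=np.asarray(d["gamma"], dtype=float),
        regularization=float(d["regularization"]),
        input_dim=int(d["input_dim"]),
        random_layer=_layer_from_dict(d["random_layer"]),
        kernel=_kernel_from_dict(d["kernel"]),
        references=_refs_from_dict(d["references"]),
        seed=d["seed"],
    )


def _classifier_to_dict(c: ELMClassifier) -> dict:
    return {
        "hidden_layer": _layer_to_dict(c.hidden_layer),
        "beta": _arr(c.beta),
        "classes": _arr(c.classes),
        "target_coding": c.target_coding,
        "regularization": c.regularization,
    }


def _classifier_from_dict(d: dict) -> ELMClassifier:
    return ELMClassifier(
        _layer_from_dict(d["hidden_layer"]),
        np.asarray(d["beta"], dtype=float),
        np.asarray(d["classes"]),
        d["target_coding"],
        float(d["regularization"]),
    )


def _bounds_to_dict(b: Optional[MinMaxBounds]) -> Optional[dict]:
    if b is None:
        return None
    return {"minima": _arr(b.minima), "maxima": _arr(b.maxima)}


def _bounds_from_dict(d: Optional[dict]) -> Optional[MinMaxBounds]:
    if d is None:
        return None
    return MinMaxBounds(
        np.asarray(d["minima"], dtype=float), np.asarray(d["maxima"], dtype=float)
    )


def save_model(
    model: MultiKernelModel,
    path: PathLike,
    bounds: Optional[MinMaxBounds] = None,
) -> None:
    """Serialize a fitted multi-kernel model (optionally with its
    input feature-normalization bounds) to a JSON archive."""
    doc = {
        "format": "mkelm-model",
        "version": ARCHIVE_VERSION,
        "architecture": model.architecture,
        "r1": model.r1,
        "r2": model.r2,
        "seed": model.seed,
        "encoders": [_encoder_to_dict(e) for e in model.encoders],
        "classifier": _classifier_to_dict(model.classifier),
        "stage_bounds": [_bounds_to_dict(b) for b in model.stage_bounds],
        "final_bounds": _bounds_to_dict(model.final_bounds),
        "bounds": _bounds_to_dict(bounds),
    }
    atomic_write_text(path, json.dumps(doc))


def load_model(path: PathLike) -> tuple[MultiKernelModel, Optional[MinMaxBounds]]:
    """Load a model archive; raises :class:`ArchiveError` on corruption
    or version mismatch, never returning a partial model."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ArchiveError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "mkelm-model":
        raise ArchiveError(f"{path} is not an mkelm model archive")
    if doc.get("version") != ARCHIVE_VERSION:
        raise ArchiveError(
            f"archive version {doc.get('version')} unsupported (expected {ARCHIVE_VERSION})"
        )
    try:
        model = MultiKernelModel(
            architecture=doc["architecture"],
            encoders=tuple(_encoder_from_dict(e) for e in doc["encoders"]),
            classifier=_classifier_from_dict(doc["classifier"]),
            r1=float(doc["r1"]),
            r2=float(doc["r2"]),
            seed=int(doc["seed"]),
            stage_bounds=tuple(_bounds_from_dict(b) for b in doc["stage_bounds"]),
            final_bounds=_bounds_from_dict(doc["final_bounds"]),
        )
        bounds = _bounds_from_dict(doc.get("bounds"))
    except (KeyError, TypeError, ValueError) as exc:
        raise ArchiveError(f"corrupt model archive {path}: {exc}") from exc
    return model, bounds


def save_cost_matrix(cost: CostMatrix, path: PathLike) -> None:
    """Write a cost matrix as CSV with a header row of class labels."""
    df = pd.DataFrame(
        cost.costs,
        columns=[str(c) for c in cost.class_order],
        index=[str(c) for c in cost.class_order],
    )
    atomic_write_text(path, df.to_csv(index_label="class"))


def load_cost_matrix(path: PathLike) -> CostMatrix:
    """Read a cost matrix CSV written by :func:`save_cost_matrix`."""
    df = pd.read_csv(path, index_col="class")
    order = np.array([_maybe_int(c) for c in df.columns])
    return CostMatrix(df.to_numpy(dtype=float), order)


def _maybe_int(label: str):
    try:
        return int(label)
    except (TypeError, ValueError):
        return label


def save_dataset(
    X: np.ndarray, labels: np.ndarray, path: PathLike, label_column: str = "label"
) -> None:
    """Write features + labels as CSV (features f0..f{d-1}, label column)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df[label_column] = np.asarray(labels)
    atomic_write_text(path, df.to_csv(index=False))


def load_dataset(
    path: PathLike, label_column: str = "label"
) -> tuple[np.ndarray, np.ndarray]:
    """Read a delimited dataset; returns (X, labels)."""
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise InvalidArgumentError(
            f"dataset {path} has no {label_column!r} column"
        )
    y = df[label_column].to_numpy()
    X = df.drop(columns=[label_column]).to_numpy(dtype=float)
    return X, y
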