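"""Class-weighted kernel SVM: kernels, scaling, decision rule, persistence.

Kernels (x.z denotes the inner product):

* linear      K = x.z
* polynomial  K = (gamma * x.z + r)^d
* rbf         K = exp(-gamma * ||x - z||^2)
* sigmoid     K = tanh(gamma * x.z + r)

Defaults mirror the SVMlight-style flag mapping g->gamma (1e-4), c->C (5),
j->positive-class cost multiplier (3), t=2->rbf.  Features are used raw by
default (an SVMlight convention the tiny default gamma is calibrated to:
min-max compression to [0,1] makes the RBF kernel numerically constant at
gamma=1e-4); optional min-max scaling to [0,1] is fitted on the training
fold only and stored inside the model.  The quadratic program is delegated
to scikit-learn's SVC; kernels, class weighting, scaling, the
positive-score decision rule and model persistence are owned and tested
here.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .features import FeatureCatalog, LabeledSet

__all__ = [
    "KernelSpec",
    "SVMModel",
    "kernel",
    "kernel_matrix",
    "train",
    "decision_score",
    "classify",
    "DEFAULT_GAMMA",
    "DEFAULT_C",
    "DEFAULT_J",
]

KERNEL_KINDS = ("linear", "polynomial", "rbf", "sigmoid")

DEFAULT_GAMMA = 1e-4
DEFAULT_C = 5.0
DEFAULT_J = 3.0


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "rbf"
    gamma: float = DEFAULT_GAMMA
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kernel kind must be one of {KERNEL_KINDS}")
        if self.kind != "linear" and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("degree must be >= 1")

    @property
    def sklearn_name(self) -> str:
        return {"polynomial": "poly"}.get(self.kind, self.kind)


def kernel(x, z, spec: KernelSpec) -> float:
    """Evaluate the kernel on two vectors."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    if spec.kind == "linear":
        return float(x @ z)
    if spec.kind == "polynomial":
        return float((spec.gamma * (x @ z) + spec.coef0) ** spec.degree)
    if spec.kind == "rbf":
        d = x - z
        return float(np.exp(-spec.gamma * (d @ d)))
    return float(np.tanh(spec.gamma * (x @ z) + spec.coef0))


def kernel_matrix(X, Z, spec: KernelSpec) -> np.ndarray:
    """Gram matrix K[i, j] = kernel(X[i], Z[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    G = X @ Z.T
    if spec.kind == "linear":
        return G
    if spec.kind == "polynomial":
        return (spec.gamma * G + spec.coef0) ** spec.degree
    if spec.kind == "sigmoid":
        return np.tanh(spec.gamma * G + spec.coef0)
    sq = (
        np.sum(X * X, axis=1)[:, None] - 2 * G + np.sum(Z * Z, axis=1)[None, :]
    )
    return np.exp(-spec.gamma * np.maximum(sq, 0.0))


@dataclass
class MinMaxScaler01:
    """Min-max scaling to [0,1]; constant features map to 0."""

    mins: np.ndarray
    ranges: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler01":
        mins = X.min(axis=0)
        ranges = X.max(axis=0) - mins
        return cls(mins=mins, ranges=ranges)

    @classmethod
    def identity(cls, dim: int) -> "MinMaxScaler01":
        return cls(mins=np.zeros(dim), ranges=np.ones(dim))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        safe = np.where(self.ranges > 0, self.ranges, 1.0)
        out = (X - self.mins) / safe
        out[:, self.ranges == 0] = 0.0
        return out


@dataclass
class SVMModel:
    kernel: KernelSpec
    C: float
    j: float
    support_vectors: np.ndarray  # scaled space
    dual_coef: np.ndarray  # alpha_i * y_i
    bias: float
    scaler: MinMaxScaler01
    catalog_hash: str
    metadata: dict = field(default_factory=dict)

    def decision(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = self.scaler.transform(X)
        K = kernel_matrix(Xs, self.support_vectors, self.kernel)
        return K @ self.dual_coef + self.bias

    def save(self, path) -> None:
        payload = {
            "format_version": 1,
            "kernel": {
                "kind": self.kernel.kind,
                "gamma": self.kernel.gamma,
                "degree": self.kernel.degree,
                "coef0": self.kernel.coef0,
            },
            "C": self.C,
            "j": self.j,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "scaler": {
                "mins": self.scaler.mins.tolist(),
                "ranges": self.scaler.ranges.tolist(),
            },
            "catalog_hash": self.catalog_hash,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "SVMModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != 1:
            raise ValueError("unsupported model file version")
        return cls(
            kernel=KernelSpec(**payload["kernel"]),
            C=payload["C"],
            j=payload["j"],
            support_vectors=np.array(payload["support_vectors"], dtype=float),
            dual_coef=np.array(payload["dual_coef"], dtype=float),
            bias=payload["bias"],
            scaler=MinMaxScaler01(
                mins=np.array(payload["scaler"]["mins"], dtype=float),
                ranges=np.array(payload["scaler"]["ranges"], dtype=float),
            ),
            catalog_hash=payload["catalog_hash"],
            metadata=payload["metadata"],
        )


def train(
    labeled: LabeledSet,
    kernel_spec: KernelSpec | None = None,
    C: float = DEFAULT_C,
    j: float = DEFAULT_J,
    seed: int = 0,
    scale: str = "none",
) -> SVMModel:
    """Train a soft-margin SVM with positive-class cost C*j.

    Deterministic for a fixed seed.  ``scale`` is "none" (raw features, the
    default the gamma=1e-4 convention expects) or "minmax"; when "minmax"
    the scaler is fitted on this training set only and stored in the model.
    """
    spec = kernel_spec or KernelSpec()
    X = labeled.matrix()
    y = labeled.y()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if scale == "minmax":
        scaler = MinMaxScaler01.fit(X)
    elif scale == "none":
        scaler = MinMaxScaler01.identity(X.shape[1])
    else:
        raise ValueError("scale must be 'none' or 'minmax'")
    Xs = scaler.transform(X)
    clf = SVC(
        kernel=spec.sklearn_name,
        C=C,
        gamma=spec.gamma,
        degree=spec.degree,
        coef0=spec.coef0,
        class_weight={1: j, -1: 1.0},
        random_state=seed,
        cache_size=200,
    )
    clf.fit(Xs, y)
    model = SVMModel(
        kernel=spec,
        C=C,
        j=j,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        scaler=scaler,
        catalog_hash=labeled.catalog.digest(),
        metadata={
            "scale": scale,
            "seed": seed,
            "date": datetime.date.today().isoformat(),
            "n_pos": int((y == 1).sum()),
            "n_neg": int((y == -1).sum()),
            "n_features": X.shape[1],
        },
    )
    return model


def _check_catalog(model: SVMModel, catalog: FeatureCatalog | None) -> None:
    if catalog is not None and catalog.digest() != model.catalog_hash:
        raise ValueError(
            "feature catalog mismatch: model was trained with a different "
            f"catalog (hash {model.catalog_hash})"
        )


def decision_score(model: SVMModel, x, catalog: FeatureCatalog | None = None) -> float:
    """Signed decision value for a single unscaled feature vector."""
    _check_catalog(model, catalog)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != model.support_vectors.shape[1]:
        raise ValueError(
            f"expected vector of dimension {model.support_vectors.shape[1]}"
        )
    return float(model.decision(x[None, :])[0])


def classify(model: SVMModel, x, catalog: FeatureCatalog | None = None) -> int:
    """+1 iff decision score > 0 (ties break to -1)."""
    return 1 if decision_score(model, x, catalog) > 0 else -1
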