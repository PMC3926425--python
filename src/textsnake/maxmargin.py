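"""Maximum-margin kernel classification.

The binary core learns the dual soft-margin problem

    max_l  sum_i l_i - 1/2 sum_ij l_i l_j y_i y_j K(x_i, x_j)
    s.t.   0 <= l_i <= c,  sum_i l_i y_i = 0

and classifies with  sign( sum_i l_i y_i K(x_i, x) + w0 ),  with w0
recovered from the Karush-Kuhn-Tucker complementarity conditions.  The
quadratic program is delegated to a standard SMO solver; the trained
model stores the raw multipliers, support vectors and bias, and all
decision values are computed here from those quantities.

Multi-class problems use one-vs-one voting over all class pairs, with a
deterministic tie-break (largest summed decision magnitude, then
lexicographic class name).  An optional per-feature z-score scaling is
stored with the model so that margins are not dominated by large-range
features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "KernelSpec",
    "FeatureScaling",
    "MaxMarginModel",
    "MulticlassModel",
    "TrainingError",
    "kernel_eval",
    "train_binary",
    "decision_value",
    "predict",
    "train_multiclass",
    "predict_multiclass",
    "cv_splits",
]

KKT_BALANCE_TOL = 1e-6


class TrainingError(ValueError):
    """Invalid training input or solver failure."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel function specification.

    kind
        'linear' (x.y), 'polynomial' ((gamma x.y + 1)^degree) or
        'rbf' (exp(-||x-y||^2 / gamma)).
    gamma
        Polynomial scale or RBF width; strictly positive where used.
    degree
        Polynomial order, 2 or 3.
    """

    kind: str = "linear"
    gamma: float = 1.0
    degree: int = 2

    def __post_init__(self):
        if self.kind not in ("linear", "polynomial", "rbf"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind != "linear" and not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if self.kind == "polynomial" and self.degree not in (2, 3):
            raise ValueError("polynomial degree must be 2 or 3")


@dataclass(frozen=True)
class FeatureScaling:
    """Per-feature z-score constants estimated on the training set."""

    mean: np.ndarray
    std: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.std

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaling":
        X = np.asarray(X, dtype=float)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)  # constant features pass through
        return cls(mean=X.mean(axis=0), std=std)


def kernel_eval(spec: KernelSpec, a, b) -> float:
    """Evaluate K(a, b) for a single pair of feature vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if spec.kind == "linear":
        return float(a @ b)
    if spec.kind == "polynomial":
        return float((spec.gamma * (a @ b) + 1.0) ** spec.degree)
    d2 = float(((a - b) ** 2).sum())
    return float(np.exp(-d2 / spec.gamma))


def _kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    G = A @ B.T
    if spec.kind == "linear":
        return G
    if spec.kind == "polynomial":
        return (spec.gamma * G + 1.0) ** spec.degree
    d2 = (A * A).sum(1)[:, None] - 2.0 * G + (B * B).sum(1)[None, :]
    return np.exp(-np.maximum(d2, 0.0) / spec.gamma)


@dataclass
class MaxMarginModel:
    """A trained binary maximum-margin classifier.

    Stores only the vectors with nonzero multiplier (0 < l_i <= c),
    their labels y_i in {-1, +1}, the bias w0, the kernel and cost, and
    optional feature scaling applied before kernel evaluation.
    """

    support_vectors: np.ndarray
    multipliers: np.ndarray
    labels: np.ndarray
    bias: float
    kernel: KernelSpec
    cost: float
    scaling: FeatureScaling | None = None

    def check_kkt(self) -> None:
        lam = self.multipliers
        if np.any(lam < -1e-12) or np.any(lam > self.cost + 1e-9):
            raise TrainingError("box constraint 0 <= lambda <= c violated")
        if abs(float(lam @ self.labels)) > KKT_BALANCE_TOL:
            raise TrainingError("KKT balance sum(lambda_i y_i) = 0 violated")


def train_binary(X, y, spec: KernelSpec = KernelSpec(), c: float = 1.5,
                 scaling: FeatureScaling | None = None) -> MaxMarginModel:
    """Solve the dual soft-margin problem and return the trained model.

    Raises :class:`TrainingError` when only one class is present or the
    solver fails to satisfy the KKT balance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {-1, 1}:
        raise TrainingError("training labels must contain both -1 and +1")
    if not c > 0:
        raise TrainingError("cost c must be > 0")
    Xs = scaling.apply(X) if scaling is not None else X

    if spec.kind == "linear":
        svc = SVC(kernel="linear", C=c)
    elif spec.kind == "polynomial":
        svc = SVC(kernel="poly", C=c, gamma=spec.gamma, coef0=1.0, degree=spec.degree)
    else:
        svc = SVC(kernel="rbf", C=c, gamma=1.0 / spec.gamma)
    svc.fit(Xs, y)

    dual = svc.dual_coef_.ravel()  # = lambda_i * y_i
    sv = svc.support_vectors_
    ysv = y[svc.support_]
    lam = dual * ysv  # recover nonnegative multipliers
    model = MaxMarginModel(
        support_vectors=np.array(sv, dtype=float),
        multipliers=np.array(lam, dtype=float),
        labels=np.array(ysv, dtype=int),
        bias=float(svc.intercept_[0]),
        kernel=spec,
        cost=float(c),
        scaling=scaling,
    )
    model.check_kkt()
    return model


def decision_value(model: MaxMarginModel, x) -> float:
    """Signed distance surrogate  sum_i l_i y_i K(x_i, x) + w0."""
    x = np.asarray(x, dtype=float)
    if model.scaling is not None:
        x = model.scaling.apply(x)
    if x.ndim != 1 or x.shape[0] != model.support_vectors.shape[1]:
        raise ValueError(
            f"dimension mismatch: model expects {model.support_vectors.shape[1]} features"
        )
    k = _kernel_matrix(model.kernel, model.support_vectors, x[None, :]).ravel()
    return float((model.multipliers * model.labels) @ k + model.bias)


def predict(model: MaxMarginModel, x) -> int:
    """Class label in {-1, +1}; a decision value of exactly 0 maps to +1."""
    return 1 if decision_value(model, x) >= 0 else -1


# ---------------------------------------------------------------------------
# one-vs-one multi-class wrapper


@dataclass
class MulticlassModel:
    """One-vs-one ensemble over all unordered class pairs.

    Each pair ``(a, b)`` with ``a < b`` lexicographically holds a binary
    model trained with y=-1 for `a` and y=+1 for `b`.  Feature scaling
    is fitted once on the pooled training set and shared by all pairs.
    """

    class_names: list
    pairwise: dict = field(default_factory=dict)
    scaling: FeatureScaling | None = None

    def classes(self) -> list:
        return list(self.class_names)


def train_multiclass(X, y, spec: KernelSpec = KernelSpec(), c: float = 1.5,
                     standardize: bool = True) -> MulticlassModel:
    """Train a one-vs-one multiclass ensemble from string class labels."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=object)
    names = sorted(set(y))
    if len(names) < 2:
        raise TrainingError("need at least 2 classes")
    scaling = FeatureScaling.fit(X) if standardize else None
    Xs = scaling.apply(X) if scaling is not None else X
    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        sel = (y == a) | (y == b)
        yy = np.where(y[sel] == b, 1, -1)
        pairwise[(a, b)] = train_binary(Xs[sel], yy, spec, c)
    return MulticlassModel(class_names=names, pairwise=pairwise, scaling=scaling)


def predict_multiclass(model: MulticlassModel, x) -> str:
    """One-vs-one vote; ties broken by largest summed |decision value|,
    then lexicographic class name."""
    x = np.asarray(x, dtype=float)
    if model.scaling is not None:
        x = model.scaling.apply(x)
    votes = {name: 0 for name in model.class_names}
    margin = {name: 0.0 for name in model.class_names}
    for (a, b), m in model.pairwise.items():
        v = decision_value(m, x)
        winner = b if v >= 0 else a
        votes[winner] += 1
        margin[a] += abs(v)
        margin[b] += abs(v)
    best = max(votes.values())
    tied = [n for n, v in votes.items() if v == best]
    if len(tied) == 1:
        return tied[0]
    best_margin = max(margin[n] for n in tied)
    tied = [n for n in tied if margin[n] == best_margin]
    return min(tied)


def predict_multiclass_batch(model: MulticlassModel, X) -> list:
    return [predict_multiclass(model, x) for x in np.atleast_2d(np.asarray(X, dtype=float))]


def cv_splits(n: int, k: int = 10, seed: int = 0) -> list:
    """Random k-fold index splits: list of (train_idx, test_idx)."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, k)
    return [
        (np.concatenate([f for j, f in enumerate(folds) if j != i]), folds[i])
        for i in range(k)
    ]


# ---------------------------------------------------------------------------
# serialization hooks used by textsnake.io


def _kernel_to_dict(spec: KernelSpec) -> dict:
    return {"kind": spec.kind, "gamma": spec.gamma, "degree": spec.degree}


def _kernel_from_dict(d: dict) -> KernelSpec:
    return KernelSpec(kind=d["kind"], gamma=d["gamma"], degree=d["degree"])


def _scaling_to_dict(s: FeatureScaling | None):
    if s is None:
        return None
    return {"mean": s.mean.tolist(), "std": s.std.tolist()}


def _scaling_from_dict(d):
    if d is None:
        return None
    return FeatureScaling(mean=np.array(d["mean"]), std=np.array(d["std"]))


def _binary_to_dict(m: MaxMarginModel) -> dict:
    return {
        "support_vectors": m.support_vectors.tolist(),
        "multipliers": m.multipliers.tolist(),
        "labels": m.labels.tolist(),
        "bias": m.bias,
        "kernel": _kernel_to_dict(m.kernel),
        "cost": m.cost,
        "scaling": _scaling_to_dict(m.scaling),
    }


def _binary_from_dict(d: dict) -> MaxMarginModel:
    return MaxMarginModel(
        support_vectors=np.array(d["support_vectors"], dtype=float),
        multipliers=np.array(d["multipliers"], dtype=float),
        labels=np.array(d["labels"], dtype=int),
        bias=float(d["bias"]),
        kernel=_kernel_from_dict(d["kernel"]),
        cost=float(d["cost"]),
        scaling=_scaling_from_dict(d["scaling"]),
    )


def model_to_dict(model) -> dict:
    if isinstance(model, MaxMarginModel):
        return {"model_type": "binary", "model": _binary_to_dict(model)}
    if isinstance(model, MulticlassModel):
        return {
            "model_type": "multiclass",
            "class_names": list(model.class_names),
            "pairwise": [
                {"pair": [a, b], "model": _binary_to_dict(m)}
                for (a, b), m in sorted(model.pairwise.items())
            ],
            "scaling": _scaling_to_dict(model.scaling),
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_dict(payload: dict):
    kind = payload.get("model_type")
    if kind == "binary":
        return _binary_from_dict(payload["model"])
    if kind == "multiclass":
        return MulticlassModel(
            class_names=list(payload["class_names"]),
            pairwise={
                tuple(item["pair"]): _binary_from_dict(item["model"])
                for item in payload["pairwise"]
            },
            scaling=_scaling_from_dict(payload["scaling"]),
        )
    from .io import ModelFormatError

    raise ModelFormatError(f"unknown model_type {kind!r}")
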