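"""Margin classifiers: soft-margin SVM, twin SVM, least-squares twin SVM.

The twin family fits one "proximal" hyperplane per class: each plane is
pulled toward its own class's samples and pushed at least unit distance from
the other class's.  A sample is assigned to the class whose plane is nearer.
TWSVM solves two small box-constrained quadratic programs (each of the size
of the *opposite* class); the least-squares variant replaces the inequality
constraints with equalities and the hinge with squared loss, so each plane
comes from one symmetric positive-definite linear solve — no QP at all,
which is the source of its training-speed advantage.

Binary conventions: labels are exactly {+1, -1}; plane 1 belongs to class
+1.  Exact distance ties predict class +1.  Multiclass is one-vs-one with
majority vote, vote ties broken by summed signed plane-distance margins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy import optimize
from sklearn.metrics.pairwise import pairwise_kernels
from sklearn.svm import SVC

_RIDGE = 1e-8  # conditioning ridge on every normal-matrix solve


# ---------------------------------------------------------------------------
# kernels and training-set plumbing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters (linear, rbf, polynomial)."""

    family: str = "linear"
    gamma: float = 1.0
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("linear", "rbf", "polynomial"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf" and not self.gamma > 0:
            raise ValueError("rbf kernel requires gamma > 0")
        if self.family == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")

    def matrix(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        if self.family == "linear":
            return X @ Y.T
        if self.family == "rbf":
            return pairwise_kernels(X, Y, metric="rbf", gamma=self.gamma)
        return pairwise_kernels(X, Y, metric="polynomial",
                                gamma=1.0, degree=self.degree, coef0=self.coef0)


@dataclass
class TrainingSet:
    """Samples (trial x feature) with labels; binary uses {+1, -1}."""

    samples: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D")
        if self.labels.shape != (self.samples.shape[0],):
            raise ValueError("labels length must match sample count")


def _check_binary(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("expected 2-D samples and matching label vector")
    present = set(np.unique(y).tolist())
    if present != {-1.0, 1.0}:
        raise ValueError(f"binary routines require labels {{+1, -1}}, got {present}")
    return X, y


# ---------------------------------------------------------------------------
# soft-margin SVM (backed by libsvm for the dual solve)
# ---------------------------------------------------------------------------

@dataclass
class SVMModel:
    """Soft-margin SVM solution.

    ``w`` is populated only for the linear kernel; predictions always go
    through the retained support samples so the model is self-contained.
    """

    kernel: KernelSpec
    lam: float
    b: float
    support_samples: np.ndarray      # (n_sv, n_features)
    dual_coef: np.ndarray            # (n_sv,), alpha_i * y_i
    w: Optional[np.ndarray] = None   # linear kernel only
    xi: Optional[np.ndarray] = None  # slack at solution, per training sample
    n_features: int = 0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != training dimension {self.n_features}"
            )
        K = self.kernel.matrix(X, self.support_samples)
        return K @ self.dual_coef + self.b

    def dual_objective(self) -> float:
        """Value of the dual objective sum(alpha) - 1/2 a^T Q a at the solution."""
        alpha_signed = self.dual_coef  # alpha_i * y_i
        K = self.kernel.matrix(self.support_samples, self.support_samples)
        return float(np.abs(alpha_signed).sum()
                     - 0.5 * alpha_signed @ K @ alpha_signed)


def train_svm(X: np.ndarray, y: np.ndarray, lam: float,
              kernel: KernelSpec = KernelSpec()) -> SVMModel:
    """Train a soft-margin SVM: min 1/2 ||w||^2 + lam * sum(xi).

    Solved in the dual (libsvm) so every kernel family is supported; slack
    values xi_i = max(0, 1 - y_i f(x_i)) are reported as a diagnostic.
    """
    X, y = _check_binary(X, y)
    if not lam > 0:
        raise ValueError("penalty factor lam must be positive")
    if kernel.family == "linear":
        svc = SVC(C=lam, kernel="linear", tol=1e-8, max_iter=1_000_000)
    elif kernel.family == "rbf":
        svc = SVC(C=lam, kernel="rbf", gamma=kernel.gamma, tol=1e-8,
                  max_iter=1_000_000)
    else:
        svc = SVC(C=lam, kernel="poly", degree=kernel.degree,
                  gamma=1.0, coef0=kernel.coef0, tol=1e-8, max_iter=1_000_000)
    svc.fit(X, y)
    model = SVMModel(
        kernel=kernel,
        lam=lam,
        b=float(svc.intercept_[0]),
        support_samples=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        w=(svc.coef_[0].copy() if kernel.family == "linear" else None),
        n_features=X.shape[1],
    )
    margins = y * model.decision_function(X)
    model.xi = np.maximum(0.0, 1.0 - margins)
    return model


# ---------------------------------------------------------------------------
# twin SVM and least-squares twin SVM
# ---------------------------------------------------------------------------

@dataclass
class TwinSVMModel:
    """Two proximal hyperplanes; plane 1 is class +1's, plane 2 class -1's.

    In the kernel case the plane normals are expansions over the full
    training set (``reference_samples``); in the linear case they live in
    input space and ``reference_samples`` is None.
    """

    kernel: KernelSpec
    costs: Tuple[float, float]
    w1: np.ndarray
    b1: float
    w2: np.ndarray
    b2: float
    reference_samples: Optional[np.ndarray] = None
    n_features: int = 0

    def _surfaces(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Signed plane values (not yet normalized) for both planes."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != training dimension {self.n_features}"
            )
        if self.reference_samples is None:
            phi = X
        else:
            phi = self.kernel.matrix(X, self.reference_samples)
        return phi @ self.w1 + self.b1, phi @ self.w2 + self.b2

    def _norms(self) -> Tuple[float, float]:
        if self.reference_samples is None:
            n1 = float(np.linalg.norm(self.w1))
            n2 = float(np.linalg.norm(self.w2))
        else:
            K = self.kernel.matrix(self.reference_samples, self.reference_samples)
            n1 = float(np.sqrt(max(self.w1 @ K @ self.w1, 0.0)))
            n2 = float(np.sqrt(max(self.w2 @ K @ self.w2, 0.0)))
        return max(n1, _RIDGE), max(n2, _RIDGE)

    def plane_distances(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Perpendicular (kernel-space) distance of each sample to each plane."""
        f1, f2 = self._surfaces(X)
        n1, n2 = self._norms()
        return np.abs(f1) / n1, np.abs(f2) / n2

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed margin d2 - d1: positive means nearer plane 1 (class +1)."""
        d1, d2 = self.plane_distances(X)
        return d2 - d1


def _solve_box_qp(Q: np.ndarray, upper: float) -> np.ndarray:
    """min 1/2 a^T Q a - e^T a  subject to  0 <= a <= upper."""
    n = Q.shape[0]
    e = np.ones(n)

    def fun(a):
        Qa = Q @ a
        return 0.5 * a @ Qa - a.sum(), Qa - e

    res = optimize.minimize(
        fun, x0=np.full(n, min(upper, 1.0) / 2.0), jac=True,
        method="L-BFGS-B", bounds=[(0.0, upper)] * n,
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return np.clip(res.x, 0.0, upper)


def _twin_design(X: np.ndarray, y: np.ndarray,
                 kernel: KernelSpec) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Augmented own-class/other-class design matrices H=[A e], G=[B e]."""
    A = X[y == 1]
    B = X[y == -1]
    if kernel.family == "linear":
        phi_a, phi_b, ref = A, B, None
    else:
        ref = X.copy()
        phi_a = kernel.matrix(A, ref)
        phi_b = kernel.matrix(B, ref)
    H = np.hstack([phi_a, np.ones((phi_a.shape[0], 1))])
    G = np.hstack([phi_b, np.ones((phi_b.shape[0], 1))])
    return H, G, ref


def train_twsvm(X: np.ndarray, y: np.ndarray, c1: float, c2: float,
                kernel: KernelSpec = KernelSpec()) -> TwinSVMModel:
    """Twin SVM: two box-constrained dual QPs, one per plane.

    Plane 1 minimizes its own class's squared plane distances plus ``c1``
    times the hinge penalty on class -1 samples closer than unit distance;
    symmetrically for plane 2.  Each dual has as many variables as the
    opposite class has samples.
    """
    X, y = _check_binary(X, y)
    if not (c1 > 0 and c2 > 0):
        raise ValueError("costs must be positive")
    H, G, ref = _twin_design(X, y, kernel)

    HtH = H.T @ H + _RIDGE * np.eye(H.shape[1])
    GtG = G.T @ G + _RIDGE * np.eye(G.shape[1])

    # plane 1: dual over class -1 samples
    S1 = np.linalg.solve(HtH, G.T)           # (d+1, m2)
    alpha = _solve_box_qp(G @ S1, c1)
    u1 = -S1 @ alpha
    # plane 2: dual over class +1 samples
    S2 = np.linalg.solve(GtG, H.T)
    gamma = _solve_box_qp(H @ S2, c2)
    u2 = S2 @ gamma

    return TwinSVMModel(
        kernel=kernel, costs=(c1, c2),
        w1=u1[:-1], b1=float(u1[-1]),
        w2=u2[:-1], b2=float(u2[-1]),
        reference_samples=ref, n_features=X.shape[1],
    )


def train_lstwsvm(X: np.ndarray, y: np.ndarray, c1: float, c2: float,
                  kernel: KernelSpec = KernelSpec(),
                  ridge: float = _RIDGE) -> TwinSVMModel:
    """Least-squares twin SVM: one SPD linear solve per plane.

    Plane 1 solves (G^T G + (1/c1) H^T H + ridge I) u = -G^T e with
    H = [A e] stacking class +1 samples and G = [B e] class -1; plane 2 is
    the mirror image.  Raising ``ridge`` is the remedy if the system is
    numerically singular.
    """
    X, y = _check_binary(X, y)
    if not (c1 > 0 and c2 > 0):
        raise ValueError("costs must be positive")
    H, G, ref = _twin_design(X, y, kernel)
    d = H.shape[1]
    eye = np.eye(d)
    e_b = np.ones(G.shape[0])
    e_a = np.ones(H.shape[0])

    M1 = G.T @ G + (1.0 / c1) * (H.T @ H) + ridge * eye
    M2 = H.T @ H + (1.0 / c2) * (G.T @ G) + ridge * eye
    try:
        u1 = np.linalg.solve(M1, -G.T @ e_b)
        u2 = np.linalg.solve(M2, H.T @ e_a)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular twin system ({err}); raise the ridge term"
        ) from err

    return TwinSVMModel(
        kernel=kernel, costs=(c1, c2),
        w1=u1[:-1], b1=float(u1[-1]),
        w2=u2[:-1], b2=float(u2[-1]),
        reference_samples=ref, n_features=X.shape[1],
    )


def predict(model: Union[SVMModel, TwinSVMModel], X: np.ndarray) -> np.ndarray:
    """Labels in {+1, -1}; exact ties (decision value 0) go to class +1."""
    f = model.decision_function(X)
    return np.where(f >= 0.0, 1, -1)


# ---------------------------------------------------------------------------
# one-vs-one multiclass wrapper
# ---------------------------------------------------------------------------

_TRAINERS = {"svm": None, "twsvm": train_twsvm, "lstwsvm": train_lstwsvm}


@dataclass
class MulticlassModel:
    """One binary model per unordered class pair; majority-vote prediction."""

    classes: np.ndarray
    base: str
    pairwise_models: Dict[Tuple[int, int], Union[SVMModel, TwinSVMModel]]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        n = X.shape[0]
        votes = np.zeros((n, len(self.classes)))
        margin = np.zeros((n, len(self.classes)))
        index = {int(c): i for i, c in enumerate(self.classes)}
        for (ci, cj), model in self.pairwise_models.items():
            f = model.decision_function(X)      # >0 favors ci (mapped to +1)
            win_i = f >= 0.0
            votes[win_i, index[ci]] += 1
            votes[~win_i, index[cj]] += 1
            margin[:, index[ci]] += f
            margin[:, index[cj]] -= f
        # majority vote; ties broken by summed signed margins, then by the
        # lower class-pair index (argmax picks the first maximum)
        best = np.empty(n, dtype=np.int64)
        for r in range(n):
            top = np.flatnonzero(votes[r] == votes[r].max())
            if len(top) > 1:
                top = top[np.argsort(-margin[r, top], kind="stable")[:1]]
            best[r] = self.classes[top[0]]
        return best


def train_multiclass(X: np.ndarray, y: np.ndarray, base: str = "lstwsvm",
                     costs: Tuple[float, float] = (1.0, 1.0),
                     kernel: KernelSpec = KernelSpec()) -> MulticlassModel:
    """One-vs-one decomposition over all n(n-1)/2 class pairs."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if base not in _TRAINERS:
        raise ValueError(f"unknown base classifier {base!r}")
    models: Dict[Tuple[int, int], Union[SVMModel, TwinSVMModel]] = {}
    for i, ci in enumerate(classes):
        for cj in classes[i + 1:]:
            mask = (y == ci) | (y == cj)
            yy = np.where(y[mask] == ci, 1.0, -1.0)
            if base == "svm":
                m = train_svm(X[mask], yy, lam=costs[0], kernel=kernel)
            else:
                m = _TRAINERS[base](X[mask], yy, costs[0], costs[1], kernel)
            models[(int(ci), int(cj))] = m
    return MulticlassModel(classes=classes, base=base, pairwise_models=models)


# ---------------------------------------------------------------------------
# sklearn-style estimator facades (used by CV, band selection, optimizers)
# ---------------------------------------------------------------------------

class LSTwinSVMClassifier:
    """fit/predict facade over the least-squares twin SVM (OvO if multiclass)."""

    def __init__(self, c1: float = 1.0, c2: float = 1.0,
                 kernel: KernelSpec = KernelSpec()):
        self.c1, self.c2, self.kernel = c1, c2, kernel
        self.model_: Union[TwinSVMModel, MulticlassModel, None] = None
        self._binary_classes: Optional[np.ndarray] = None

    def _train_binary(self, X, yy):
        return train_lstwsvm(X, yy, self.c1, self.c2, self.kernel)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTwinSVMClassifier":
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) == 2:
            yy = np.where(y == classes[0], 1.0, -1.0)
            self.model_ = self._train_binary(np.asarray(X, dtype=np.float64), yy)
            self._binary_classes = classes
        else:
            self.model_ = self._train_multiclass(X, y)
            self._binary_classes = None
        return self

    def _train_multiclass(self, X, y):
        return train_multiclass(X, y, base="lstwsvm",
                                costs=(self.c1, self.c2), kernel=self.kernel)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        if self._binary_classes is not None:
            pm = predict(self.model_, X)
            return np.where(pm == 1, self._binary_classes[0], self._binary_classes[1])
        return self.model_.predict(X)


class TwinSVMClassifier(LSTwinSVMClassifier):
    """fit/predict facade over the hinge-loss twin SVM."""

    def _train_binary(self, X, yy):
        return train_twsvm(X, yy, self.c1, self.c2, self.kernel)

    def _train_multiclass(self, X, y):
        return train_multiclass(X, y, base="twsvm",
                                costs=(self.c1, self.c2), kernel=self.kernel)


class SVMClassifier(LSTwinSVMClassifier):
    """fit/predict facade over the soft-margin SVM (c1 acts as the penalty)."""

    def _train_binary(self, X, yy):
        return train_svm(X, yy, lam=self.c1, kernel=self.kernel)

    def _train_multiclass(self, X, y):
        return train_multiclass(X, y, base="svm",
                                costs=(self.c1, self.c2), kernel=self.kernel)


# ---------------------------------------------------------------------------
# serialization (documented JSON container, round-trip guaranteed)
# ---------------------------------------------------------------------------

def _kernel_to_dict(k: KernelSpec) -> dict:
    return {"family": k.family, "gamma": k.gamma,
            "degree": k.degree, "coef0": k.coef0}


def model_to_json(model: Union[SVMModel, TwinSVMModel]) -> str:
    """Serialize a fitted binary model to a JSON document."""
    if isinstance(model, TwinSVMModel):
        doc = {
            "type": "twin",
            "kernel": _kernel_to_dict(model.kernel),
            "costs": list(model.costs),
            "w1": model.w1.tolist(), "b1": model.b1,
            "w2": model.w2.tolist(), "b2": model.b2,
            "reference_samples": (None if model.reference_samples is None
                                  else model.reference_samples.tolist()),
            "n_features": model.n_features,
        }
    elif isinstance(model, SVMModel):
        doc = {
            "type": "svm",
            "kernel": _kernel_to_dict(model.kernel),
            "lam": model.lam,
            "b": model.b,
            "support_samples": model.support_samples.tolist(),
            "dual_coef": model.dual_coef.tolist(),
            "w": None if model.w is None else model.w.tolist(),
            "n_features": model.n_features,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    return json.dumps(doc)


def model_from_json(text: str) -> Union[SVMModel, TwinSVMModel]:
    doc = json.loads(text)
    kernel = KernelSpec(**doc["kernel"])
    if doc["type"] == "twin":
        return TwinSVMModel(
            kernel=kernel, costs=tuple(doc["costs"]),
            w1=np.asarray(doc["w1"]), b1=doc["b1"],
            w2=np.asarray(doc["w2"]), b2=doc["b2"],
            reference_samples=(None if doc["reference_samples"] is None
                               else np.asarray(doc["reference_samples"])),
            n_features=doc["n_features"],
        )
    if doc["type"] == "svm":
        return SVMModel(
            kernel=kernel, lam=doc["lam"], b=doc["b"],
            support_samples=np.asarray(doc["support_samples"]),
            dual_coef=np.asarray(doc["dual_coef"]),
            w=None if doc["w"] is None else np.asarray(doc["w"]),
            n_features=doc["n_features"],
        )
    raise ValueError(f"unknown model type {doc.get('type')!r}")
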