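"""Common spatial patterns and per-subject adaptive band selection.

Two-class CSP: average the trace-normalized trial covariances per class,
shrink toward the identity, and solve the generalized eigenproblem
C1 w = lambda (C1 + C2) w.  Eigenvectors with extreme eigenvalues maximize
the variance ratio between the classes; the feature for a trial is the log
of each retained component's variance share.

Band selection scores each candidate band's features by stratified k-fold
cross-validation of the downstream classifier and keeps the best band —
the "adaptive frequency band selection" step that absorbs inter-subject
variability of the sensorimotor rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg
from sklearn.model_selection import StratifiedKFold

from .containers import EpochSet, FeatureMatrix

_VAR_FLOOR = np.finfo(float).tiny


@dataclass
class CSPModel:
    """Fitted spatial filters (rows of ``filters``) and their eigenvalues."""

    filters: np.ndarray          # (n_components, n_channels)
    eigenvalues: np.ndarray      # (n_components,), each in [0, 1], descending ends
    n_components: int
    band: Optional[Tuple[float, float]] = None
    regularization: float = 0.0
    classes: Optional[Tuple[int, int]] = None


def _class_covariance(data: np.ndarray, regularization: float) -> np.ndarray:
    """Average of trace-normalized trial covariances, shrunk toward identity."""
    n_channels = data.shape[1]
    covs = np.einsum("tcs,tds->tcd", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    traces[traces == 0] = 1.0
    cov = (covs / traces[:, None, None]).mean(axis=0)
    if regularization > 0:
        mu = np.trace(cov) / n_channels
        cov = (1.0 - regularization) * cov + regularization * mu * np.eye(n_channels)
    return cov


def csp_eigendecomposition(c1: np.ndarray, c2: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Solve C1 w = lambda (C1 + C2) w; eigenvalues descending in [0, 1].

    Eigenvectors (columns) are scaled so that W^T (C1 + C2) W = I.
    """
    eigvals, eigvecs = linalg.eigh(c1, c1 + c2)
    order = np.argsort(eigvals)[::-1]
    return np.clip(eigvals[order], 0.0, 1.0), eigvecs[:, order]


def fit_csp(epochs: EpochSet, n_components: int = 4,
            regularization: float = 0.05) -> CSPModel:
    """Fit two-class CSP filters.

    ``n_components`` must be even; half the filters come from the top of the
    eigenvalue spectrum (variance concentrated in the lower-labelled class)
    and half from the bottom.
    """
    classes = np.unique(epochs.labels)
    if len(classes) != 2:
        raise ValueError(
            f"CSP requires exactly 2 classes, got {len(classes)}; "
            "use the one-vs-one multiclass wrapper upstream"
        )
    if n_components % 2 != 0 or n_components < 2:
        raise ValueError("n_components must be a positive even number")
    if n_components > epochs.n_channels:
        raise ValueError("n_components cannot exceed the channel count")
    if not 0.0 <= regularization <= 1.0:
        raise ValueError("regularization must lie in [0, 1]")

    c1 = _class_covariance(epochs.data[epochs.labels == classes[0]], regularization)
    c2 = _class_covariance(epochs.data[epochs.labels == classes[1]], regularization)
    composite = c1 + c2
    if regularization == 0.0:
        rank = np.linalg.matrix_rank(composite)
        if rank < epochs.n_channels:
            raise ValueError(
                "composite covariance is rank-deficient; raise `regularization`"
            )
    eigvals, eigvecs = csp_eigendecomposition(c1, c2)

    half = n_components // 2
    pick = np.concatenate([np.arange(half),
                           np.arange(len(eigvals) - half, len(eigvals))])
    return CSPModel(
        filters=eigvecs[:, pick].T.copy(),
        eigenvalues=eigvals[pick].copy(),
        n_components=n_components,
        band=epochs.band,
        regularization=regularization,
        classes=(int(classes[0]), int(classes[1])),
    )


def csp_features(model: CSPModel, epochs: EpochSet) -> FeatureMatrix:
    """Log of each component's normalized variance, per trial.

    Normalizing by the summed variance over retained components makes the
    features invariant to global trial scaling; a zero-variance component is
    floored at the machine minimum before the log.
    """
    if epochs.n_channels != model.filters.shape[1]:
        raise ValueError(
            f"epochs have {epochs.n_channels} channels, model expects "
            f"{model.filters.shape[1]}"
        )
    projected = np.einsum("kc,tcs->tks", model.filters, epochs.data)
    variances = projected.var(axis=-1)
    totals = variances.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    shares = variances / totals
    values = np.log(np.maximum(shares, _VAR_FLOOR))
    tag = f"{model.band[0]:g}-{model.band[1]:g}Hz" if model.band else "broadband"
    names = [f"csp{k}@{tag}" for k in range(model.n_components)]
    return FeatureMatrix(values=values, labels=epochs.labels.copy(),
                         feature_names=names)


def select_band(
    band_features: Sequence[FeatureMatrix],
    labels: np.ndarray,
    folds: int,
    classifier_factory: Callable[[], object],
    seed: int = 0,
) -> Tuple[int, np.ndarray]:
    """Pick the band whose features cross-validate best.

    Runs stratified ``folds``-fold CV of ``classifier_factory()`` (an object
    with fit/predict) on each band's features; returns the argmax-accuracy
    band index (ties broken toward the lower-frequency band, i.e. the lower
    index) plus the per-band score vector.
    """
    if not band_features:
        raise ValueError("need at least one band")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class count ({counts.min()})"
        )
    for fm in band_features:
        if fm.n_trials != len(labels):
            raise ValueError("all bands must share the same trials/labels")

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(np.zeros(len(labels)), labels))
    scores = np.empty(len(band_features))
    for b, fm in enumerate(band_features):
        accs = []
        for train, test in splits:
            clf = classifier_factory()
            clf.fit(fm.values[train], labels[train])
            accs.append(np.mean(clf.predict(fm.values[test]) == labels[test]))
        scores[b] = np.mean(accs)
    best = int(np.argmax(scores))  # argmax returns the first (lowest) index on ties
    return best, scores
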