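"""End-to-end evaluation: pipeline runs, baselines, and comparison reports.

The reported accuracy is held-out stratified outer cross-validation of the
whole chain — artifact removal, filter bank, per-band CSP, adaptive band
selection, optional hyperparameter tuning, classifier training — with every
data-dependent choice (CSP filters, band, hyperparameters) made on the
training folds only.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KernelDensity

from . import classifiers as clf
from .config import PipelineConfig
from .containers import EpochSet, FeatureMatrix
from .csp import csp_features, fit_csp, select_band
from .optimizers import classifier_search_space, cv_fitness, optimize
from .preprocess import apply_filter_bank, remove_artifacts

logger = logging.getLogger(__name__)

KNOWN_METHODS = ("pso-ls-twin-svm", "ls-twin-svm", "twsvm", "svm", "lda", "pnn")


# ---------------------------------------------------------------------------
# baseline classifiers
# ---------------------------------------------------------------------------

class LDAClassifier:
    """Two-class Fisher discriminant with pooled covariance (ridge 1e-6)."""

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LDAClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("this LDA is two-class only")
        X0 = X[y == self.classes_[0]]
        X1 = X[y == self.classes_[1]]
        pooled = (np.cov(X0, rowvar=False, bias=False) * (len(X0) - 1)
                  + np.cov(X1, rowvar=False, bias=False) * (len(X1) - 1))
        pooled /= max(len(X0) + len(X1) - 2, 1)
        pooled = np.atleast_2d(pooled) + self.ridge * np.eye(X.shape[1])
        try:
            self.w_ = np.linalg.solve(pooled, X1.mean(axis=0) - X0.mean(axis=0))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular pooled covariance ({err}); raise the ridge"
            ) from err
        self.threshold_ = 0.5 * (X0.mean(axis=0) + X1.mean(axis=0)) @ self.w_
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=np.float64)) @ self.w_ - self.threshold_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0,
                        self.classes_[1], self.classes_[0])


class PNNClassifier:
    """Probabilistic neural network: Parzen-window class densities.

    Gaussian kernel of fixed ``bandwidth``; prediction is the argmax of
    prior times class-conditional density.  ``priors='equal'`` (default)
    weighs classes equally; ``priors='empirical'`` weighs by training
    frequency, in which case a very large bandwidth degenerates to always
    predicting the majority class.
    """

    def __init__(self, bandwidth: float = 1.0, priors: str = "equal"):
        if not bandwidth > 0:
            raise ValueError("bandwidth must be positive")
        if priors not in ("equal", "empirical"):
            raise ValueError("priors must be 'equal' or 'empirical'")
        self.bandwidth = bandwidth
        self.priors = priors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PNNClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.kdes_ = []
        self.log_priors_ = []
        for c in self.classes_:
            Xc = X[y == c]
            self.kdes_.append(
                KernelDensity(kernel="gaussian", bandwidth=self.bandwidth).fit(Xc))
            prior = (len(Xc) / len(X)) if self.priors == "empirical" \
                else 1.0 / len(self.classes_)
            self.log_priors_.append(np.log(prior))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        scores = np.column_stack([
            kde.score_samples(X) + lp
            for kde, lp in zip(self.kdes_, self.log_priors_)
        ])
        return self.classes_[np.argmax(scores, axis=1)]


def _cv_accuracy(estimator_factory: Callable[[], object],
                 X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in cv.split(X, y):
        est = estimator_factory()
        est.fit(X[train], y[train])
        accs.append(np.mean(est.predict(X[test]) == y[test]))
    return float(np.mean(accs))


def baseline_lda(features: FeatureMatrix, folds: int = 10, seed: int = 0) -> float:
    """Cross-validated LDA accuracy in percent."""
    return 100.0 * _cv_accuracy(LDAClassifier, features.values, features.labels,
                                folds, seed)


def baseline_pnn(features: FeatureMatrix, smoothing: float = 1.0,
                 folds: int = 10, seed: int = 0) -> float:
    """Cross-validated PNN accuracy in percent for the given bandwidth."""
    return 100.0 * _cv_accuracy(lambda: PNNClassifier(bandwidth=smoothing),
                                features.values, features.labels, folds, seed)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summarize(per_subject: Sequence[float]) -> Tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator) and SE = SD/sqrt(n), in the input's units."""
    vals = np.asarray(per_subject, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("need at least one accuracy value")
    mean = float(vals.mean())
    if vals.size == 1:
        return mean, 0.0, 0.0
    sd = float(vals.std(ddof=1))
    return mean, sd, sd / np.sqrt(vals.size)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _auto_references(epochs: EpochSet, config: PipelineConfig) -> List[str]:
    if config.reference_channels is not None:
        return list(config.reference_channels)
    return [c for c in epochs.channel_names if c.upper().startswith("EOG")]


def _method_factory(method: str, config: PipelineConfig,
                    params: Optional[Dict[str, float]] = None) -> object:
    """Instantiate the classifier a method name refers to."""
    kernel = config.kernel
    c1, c2 = config.costs
    if params:
        c1 = params.get("c1", c1)
        c2 = params.get("c2", c2)
        if kernel.family == "rbf" and "gamma" in params:
            kernel = dataclasses.replace(kernel, gamma=params["gamma"])
    if method in ("pso-ls-twin-svm", "ls-twin-svm"):
        return clf.LSTwinSVMClassifier(c1=c1, c2=c2, kernel=kernel)
    if method == "twsvm":
        return clf.TwinSVMClassifier(c1=c1, c2=c2, kernel=kernel)
    if method == "svm":
        return clf.SVMClassifier(c1=c1, c2=c2, kernel=kernel)
    if method == "lda":
        return LDAClassifier()
    if method == "pnn":
        return PNNClassifier(bandwidth=config.pnn_bandwidth)
    raise ValueError(f"unknown method {method!r}; known: {KNOWN_METHODS}")


def _tune_on_features(features: FeatureMatrix, config: PipelineConfig,
                      method: str) -> Dict[str, float]:
    """Hyperparameter search on training-fold features only."""
    space = classifier_search_space(config.kernel.family)

    _, counts = np.unique(features.labels, return_counts=True)
    folds = min(config.optimizer_folds, int(counts.min()))

    def fitness(params: Dict[str, float]) -> float:
        return cv_fitness(
            params, features,
            classifier_factory=lambda p, _m=method: _method_factory(_m, config, p),
            folds=folds,
            seed=config.optimizer.seed,
        )

    result = optimize(fitness, space, config.optimizer)
    logger.info("tuned params %s (fitness %.3f)", result.best_params,
                result.best_fitness)
    return result.best_params


def _run_methods(epochs: EpochSet, config: PipelineConfig,
                 methods: Sequence[str]) -> Dict[str, float]:
    """Shared-split evaluation of several methods on one subject.

    All methods see identical outer folds, identical band-passed epochs and
    identical per-fold CSP models; they differ only in band selection scoring
    and the final classifier.  Returns accuracy in percent per method.
    """
    for m in methods:
        if m not in KNOWN_METHODS:
            raise ValueError(f"unknown method {m!r}; known: {KNOWN_METHODS}")
    refs = _auto_references(epochs, config)
    if refs:
        epochs = remove_artifacts(epochs, refs)

    band_epochs = apply_filter_bank(epochs, config.filter_bank)
    y = epochs.labels
    cv = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                         random_state=config.seed)
    correct: Dict[str, int] = {m: 0 for m in methods}
    total = 0
    for fold, (train, test) in enumerate(cv.split(np.zeros(len(y)), y)):
        # per-band CSP fitted on the training fold, shared by every method
        train_feats: List[FeatureMatrix] = []
        test_feats: List[FeatureMatrix] = []
        for be in band_epochs:
            sub = EpochSet(be.data[train], y[train], be.sampling_rate,
                           be.channel_names, band=be.band)
            model = fit_csp(sub, config.csp_components, config.csp_regularization)
            train_feats.append(csp_features(model, sub))
            tst = EpochSet(be.data[test], y[test], be.sampling_rate,
                           be.channel_names, band=be.band)
            test_feats.append(csp_features(model, tst))
        for m in methods:
            band_idx, _ = select_band(
                train_feats, y[train], folds=config.band_folds,
                classifier_factory=lambda _m=m: _method_factory(_m, config),
                seed=config.seed + fold,
            )
            params = None
            if m == "pso-ls-twin-svm":
                if config.optimizer is None:
                    raise ValueError(
                        "method 'pso-ls-twin-svm' needs config.optimizer set")
                params = _tune_on_features(train_feats[band_idx], config, m)
            est = _method_factory(m, config, params)
            est.fit(train_feats[band_idx].values, y[train])
            pred = est.predict(test_feats[band_idx].values)
            correct[m] += int(np.sum(pred == y[test]))
        total += len(test)
    return {m: 100.0 * correct[m] / total for m in methods}


def run_pipeline(epochs: EpochSet, config: PipelineConfig) -> float:
    """Held-out accuracy (percent) of the configured pipeline on one subject."""
    method = "pso-ls-twin-svm" if (config.optimizer is not None
                                   and config.classifier == "lstwsvm") \
        else {"lstwsvm": "ls-twin-svm", "twsvm": "twsvm", "svm": "svm"}[config.classifier]
    return _run_methods(epochs, config, [method])[method]


# ---------------------------------------------------------------------------
# multi-subject comparison report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-subject accuracy matrix (percent) plus summary rows.

    Both the sample SD and the standard error SD/sqrt(n) are reported, since
    summary conventions differ between publications.
    """

    methods: List[str]
    per_subject_accuracy: np.ndarray   # (n_subjects, n_methods), percent
    mean: np.ndarray
    sd: np.ndarray
    standard_error: np.ndarray
    config_snapshot: dict
    seeds: List[int]

    def to_dataframe(self) -> pd.DataFrame:
        idx = [str(i + 1) for i in range(self.per_subject_accuracy.shape[0])]
        df = pd.DataFrame(self.per_subject_accuracy, index=idx,
                          columns=self.methods)
        df.loc["Mean"] = self.mean
        df.loc["SD"] = self.sd
        df.loc["SE"] = self.standard_error
        return df.round(2)

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index_label="testing_object")


def compare_methods(subject_epochs: Sequence[EpochSet],
                    methods: Sequence[str],
                    config: PipelineConfig) -> EvaluationReport:
    """Evaluate several methods on several subjects with paired splits.

    Each subject gets its own derived seed; within a subject every method is
    scored on identical train/test splits so the comparison is paired.
    """
    if not subject_epochs:
        raise ValueError("need at least one subject")
    methods = list(methods)
    accs = np.empty((len(subject_epochs), len(methods)))
    seeds = []
    for s, epochs in enumerate(subject_epochs):
        sub_cfg = config.replace(seed=config.seed + 1000 * s)
        seeds.append(sub_cfg.seed)
        result = _run_methods(epochs, sub_cfg, methods)
        accs[s] = [result[m] for m in methods]
        logger.info("subject %d: %s", s + 1,
                    {m: f"{result[m]:.2f}%" for m in methods})
    summaries = [summarize(accs[:, j]) for j in range(len(methods))]
    return EvaluationReport(
        methods=methods,
        per_subject_accuracy=accs,
        mean=np.array([s[0] for s in summaries]),
        sd=np.array([s[1] for s in summaries]),
        standard_error=np.array([s[2] for s in summaries]),
        config_snapshot=config.to_dict(),
        seeds=seeds,
    )
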