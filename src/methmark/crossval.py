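"""Repeated holdout cross-validation of multi-marker classifiers.

The harness repeats a stratified random 80/20 train/test split (class
proportions preserved to within one sample), fits each registered
classifier on the training split, and averages sensitivity, specificity
and accuracy over repeats for both splits.  The default of 1,000
repeats can be scaled down; the whole repeat schedule is a deterministic
function of the seed.  A k-fold mode is provided as an alternative
protocol.

Three classifiers are implemented natively and registered by default:

* ``logistic`` — multivariate logistic regression (same IRLS core as
  the univariate diagnostics);
* ``naive_bayes`` — Gaussian naive Bayes with per-class, per-feature
  means and variances;
* ``nearest_centroid`` — Euclidean nearest class centroid.

Further algorithms (SVMs, forests, boosting, ...) can be bound to the
same fit/predict contract through :func:`register_classifier`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, RegistryError, StratumError
from .diagnostics import logistic_irls


# ---------------------------------------------------------------------------
# native classifiers

class LogisticClassifier:
    """Multivariate logistic regression (IRLS), decision at p = 0.5."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        design = np.column_stack([np.ones(len(X)), X])
        self._fit = logistic_irls(design, np.asarray(y, dtype=float),
                                  ridge=1e-8)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        design = np.column_stack([np.ones(len(X)), X])
        eta = design @ self._fit.coef
        return (eta >= 0).astype(int)


class GaussianNaiveBayes:
    """Gaussian naive Bayes: independent normal features per class."""

    var_floor = 1e-9

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.theta_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        self.var_ = np.array(
            [X[y == c].var(axis=0) + self.var_floor for c in self.classes_])
        self.log_prior_ = np.log(
            np.array([(y == c).mean() for c in self.classes_]))
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = []
        for k in range(len(self.classes_)):
            ll = -0.5 * np.sum(
                np.log(2.0 * np.pi * self.var_[k])
                + (X - self.theta_[k]) ** 2 / self.var_[k],
                axis=1,
            )
            jll.append(self.log_prior_[k] + ll)
        return np.column_stack(jll)

    def predict(self, X):
        jll = self._joint_log_likelihood(X)
        return self.classes_[np.argmax(jll, axis=1)]


class NearestCentroid:
    """Assign each sample to the class with the nearest (Euclidean) mean."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.centroids_ = np.array(
            [X[y == c].mean(axis=0) for c in self.classes_])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(
            X[:, None, :] - self.centroids_[None, :, :], axis=2)
        return self.classes_[np.argmin(d, axis=1)]


_REGISTRY: dict[str, type] = {}


def register_classifier(name: str, factory, overwrite: bool = False):
    """Register a classifier factory under a unique name.

    The factory must produce objects with ``fit(X, y) -> self`` and
    ``predict(X) -> labels``.  Registering an existing name raises
    unless ``overwrite=True``.
    """
    if name in _REGISTRY and not overwrite:
        raise RegistryError(f"classifier {name!r} is already registered")
    _REGISTRY[name] = factory
    return factory


def get_classifier(name: str):
    if name not in _REGISTRY:
        raise RegistryError(
            f"unknown classifier {name!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name]()


def registered_classifiers() -> list[str]:
    return sorted(_REGISTRY)


register_classifier("logistic", LogisticClassifier)
register_classifier("naive_bayes", GaussianNaiveBayes)
register_classifier("nearest_centroid", NearestCentroid)


# ---------------------------------------------------------------------------
# the repeated-holdout harness

@dataclass(frozen=True)
class CVConfig:
    """Repeated-holdout protocol parameters."""

    train_fraction: float = 0.8
    n_repeats: int = 1000
    classifiers: tuple[str, ...] = ("logistic", "naive_bayes",
                                    "nearest_centroid")
    stratum: str = "all"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise InputError("train_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise InputError("n_repeats must be >= 1")
        for name in self.classifiers:
            if name not in _REGISTRY:
                raise RegistryError(f"unknown classifier {name!r}")


@dataclass
class CVResult:
    """Averaged metrics for one classifier over the repeat schedule."""

    classifier: str
    stratum: str
    n_repeats: int
    seed: int
    train_sensitivity: float = np.nan
    train_specificity: float = np.nan
    train_accuracy: float = np.nan
    test_sensitivity: float = np.nan
    test_specificity: float = np.nan
    test_accuracy: float = np.nan
    train_accuracy_sd: float = np.nan
    test_accuracy_sd: float = np.nan
    n_degenerate_resampled: int = 0
    per_repeat: pd.DataFrame | None = field(default=None, repr=False)


def _metrics(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    neg = y_true == 0
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == 0).mean()) if neg.any() else np.nan
    acc = float((y_pred == y_true).mean())
    return sens, spec, acc


def stratified_split(y, train_fraction: float, rng: np.random.Generator):
    """Random train/test index split preserving class proportions (+/- 1)."""
    y = np.asarray(y)
    train_idx, test_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def repeated_holdout(features, labels, config: CVConfig) -> list[CVResult]:
    """Repeated stratified holdout evaluation of the configured classifiers.

    ``features`` is a samples x markers matrix (DataFrame or array);
    ``labels`` are binary (1 = tumor).  Splits are shared across
    classifiers within a repeat, so classifier comparisons are paired.
    """
    X = (features.to_numpy(dtype=float)
         if isinstance(features, pd.DataFrame)
         else np.asarray(features, dtype=float))
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.shape[0]:
        raise InputError("features and labels must align on samples")
    if np.any(~np.isfinite(X)):
        raise InputError("features must be complete (impute or drop first)")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise StratumError("need >= 2 samples in each class")

    rng = np.random.default_rng([config.seed, 53])
    rows = {name: [] for name in config.classifiers}
    n_degenerate = 0
    for rep in range(config.n_repeats):
        tr, te = stratified_split(y, config.train_fraction, rng)
        while len(np.unique(y[tr])) < 2:      # unreachable with stratification
            n_degenerate += 1
            tr, te = stratified_split(y, config.train_fraction, rng)
        for name in config.classifiers:
            clf = get_classifier(name).fit(X[tr], y[tr])
            m_tr = _metrics(y[tr], clf.predict(X[tr]))
            m_te = _metrics(y[te], clf.predict(X[te]))
            rows[name].append((rep,) + m_tr + m_te)

    results = []
    for name in config.classifiers:
        df = pd.DataFrame(
            rows[name],
            columns=["repeat", "train_sens", "train_spec", "train_acc",
                     "test_sens", "test_spec", "test_acc"],
        )
        results.append(CVResult(
            classifier=name,
            stratum=config.stratum,
            n_repeats=config.n_repeats,
            seed=config.seed,
            train_sensitivity=float(df["train_sens"].mean()),
            train_specificity=float(df["train_spec"].mean()),
            train_accuracy=float(df["train_acc"].mean()),
            test_sensitivity=float(df["test_sens"].mean()),
            test_specificity=float(df["test_spec"].mean()),
            test_accuracy=float(df["test_acc"].mean()),
            train_accuracy_sd=float(df["train_acc"].std(ddof=1))
            if len(df) > 1 else 0.0,
            test_accuracy_sd=float(df["test_acc"].std(ddof=1))
            if len(df) > 1 else 0.0,
            n_degenerate_resampled=n_degenerate,
            per_repeat=df,
        ))
    return results


def kfold_cv(features, labels, n_folds: int = 5, classifiers=None,
             seed: int = 0) -> list[CVResult]:
    """Stratified k-fold alternative to the repeated-holdout protocol."""
    X = (features.to_numpy(dtype=float)
         if isinstance(features, pd.DataFrame)
         else np.asarray(features, dtype=float))
    y = np.asarray(labels).astype(int)
    if classifiers is None:
        classifiers = ("logistic", "naive_bayes", "nearest_centroid")
    rng = np.random.default_rng([seed, 59])

    folds = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds

    results = []
    for name in classifiers:
        rows = []
        for k in range(n_folds):
            tr, te = folds != k, folds == k
            if len(np.unique(y[tr])) < 2 or te.sum() == 0:
                continue
            clf = get_classifier(name).fit(X[tr], y[tr])
            rows.append((k,) + _metrics(y[tr], clf.predict(X[tr]))
                        + _metrics(y[te], clf.predict(X[te])))
        df = pd.DataFrame(
            rows, columns=["repeat", "train_sens", "train_spec", "train_acc",
                           "test_sens", "test_spec", "test_acc"])
        results.append(CVResult(
            classifier=name, stratum="all", n_repeats=len(rows), seed=seed,
            train_sensitivity=float(df["train_sens"].mean()),
            train_specificity=float(df["train_spec"].mean()),
            train_accuracy=float(df["train_acc"].mean()),
            test_sensitivity=float(df["test_sens"].mean()),
            test_specificity=float(df["test_spec"].mean()),
            test_accuracy=float(df["test_acc"].mean()),
            per_repeat=df,
        ))
    return results
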