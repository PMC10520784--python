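"""PCA dimensionality search, Fisher LDA and random-sampling validation.

The classifier pipeline mirrors common practice for small neuroimaging
cohorts: mean-centered PCA fit on training subjects only, a search over
PC counts whose cumulative explained variance lies in a 50-90% window
(picked by inner cross-validated training accuracy), and a two-class
Fisher linear discriminant predicting by nearest projected class mean
with equal priors. Performance is reported as the average sensitivity /
specificity / accuracy over repeated stratified 75/25 splits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from rehoseed.errors import InputError, ParameterError
from rehoseed.features import FeatureMatrix
from rehoseed.groupstats import SubjectTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PCSearchSpec:
    """Window of cumulative explained variance searched for the PC count."""

    variance_lo: float = 0.50
    variance_hi: float = 0.90
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.variance_lo < self.variance_hi <= 1.0):
            raise ParameterError(
                f"need 0 < lo < hi <= 1, got {self.variance_lo}, {self.variance_hi}"
            )


class FisherLDA:
    """Two-class Fisher linear discriminant.

    Projects onto w = Sw^-1 (m1 - m0) where Sw is the pooled within-class
    scatter, and predicts by the nearest projected class mean (equal
    priors). A ridge of 1e-6 * trace(Sw)/dim is added when Sw is singular.
    """

    def __init__(self) -> None:
        self.w_: np.ndarray | None = None
        self.threshold_: float | None = None
        self.classes_: np.ndarray | None = None
        self._flip = 1.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FisherLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise InputError(f"FisherLDA is two-class; got classes {self.classes_}")
        X0, X1 = X[y == self.classes_[0]], X[y == self.classes_[1]]
        if len(X0) < 2 or len(X1) < 2:
            raise InputError("need at least 2 subjects per class")
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        sw = (X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)
        sw = np.atleast_2d(sw)
        d = sw.shape[0]
        if np.linalg.matrix_rank(sw) < d or np.linalg.cond(sw) > 1e12:
            ridge = 1e-6 * np.trace(sw) / d
            ridge = ridge if ridge > 0 else 1e-6
            logger.info("singular within-class scatter; adding ridge %.3g", ridge)
            sw = sw + ridge * np.eye(d)
        w = np.linalg.solve(sw, m1 - m0)
        mu0, mu1 = float(m0 @ w), float(m1 @ w)
        self.w_ = w
        self.threshold_ = 0.5 * (mu0 + mu1)
        self._flip = 1.0 if mu1 >= mu0 else -1.0
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) @ self.w_ - self.threshold_) * self._flip

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


class LinearSVM:
    """Linear soft-margin SVM (C=1) behind the same fit/predict surface."""

    def __init__(self, C: float = 1.0) -> None:
        self._svc = SVC(kernel="linear", C=C)

    def fit(self, X, y) -> "LinearSVM":
        self._svc.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict(self, X) -> np.ndarray:
        return self._svc.predict(np.asarray(X, dtype=float))


CLASSIFIERS = {"lda": FisherLDA, "linsvm": LinearSVM}


def make_classifier(name: str):
    if name not in CLASSIFIERS:
        raise ParameterError(f"unknown classifier {name!r}; choose from {sorted(CLASSIFIERS)}")
    return CLASSIFIERS[name]()


def pca_fit_reduce(train: np.ndarray, n_components: int, *tests: np.ndarray):
    """Fit mean-centered PCA on training rows and project.

    Returns (fitted PCA, reduced training matrix, *reduced test matrices);
    test rows are projected with the training mean and components only.
    """
    train = np.asarray(train, dtype=float)
    max_nc = min(train.shape[0] - 1, train.shape[1])
    if not (1 <= n_components <= max_nc):
        raise ParameterError(
            f"n_components={n_components} not in [1, {max_nc}] for shape {train.shape}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    reduced = pca.fit_transform(train)
    projected = [pca.transform(np.asarray(t, dtype=float)) for t in tests]
    return (pca, reduced, *projected)


def _inner_cv_accuracy(
    X: np.ndarray, y: np.ndarray, n_components: int, classifier_name: str,
    n_splits: int, seed: int,
) -> float:
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = total = 0
    for tr, te in skf.split(X, y):
        if min(np.bincount(y[tr].astype(int))) < 2:
            continue
        nc = min(n_components, len(tr) - 1, X.shape[1])
        _, r_tr, r_te = pca_fit_reduce(X[tr], nc, X[te])
        clf = make_classifier(classifier_name).fit(r_tr, y[tr])
        correct += int((clf.predict(r_te) == y[te]).sum())
        total += len(te)
    return correct / total if total else 0.0


def choose_n_components(
    train: np.ndarray,
    labels: np.ndarray,
    spec: PCSearchSpec = PCSearchSpec(),
    classifier: str = "lda",
    seed: int = 0,
) -> int:
    """PC count with best inner-CV training accuracy in the variance window.

    Candidates are counts whose cumulative explained variance on the
    training set falls in [variance_lo, variance_hi]; ties break to the
    smaller count. If no count lands in the window, the count nearest
    variance_lo is used with a warning.
    """
    train = np.asarray(train, dtype=float)
    labels = np.asarray(labels)
    max_nc = min(train.shape[0] - 1, train.shape[1])
    pca = PCA(n_components=max_nc, svd_solver="full").fit(train)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    counts = np.arange(1, max_nc + 1)
    in_window = counts[(cumvar >= spec.variance_lo) & (cumvar <= spec.variance_hi)]
    if in_window.size == 0:
        nearest = int(counts[np.argmin(np.abs(cumvar - spec.variance_lo))])
        logger.warning(
            "no PC count reaches the %.0f-%.0f%% variance window; using %d",
            100 * spec.variance_lo, 100 * spec.variance_hi, nearest,
        )
        return nearest
    y_int = np.unique(labels, return_inverse=True)[1]
    n_splits = int(min(spec.inner_folds, np.bincount(y_int).min()))
    if n_splits < 2:
        return int(in_window[0])
    best_nc, best_acc = int(in_window[0]), -1.0
    for nc in in_window:
        acc = _inner_cv_accuracy(train, y_int, int(nc), classifier, n_splits, seed)
        if acc > best_acc + 1e-12:
            best_nc, best_acc = int(nc), acc
    return best_nc


@dataclass
class ValidationReport:
    """Confusion counts and chosen PC count per random-sampling repeat."""

    repeats: list[dict] = field(default_factory=list)
    mode: str = "paper"
    classifier: str = "lda"
    seed: int = 0

    @staticmethod
    def metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
        return {
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
            "accuracy": (tp + tn) / (tp + tn + fp + fn),
        }

    def add_repeat(self, tp: int, tn: int, fp: int, fn: int, n_components: int) -> None:
        rec = {"tp": tp, "tn": tn, "fp": fp, "fn": fn, "n_components": n_components}
        rec.update(self.metrics(tp, tn, fp, fn))
        self.repeats.append(rec)

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([r["sensitivity"] for r in self.repeats]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([r["specificity"] for r in self.repeats]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r["accuracy"] for r in self.repeats]))

    @property
    def mean_n_components(self) -> float:
        return float(np.mean([r["n_components"] for r in self.repeats]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.repeats)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "classifier": self.classifier,
                "seed": self.seed,
                "repeats": self.repeats,
                "mean_sensitivity": self.mean_sensitivity,
                "mean_specificity": self.mean_specificity,
                "mean_accuracy": self.mean_accuracy,
                "mean_n_components": self.mean_n_components,
            },
            indent=2,
        )


def _stratified_split(table: SubjectTable, test_fraction: float, rng: np.random.Generator):
    """Index split stratified by group; both groups kept nonempty in train."""
    group = table.group_indicator()
    test_idx = []
    for g in (0.0, 1.0):
        idx = np.flatnonzero(group == g)
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 2)
        test_idx.extend(rng.permutation(idx)[:n_test])
    test_idx = np.sort(np.asarray(test_idx))
    train_idx = np.setdiff1d(np.arange(table.n_subjects), test_idx)
    return train_idx, test_idx


def random_sampling_validate(
    features,
    table: SubjectTable,
    test_fraction: float = 0.25,
    repeats: int = 10,
    seed: int = 0,
    mode: str = "paper",
    classifier: str = "lda",
    pc_spec: PCSearchSpec = PCSearchSpec(),
) -> ValidationReport:
    """Repeated stratified random-sampling validation.

    Each repeat holds out ``test_fraction`` of subjects (stratified by
    group), chooses the PC count on the training set, fits the classifier
    and scores the held-out subjects; sensitivity (ADHD recall),
    specificity (control recall) and accuracy are averaged over repeats.

    In ``mode="paper"`` ``features`` is a FeatureMatrix built upstream
    from full-sample candidate voxels. In ``mode="nested"`` ``features``
    is a callable ``builder(train_table) -> (X_train, transform)`` that
    derives seeds and candidates from the training subjects only and
    projects any subject list with ``transform(subject_ids)``.
    """
    if mode not in ("paper", "nested"):
        raise ParameterError(f"mode must be 'paper' or 'nested', got {mode!r}")
    if mode == "paper" and not isinstance(features, FeatureMatrix):
        raise InputError("paper mode requires a FeatureMatrix")
    if mode == "nested" and not callable(features):
        raise InputError("nested mode requires a builder callable")
    report = ValidationReport(mode=mode, classifier=classifier, seed=seed)
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(repeats):
        rng = np.random.default_rng(child)
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        train_idx, test_idx = _stratified_split(table, test_fraction, rng)
        train_tab, test_tab = table.subset(train_idx), table.subset(test_idx)
        y_train = train_tab.group_indicator()
        y_test = test_tab.group_indicator()
        if mode == "paper":
            X_train = features.rows(train_tab.subject_ids)
            X_test = features.rows(test_tab.subject_ids)
        else:
            X_train, transform = features(train_tab)
            X_test = transform(test_tab.subject_ids)
        nc = choose_n_components(X_train, y_train, pc_spec, classifier, seed=sub_seed)
        _, r_train, r_test = pca_fit_reduce(X_train, nc, X_test)
        clf = make_classifier(classifier).fit(r_train, y_train)
        pred = clf.predict(r_test)
        tp = int(((pred == 1) & (y_test == 1)).sum())
        tn = int(((pred == 0) & (y_test == 0)).sum())
        fp = int(((pred == 1) & (y_test == 0)).sum())
        fn = int(((pred == 0) & (y_test == 1)).sum())
        report.add_repeat(tp, tn, fp, fn, nc)
    return report
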