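"""Stress-level classification: class balancing, feature selection and
reduction, cross-validated training, and the separability experiments.

The learning stage follows scikit-learn conventions: a correlation-based
feature selector (:class:`CBFSSelector`) and a stress classifier
(:class:`StressLevelClassifier`) that compose into ordinary sklearn
pipelines, plus thin functions for undersampling, cross-validated
evaluation and the per-modality experiment grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .io_e4 import ValidationError

__all__ = [
    "ALGORITHMS",
    "MODALITY_PREFIXES",
    "CVResult",
    "undersample",
    "CBFSSelector",
    "cbfs_select",
    "pca_reduce",
    "StressLevelClassifier",
    "train_eval",
    "feature_columns",
    "modality_columns",
    "separability_experiment",
    "run_separability_suite",
]

ALGORITHMS = ("mlp", "rf", "knn", "lda", "svm")
MODALITY_PREFIXES = {"hrv": "hrv_", "eda": "eda_", "acc": "acc_"}

#: small documented grids searched within training folds
GRIDS: dict[str, dict[str, list]] = {
    "mlp": {"clf__hidden_layer_sizes": [(16,), (64,)]},
    "rf": {},
    "knn": {"clf__n_neighbors": [1, 2, 3, 4]},
    "lda": {},
    "svm": {"clf__C": [0.1, 1.0, 10.0]},
}


def undersample(
    table: pd.DataFrame, seed: int = 0, label_col: str = "label"
) -> pd.DataFrame:
    """Randomly downsample every class to the minority-class count.

    Deterministic under ``seed``; raises when fewer than two classes are
    present.
    """
    counts = table[label_col].value_counts()
    if len(counts) < 2:
        raise ValidationError("undersampling needs at least two classes")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls, group in table.groupby(label_col, sort=True):
        idx = rng.choice(len(group), size=n_min, replace=False)
        parts.append(group.iloc[np.sort(idx)])
    return pd.concat(parts).sort_index().reset_index(drop=True)


class CBFSSelector(SelectorMixin, BaseEstimator):
    """Correlation-based feature selection: keep the k features most
    correlated with the class label.

    Each feature is scored by the absolute Pearson correlation with the
    class indicator — point-biserial for two classes, and the maximum over
    one-vs-rest indicators for more.  Constant features score 0.
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, X, y):
        X = validate_data(self, X, reset=True)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValidationError("CBFS needs at least two classes")
        Xc = X - X.mean(axis=0)
        sx = X.std(axis=0)
        scores = np.zeros(X.shape[1])
        for cls in classes:
            ind = (y == cls).astype(float)
            ind -= ind.mean()
            s_ind = ind.std()
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (Xc.T @ ind) / (len(y) * sx * s_ind)
            scores = np.maximum(scores, np.abs(np.nan_to_num(r)))
        self.scores_ = scores
        k = self.k
        if k > X.shape[1]:
            warnings.warn(
                f"k={k} exceeds {X.shape[1]} features; keeping all", stacklevel=2
            )
            k = X.shape[1]
        order = np.argsort(-scores, kind="stable")
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[order[:k]] = True
        self.ranking_ = order
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


def cbfs_select(
    table: pd.DataFrame, k: int = 10, label_col: str = "label"
) -> pd.DataFrame:
    """Rank feature columns by class correlation; return the top k with scores."""
    cols = feature_columns(table)
    sel = CBFSSelector(k=k).fit(table[cols].to_numpy(), table[label_col].to_numpy())
    ranked = pd.DataFrame(
        {"feature": np.array(cols)[sel.ranking_], "score": sel.scores_[sel.ranking_]}
    )
    return ranked.head(min(k, len(cols))).reset_index(drop=True)


def pca_reduce(X: np.ndarray, variance: float = 0.95) -> tuple[np.ndarray, Pipeline]:
    """Standardize and project onto the fewest components covering
    ``variance`` of the total; returns the data and the fitted transform
    (reusable on held-out folds)."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("PCA input must be finite")
    pipe = Pipeline(
        [("scale", StandardScaler()), ("pca", PCA(n_components=variance, svd_solver="full"))]
    )
    return pipe.fit_transform(X), pipe


class StressLevelClassifier(ClassifierMixin, BaseEstimator):
    """One of the five stress classifiers behind a uniform sklearn facade.

    Parameters
    ----------
    algorithm : {"mlp", "rf", "knn", "lda", "svm"}
        MLP, 100-tree random forest, k-nearest neighbours (k searched over
        1–4), linear discriminant analysis, or an RBF support vector
        machine.
    reducer : {"auto", "cbfs", "pca", "none"}
        Feature reduction fitted inside the training data: CBFS top-``k``
        for MLP/RF/kNN/LDA and PCA at ``variance`` covered variance for the
        SVM when "auto".
    grid_search : bool
        Nested 3-fold grid search over the algorithm's small grid.
    """

    def __init__(
        self,
        algorithm: str = "rf",
        reducer: str = "auto",
        k: int = 10,
        variance: float = 0.95,
        grid_search: bool = False,
        seed: int = 0,
    ):
        self.algorithm = algorithm
        self.reducer = reducer
        self.k = k
        self.variance = variance
        self.grid_search = grid_search
        self.seed = seed

    def _base_estimator(self):
        if self.algorithm == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=(16,), max_iter=500, random_state=self.seed
            )
        if self.algorithm == "rf":
            return RandomForestClassifier(n_estimators=100, random_state=self.seed)
        if self.algorithm == "knn":
            return KNeighborsClassifier(n_neighbors=4)
        if self.algorithm == "lda":
            return LinearDiscriminantAnalysis()
        if self.algorithm == "svm":
            return SVC(kernel="rbf", random_state=self.seed)
        raise ValidationError(f"unknown algorithm {self.algorithm!r}")

    def _build_pipeline(self) -> Pipeline:
        reducer = self.reducer
        if reducer == "auto":
            reducer = "pca" if self.algorithm == "svm" else "cbfs"
        steps: list[tuple] = []
        if reducer == "cbfs":
            steps.append(("reduce", CBFSSelector(k=self.k)))
        if self.algorithm != "rf":  # tree ensembles use raw feature scales
            steps.append(("scale", StandardScaler()))
        if reducer == "pca":
            steps.append(("pca", PCA(n_components=self.variance, svd_solver="full")))
        steps.append(("clf", self._base_estimator()))
        return Pipeline(steps)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValidationError("need at least two classes")
        pipe = self._build_pipeline()
        grid = GRIDS.get(self.algorithm, {}) if self.grid_search else {}
        if grid:
            search = GridSearchCV(
                pipe,
                grid,
                cv=StratifiedKFold(3, shuffle=True, random_state=self.seed),
                n_jobs=1,
            )
            search.fit(X, y)
            self.pipeline_ = search.best_estimator_
            self.best_params_ = search.best_params_
        else:
            self.pipeline_ = pipe.fit(X, y)
            self.best_params_ = {}
        self.classes_ = self.pipeline_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(np.asarray(X, dtype=float))

    def selected_support_(self) -> np.ndarray | None:
        check_is_fitted(self, "pipeline_")
        step = self.pipeline_.named_steps.get("reduce")
        return step.get_support() if step is not None else None


@dataclass
class CVResult:
    """Stratified cross-validation outcome for one model configuration."""

    accuracy: float  # %, pooled over folds
    fold_accuracies: list[float] = field(default_factory=list)
    confusion: pd.DataFrame | None = None
    selected_features: list[str] | None = None
    seed: int = 0
    n: int = 0


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Numeric feature columns of a merged table (modality-prefixed)."""
    return [
        c
        for c in table.columns
        if any(c.startswith(p) for p in MODALITY_PREFIXES.values())
    ]


def modality_columns(table: pd.DataFrame, modality: str) -> list[str]:
    """Feature columns of one modality, or all of them for "combined"."""
    if modality == "combined":
        return feature_columns(table)
    prefix = MODALITY_PREFIXES[modality]
    return [c for c in table.columns if c.startswith(prefix)]


def train_eval(
    table: pd.DataFrame,
    classifier: StressLevelClassifier | None = None,
    columns: list[str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    label_col: str = "label",
) -> CVResult:
    """10-fold stratified cross-validation of one classifier.

    Reducers and scalers live inside the classifier's pipeline, so they are
    fitted on each training fold only.  Accuracy is the pooled
    confusion-matrix trace ratio, in percent.
    """
    classifier = classifier or StressLevelClassifier(seed=seed)
    columns = columns or feature_columns(table)
    X = table[columns].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("need at least two classes")
    if len(table) < n_folds:
        raise ValidationError("fewer rows than folds")
    min_class = int(pd.Series(y).value_counts().min())
    if min_class < n_folds:
        warnings.warn(
            f"capping folds at the smallest class count ({min_class})",
            stacklevel=2,
        )
        n_folds = min_class
    if n_folds < 2:
        raise ValidationError("need at least 2 members per class to cross-validate")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_true_all, y_pred_all, fold_acc = [], [], []
    for train_idx, test_idx in skf.split(X, y):
        est = clone(classifier).fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        y_true_all.append(y[test_idx])
        y_pred_all.append(pred)
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    selected = None
    full_fit = clone(classifier).fit(X, y)
    support = full_fit.selected_support_()
    if support is not None:
        selected = [c for c, s in zip(columns, support) if s]
    return CVResult(
        accuracy=float(np.trace(cm) / cm.sum() * 100.0),
        fold_accuracies=fold_acc,
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        selected_features=selected,
        seed=seed,
        n=len(y),
    )


#: the experiment designs: name -> mapping from session label/method to class
DESIGNS = {
    "3class": ("high", "mild", "relax"),
    "high_vs_mild": ("high", "mild"),
    "high_vs_relax": ("high", "relax"),
}


def separability_experiment(
    table: pd.DataFrame,
    design: str | tuple[str, ...],
    algorithms: tuple[str, ...] = ALGORITHMS,
    modalities: tuple[str, ...] = ("hrv", "eda", "acc", "combined"),
    seed: int = 0,
    grid_search: bool = False,
    label_col: str = "label",
) -> pd.DataFrame:
    """Accuracy matrix (algorithm × modality) for one class design.

    ``design`` is a named design ("3class", "high_vs_mild",
    "high_vs_relax") or an explicit tuple of class labels.  The table is
    restricted to those labels, undersampled to balance, and each
    algorithm/modality cell is a 10-fold stratified CV accuracy in percent.
    """
    labels = DESIGNS[design] if isinstance(design, str) else tuple(design)
    sub = table[table[label_col].isin(labels)]
    missing = set(labels) - set(sub[label_col])
    if missing:
        raise ValidationError(f"conditions {sorted(missing)} absent from table")
    sub = undersample(sub, seed=seed, label_col=label_col)
    out = pd.DataFrame(index=list(algorithms), columns=list(modalities), dtype=float)
    for alg in algorithms:
        for mod in modalities:
            clf = StressLevelClassifier(algorithm=alg, seed=seed, grid_search=grid_search)
            res = train_eval(
                sub, clf, columns=modality_columns(sub, mod), seed=seed,
                label_col=label_col,
            )
            out.loc[alg, mod] = res.accuracy
    out.index.name = "algorithm"
    return out


def run_separability_suite(
    table: pd.DataFrame,
    method_col: str | None = "method",
    seed: int = 0,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """The full experiment grid: 3-class, both pairwise designs, and — when
    a relaxation-method column is present — each method vs the high-stress
    presentation, per modality and combined."""
    reports = {
        name: separability_experiment(table, name, seed=seed, **kwargs)
        for name in DESIGNS
    }
    if method_col and method_col in table.columns:
        methods = sorted(
            m for m in table.loc[table["label"] == "relax", method_col].dropna().unique()
        )
        for m in methods:
            sub = table[
                (table["label"] == "high") | (table[method_col] == m)
            ].copy()
            reports[f"high_vs_{m}"] = separability_experiment(
                sub, ("high", "relax"), seed=seed, **kwargs
            )
    return reports
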