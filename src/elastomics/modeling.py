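"""Cohort splitting, SMOTE rebalancing, LASSO selection and risk scoring.

The modelling stage mirrors standard ultrasomics practice for a
benign/malignant endpoint:

1. stratified random split of the cohort (default 1:1 train:validation),
2. SMOTE oversampling of the minority class — *training set only*, so no
   synthetic sample can leak information into validation,
3. L1-penalized (LASSO) logistic regression over a lambda grid, lambda
   chosen by k-fold cross-validated deviance with the one-standard-error
   rule, the surviving nonzero-coefficient features being the selected
   signature,
4. one of four classifiers (random forest, RBF support-vector machine,
   AdaBoost stumps, plain logistic regression) fitted on the selected
   features.  Margin classifiers (SVM, AdaBoost) are passed through
   Platt-style sigmoid calibration fitted on training folds so every
   model emits a comparable malignancy risk score in [0, 1].

Every stochastic step takes an explicit seed; a run manifest of all
seeds and hyperparameters makes two runs with the same manifest agree
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, DomainError, SchemaError
from .features import FeatureTable

# ---------------------------------------------------------------------------
# Split


@dataclass(frozen=True)
class SplitSpec:
    """Stratified random train:validation split specification."""

    train_fraction: float = 0.5  # 1:1 by default
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train fraction must be in (0, 1)")


def stratified_split(table: FeatureTable, spec: SplitSpec
                     ) -> tuple[FeatureTable, FeatureTable]:
    """Split rows preserving class proportions to integer rounding.

    The two sides partition the input exactly; reproducible by seed.
    """
    classes, counts = np.unique(table.labels, return_counts=True)
    if spec.stratified and (len(classes) < 2 or counts.min() < 2):
        raise DomainError("stratified split needs >= 2 lesions per class")
    idx = np.arange(table.n)
    train_idx, valid_idx = train_test_split(
        idx, train_size=spec.train_fraction, shuffle=True,
        stratify=table.labels if spec.stratified else None,
        random_state=spec.seed,
    )
    return table.subset(np.sort(train_idx)), table.subset(np.sort(valid_idx))


# ---------------------------------------------------------------------------
# SMOTE


def smote_oversample(train: FeatureTable, k_neighbors: int = 5,
                     seed: int = 0) -> FeatureTable:
    """Raise the minority class to the majority count by interpolation.

    Each synthetic sample is ``x + u * (x' - x)`` with ``u ~ U(0, 1)``,
    ``x`` a minority sample and ``x'`` one of its ``k_neighbors``
    nearest minority neighbours (Euclidean distance on features
    standardized over the training set; interpolation happens in the
    original feature space).  Majority rows pass through untouched; an
    already balanced table is returned unchanged.
    """
    classes, counts = np.unique(train.labels, return_counts=True)
    if len(classes) != 2:
        raise DomainError("SMOTE expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return train
    if n_min < 2:
        raise DomainError("SMOTE needs >= 2 minority samples to interpolate")
    k = k_neighbors
    if k > n_min - 1:
        warnings.warn(
            f"k_neighbors={k} > minority-1={n_min - 1}; truncating",
            stacklevel=2,
        )
        k = n_min - 1

    rng = np.random.default_rng(seed)
    min_idx = np.nonzero(train.labels == minority)[0]
    X_min = train.X[min_idx]
    sd = train.X.std(axis=0)
    sd[sd == 0] = 1.0
    Z_min = (X_min - train.X.mean(axis=0)) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z_min)
    neigh = nn.kneighbors(Z_min, return_distance=False)[:, 1:]

    n_new = int(n_maj - n_min)
    base = rng.integers(0, len(min_idx), size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    X_new = X_min[base] + u[:, None] * (X_min[neigh[base, pick]] - X_min[base])

    ids = train.ids + [f"smote_{i:04d}" for i in range(n_new)]
    labels = np.concatenate([train.labels, np.full(n_new, minority)])
    X = np.vstack([train.X, X_new])
    return FeatureTable(ids, labels, train.feature_names, X)


# ---------------------------------------------------------------------------
# LASSO selection


@dataclass
class LassoResult:
    """Outcome of cross-validated L1 logistic feature selection."""

    selected: list[str]
    lambda_grid: np.ndarray
    chosen_lambda: float
    cv_deviance: np.ndarray  # mean held-out deviance per lambda
    cv_se: np.ndarray
    folds: int
    seed: int
    dropped_constant: list[str] = field(default_factory=list)
    collapsed_duplicates: list[str] = field(default_factory=list)
    coefficients: dict[str, float] = field(default_factory=dict)


def _preprocess_columns(table: FeatureTable) -> tuple[FeatureTable, list[str], list[str]]:
    """Drop constant columns; collapse exact duplicates keeping lowest index."""
    X = table.X
    keep: list[int] = []
    dropped: list[str] = []
    collapsed: list[str] = []
    seen: dict[bytes, int] = {}
    for j, name in enumerate(table.feature_names):
        col = X[:, j]
        if np.all(col == col[0]):
            dropped.append(name)
            continue
        key = col.tobytes()
        if key in seen:
            collapsed.append(name)
            continue
        seen[key] = j
        keep.append(j)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature columns", stacklevel=3)
    if collapsed:
        warnings.warn(
            f"collapsing {len(collapsed)} duplicate feature columns "
            "(keeping lowest index)", stacklevel=3,
        )
    reduced = FeatureTable(table.ids, table.labels,
                           [table.feature_names[j] for j in keep], X[:, keep])
    return reduced, dropped, collapsed


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                 seed: int = 0) -> LogisticRegression:
    # liblinear objective: C * sum(logloss) + |w|_1  ==  mean logloss + lam*|w|_1
    # up to scale, with C = 1 / (n * lam); random_state pins liblinear's
    # internal shuffling so identical calls give identical paths
    model = LogisticRegression(
        solver="liblinear", l1_ratio=1.0, C=1.0 / (len(y) * lam),
        max_iter=2000, random_state=seed,
    )
    return model.fit(X, y)


def lasso_select(train: FeatureTable, folds: int = 5,
                 lambda_grid: Sequence[float] | None = None,
                 seed: int = 0) -> LassoResult:
    """Select features by cross-validated L1 logistic regression.

    Features are standardized on the training table; constant columns
    are dropped and exact duplicate columns collapsed to the lowest
    index before fitting.  Lambda is the largest grid value whose mean
    held-out deviance is within one standard error of the minimum
    (1-SE rule); if the refit at that lambda selects nothing, the
    minimum-deviance lambda is used as a fallback.
    """
    reduced, dropped, collapsed = _preprocess_columns(train)
    if not reduced.feature_names:
        raise DomainError("no non-constant features to select from")
    y = reduced.labels
    if len(np.unique(y)) < 2:
        raise DomainError("training set must contain both classes")
    mu, sd = reduced.X.mean(axis=0), reduced.X.std(axis=0)
    Z = (reduced.X - mu) / sd

    if lambda_grid is None:
        # lambda_max: smallest penalty with all-zero solution for the
        # standardized logistic problem; descend three decades from it.
        pbar = y.mean()
        lam_max = np.abs(Z.T @ (y - pbar)).max() / len(y)
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-3, 30)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=np.float64)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((len(lambda_grid), folds))
    for f, (tr, te) in enumerate(skf.split(Z, y)):
        for i, lam in enumerate(lambda_grid):
            model = _l1_logistic(Z[tr], y[tr], lam, seed)
            prob = model.predict_proba(Z[te])[:, 1]
            dev[i, f] = 2.0 * log_loss(y[te], prob, labels=[0, 1])
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_dev))
    threshold = mean_dev[best] + se_dev[best]
    # grid is descending: index 0 is the strongest shrinkage
    one_se = int(np.nonzero(mean_dev <= threshold)[0][0])

    def _fit_select(lam: float) -> tuple[list[str], dict[str, float]]:
        model = _l1_logistic(Z, y, lam, seed)
        coef = model.coef_.ravel()
        nz = np.nonzero(coef)[0]
        return ([reduced.feature_names[j] for j in nz],
                {reduced.feature_names[j]: float(coef[j]) for j in nz})

    chosen = float(lambda_grid[one_se])
    selected, coefs = _fit_select(chosen)
    if not selected and one_se != best:
        chosen = float(lambda_grid[best])
        selected, coefs = _fit_select(chosen)
    return LassoResult(
        selected=selected, lambda_grid=lambda_grid, chosen_lambda=chosen,
        cv_deviance=mean_dev, cv_se=se_dev, folds=folds, seed=seed,
        dropped_constant=dropped, collapsed_duplicates=collapsed,
        coefficients=coefs,
    )


# ---------------------------------------------------------------------------
# Classifiers


CLASSIFIER_KINDS = ("RF", "SVM", "AdaBoost", "LR")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four risk-score classifiers with its hyperparameters."""

    kind: str = "RF"
    seed: int = 0
    n_trees: int = 500  # RF
    n_stumps: int = 100  # AdaBoost
    svm_c: float = 1.0
    calibration_folds: int = 5  # sigmoid calibration for SVM / AdaBoost

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigError(f"classifier kind must be one of {CLASSIFIER_KINDS}")


@dataclass
class FittedModel:
    """A fitted risk-score model bound to its feature signature."""

    spec: ClassifierSpec
    feature_names: list[str]
    pipeline: Pipeline


@dataclass
class RiskScore:
    """Per-lesion malignancy scores in [0, 1] for one model and cohort."""

    ids: list[str]
    scores: np.ndarray
    model: str
    cohort: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise DomainError("risk scores must lie in [0, 1]")


def _build_estimator(spec: ClassifierSpec, n_min_class: int):
    cal_cv = max(2, min(spec.calibration_folds, n_min_class))
    if spec.kind == "RF":
        return RandomForestClassifier(n_estimators=spec.n_trees,
                                      random_state=spec.seed)
    if spec.kind == "SVM":
        base = SVC(kernel="rbf", C=spec.svm_c, gamma="scale",
                   random_state=spec.seed)
        return CalibratedClassifierCV(base, method="sigmoid", cv=cal_cv)
    if spec.kind == "AdaBoost":
        base = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=spec.n_stumps, random_state=spec.seed,
        )
        return CalibratedClassifierCV(base, method="sigmoid", cv=cal_cv)
    # unpenalized logistic regression on the (few) selected features
    return LogisticRegression(C=np.inf, max_iter=5000)


def train_score(train: FeatureTable, spec: ClassifierSpec) -> FittedModel:
    """Fit one risk-score classifier on the (selected-feature) table."""
    classes, counts = np.unique(train.labels, return_counts=True)
    if len(classes) < 2:
        raise DomainError("single-class training set")
    pipeline = Pipeline([
        ("scale", StandardScaler()),
        ("clf", _build_estimator(spec, int(counts.min()))),
    ])
    pipeline.fit(train.X, train.labels)
    return FittedModel(spec=spec, feature_names=list(train.feature_names),
                       pipeline=pipeline)


def predict_scores(model: FittedModel, table: FeatureTable,
                   cohort: str = "") -> RiskScore:
    """Malignancy probability per lesion, in the table's row order."""
    missing = set(model.feature_names) - set(table.feature_names)
    if missing:
        raise SchemaError(f"table lacks model features: {sorted(missing)[:5]}")
    restricted = table.select(model.feature_names)
    prob = model.pipeline.predict_proba(restricted.X)[:, 1]
    return RiskScore(ids=list(table.ids), scores=np.clip(prob, 0.0, 1.0),
                     model=model.spec.kind, cohort=cohort)


# ---------------------------------------------------------------------------
# Operating cutoff


def choose_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Youden-optimal cutoff (max sensitivity + specificity - 1).

    Candidates are the midpoints between consecutive distinct scores
    (prediction rule: score >= cutoff is malignant); ties are broken
    toward the lower cutoff.  Degenerate single-valued scores give 0.5
    with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DomainError("cutoff needs both classes")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        warnings.warn("all scores identical; returning cutoff 0.5", stacklevel=2)
        return 0.5
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_cut, best_j = None, -np.inf
    for cut in candidates:  # ascending; strict > keeps the lowest tie
        pred = scores >= cut
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_cut = j, float(cut)
    return best_cut
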