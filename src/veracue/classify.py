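"""Truth/lie classification from the stylometric feature battery.

Features are converted to per-token rates (count families), standardized
with training-fold statistics only, and evaluated by k-fold
cross-validation (20 folds by default), reporting mean accuracy and the
standard error of the fold accuracies. Because every subject contributes
four statements, folds are grouped by subject by default so the model is
scored on unseen authors rather than on recognized personal style; a
non-grouped mode is available for comparison.

The built-in baseline is an L2-regularized logistic regression fitted by
full-batch gradient descent (deterministic, dependency-free). SVM with an
RBF kernel and gradient boosting are available behind the same interface
as thin adapters over scikit-learn and XGBoost with their default
hyperparameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon_features import FeatureConfig, count_feature_names, feature_names

logger = logging.getLogger(__name__)

LABEL_MAP = {"truth": 0, "lie": 1}


@dataclass
class CVResult:
    subset: str
    model_name: str
    fold_accuracies: list[float]
    mean_acc: float
    se_acc: float
    seed: int
    k: int
    n_rows: int
    group_aware: bool

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "model": self.model_name,
            "k": self.k,
            "n_rows": self.n_rows,
            "group_aware": self.group_aware,
            "seed": self.seed,
            "mean_accuracy": self.mean_acc,
            "se_accuracy": self.se_acc,
            "fold_accuracies": self.fold_accuracies,
        }


def assemble_matrix(
    table: pd.DataFrame,
    subset: str = "all",
    config: FeatureConfig = FeatureConfig(),
    columns: list[str] | None = None,
):
    """Build (X, y, groups) for classification.

    ``subset`` filters by modality (``all`` / ``written`` /
    ``transcribed``). Count features become per-token rates; rows with any
    missing selected feature are dropped (and logged). Labels are 0 =
    truth, 1 = lie; groups are subject ids.
    """
    if subset not in ("all", "written", "transcribed"):
        raise ValueError(f"unknown subset {subset!r}")
    df = table if subset == "all" else table[table["modality"] == subset]
    if df.empty:
        raise ValueError(f"subset {subset!r} selects no rows")
    if columns is None:
        present = set(df.columns)
        columns = [n for n in feature_names(config) if n in present]
        if "ne_count" in present:
            columns.append("ne_count")
    missing_cols = [c for c in columns if c not in df.columns]
    if missing_cols:
        raise ValueError(f"feature columns absent from table: {missing_cols}")

    X = df[columns].to_numpy(dtype=float).copy()
    count_set = set(count_feature_names(config)) | {"ne_count"}
    n_tokens = df["n_tokens"].to_numpy(dtype=float)
    for j, name in enumerate(columns):
        if name in count_set:
            X[:, j] = X[:, j] / n_tokens

    keep = np.isfinite(X).all(axis=1)
    if not keep.all():
        logger.info("dropping %d rows with missing features", int((~keep).sum()))
    X = X[keep]
    y = df["veracity"].map(LABEL_MAP).to_numpy(dtype=int)[keep]
    groups = df["subject_id"].to_numpy()[keep]
    return X, y, groups, columns


@dataclass
class LogisticBaseline:
    """L2-regularized logistic regression, full-batch gradient descent.

    The step size is the inverse of a Lipschitz bound on the gradient, so
    descent is monotone without line search; iteration stops when the
    gradient's max-norm drops below ``tol``. The intercept is not
    penalized. Deterministic (zero initialization).
    """

    l2: float = 1.0
    tol: float = 1e-6
    max_iter: int = 10000
    w: np.ndarray = field(default=None)  # type: ignore[assignment]
    b: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticBaseline":
        if not np.isfinite(X).all():
            raise ValueError("non-finite features")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        n, d = X.shape
        self.w = np.zeros(d)
        self.b = 0.0
        # Lipschitz bound for mean log-loss gradient: 0.25 * lam_max(G)/n + l2,
        # bounded above via the Frobenius norm of [X, 1].
        lip = 0.25 * (float(np.sum(X * X)) + n) / n + self.l2
        step = 1.0 / lip
        for _ in range(self.max_iter):
            z = np.clip(X @ self.w + self.b, -35.0, 35.0)
            p = 1.0 / (1.0 + np.exp(-z))
            err = p - y
            gw = X.T @ err / n + self.l2 * self.w
            gb = float(err.mean())
            if max(float(np.abs(gw).max()), abs(gb)) < self.tol:
                break
            self.w -= step * gw
            self.b -= step * gb
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = np.clip(X @ self.w + self.b, -35.0, 35.0)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_baseline_classifier(X: np.ndarray, y: np.ndarray, l2: float = 1.0, tol: float = 1e-6):
    """Fit the native logistic baseline; returns the fitted model."""
    return LogisticBaseline(l2=l2, tol=tol).fit(X, y)


def _make_model(model_spec: str, seed: int):
    """Model registry: 'baseline' (native), 'svm' and 'gboost' adapters."""
    if model_spec == "baseline":
        return LogisticBaseline()
    if model_spec == "svm":
        from sklearn.svm import SVC  # noqa: PLC0415 - optional dependency

        return SVC(kernel="rbf", random_state=seed)
    if model_spec == "gboost":
        try:
            from xgboost import XGBClassifier  # noqa: PLC0415

            return XGBClassifier(random_state=seed, verbosity=0)
        except ImportError:
            from sklearn.ensemble import GradientBoostingClassifier  # noqa: PLC0415

            return GradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown model spec {model_spec!r}")


def _standardize(train: np.ndarray, test: np.ndarray):
    """Z-score both splits using training-fold statistics only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def make_folds(
    n: int,
    groups: np.ndarray,
    k: int,
    seed: int,
    group_aware: bool = True,
) -> np.ndarray:
    """Deterministic fold assignment (0..k-1) per row.

    Group-aware mode shuffles the unique groups with the seeded generator
    and deals them round-robin into k folds, so all statements of one
    subject share a fold. Non-grouped mode shuffles row indices directly.
    """
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if group_aware:
        uniq = np.unique(groups)
        if k > uniq.size:
            raise ValueError(f"k={k} exceeds number of groups ({uniq.size})")
        perm = rng.permutation(uniq.size)
        fold_of_group = {uniq[g]: i % k for i, g in enumerate(perm)}
        for row, g in enumerate(groups):
            assign[row] = fold_of_group[g]
    else:
        if k > n:
            raise ValueError(f"k={k} exceeds number of rows ({n})")
        perm = rng.permutation(n)
        for i, row in enumerate(perm):
            assign[row] = i % k
    return assign


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    k: int = 20,
    model_spec: str = "baseline",
    seed: int = 0,
    group_aware: bool = True,
    standardize: bool = True,
    subset: str = "all",
) -> CVResult:
    """k-fold cross-validated accuracy with per-fold preprocessing.

    Standardization statistics come from each training fold only — test
    rows never influence preprocessing. Reports the mean fold accuracy and
    its standard error sd(folds)/sqrt(k). Deterministic given the seed.
    """
    n = X.shape[0]
    assign = make_folds(n, groups, k, seed, group_aware=group_aware)
    accs = []
    for fold in range(k):
        test_mask = assign == fold
        train_mask = ~test_mask
        Xtr, Xte = X[train_mask], X[test_mask]
        ytr, yte = y[train_mask], y[test_mask]
        if len(np.unique(yte)) < 2:
            logger.warning("fold %d has a single class in its test split", fold)
        if standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        model = _make_model(model_spec, seed)
        model.fit(Xtr, ytr)
        pred = np.asarray(model.predict(Xte))
        accs.append(float((pred == yte).mean()))
    mean_acc = float(np.mean(accs))
    se_acc = float(np.std(accs, ddof=1) / math.sqrt(k)) if k > 1 else math.nan
    return CVResult(
        subset=subset,
        model_name=model_spec,
        fold_accuracies=accs,
        mean_acc=mean_acc,
        se_acc=se_acc,
        seed=seed,
        k=k,
        n_rows=n,
        group_aware=group_aware,
    )


def classify_subsets(
    table: pd.DataFrame,
    subsets=("all", "transcribed", "written"),
    k: int = 20,
    model_spec: str = "baseline",
    seed: int = 0,
    group_aware: bool = True,
    config: FeatureConfig = FeatureConfig(),
) -> list[CVResult]:
    """Run the cross-validated classifier on each modality subset."""
    results = []
    for subset in subsets:
        X, y, groups, _ = assemble_matrix(table, subset=subset, config=config)
        results.append(
            kfold_cv(
                X,
                y,
                groups,
                k=k,
                model_spec=model_spec,
                seed=seed,
                group_aware=group_aware,
                subset=subset,
            )
        )
    return results
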