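"""Risk models, cohort splitting and evaluation metrics.

The headline predictor is a gradient-boosted regression tree (GBRT)
model — classification for binary traits, regression for continuous
ones — trained on the concatenated reduced epigenomic features of the
selected LD blocks.  Baselines share the interface: a GBRT on raw
dosages, a GBRT on PCA-compressed dosages, and an L2-penalized logistic
regression on standardized dosages standing in for summary-statistic
linear PRS methods.

Evaluation uses the area under the ROC curve computed from rank sums
(the Mann-Whitney statistic, ties counting one half) and the relative
gain index lambda = (A - 0.5) / 0.5, which is 0 for a random predictor
and 1 for a perfect one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupShuffleSplit, train_test_split

__all__ = [
    "SplitSpec",
    "GBRTConfig",
    "RiskModel",
    "split_cohort",
    "train",
    "auroc",
    "lambda_index",
    "r_squared",
    "combine_block_models",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split protocol: stratified 80/20 by default."""

    train_fraction: float = 0.8
    stratify: bool = True
    group_column: Sequence | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GBRTConfig:
    """GBRT hyperparameters; conservative defaults, all overridable.

    Early stopping watches a 10% carve-out of the training data, so the
    nominal tree count is an upper bound.
    """

    n_estimators: int = 500
    max_depth: int = 3
    learning_rate: float = 0.05
    subsample: float = 0.8
    early_stopping: bool = True
    n_iter_no_change: int = 10
    validation_fraction: float = 0.1


@dataclass
class RiskModel:
    """A fitted predictor plus the provenance needed to reproduce it."""

    kind: str
    estimator: object
    provenance: dict = field(default_factory=dict)
    seed: int = 0

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        """Continuous risk scores: P(case) for classifiers, y-hat else."""
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(features)[:, 1]
        return self.estimator.predict(features)

    def feature_importances(self) -> np.ndarray:
        imp = getattr(self.estimator, "feature_importances_", None)
        if imp is None:
            raise AttributeError(f"model kind {self.kind!r} has no Gini importances")
        return imp


def split_cohort(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into disjoint, exhaustive train/test sets.

    Stratified by label (the default) so both splits keep the cohort's
    case/control proportions; alternatively grouped, in which case no
    group spans the two splits.  Reproducible from the spec's seed.
    """
    labels = np.asarray(labels)
    idx = np.arange(labels.size)
    if spec.group_column is not None:
        gss = GroupShuffleSplit(
            n_splits=1, train_size=spec.train_fraction, random_state=spec.seed
        )
        tr, te = next(gss.split(idx, labels, groups=np.asarray(spec.group_column)))
        return idx[tr], idx[te]
    classes, counts = np.unique(labels, return_counts=True)
    if spec.stratify and (len(classes) < 2 or counts.min() < 2):
        raise ValueError("stratified split needs >= 2 samples in each class")
    tr, te = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=labels if spec.stratify else None,
        random_state=spec.seed,
    )
    return np.sort(tr), np.sort(te)


def train(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str = "gbrt-classify",
    gbrt: GBRTConfig = GBRTConfig(),
    seed: int = 0,
    provenance: dict | None = None,
) -> RiskModel:
    """Fit a risk model of the requested kind.

    Kinds: "gbrt-classify" (binary labels), "gbrt-regress" (continuous),
    "linear-penalized" (L2 logistic regression on the same matrix; the
    matrix should be standardized by the caller for the dosage
    baseline).  Deterministic given the seed.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[1] == 0:
        raise ValueError("feature matrix must be 2-D with >= 1 column")
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite feature values")
    if features.shape[0] != labels.size:
        raise ValueError("features and labels are misaligned")

    common = dict(
        n_estimators=gbrt.n_estimators,
        max_depth=gbrt.max_depth,
        learning_rate=gbrt.learning_rate,
        subsample=gbrt.subsample,
        random_state=seed,
    )
    if gbrt.early_stopping:
        common.update(
            n_iter_no_change=gbrt.n_iter_no_change,
            validation_fraction=gbrt.validation_fraction,
        )
    if kind == "gbrt-classify":
        est = GradientBoostingClassifier(**common)
    elif kind == "gbrt-regress":
        est = GradientBoostingRegressor(**common)
    elif kind == "linear-penalized":
        est = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    est.fit(features, labels)
    return RiskModel(kind=kind, estimator=est, provenance=provenance or {}, seed=seed)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve from rank sums (ties count one half).

    A = (R1 - n1(n1+1)/2) / (n1 * n0) where R1 is the rank sum of case
    scores under average ranking of the pooled scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auROC needs both classes present")
    ranks = stats.rankdata(scores, method="average")
    r1 = ranks[labels].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def lambda_index(a: float) -> float:
    """Relative gain over random: lambda = (A - 0.5) / 0.5 = 2A - 1."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("auROC must lie in [0, 1]")
    return (a - 0.5) / 0.5


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot on held-out data."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    ss_tot = ((y_true - y_true.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("constant truth values; R^2 undefined")
    return float(1.0 - ((y_true - y_pred) ** 2).sum() / ss_tot)


def dosage_pca_features(
    dosages_train: np.ndarray,
    dosages_test: np.ndarray,
    n_components: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA-compressed standardized dosages, fitted on the training split."""
    mean = dosages_train.mean(axis=0)
    sd = dosages_train.std(axis=0)
    sd[sd == 0] = 1.0
    z_tr = (dosages_train - mean) / sd
    z_te = (dosages_test - mean) / sd
    k = min(n_components, z_tr.shape[0] - 1, z_tr.shape[1])
    pca = PCA(n_components=k, random_state=seed)
    return pca.fit_transform(z_tr), pca.transform(z_te)


def combine_block_models(
    train_scores: np.ndarray,
    train_labels: np.ndarray,
    test_scores: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Optimally weighted combination of per-block risk scores.

    Weights come from a logistic regression (with intercept) of the
    training labels on the per-block training scores; the combined test
    score is the fitted linear predictor.  Constant score columns are
    dropped with a warning.  Returns (combined test scores, weights
    aligned to the input columns, zero for dropped ones).
    """
    import warnings

    tr = np.atleast_2d(np.asarray(train_scores, dtype=np.float64))
    te = np.atleast_2d(np.asarray(test_scores, dtype=np.float64))
    if tr.shape[1] != te.shape[1]:
        raise ValueError("train and test score column counts differ")
    keep = tr.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant score columns", stacklevel=2)
    if not keep.any():
        raise ValueError("all score columns are constant")
    lr = LogisticRegression(C=1e6, max_iter=2000, random_state=seed)
    lr.fit(tr[:, keep], np.asarray(train_labels))
    weights = np.zeros(tr.shape[1])
    weights[keep] = lr.coef_[0]
    combined = te[:, keep] @ lr.coef_[0] + lr.intercept_[0]
    return combined, weights
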