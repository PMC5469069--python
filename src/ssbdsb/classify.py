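"""Balanced training, per-family SVM/random-forest models, majority-voting
ensemble, permutation baseline, stratified cross-validation and metrics.

The positive class defaults to DSB (the majority class); it is configurable
everywhere through ``positive_class``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureMatrix, MODEL_FAMILIES
from .seqio import LABEL_DSB, LabeledDataset

#: Row label used for the voting ensemble in reports.
ENSEMBLE_KEY = "ALL"

METRIC_COLUMNS = ("ACC", "SN", "SP", "AUC", "MCC", "F1")


@dataclass
class ModelConfig:
    """Classifier settings: algorithm, forest size, seed."""

    algorithm: str = "RF"
    rf_trees: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        self.algorithm = self.algorithm.upper()
        if self.algorithm not in {"RF", "SVM"}:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")


@dataclass
class EvaluationReport:
    """Confusion counts plus the six derived metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sn: float
    sp: float
    mcc: float
    f1: float
    auc: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.acc, "SN": self.sn, "SP": self.sp,
            "AUC": self.auc, "MCC": self.mcc, "F1": self.f1,
        }


def auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) statistic with midranks for ties."""
    y = np.asarray(y_true, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
) -> EvaluationReport:
    """Compute confusion counts and all six metrics.

    ``y_true``/``y_pred`` are boolean/0-1 vectors with 1 = positive class.
    ``scores`` (positive-class scores) are needed for AUC; without them AUC
    is computed from the hard labels.
    """
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) == 0:
        raise ValueError("predictions and truth must be equal-length 1-D, n >= 1")
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    n = len(y_true)
    acc = (tp + tn) / n
    sn = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    if scores is None:
        scores = y_pred.astype(float)
    auc = auc_rank(y_true, scores)
    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=acc, sn=sn, sp=sp, mcc=float(mcc), f1=f1, auc=auc,
    )


def downsample_majority(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """Keep all minority-class members and a uniform random equal-size
    subset of the majority class. Original record order is preserved."""
    counts = dataset.class_counts()
    if min(counts.values()) == 0:
        raise ValueError(f"both classes required, got counts {counts}")
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    if counts[minority] == counts[majority]:
        return dataset
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(np.asarray(dataset.labels) == majority)
    keep_maj = set(
        rng.choice(maj_idx, size=counts[minority], replace=False).tolist()
    )
    keep = [
        i
        for i in range(len(dataset))
        if dataset.labels[i] == minority or i in keep_maj
    ]
    return dataset.subset(keep)


def make_folds(dataset: LabeledDataset, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified ``k``-fold assignment: fold index in ``0..k-1`` per record."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(dataset.labels)
    counts = dataset.class_counts()
    small = [c for c, n in counts.items() if n < k]
    if small:
        raise ValueError(
            f"classes {small} have fewer than k={k} members: {counts}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(dataset), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(dataset)), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class TrainedModel:
    """Opaque handle around a fitted scikit-learn estimator."""

    estimator: object
    feature_names: list[str]
    family: str
    positive_class: str

    def predict_scores(self, features: FeatureMatrix) -> np.ndarray:
        """Positive-class scores in [0, 1] for each row of ``features``."""
        if features.names != self.feature_names:
            missing = set(self.feature_names) - set(features.names)
            extra = set(features.names) - set(self.feature_names)
            raise ValueError(
                f"feature layout mismatch for family {self.family}: "
                f"missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]}"
            )
        proba = self.estimator.predict_proba(features.values)
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]

    def predict_labels(self, features: FeatureMatrix) -> np.ndarray:
        """Hard 0/1 labels at threshold 0.5 (ties go to positive)."""
        return self.predict_scores(features) >= 0.5


def _make_estimator(config: ModelConfig):
    if config.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=config.rf_trees,
            random_state=config.seed,
            n_jobs=1,
        )
    # Default-parameter SVM; Platt-style calibration supplies [0,1] scores.
    return SVC(probability=True, random_state=config.seed)


def train_model(
    features: FeatureMatrix, y: np.ndarray, config: ModelConfig,
    positive_class: str = LABEL_DSB,
) -> TrainedModel:
    """Fit one classifier on an aligned feature matrix and 0/1 labels."""
    y = np.asarray(y, dtype=int)
    if len(y) != len(features.ids):
        raise ValueError("features and labels are not aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    est = _make_estimator(config)
    est.fit(features.values, y)
    return TrainedModel(
        estimator=est,
        feature_names=list(features.names),
        family=features.family,
        positive_class=positive_class,
    )


def majority_vote(
    votes: Sequence[int], scores: Sequence[float], expected_n: int = 6
) -> tuple[int, float]:
    """Combine per-family hard labels by strict majority.

    An even split is broken by the mean positive-class score (positive iff
    mean >= 0.5). Returns ``(label, mean_score)``.
    """
    if len(votes) != expected_n or len(scores) != expected_n:
        raise ValueError(
            f"expected {expected_n} votes and scores, got "
            f"{len(votes)}/{len(scores)}"
        )
    votes_arr = np.asarray(votes, dtype=int)
    mean_score = float(np.mean(scores))
    n_pos = int(votes_arr.sum())
    n_neg = len(votes_arr) - n_pos
    if n_pos > n_neg:
        label = 1
    elif n_pos < n_neg:
        label = 0
    else:
        label = int(mean_score >= 0.5)
    return label, mean_score


@dataclass
class CVResult:
    """Pooled cross-validation predictions and per-family reports."""

    ids: list[str]
    y_true: np.ndarray
    fold_assignment: np.ndarray
    scores: dict[str, np.ndarray]
    predictions: dict[str, np.ndarray]
    reports: dict[str, EvaluationReport]
    families: tuple[str, ...]
    importances: dict[str, np.ndarray] = field(default_factory=dict)
    feature_names: dict[str, list[str]] = field(default_factory=dict)
    algorithm: str = "RF"

    def metrics_frame(self) -> pd.DataFrame:
        """Table mirroring the per-family + 'All features' report layout."""
        rows = {}
        for fam in list(self.families) + [ENSEMBLE_KEY]:
            if fam in self.reports:
                name = "All features" if fam == ENSEMBLE_KEY else fam
                rows[name] = self.reports[fam].as_dict()
        return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_COLUMNS)]


def _check_alignment(
    dataset: LabeledDataset, features: Mapping[str, FeatureMatrix]
) -> None:
    for fam, fm in features.items():
        if fm.ids != dataset.ids:
            raise ValueError(
                f"feature matrix for {fam} is not aligned with the dataset ids"
            )


def _subset_matrix(fm: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        ids=[fm.ids[i] for i in idx],
        names=fm.names,
        values=fm.values[idx],
        family=fm.family,
    )


def run_cv(
    dataset: LabeledDataset,
    features: Mapping[str, FeatureMatrix],
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    positive_class: str = LABEL_DSB,
    downsample: bool = True,
    permute_training_labels: bool = False,
    ensemble: str = "vote",
    collect_importances: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of one model per feature family.

    Per fold the training part is down-sampled to class balance (test parts
    are never touched), one model per family is fitted, and test-part
    predictions are pooled across folds. The ensemble row combines family
    votes by strict majority (``ensemble='vote'``) or trains a single model
    on concatenated features (``ensemble='concat'``).

    ``permute_training_labels=True`` turns the run into the permutation
    baseline: the (down-sampled) training labels are shuffled uniformly in
    every fold; test labels are untouched.
    """
    if ensemble not in {"vote", "concat"}:
        raise ValueError(f"unknown ensemble mode {ensemble!r}")
    families = tuple(features.keys())
    if not families:
        raise ValueError("at least one feature family required")
    _check_alignment(dataset, features)

    y_true = (np.asarray(dataset.labels) == positive_class).astype(int)
    fold_assignment = make_folds(dataset, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=k)

    n = len(dataset)
    scores = {fam: np.full(n, np.nan) for fam in families}
    importance_sums: dict[str, np.ndarray] = {}

    concat_names: list[str] = []
    concat_values: np.ndarray | None = None
    if ensemble == "concat":
        concat_names = [nm for fam in families for nm in features[fam].names]
        concat_values = np.hstack([features[fam].values for fam in families])
        scores[ENSEMBLE_KEY] = np.full(n, np.nan)

    for fold in range(k):
        test_idx = np.flatnonzero(fold_assignment == fold)
        train_idx = np.flatnonzero(fold_assignment != fold)
        fold_seed = int(fold_seeds[fold])
        if downsample:
            train_ds = dataset.subset(train_idx)
            balanced = downsample_majority(train_ds, seed=fold_seed)
            keep_ids = set(balanced.ids)
            train_idx = np.asarray(
                [i for i in train_idx if dataset.records[i].id in keep_ids]
            )
        y_train = y_true[train_idx]
        if permute_training_labels:
            perm_rng = np.random.default_rng(fold_seed + 1)
            y_train = perm_rng.permutation(y_train)
        fold_config = ModelConfig(
            algorithm=config.algorithm,
            rf_trees=config.rf_trees,
            seed=fold_seed,
        )
        for fam in families:
            model = train_model(
                _subset_matrix(features[fam], train_idx),
                y_train,
                fold_config,
                positive_class=positive_class,
            )
            scores[fam][test_idx] = model.predict_scores(
                _subset_matrix(features[fam], test_idx)
            )
            if collect_importances:
                if config.algorithm != "RF":
                    raise ValueError("importances require the RF algorithm")
                imp = model.estimator.feature_importances_
                importance_sums.setdefault(fam, np.zeros(len(imp)))
                importance_sums[fam] += imp
        if ensemble == "concat":
            concat_matrix = FeatureMatrix(
                ids=dataset.ids, names=concat_names,
                values=concat_values, family="CONCAT",
            )
            model = train_model(
                _subset_matrix(concat_matrix, train_idx),
                y_train, fold_config, positive_class=positive_class,
            )
            scores[ENSEMBLE_KEY][test_idx] = model.predict_scores(
                _subset_matrix(concat_matrix, test_idx)
            )

    predictions = {fam: (scores[fam] >= 0.5).astype(int) for fam in families}
    if ensemble == "vote":
        vote_labels = np.empty(n, dtype=int)
        vote_scores = np.empty(n)
        fam_scores = np.vstack([scores[fam] for fam in families])
        fam_votes = (fam_scores >= 0.5).astype(int)
        for i in range(n):
            vote_labels[i], vote_scores[i] = majority_vote(
                fam_votes[:, i], fam_scores[:, i], expected_n=len(families)
            )
        scores[ENSEMBLE_KEY] = vote_scores
        predictions[ENSEMBLE_KEY] = vote_labels
    else:
        predictions[ENSEMBLE_KEY] = (scores[ENSEMBLE_KEY] >= 0.5).astype(int)

    reports = {
        key: evaluate(y_true, predictions[key], scores[key])
        for key in list(families) + [ENSEMBLE_KEY]
    }
    importances = {
        fam: total / k for fam, total in importance_sums.items()
    }
    return CVResult(
        ids=dataset.ids,
        y_true=y_true,
        fold_assignment=fold_assignment,
        scores=scores,
        predictions=predictions,
        reports=reports,
        families=families,
        importances=importances,
        feature_names={fam: list(features[fam].names) for fam in families},
        algorithm=config.algorithm,
    )


def permutation_baseline(
    dataset: LabeledDataset,
    features: Mapping[str, FeatureMatrix],
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    positive_class: str = LABEL_DSB,
    downsample: bool = True,
    ensemble: str = "vote",
) -> CVResult:
    """Same protocol as :func:`run_cv` with training labels permuted."""
    return run_cv(
        dataset, features, config, k=k, seed=seed,
        positive_class=positive_class, downsample=downsample,
        permute_training_labels=True, ensemble=ensemble,
    )


def independent_test(
    train_dataset: LabeledDataset,
    test_dataset: LabeledDataset,
    train_features: Mapping[str, FeatureMatrix],
    test_features: Mapping[str, FeatureMatrix],
    config: ModelConfig,
    seed: int = 0,
    positive_class: str = LABEL_DSB,
    downsample: bool = True,
) -> dict[str, EvaluationReport]:
    """Train once on the (down-sampled) training set; evaluate on the full
    held-out set. Train/test id sets must be disjoint."""
    if len(test_dataset) == 0:
        raise ValueError("empty test set")
    overlap = set(train_dataset.ids) & set(test_dataset.ids)
    if overlap:
        raise ValueError(
            f"train and test sets share ids: {sorted(overlap)[:10]}"
        )
    families = tuple(train_features.keys())
    if set(families) != set(test_features.keys()):
        raise ValueError("train and test feature families differ")
    _check_alignment(train_dataset, train_features)
    _check_alignment(test_dataset, test_features)

    if downsample:
        balanced = downsample_majority(train_dataset, seed=seed)
        keep_ids = set(balanced.ids)
        keep_idx = np.asarray(
            [i for i, r in enumerate(train_dataset.records) if r.id in keep_ids]
        )
    else:
        keep_idx = np.arange(len(train_dataset))
    y_train = (
        np.asarray(train_dataset.labels)[keep_idx] == positive_class
    ).astype(int)
    y_test = (np.asarray(test_dataset.labels) == positive_class).astype(int)

    scores: dict[str, np.ndarray] = {}
    for fam in families:
        model = train_model(
            _subset_matrix(train_features[fam], keep_idx),
            y_train,
            ModelConfig(
                algorithm=config.algorithm, rf_trees=config.rf_trees, seed=seed
            ),
            positive_class=positive_class,
        )
        scores[fam] = model.predict_scores(test_features[fam])

    fam_scores = np.vstack([scores[fam] for fam in families])
    fam_votes = (fam_scores >= 0.5).astype(int)
    n = len(test_dataset)
    vote_labels = np.empty(n, dtype=int)
    vote_scores = np.empty(n)
    for i in range(n):
        vote_labels[i], vote_scores[i] = majority_vote(
            fam_votes[:, i], fam_scores[:, i], expected_n=len(families)
        )
    reports = {
        fam: evaluate(y_test, (scores[fam] >= 0.5).astype(int), scores[fam])
        for fam in families
    }
    reports[ENSEMBLE_KEY] = evaluate(y_test, vote_labels, vote_scores)
    return reports


def reports_to_frame(
    reports: Mapping[str, EvaluationReport],
    families: Sequence[str] = MODEL_FAMILIES,
) -> pd.DataFrame:
    """Metrics table: one row per family plus 'All features'."""
    rows = {}
    for fam in list(families) + [ENSEMBLE_KEY]:
        if fam in reports:
            name = "All features" if fam == ENSEMBLE_KEY else fam
            rows[name] = reports[fam].as_dict()
    return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_COLUMNS)]
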