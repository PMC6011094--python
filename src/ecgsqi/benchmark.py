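"""Evaluation harness: repeated stratified CV, weight sweeps and ROC curves.

The classifiers under study (heuristic rule fusion and the fuzzy engine) have
no trainable parameters, so cross-validation here measures sampling
variability of the accuracy rather than generalization of a fit: each record
is assessed once, and the repeated stratified 10-fold partition scores the
fixed predictions fold by fold.  Quality labels are binarized for scoring
(acceptable = {E, B} by default, configurable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

from .fuzzy import build_fuzzy_matrix, decide, synthesize
from .heuristic import ConfusionCounts, confusion_metrics, fuse_heuristic
from .io import AnalysisConfig, UndefinedIndexError
from .sqi import compute_all_sqis
from .synthetic import LabeledRecord

__all__ = ["CvResult", "RocCurve", "extract_features", "predict_labels",
           "crossvalidate", "weight_sweep", "roc_over_v"]

log = logging.getLogger(__name__)

# order in which indices enter the k-SQI heuristic tables
HEURISTIC_ORDER = ("qsqi", "psqi", "ksqi", "bassqi", "csqi")


@dataclass(frozen=True)
class CvResult:
    """Per-fold metrics plus grand means/SDs over repeats."""

    per_fold: pd.DataFrame  # columns: repeat, fold, acc, se, sp
    n_splits: int
    repeats: int

    @property
    def mean_acc(self) -> float:
        return float(self.per_fold["acc"].mean())

    @property
    def sd_acc(self) -> float:
        return float(self.per_fold.groupby("repeat")["acc"].mean().std(ddof=1))

    def summary(self) -> dict:
        g = self.per_fold.groupby("repeat").mean(numeric_only=True)
        return dict(acc=float(g["acc"].mean()), se=float(g["se"].mean()),
                    sp=float(g["sp"].mean()),
                    acc_sd=float(g["acc"].std(ddof=1)) if len(g) > 1 else 0.0)


@dataclass(frozen=True)
class RocCurve:
    """Operating points over a grid of decision-score thresholds."""

    points: pd.DataFrame  # columns: threshold, se, sp, acc
    best_threshold: float
    best_acc: float


def extract_features(dataset: list[LabeledRecord],
                     config: AnalysisConfig | None = None):
    """Compute (SqiVector, SqiGradeVector) once per record."""
    config = config or AnalysisConfig()
    return [compute_all_sqis(lr.record, config) for lr in dataset]


def _fuzzy_label(sqis, config: AnalysisConfig) -> str:
    try:
        matrix = build_fuzzy_matrix(sqis, config.membership_mode)
    except UndefinedIndexError:
        return "U"
    s = synthesize(config.weights, matrix)
    return decide(s, config.decision_thresholds)[1]


def predict_labels(dataset: list[LabeledRecord], method: str = "fuzzy", *,
                   config: AnalysisConfig | None = None, n_sqis: int = 4,
                   features=None) -> list[str]:
    """E/B/U predictions for every record.

    ``method`` is "fuzzy" or "heuristic"; for the heuristic tables ``n_sqis``
    selects how many indices enter, in the order qSQI, pSQI, kSQI, basSQI,
    cSQI.  Precomputed ``features`` (from :func:`extract_features`) are
    reused when given.
    """
    config = config or AnalysisConfig()
    if features is None:
        features = extract_features(dataset, config)
    labels = []
    for sqis, grades in features:
        if method == "fuzzy":
            labels.append(_fuzzy_label(sqis, config))
        elif method == "heuristic":
            if not 2 <= n_sqis <= 5:
                raise ValueError("heuristic fusion takes 2-5 SQIs")
            labels.append(fuse_heuristic(grades.subset(HEURISTIC_ORDER[:n_sqis])))
        else:
            raise ValueError(f"unknown method {method!r}")
    return labels


def _binary(labels, acceptable) -> np.ndarray:
    return np.asarray([lbl in acceptable for lbl in labels], dtype=bool)


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum(y_pred & y_true))
    tn = int(np.sum(~y_pred & ~y_true))
    fp = int(np.sum(y_pred & ~y_true))
    fn = int(np.sum(~y_pred & y_true))
    se, sp, acc = confusion_metrics(ConfusionCounts(tp, tn, fp, fn))
    return acc, se, sp


def crossvalidate(dataset: list[LabeledRecord], method: str = "fuzzy", *,
                  repeats: int = 10, seed: int = 0,
                  config: AnalysisConfig | None = None, n_sqis: int = 4,
                  predictions: list[str] | None = None) -> CvResult:
    """Repeated stratified 10-fold scoring of the fixed classifier.

    The dataset is partitioned into 10 stratified folds (fewer if the
    smaller class has under 10 members, with a warning); per-fold
    sensitivity/specificity/accuracy are averaged per repeat and over the
    ``repeats`` independent partitions.
    """
    config = config or AnalysisConfig()
    if len(dataset) < 20:
        raise ValueError("need at least 20 records for cross-validation")
    y_true = _binary([lr.intended_label for lr in dataset], config.acceptable_levels)
    if len(set(y_true.tolist())) < 2:
        raise ValueError("dataset must contain both classes")
    if predictions is None:
        predictions = predict_labels(dataset, method, config=config, n_sqis=n_sqis)
    y_pred = _binary(predictions, config.acceptable_levels)

    min_class = int(min(np.sum(y_true), np.sum(~y_true)))
    n_splits = 10
    if min_class < 10:
        n_splits = max(2, min_class)
        warnings.warn(f"smallest class has {min_class} records; "
                      f"reducing folds to {n_splits}", stacklevel=2)

    splitter = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=repeats,
                                       random_state=seed % (2 ** 31))
    rows = []
    for split_i, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y_true)), y_true)):
        acc, se, sp = _fold_metrics(y_true[test_idx], y_pred[test_idx])
        rows.append(dict(repeat=split_i // n_splits, fold=split_i % n_splits,
                         acc=acc, se=se, sp=sp))
    return CvResult(pd.DataFrame(rows), n_splits, repeats)


def weight_sweep(dataset: list[LabeledRecord], candidate_weights, *,
                 repeats: int = 10, seed: int = 0,
                 config: AnalysisConfig | None = None,
                 features=None) -> pd.DataFrame:
    """CV accuracy of the fuzzy engine for each candidate weight vector.

    Returns one row per candidate with its mean accuracy; the index features
    are extracted once and shared across candidates.
    """
    config = config or AnalysisConfig()
    if not len(candidate_weights):
        raise ValueError("need at least one candidate weight vector")
    if features is None:
        features = extract_features(dataset, config)
    rows = []
    for w in candidate_weights:
        cfg = config.with_(weights=tuple(float(x) for x in w))  # validates sum
        preds = predict_labels(dataset, "fuzzy", config=cfg, features=features)
        cv = crossvalidate(dataset, "fuzzy", repeats=repeats, seed=seed,
                           config=cfg, predictions=preds)
        s = cv.summary()
        rows.append(dict(w1=w[0], w2=w[1], w3=w[2], w4=w[3],
                         acc=s["acc"], se=s["se"], sp=s["sp"]))
    df = pd.DataFrame(rows)
    best = df["acc"].idxmax()
    log.info("best weights: %s (acc %.2f%%)", tuple(df.loc[best, ["w1", "w2", "w3", "w4"]]),
             df.loc[best, "acc"])
    return df


def roc_over_v(dataset: list[LabeledRecord], grid, *,
               config: AnalysisConfig | None = None,
               features=None) -> RocCurve:
    """Operating characteristic over decision-score thresholds.

    For each threshold in ``grid`` (within [1, 3]) a segment is acceptable
    when its score v is at or below the threshold; sensitivity, specificity
    and accuracy against the intended labels are reported per point along
    with the accuracy-maximizing threshold.
    """
    config = config or AnalysisConfig()
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must not be empty")
    if np.any((grid < 1.0) | (grid > 3.0)):
        raise ValueError("thresholds must lie in [1, 3]")
    if features is None:
        features = extract_features(dataset, config)
    vs = []
    for sqis, _ in features:
        try:
            matrix = build_fuzzy_matrix(sqis, config.membership_mode)
            v, _ = decide(synthesize(config.weights, matrix),
                          config.decision_thresholds)
        except UndefinedIndexError:
            v = 3.0
        vs.append(v)
    vs = np.asarray(vs)
    y_true = _binary([lr.intended_label for lr in dataset], config.acceptable_levels)

    rows = []
    for thr in grid:
        y_pred = vs <= thr
        acc, se, sp = _fold_metrics(y_true, y_pred)
        rows.append(dict(threshold=float(thr), se=se, sp=sp, acc=acc))
    df = pd.DataFrame(rows)
    best = df["acc"].idxmax()
    return RocCurve(df, float(df.loc[best, "threshold"]), float(df.loc[best, "acc"]))
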