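"""Replication by nearest centroid; outcome prediction; k-means comparators.

The stratification found in one cohort is replicated in a second cohort by
nearest-centroid assignment: each new patient gets the label of the group
whose mean 30-item symptom vector (centroid) is closest in raw Euclidean
distance.  Functional outcome (good = GAF > 65) is predicted with
L2-penalized logistic regression on either the raw PANSS items or the
group membership indicators, and evaluated with accuracy / precision /
recall and the precision-recall curve; the reference line is the
prevalence of good outcome (the precision of always predicting good).
k-means (k = 3), raw or on the 2-dim PCA lens, serves as the standard
clustering comparator; partitions are compared by contingency table and
adjusted Rand index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import StratifiedKFold

from .characterize import GROUP_LABELS, UNASSIGNED
from .cohort import PANSS_ITEMS
from .mapper import pca_lens

logger = logging.getLogger(__name__)


@dataclass
class PredictConfig:
    gaf_threshold: float = 65.0
    regularization_strength: float = 1.0  # inverse-penalty convention (sklearn C)
    feature_set: str = "panss_items"  # panss_items | group_onehot | kmeans_onehot | kmeans_pca_onehot
    scheme: str = "train_test"  # train_test | fivefold_cv
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regularization_strength <= 0:
            raise ValueError("regularization_strength must be > 0")


# -- centroids ---------------------------------------------------------


@dataclass
class Centroids:
    means: pd.DataFrame  # group label -> 30-vector (rows indexed by group)
    sizes: dict[str, int] = field(default_factory=dict)
    source: str = ""


def group_centroids(symptoms: np.ndarray, labels: pd.Series | np.ndarray, source: str = "") -> Centroids:
    """Per-group coordinate-wise mean of the 30 PANSS items."""
    symptoms = np.asarray(symptoms, dtype=float)
    labels = np.asarray(labels)
    rows, sizes = {}, {}
    for g in GROUP_LABELS:
        mask = labels == g
        if not mask.any():
            raise ValueError(f"group {g} is empty; cannot form its centroid")
        rows[g] = symptoms[mask].mean(axis=0)
        sizes[g] = int(mask.sum())
    means = pd.DataFrame(rows, index=list(PANSS_ITEMS)).T
    return Centroids(means=means, sizes=sizes, source=source)


def assign_by_centroid(symptoms: np.ndarray, centroids: Centroids) -> pd.Series:
    """Nearest-centroid labels in raw Euclidean distance; ties go to the
    lexicographically first group label (logged)."""
    symptoms = np.asarray(symptoms, dtype=float)
    groups = list(centroids.means.index)
    M = centroids.means.to_numpy()
    d2 = ((symptoms[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)  # argmin takes the first index on ties
    ties = (d2 == d2.min(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("%d patients equidistant from >= 2 centroids; first label taken", int(ties.sum()))
    return pd.Series([groups[i] for i in best])


# -- outcome prediction ------------------------------------------------


def dichotomize_outcome(gaf: pd.Series | np.ndarray, threshold: float = 65.0) -> pd.Series:
    """Good outcome iff GAF strictly exceeds the threshold; missing GAF
    rows are dropped (count logged)."""
    gaf = pd.Series(np.asarray(gaf, dtype=float))
    missing = gaf.isna()
    if missing.any():
        logger.warning("%d patients without GAF excluded from prediction", int(missing.sum()))
    return (gaf[~missing] > threshold)


def group_onehot(labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Indicator columns for A/B/C; unassigned patients get all-NaN rows
    (dropped by the callers that use group features)."""
    labels = pd.Series(np.asarray(labels))
    out = pd.DataFrame({g: (labels == g).astype(float) for g in GROUP_LABELS})
    out[labels == UNASSIGNED] = np.nan
    return out


def fit_outcome_model(features: np.ndarray, labels: np.ndarray, config: PredictConfig | None = None) -> LogisticRegression:
    """L2 logistic regression (inverse penalty = regularization_strength,
    unpenalized intercept, deterministic lbfgs fit)."""
    config = config or PredictConfig()
    labels = np.asarray(labels, dtype=bool)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    # L2 penalty (sklearn default), inverse strength C, unpenalized intercept
    model = LogisticRegression(
        C=config.regularization_strength, solver="lbfgs", tol=1e-8, max_iter=1000,
    )
    model.fit(np.asarray(features, dtype=float), labels)
    return model


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    return {
        "tp": int(np.sum(y_pred & y_true)),
        "fp": int(np.sum(y_pred & ~y_true)),
        "fn": int(np.sum(~y_pred & y_true)),
        "tn": int(np.sum(~y_pred & ~y_true)),
    }


def pr_curve(y_true: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """Precision-recall pairs at thresholds = unique predicted scores
    (predict positive iff score >= threshold), descending."""
    y_true = np.asarray(y_true, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    rows = []
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        c = confusion_counts(y_true, pred)
        prec = c["tp"] / (c["tp"] + c["fp"]) if (c["tp"] + c["fp"]) else 1.0
        rec = c["tp"] / (c["tp"] + c["fn"]) if (c["tp"] + c["fn"]) else 0.0
        rows.append({"threshold": t, "precision": prec, "recall": rec})
    return pd.DataFrame(rows)


def average_precision(y_true: np.ndarray, scores: np.ndarray) -> float:
    """PR-AUC as average precision (step interpolation): sum over the
    curve of precision x recall increment."""
    curve = pr_curve(y_true, scores)
    auc, prev_rec = 0.0, 0.0
    for _, row in curve.iterrows():
        auc += row["precision"] * (row["recall"] - prev_rec)
        prev_rec = row["recall"]
    return float(auc)


def evaluate_model(model, features: np.ndarray, labels: np.ndarray) -> dict:
    """Prediction report: confusion at probability 0.5, accuracy /
    precision / recall, PR curve and PR-AUC, prevalence baseline."""
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("empty evaluation set")
    scores = model.predict_proba(np.asarray(features, dtype=float))[:, 1]
    return evaluate_scores(labels, scores)


def metrics_from_confusion(c: dict[str, int]) -> dict:
    """Accuracy / precision / recall from confusion counts; an undefined
    precision (no positive predictions) is reported as 0 and flagged."""
    n = c["tp"] + c["fp"] + c["fn"] + c["tn"]
    denom_p = c["tp"] + c["fp"]
    denom_r = c["tp"] + c["fn"]
    return {
        "accuracy": (c["tp"] + c["tn"]) / n,
        "precision": c["tp"] / denom_p if denom_p else 0.0,
        "precision_undefined": denom_p == 0,
        "recall": c["tp"] / denom_r if denom_r else 0.0,
    }


def evaluate_scores(labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict:
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pred = scores > threshold
    c = confusion_counts(labels, pred)
    report = metrics_from_confusion(c)
    report.update(
        confusion=c,
        pr_curve=pr_curve(labels, scores),
        pr_auc=average_precision(labels, scores),
        baseline=float(labels.mean()),
        n=int(labels.size),
    )
    return report


# -- k-means comparators ----------------------------------------------


def kmeans_partition(symptoms: np.ndarray, k: int = 3, on_pca: bool = False, seed: int = 0) -> np.ndarray:
    """k-means (Lloyd, k-means++ init, 10 restarts) on the raw 30-item
    vectors or on the 2-dim PCA lens coordinates."""
    X = np.asarray(symptoms, dtype=float)
    if on_pca:
        X = pca_lens(X, dims=2)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(X)


def compare_partitions(p1, p2) -> dict:
    """Contingency table, adjusted Rand index, and the best label matching
    (maximum-weight bipartite assignment on the contingency table)."""
    p1 = pd.Series(np.asarray(p1).astype(str))
    p2 = pd.Series(np.asarray(p2).astype(str))
    if len(p1) != len(p2):
        raise ValueError("partitions cover different patient sets")
    table = pd.crosstab(p1, p2)
    ari = adjusted_rand_score(p1, p2)
    rows, cols = linear_sum_assignment(-table.to_numpy())
    matching = {str(table.index[i]): str(table.columns[j]) for i, j in zip(rows, cols)}
    matched = int(table.to_numpy()[rows, cols].sum())
    return {"table": table, "ari": float(ari), "matching": matching,
            "matched_fraction": matched / len(p1)}


def partition_agreement(p1, p2) -> float:
    """Fraction of patients on which two labelings agree exactly."""
    p1, p2 = np.asarray(p1), np.asarray(p2)
    return float(np.mean(p1 == p2))


# -- experiment driver -------------------------------------------------


def _features(symptoms: np.ndarray, labels, feature_set: str, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix + row mask (rows usable for this feature set)."""
    symptoms = np.asarray(symptoms, dtype=float)
    n = symptoms.shape[0]
    if feature_set == "panss_items":
        return symptoms, np.ones(n, dtype=bool)
    if feature_set == "group_onehot":
        oh = group_onehot(labels)
        mask = ~oh.isna().any(axis=1).to_numpy()
        return oh.to_numpy(), mask
    if feature_set == "kmeans_onehot":
        part = kmeans_partition(symptoms, 3, on_pca=False, seed=seed)
        return pd.get_dummies(part).to_numpy(dtype=float), np.ones(n, dtype=bool)
    if feature_set == "kmeans_pca_onehot":
        part = kmeans_partition(symptoms, 3, on_pca=True, seed=seed)
        return pd.get_dummies(part).to_numpy(dtype=float), np.ones(n, dtype=bool)
    raise ValueError(f"unknown feature set {feature_set!r}")


def run_prediction_experiment(
    cohort1_symptoms: np.ndarray,
    cohort1_gaf: np.ndarray,
    cohort2_symptoms: np.ndarray,
    cohort2_gaf: np.ndarray,
    labels1,
    labels2,
    config: PredictConfig | None = None,
    feature_sets: tuple[str, ...] = ("panss_items", "group_onehot"),
) -> dict:
    """Train on cohort 1, validate on cohort 2, for each feature set, under
    both the train/test and the stratified fivefold-CV (cohort 2) schemes."""
    config = config or PredictConfig()
    reports: dict = {}
    for fs in feature_sets:
        X1, m1 = _features(cohort1_symptoms, labels1, fs, config.seed)
        X2, m2 = _features(cohort2_symptoms, labels2, fs, config.seed + 1)
        y1 = np.asarray(cohort1_gaf, dtype=float) > config.gaf_threshold
        y2 = np.asarray(cohort2_gaf, dtype=float) > config.gaf_threshold
        ok1 = m1 & ~np.isnan(np.asarray(cohort1_gaf, dtype=float))
        ok2 = m2 & ~np.isnan(np.asarray(cohort2_gaf, dtype=float))
        model = fit_outcome_model(X1[ok1], y1[ok1], config)
        train_test = evaluate_model(model, X2[ok2], y2[ok2])
        cv = fivefold_cv(X2[ok2], y2[ok2], config)
        reports[fs] = {"train_test": train_test, "fivefold_cv": cv,
                       "n_train": int(ok1.sum()), "n_test": int(ok2.sum())}
    return reports


def fivefold_cv(features: np.ndarray, labels: np.ndarray, config: PredictConfig | None = None) -> dict:
    """Label-stratified fivefold cross-validation; out-of-fold scores are
    pooled into a single prediction report."""
    config = config or PredictConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=config.seed)
    scores = np.empty(labels.size)
    for train, test in skf.split(features, labels):
        model = fit_outcome_model(features[train], labels[train], config)
        scores[test] = model.predict_proba(features[test])[:, 1]
    return evaluate_scores(labels, scores)
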