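"""Classifier training and evaluation on discretized neighborhood profiles.

The positive ("T", photosynthetic) class is the minority class throughout;
F1-minor is the F1 of that class and MCC the Matthews correlation
coefficient.  Model selection follows a nested cross-validation protocol:
stratified outer folds estimate generalisation, and two inner folds inside
each outer training set pick hyperparameters by F1-minor, so every fitted
component (quartile cutpoints, gain-ratio feature ranking, PCA, balancing)
sees only the outer training data.

Class imbalance can be addressed either by reweighting instances so both
class weight sums are equal while the total weight equals the instance
count, or by SMOTE oversampling (interpolation between minority nearest
neighbours on the level-coded features).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import CategoricalNB
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import LinearSVC

from .genome_io import SimilarityHit
from .profile import (
    DiscretizedProfile,
    NeighborhoodProfile,
    discretize,
    fit_quartile_cutpoints,
)

POSITIVE, NEGATIVE = "T", "F"
NOT_ASSIGNABLE = "NOT_ASSIGNABLE"


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1_minor: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1_minor": self.f1_minor,
            "mcc": self.mcc,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision/recall/F1 on the positive (minority) class and
    MCC; any zero denominator yields 0 for that metric by convention."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    accuracy = _safe_div(tp + tn, cm.total)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, denom)
    return MetricsReport(accuracy, precision, recall, f1, mcc)


def confusion_from_labels(
    y_true: list[str] | np.ndarray, y_pred: list[str] | np.ndarray
) -> ConfusionMatrix:
    """Count T/F outcomes; NOT_ASSIGNABLE predictions count as wrong."""
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred, strict=True):
        if t == POSITIVE:
            if p == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, tn, fp, fn)


# ---------------------------------------------------------------------------
# feature selection / reduction
# ---------------------------------------------------------------------------

def _entropy(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def gain_ratio(feature: np.ndarray, labels: np.ndarray) -> float:
    """Information gain of the label given the feature, over the feature's
    own entropy (log base 2).  Constant features score 0 by convention."""
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    if feature.shape != labels.shape:
        raise ValueError("feature and labels must have equal length")
    if feature.size == 0:
        raise ValueError("empty column")
    h_a = _entropy(feature)
    if h_a == 0:
        return 0.0
    h_y = _entropy(labels)
    cond = 0.0
    for value in np.unique(feature):
        mask = feature == value
        cond += mask.mean() * _entropy(labels[mask])
    ig = h_y - cond
    return max(0.0, ig / h_a)


def rank_features(profile: DiscretizedProfile) -> pd.Series:
    """Gain ratio per column, sorted descending (ties by column name)."""
    labels = profile.labels.values
    scores = {
        col: gain_ratio(profile.data[col].values, labels)
        for col in profile.data.columns
    }
    s = pd.Series(scores)
    return s.sort_values(ascending=False, kind="stable").reindex(
        sorted(s.index, key=lambda c: (-s[c], c))
    )


def select_top_features(profile: DiscretizedProfile, k: int) -> DiscretizedProfile:
    """Keep the k highest-gain-ratio columns (ties break by column name)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > profile.data.shape[1]:
        raise ValueError(f"k={k} exceeds column count {profile.data.shape[1]}")
    ranked = rank_features(profile)
    keep = list(ranked.index[:k])
    keep_in_order = [c for c in profile.data.columns if c in set(keep)]
    return DiscretizedProfile(
        data=profile.data[keep_in_order],
        labels=profile.labels.copy(),
        q1=profile.q1,
        q3=profile.q3,
    )


def selection_composition(selected_columns: list[str]) -> dict[str, int]:
    """Per-threshold counts of a selected feature set (columns are
    '{threshold tag}|{family}')."""
    out: dict[str, int] = {}
    for col in selected_columns:
        tag = col.split("|", 1)[0]
        out[tag] = out.get(tag, 0) + 1
    return out


def pca_reduce(
    matrix: np.ndarray, variance_retained: float = 0.95
) -> tuple[np.ndarray, PCA]:
    """Fit a PCA keeping the smallest component count reaching the variance
    fraction; levels are treated as numeric.  The fitted transform is
    returned for reuse on held-out rows."""
    if not 0 < variance_retained <= 1:
        raise ValueError("variance_retained must be in (0, 1]")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty input")
    if variance_retained == 1.0:
        pca = PCA()
        transformed = pca.fit_transform(matrix)
        rank = int((pca.explained_variance_ > 1e-12).sum())
        pca_final = PCA(n_components=max(1, rank))
        return pca_final.fit_transform(matrix), pca_final
    pca = PCA(n_components=variance_retained, svd_solver="full")
    return pca.fit_transform(matrix), pca


# ---------------------------------------------------------------------------
# class balancing
# ---------------------------------------------------------------------------

def reweight_balanced(labels: np.ndarray | pd.Series) -> np.ndarray:
    """Per-instance weights equalising the class weight sums while keeping
    the total weight equal to the instance count."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("reweighting needs both classes present")
    n = labels.size
    per_class = n / len(classes)
    weight_of = {c: per_class / cnt for c, cnt in zip(classes, counts)}
    return np.array([weight_of[c] for c in labels])


def smote_oversample(
    minority_rows: np.ndarray,
    k_neighbors: int = 5,
    rate: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """Standard SMOTE on numeric (level-coded) rows.

    ``rate`` is a percentage: 100 produces one synthetic row per minority
    row.  Each synthetic row interpolates uniformly between a minority row
    and one of its k nearest minority neighbours (Euclidean).
    """
    minority_rows = np.asarray(minority_rows, dtype=float)
    n = minority_rows.shape[0]
    if n <= k_neighbors:
        raise ValueError(
            f"need more than k_neighbors={k_neighbors} minority rows, got {n}"
        )
    rng = np.random.default_rng(seed)
    n_new = int(round(n * rate / 100.0))
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority_rows)
    _, neighbor_idx = nn.kneighbors(minority_rows)
    base = rng.integers(0, n, size=n_new)
    out = np.empty((n_new, minority_rows.shape[1]))
    for row, b in enumerate(base):
        choice = neighbor_idx[b][1:][rng.integers(0, k_neighbors)]
        lam = rng.random()
        out[row] = minority_rows[b] + lam * (minority_rows[choice] - minority_rows[b])
    return out


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

CLASSIFIER_KINDS = ("random_forest", "bayes_net", "svm_smo")


def make_classifier(kind: str, seed: int = 0, **hyperparams):
    """Instantiate a classifier by kind.

    random_forest: RandomForestClassifier (default 500 trees, sqrt features);
    bayes_net: categorical naive Bayes over the level-coded features;
    svm_smo: linear-kernel SVM.
    """
    if kind == "random_forest":
        params = {"n_estimators": 500, "max_features": "sqrt"}
        params.update(hyperparams)
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "bayes_net":
        params = {"min_categories": 4}
        params.update(hyperparams)
        return CategoricalNB(**params)
    if kind == "svm_smo":
        params = {"C": 1.0}
        params.update(hyperparams)
        return LinearSVC(random_state=seed, **params)
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_classifier(
    profile: DiscretizedProfile,
    kind: str = "random_forest",
    seed: int = 0,
    sample_weight: np.ndarray | None = None,
    **hyperparams,
):
    """Fit a classifier on a labeled discretized profile."""
    mask = profile.labels.isin([POSITIVE, NEGATIVE])
    x = profile.data.loc[mask].values.astype(float)
    y = profile.labels.loc[mask].values
    model = make_classifier(kind, seed=seed, **hyperparams)
    if sample_weight is not None:
        model.fit(x, y, sample_weight=sample_weight)
    else:
        model.fit(x, y)
    return model


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """What the inner CV tunes and how the pipeline is assembled."""

    kind: str = "random_forest"
    grid: list[dict] = field(default_factory=lambda: [
        {"n_estimators": 100, "max_depth": None},
        {"n_estimators": 100, "max_depth": 10},
        {"n_estimators": 500, "max_depth": None},
        {"n_estimators": 500, "max_depth": 10},
    ])
    select_k: int | None = None
    pca_variance: float | None = None
    balance: str = "none"  # none | reweight | smote
    smote_rate: float = 100.0
    smote_k: int = 5


@dataclass
class CVResult:
    fold_metrics: list[MetricsReport]
    chosen_params: list[dict]

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.fold_metrics]))

    def sd(self, metric: str) -> float:
        return float(np.std([getattr(m, metric) for m in self.fold_metrics], ddof=1))

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            m: {"mean": self.mean(m), "sd": self.sd(m)}
            for m in ("accuracy", "precision", "recall", "f1_minor", "mcc")
        }


class _FoldPipeline:
    """Cutpoints -> discretize -> (select) -> (PCA) -> (balance) -> model,
    everything fitted on the training rows only."""

    def __init__(self, spec: ClassifierSpec, params: dict, seed: int):
        self.spec = spec
        self.params = params
        self.seed = seed

    def fit(self, train: NeighborhoodProfile) -> "_FoldPipeline":
        try:
            self.q1, self.q3 = fit_quartile_cutpoints(train)
        except ValueError:  # too few nonzero positive scores in this fold
            from .profile import REFERENCE_Q1, REFERENCE_Q3

            self.q1, self.q3 = REFERENCE_Q1, REFERENCE_Q3
        disc = discretize(train, self.q1, self.q3)
        if self.spec.select_k is not None:
            k = min(self.spec.select_k, disc.data.shape[1])
            disc = select_top_features(disc, k)
        self.columns = list(disc.data.columns)
        x = disc.data.values.astype(float)
        y = disc.labels.values
        self.pca = None
        if self.spec.pca_variance is not None:
            x, self.pca = pca_reduce(x, self.spec.pca_variance)
        weight = None
        if self.spec.balance == "reweight":
            weight = reweight_balanced(y)
        elif self.spec.balance == "smote":
            counts = pd.Series(y).value_counts()
            minority = counts.idxmin()
            rows = x[y == minority]
            if rows.shape[0] > self.spec.smote_k:
                synth = smote_oversample(
                    rows, self.spec.smote_k, self.spec.smote_rate, self.seed
                )
                x = np.vstack([x, synth])
                y = np.concatenate([y, np.full(len(synth), minority)])
        self.model = make_classifier(self.spec.kind, seed=self.seed, **self.params)
        if weight is not None:
            self.model.fit(x, y, sample_weight=weight)
        else:
            self.model.fit(x, y)
        return self

    def predict(self, test: NeighborhoodProfile) -> np.ndarray:
        disc = discretize(test, self.q1, self.q3)
        x = disc.data[self.columns].values.astype(float)
        if self.pca is not None:
            x = self.pca.transform(x)
        return self.model.predict(x)


def nested_cv(
    profile: NeighborhoodProfile,
    spec: ClassifierSpec | None = None,
    outer: int = 10,
    inner: int = 2,
    seed: int = 0,
) -> CVResult:
    """Nested stratified CV on the continuous profile.

    Hyperparameters are chosen per outer fold by inner-fold F1-minor; all
    fitted preprocessing (cutpoints, selection, PCA, balancing) is refit
    inside each training set, so held-out rows never leak into it.
    """
    spec = spec or ClassifierSpec()
    mask = profile.labels.isin([POSITIVE, NEGATIVE])
    data = profile.data.loc[mask]
    labels = profile.labels.loc[mask]
    y = labels.values
    if len(set(y)) < 2:
        raise ValueError("nested CV needs both classes present")
    outer_cv = StratifiedKFold(n_splits=outer, shuffle=True, random_state=seed)
    fold_metrics: list[MetricsReport] = []
    chosen: list[dict] = []
    for fold_id, (tr, te) in enumerate(outer_cv.split(data.values, y)):
        train = NeighborhoodProfile(data.iloc[tr].copy(), labels.iloc[tr].copy())
        test = NeighborhoodProfile(data.iloc[te].copy(), labels.iloc[te].copy())
        if len(set(train.labels)) < 2 or len(set(test.labels)) < 2:
            raise ValueError(
                "a fold contains a single class; use a different seed or "
                "fewer folds"
            )
        best_params, best_score = spec.grid[0], -np.inf
        if len(spec.grid) > 1:
            inner_cv = StratifiedKFold(
                n_splits=inner, shuffle=True, random_state=seed + 1
            )
            for params in spec.grid:
                scores = []
                for itr, ite in inner_cv.split(train.data.values, train.labels.values):
                    ptrain = NeighborhoodProfile(
                        train.data.iloc[itr].copy(), train.labels.iloc[itr].copy()
                    )
                    ptest = NeighborhoodProfile(
                        train.data.iloc[ite].copy(), train.labels.iloc[ite].copy()
                    )
                    pipe = _FoldPipeline(spec, params, seed).fit(ptrain)
                    pred = pipe.predict(ptest)
                    cm = confusion_from_labels(ptest.labels.values, pred)
                    scores.append(compute_metrics(cm).f1_minor)
                score = float(np.mean(scores))
                if score > best_score:
                    best_score, best_params = score, params
        pipe = _FoldPipeline(spec, best_params, seed).fit(train)
        pred = pipe.predict(test)
        cm = confusion_from_labels(test.labels.values, pred)
        fold_metrics.append(compute_metrics(cm))
        chosen.append(best_params)
    return CVResult(fold_metrics=fold_metrics, chosen_params=chosen)


def wilcoxon_compare(cv_a: CVResult, cv_b: CVResult, metric: str = "mcc"):
    """Wilcoxon signed-rank comparison of per-fold metric values."""
    a = [getattr(m, metric) for m in cv_a.fold_metrics]
    b = [getattr(m, metric) for m in cv_b.fold_metrics]
    return stats.wilcoxon(a, b)


# ---------------------------------------------------------------------------
# novel-sequence prediction and the similarity-search baseline
# ---------------------------------------------------------------------------

def predict_novel(
    query_ids: list[str],
    internal_hits: list[SimilarityHit],
    model,
    profile: DiscretizedProfile,
    evalue_max: float = 1.0,
) -> dict[str, str]:
    """Majority-vote prediction for sequences outside the collection.

    Each query's matches (hits with E-value <= ``evalue_max`` whose subject
    has a profile row) are classified by the model; the majority label wins,
    an exact tie goes to F, and a query with no usable match is
    NOT_ASSIGNABLE (treated as "not from a photosynthetic organism").
    """
    by_query: dict[str, list[str]] = {q: [] for q in query_ids}
    for h in internal_hits:
        if h.query_id in by_query and h.evalue <= evalue_max:
            if h.subject_id in profile.data.index:
                by_query[h.query_id].append(h.subject_id)
    out: dict[str, str] = {}
    for q, subjects in by_query.items():
        if not subjects:
            out[q] = NOT_ASSIGNABLE
            continue
        x = profile.data.loc[subjects].values.astype(float)
        votes = pd.Series(model.predict(x)).value_counts()
        t = int(votes.get(POSITIVE, 0))
        f = int(votes.get(NEGATIVE, 0))
        out[q] = POSITIVE if t > f else NEGATIVE
    return out


def blast_baseline(
    query_ids: list[str],
    hits: list[SimilarityHit],
    labeled_db: dict[str, str],
    evalue_max: float = 10.0,
) -> dict[str, str]:
    """Nearest-hit label transfer: best hit = highest bitscore with
    E-value <= ``evalue_max``; ties by lower E-value then subject id."""
    queries = set(query_ids)
    best: dict[str, tuple[float, float, str]] = {}
    for h in hits:
        if h.query_id not in queries or h.subject_id not in labeled_db:
            continue
        if h.evalue > evalue_max:
            continue
        key = (-h.bitscore, h.evalue, h.subject_id)
        if h.query_id not in best or key < best[h.query_id]:
            best[h.query_id] = key
    return {
        q: labeled_db[best[q][2]] if q in best else NOT_ASSIGNABLE
        for q in query_ids
    }
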