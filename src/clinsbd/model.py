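"""Linear-SVM training, evaluation and feature-relevance ranking.

The training protocol is: scale every feature to [-1, 1] on the training
data, normalize each instance vector to unit Euclidean length, select the
cost parameter C on a logarithmic grid by stratified cross-validation of
the micro-averaged F1, then fit a linear-kernel SVM (LIBLINEAR).  Feature
relevance is ranked by the squared weight w^2 of the linear decision
function f(x) = sgn(w.x + b).

Two high-level estimators operate directly on :class:`~clinsbd.text.PeriodSite`
sequences: :class:`AbbreviationDetector` and :class:`SentenceBoundaryDetector`.
Both follow scikit-learn conventions (``fit``/``predict``/``get_params``)
and compose with its model-selection utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .features import (
    ABBREV_SETS,
    SENTENCE_SETS,
    AbbreviationFeaturizer,
    SentenceFeaturizer,
    is_capitalized,
)
from .lexicon import Lexicon
from .stats import CountTable
from .text import PeriodSite, normalize_right

__all__ = [
    "DEFAULT_C_GRID",
    "RangeUnitScaler",
    "preprocess",
    "LinearPeriodSVM",
    "AbbreviationDetector",
    "SentenceBoundaryDetector",
    "RankedFeature",
    "EvalResult",
    "micro_f1",
    "cohens_kappa",
    "compare_classifiers",
    "select_c",
    "cross_validate",
    "baseline_abbrev",
    "baseline_sentence",
    "chernoff_sample_size",
]

DEFAULT_C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


# ---------------------------------------------------------------------------
# preprocessing


class RangeUnitScaler(TransformerMixin, BaseEstimator):
    """Scale features to [-1, 1] on training data, then unit-normalize rows.

    Test data is mapped with the *training* parameters and may leave the
    [-1, 1] range.  Constant training features map to 0; all-zero rows keep
    zero norm.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        rng = self.max_ - self.min_
        self.scale_ = np.where(rng > 0, 2.0 / np.where(rng > 0, rng, 1.0), 0.0)
        return self

    def affine(self, X):
        """The [-1, 1] range map alone, without the row normalization."""
        X = np.asarray(X, dtype=float)
        return (X - self.min_) * self.scale_ - np.where(self.scale_ > 0, 1.0, 0.0)

    def transform(self, X):
        Xs = self.affine(X)
        norms = np.linalg.norm(Xs, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return Xs / norms


def preprocess(train_matrix, test_matrix=None):
    """Scale training features to [-1, 1], map the test set with the training
    ranges, and normalize all rows to unit length.  Returns the scaled
    training matrix, or a (train, test) pair when a test matrix is given."""
    scaler = RangeUnitScaler().fit(train_matrix)
    train_s = scaler.transform(train_matrix)
    if test_matrix is None:
        return train_s
    return train_s, scaler.transform(test_matrix)


# ---------------------------------------------------------------------------
# metrics


def micro_f1(predictions, gold) -> float:
    """Unweighted micro-averaged F1: tp/fp/fn pooled over all classes.

    For single-label binary tasks this coincides with plain accuracy, since
    every false positive of one class is a false negative of the other.
    """
    predictions = np.asarray(predictions)
    gold = np.asarray(gold)
    if predictions.shape != gold.shape or predictions.size == 0:
        raise ValueError("predictions and gold must be equal-length, non-empty")
    labels = np.union1d(predictions, gold)
    tp = fp = fn = 0
    for lab in labels:
        tp += int(np.sum((predictions == lab) & (gold == lab)))
        fp += int(np.sum((predictions == lab) & (gold != lab)))
        fn += int(np.sum((predictions != lab) & (gold == lab)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def cohens_kappa(rater_a, rater_b) -> float:
    """Chance-corrected inter-rater agreement (p_o - p_e) / (1 - p_e)."""
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("rater label sequences must be equal-length, non-empty")
    n = a.size
    p_o = float(np.mean(a == b))
    labels = np.union1d(a, b)
    p_e = sum(
        float(np.sum(a == lab)) * float(np.sum(b == lab)) for lab in labels
    ) / (n * n)
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: expected agreement is 1 but observed is not")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    significant: bool
    table: np.ndarray
    degenerate: bool = False
    method: str = "chi2"


def compare_classifiers(
    preds_a, preds_b, gold, alpha: float = 0.05, method: str = "chi2"
) -> ComparisonResult:
    """Test whether two classifiers perform differently on the same gold.

    ``method='chi2'`` (default) builds the 2x2 table classifier x
    correct/incorrect and runs a chi-squared independence test without
    continuity correction, i.e. it compares the two accuracies; identical
    predictions give statistic 0 and p = 1.  ``method='mcnemar'`` runs the
    paired McNemar chi-squared test on the discordant site counts instead.
    Degenerate tables (an empty margin, or no discordant pairs) are
    reported as not significant and flagged.
    """
    a = np.asarray(preds_a)
    b = np.asarray(preds_b)
    g = np.asarray(gold)
    ca = a == g
    cb = b == g
    n = g.size
    if method == "mcnemar":
        n01 = int(np.sum(ca & ~cb))
        n10 = int(np.sum(~ca & cb))
        table = np.array([[np.sum(ca & cb), n01], [n10, np.sum(~ca & ~cb)]], float)
        if n01 + n10 == 0:
            return ComparisonResult(0.0, 1.0, False, table, degenerate=True, method=method)
        stat = (n01 - n10) ** 2 / (n01 + n10)
        from scipy.stats import chi2 as _chi2

        p = float(_chi2.sf(stat, df=1))
        return ComparisonResult(float(stat), p, p < alpha, table, method=method)
    table = np.array(
        [[np.sum(ca), n - np.sum(ca)], [np.sum(cb), n - np.sum(cb)]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ComparisonResult(0.0, 1.0, False, table, degenerate=True)
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return ComparisonResult(float(stat), float(p), p < alpha, table)


def chernoff_sample_size(epsilon: float, delta: float) -> int:
    """Distribution-free sample size n >= (2+eps)/eps^2 * ln(2/delta).

    The fractional part of the bound is truncated, which reproduces the
    conventional printed figure of 3024 snippets at eps = delta = 0.05.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    return int((2.0 + epsilon) / epsilon**2 * math.log(2.0 / delta))


# ---------------------------------------------------------------------------
# baselines


def baseline_abbrev(site: PeriodSite) -> int:
    """Rule baseline: abbreviation iff the candidate is followed by a lower
    case character (the first character of R)."""
    return int(site.right_token[:1].islower())


def baseline_sentence(site: PeriodSite) -> int:
    """Rule baseline: sentence delimiter iff R_norm is capitalized."""
    return int(is_capitalized(normalize_right(site.right_token)))


# ---------------------------------------------------------------------------
# model selection and evaluation


def _stratified_folds(y, k, seed):
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def _subset(X, idx):
    if isinstance(X, np.ndarray):
        return X[idx]
    return [X[i] for i in idx]


def select_c(
    instances,
    labels,
    grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 5,
    seed: int = 0,
    estimator=None,
) -> float:
    """Pick C from the grid maximizing mean CV micro-F1; ties favour the
    smallest (most regularized) C."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("C selection needs at least two classes")
    base = estimator if estimator is not None else LinearPeriodSVM()
    best_c, best_score = None, -1.0
    for c in sorted(grid):
        est = clone(base)
        est.set_params(C=c, select_C=False)
        scores = []
        skf = _stratified_folds(y, folds, seed)
        for tr, te in skf.split(np.zeros(len(y)), y):
            m = clone(est).fit(_subset(instances, tr), y[tr])
            scores.append(micro_f1(m.predict(_subset(instances, te)), y[te]))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_score, best_c = score, c
    return best_c


@dataclass
class EvalResult:
    """Pooled binary evaluation counts (positive label 1) and micro-F1."""

    tp: int
    fp: int
    tn: int
    fn: int
    micro_f1: float
    per_fold: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n": self.n,
            "micro_f1": self.micro_f1,
            "per_fold": list(self.per_fold),
        }


def evaluate(predictions, gold) -> EvalResult:
    p = np.asarray(predictions).astype(int)
    g = np.asarray(gold).astype(int)
    return EvalResult(
        tp=int(np.sum((p == 1) & (g == 1))),
        fp=int(np.sum((p == 1) & (g == 0))),
        tn=int(np.sum((p == 0) & (g == 0))),
        fn=int(np.sum((p == 0) & (g == 1))),
        micro_f1=micro_f1(p, g),
    )


def cross_validate(estimator, instances, labels, k: int = 10, seed: int = 0) -> EvalResult:
    """Stratified k-fold cross-validation pooling predictions over folds."""
    y = np.asarray(labels).astype(int)
    if len(y) < k:
        raise ValueError(f"need at least k={k} instances")
    pooled = np.empty_like(y)
    per_fold = []
    skf = _stratified_folds(y, k, seed)
    for tr, te in skf.split(np.zeros(len(y)), y):
        m = clone(estimator).fit(_subset(instances, tr), y[tr])
        pred = np.asarray(m.predict(_subset(instances, te))).astype(int)
        pooled[te] = pred
        per_fold.append(micro_f1(pred, y[te]))
    res = evaluate(pooled, y)
    res.per_fold = per_fold
    return res


# ---------------------------------------------------------------------------
# estimators


@dataclass(frozen=True)
class RankedFeature:
    name: str
    w2: float


def _rank(names, coef, n=None):
    w2 = np.asarray(coef, dtype=float).ravel() ** 2
    order = sorted(range(len(w2)), key=lambda i: (-w2[i], names[i]))
    ranked = [RankedFeature(names[i], float(w2[i])) for i in order]
    return ranked if n is None else ranked[: min(n, len(ranked))]


class LinearPeriodSVM(ClassifierMixin, BaseEstimator):
    """Linear SVM over numeric feature matrices with the package's
    preprocessing baked in.

    ``C`` may be a number, or C selection can be switched on with
    ``select_C=True`` to search ``c_grid`` by stratified CV on the scaled
    training matrix.
    """

    def __init__(
        self,
        C: float = 1.0,
        select_C: bool = False,
        c_grid: Sequence[float] = DEFAULT_C_GRID,
        select_folds: int = 3,
        random_state: int = 0,
        max_iter: int = 10000,
    ):
        self.C = C
        self.select_C = select_C
        self.c_grid = c_grid
        self.select_folds = select_folds
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.scaler_ = RangeUnitScaler().fit(X)
        Xs = self.scaler_.transform(X)
        if self.select_C:
            self.C_ = _select_c_numeric(
                Xs, y, self.c_grid, self.select_folds, self.random_state, self.max_iter
            )
        else:
            self.C_ = float(self.C)
        svc = LinearSVC(C=self.C_, max_iter=self.max_iter, dual="auto")
        svc.fit(Xs, y)
        self.classes_ = svc.classes_
        self.coef_ = svc.coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        return self

    def decision_function(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return Xs @ self.coef_ + self.intercept_

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])

    def rank_features(self, n: Optional[int] = None, feature_names=None):
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"f{i:05d}" for i in range(len(self.coef_))]
        )
        return _rank(names, self.coef_, n)


def _select_c_numeric(Xs, y, grid, folds, seed, max_iter):
    best_c, best_score = None, -1.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xs, y))
    for c in sorted(grid):
        scores = []
        for tr, te in splits:
            svc = LinearSVC(C=c, max_iter=max_iter, dual="auto")
            svc.fit(Xs[tr], y[tr])
            scores.append(micro_f1(svc.predict(Xs[te]), y[te]))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_score, best_c = score, c
    return best_c


class _SiteDetectorBase(ClassifierMixin, BaseEstimator):
    """Shared fit/predict plumbing of the two site-level detectors."""

    def _make_featurizer(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, sites: Sequence[PeriodSite], y):
        y = np.asarray(y).astype(int)
        self.featurizer_ = self._make_featurizer().fit(sites, y)
        self.feature_names_ = self.featurizer_.feature_names_
        X = self.featurizer_.transform(sites)
        self.svm_ = LinearPeriodSVM(
            C=self.C if isinstance(self.C, (int, float)) else 1.0,
            select_C=(self.C == "select"),
            c_grid=self.c_grid,
            select_folds=self.select_folds,
            random_state=self.random_state,
            max_iter=self.max_iter,
        ).fit(X, y)
        self.C_ = self.svm_.C_
        self.classes_ = self.svm_.classes_
        return self

    def decision_function(self, sites):
        return self.svm_.decision_function(self.featurizer_.transform(sites))

    def predict(self, sites):
        return self.svm_.predict(self.featurizer_.transform(sites))

    def rank_features(self, n: Optional[int] = None):
        return self.svm_.rank_features(n=n, feature_names=self.feature_names_)


class AbbreviationDetector(_SiteDetectorBase):
    """Binary classifier: does the period of a site mark an abbreviation?

    Parameters
    ----------
    feature_sets : subset of ``ABBREV_SETS``, combined in canonical order.
    mddict : abbreviation-free medical dictionary.
    count_table : corpus collocation counts (see
        :func:`clinsbd.stats.count_collocations`); build it from the
        training corpus once and share it across folds.
    C : a cost value, or "select" for grid search.
    """

    def __init__(
        self,
        feature_sets=ABBREV_SETS,
        mddict: Optional[Lexicon] = None,
        count_table: Optional[CountTable] = None,
        alpha: float = 0.01,
        C="select",
        c_grid=DEFAULT_C_GRID,
        select_folds: int = 3,
        random_state: int = 0,
        max_iter: int = 10000,
    ):
        self.feature_sets = feature_sets
        self.mddict = mddict
        self.count_table = count_table
        self.alpha = alpha
        self.C = C
        self.c_grid = c_grid
        self.select_folds = select_folds
        self.random_state = random_state
        self.max_iter = max_iter

    def _make_featurizer(self):
        return AbbreviationFeaturizer(
            feature_sets=self.feature_sets,
            mddict=self.mddict,
            count_table=self.count_table,
            alpha=self.alpha,
        )


class SentenceBoundaryDetector(_SiteDetectorBase):
    """Binary classifier: does the period of a site delimit a sentence?

    When the 'abbreviation' feature set is enabled, ``abbrev_model`` must be
    a fitted :class:`AbbreviationDetector`; its prediction on the identical
    site becomes a feature, encoding that abbreviations tend to appear
    inside sentences.
    """

    def __init__(
        self,
        feature_sets=SENTENCE_SETS,
        mddict: Optional[Lexicon] = None,
        ccdict: Optional[Lexicon] = None,
        count_table: Optional[CountTable] = None,
        abbrev_model: Optional[AbbreviationDetector] = None,
        alpha: float = 0.01,
        ccdict_plain_membership: bool = False,
        C="select",
        c_grid=DEFAULT_C_GRID,
        select_folds: int = 3,
        random_state: int = 0,
        max_iter: int = 10000,
    ):
        self.feature_sets = feature_sets
        self.mddict = mddict
        self.ccdict = ccdict
        self.count_table = count_table
        self.abbrev_model = abbrev_model
        self.alpha = alpha
        self.ccdict_plain_membership = ccdict_plain_membership
        self.C = C
        self.c_grid = c_grid
        self.select_folds = select_folds
        self.random_state = random_state
        self.max_iter = max_iter

    def _make_featurizer(self):
        return SentenceFeaturizer(
            feature_sets=self.feature_sets,
            mddict=self.mddict,
            ccdict=self.ccdict,
            count_table=self.count_table,
            abbrev_model=self.abbrev_model,
            alpha=self.alpha,
            ccdict_plain_membership=self.ccdict_plain_membership,
        )
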