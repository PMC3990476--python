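"""The 11-classifier roster, cost-sensitive thresholding and 10-fold CV.

Each roster member exposes ``fit``/``predict_proba`` over a pair of views of
the feature matrix: a numeric encoding (one-hot + min-max, median-imputed)
and a discretized level-code encoding.  Margin-only learners are calibrated
to probabilities inside the training data (Platt-style), because the
accuracy-weighted ensemble needs P(disease | x).

Several roster members reimplement classic rule/hybrid learners that have no
scikit-learn equivalent: a decision tree with naive-Bayes leaf models, a tree
with logistic leaf models, a greedy majority decision table, a decision
table / naive Bayes hybrid on complementary feature sets, a distance-weighted
nearest-neighbour learner, and a tree-augmented naive Bayes network.

Evaluation follows the positive-class convention (the disease class is the
positive class): recall = TP/(TP+FN), precision = TP/(TP+FP), and the
F-measure is their harmonic mean.  Class-averaged variants are also
available from :meth:`MetricReport.class_averaged`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_build import Discretizer, FeatureMatrix, NumericEncoder

ROSTER_NAMES = (
    "J48 (Tree)", "Random Forest", "NB Tree", "Functional Tree",
    "Decision Table", "DTNB", "LWL(J48+KNN)", "Bayes Net", "Naive Bayes",
    "SVM", "Neural Network",
)


def derive_seed(master: int, tag: str) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and a tag."""
    digest = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ClassifierSpec:
    """Roster entry: algorithm name, hyperparameters, misclassification costs.

    ``cost_matrix`` is ((0, cost_FP), (cost_FN, 0)): rows = true class
    (ND, D), columns = predicted class (ND, D).  The default all-ones
    off-diagonal is cost-neutral (decision threshold 0.5).
    """

    name: str
    params: dict = field(default_factory=dict)
    cost_matrix: tuple = ((0.0, 1.0), (1.0, 0.0))

    def __post_init__(self) -> None:
        (c00, c01), (c10, c11) = self.cost_matrix
        if min(c00, c01, c10, c11) < 0:
            raise ValueError("costs must be nonnegative")

    @property
    def cost_fp(self) -> float:
        return self.cost_matrix[0][1]

    @property
    def cost_fn(self) -> float:
        return self.cost_matrix[1][0]

    @property
    def threshold(self) -> float:
        """Expected-cost-minimizing probability threshold for predicting disease."""
        if self.cost_fp + self.cost_fn <= 0:
            raise ValueError("degenerate cost matrix: no off-diagonal cost")
        return self.cost_fp / (self.cost_fp + self.cost_fn)


def cost_sensitive_wrap(spec: ClassifierSpec, cost_matrix) -> ClassifierSpec:
    """Attach a misclassification cost matrix; prediction threshold becomes
    cost(FP)/(cost(FP)+cost(FN))."""
    cm = tuple(tuple(float(c) for c in row) for row in cost_matrix)
    wrapped = replace(spec, cost_matrix=cm)
    wrapped.threshold  # validate
    return wrapped


def default_roster(cost_matrix=((0.0, 1.0), (1.0, 0.0))) -> list:
    return [ClassifierSpec(name, cost_matrix=cost_matrix) for name in ROSTER_NAMES]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with the disease class positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)


@dataclass(frozen=True)
class MetricReport:
    tp_rate: float
    fp_rate: float
    accuracy: float
    precision: Optional[float]
    recall: float
    f_measure: Optional[float]

    @property
    def accuracy_for_weighting(self) -> float:
        """CV accuracy stored as the ensemble weight acc_j."""
        return self.accuracy

    def class_averaged(self) -> dict:
        """Unweighted mean of the positive- and negative-class metrics."""
        neg_recall = 1.0 - self.fp_rate
        out = {"recall": (self.recall + neg_recall) / 2.0}
        out["tp_rate"] = out["recall"]
        out["fp_rate"] = (self.fp_rate + (1.0 - self.tp_rate)) / 2.0
        out["accuracy"] = self.accuracy
        return out


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricReport:
    """Positive-class metrics from summed cross-validation counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    recall = cm.tp / pos if pos else 0.0
    fp_rate = cm.fp / neg if neg else 0.0
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp == 0:
        precision = None
        f_measure = None
    else:
        precision = cm.tp / (cm.tp + cm.fp)
        f_measure = (0.0 if precision + recall == 0
                     else 2 * precision * recall / (precision + recall))
    return MetricReport(tp_rate=recall, fp_rate=fp_rate, accuracy=accuracy,
                        precision=precision, recall=recall, f_measure=f_measure)


# ---------------------------------------------------------------------------
# Learner implementations.  Each takes (X_num, X_cat, y) in fit and returns
# P(disease) from predict_proba(X_num, X_cat).

class _BaseLearner:
    def fit(self, X_num, X_cat, y):  # pragma: no cover - interface
        raise NotImplementedError

    def predict_proba(self, X_num, X_cat) -> np.ndarray:
        raise NotImplementedError


class _SklearnLearner(_BaseLearner):
    """Adapter for estimators consuming the numeric encoding."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X_num, X_cat, y):
        self.classes_seen_ = np.unique(y)
        self.estimator.fit(X_num, y)
        return self

    def predict_proba(self, X_num, X_cat):
        proba = self.estimator.predict_proba(X_num)
        if proba.shape[1] == 1:
            return np.full(len(X_num), float(self.classes_seen_[0]))
        return proba[:, list(self.estimator.classes_).index(1)]


def _leaf_proba_fallback(y_leaf: np.ndarray, prior: float) -> float:
    # Laplace-smoothed leaf frequency, shrunk toward the class prior
    return (y_leaf.sum() + prior) / (len(y_leaf) + 1.0)


class _TreeWithLeafModels(_BaseLearner):
    """Decision tree whose leaves hold a secondary model (NB or logistic).

    A shallow tree partitions the space; within each leaf a local model is
    fitted when the leaf is big and mixed enough, otherwise the smoothed leaf
    class frequency is used.
    """

    def __init__(self, leaf_model: str, seed: int = 0, max_depth: int = 3,
                 min_leaf_fit: int = 15):
        self.leaf_model = leaf_model
        self.seed = seed
        self.max_depth = max_depth
        self.min_leaf_fit = min_leaf_fit

    def fit(self, X_num, X_cat, y):
        self.tree_ = DecisionTreeClassifier(
            max_depth=self.max_depth, min_samples_leaf=10, random_state=self.seed)
        self.tree_.fit(X_num, y)
        self.prior_ = float(np.mean(y))
        leaves = self.tree_.apply(X_num)
        self.leaf_models_: dict = {}
        self.leaf_proba_: dict = {}
        for leaf in np.unique(leaves):
            mask = leaves == leaf
            y_leaf = y[mask]
            self.leaf_proba_[leaf] = _leaf_proba_fallback(y_leaf, self.prior_)
            if mask.sum() >= self.min_leaf_fit and len(np.unique(y_leaf)) == 2:
                if self.leaf_model == "nb":
                    model = GaussianNB(var_smoothing=1e-6)
                else:
                    model = LogisticRegression(max_iter=200, C=1.0)
                model.fit(X_num[mask], y_leaf)
                self.leaf_models_[leaf] = model
        return self

    def predict_proba(self, X_num, X_cat):
        leaves = self.tree_.apply(X_num)
        out = np.empty(len(X_num))
        for leaf in np.unique(leaves):
            mask = leaves == leaf
            model = self.leaf_models_.get(leaf)
            if model is None:
                out[mask] = self.leaf_proba_.get(leaf, self.prior_)
            else:
                proba = model.predict_proba(X_num[mask])
                out[mask] = proba[:, list(model.classes_).index(1)]
        return np.clip(out, 0.0, 1.0)


class _DecisionTable(_BaseLearner):
    """Greedy majority decision table over discretized attributes.

    Forward-selects attributes while the table's leave-one-out accuracy
    improves (LOO penalizes memorizing singleton cells); unseen key
    combinations fall back to the class prior.
    """

    def __init__(self, max_features: int = 5):
        self.max_features = max_features

    @staticmethod
    def _loo_accuracy(keys: np.ndarray, y: np.ndarray) -> float:
        prior_pos = np.mean(y) > 0.5
        correct = 0
        _, inverse = np.unique(keys, axis=0, return_inverse=True)
        for cell in np.unique(inverse):
            y_cell = y[inverse == cell]
            n1 = int(y_cell.sum())
            n0 = len(y_cell) - n1
            # class-1 member removed: predict 1 iff n1-1 > n0 (tie -> prior)
            if n1 - 1 > n0 or (n1 - 1 == n0 and prior_pos):
                correct += n1
            if n0 - 1 > n1 or (n0 - 1 == n1 and not prior_pos):
                correct += n0
        return correct / len(y)

    def fit(self, X_num, X_cat, y):
        n_attr = X_cat.shape[1]
        self.prior_ = float(np.mean(y))
        selected: list = []
        best = max(self.prior_, 1 - self.prior_)
        remaining = list(range(n_attr))
        while remaining and len(selected) < self.max_features:
            scored = [(self._loo_accuracy(X_cat[:, selected + [j]], y), j)
                      for j in remaining]
            top_acc, top_j = max(scored, key=lambda t: (t[0], -t[1]))
            if top_acc <= best + 1e-12:
                break
            best = top_acc
            selected.append(top_j)
            remaining.remove(top_j)
        self.features_ = selected
        self.table_: dict = {}
        if selected:
            keys = X_cat[:, selected]
            for key, label in zip(map(tuple, keys), y):
                cell = self.table_.setdefault(key, [0, 0])
                cell[label] += 1
        return self

    def cell_proba(self, key: tuple) -> float:
        cell = self.table_.get(key)
        if cell is None:
            return self.prior_
        return (cell[1] + self.prior_) / (cell[0] + cell[1] + 1.0)

    def predict_proba(self, X_num, X_cat):
        if not self.features_:
            return np.full(len(X_cat), self.prior_)
        keys = X_cat[:, self.features_]
        return np.array([self.cell_proba(tuple(k)) for k in keys])


class _SmoothedCategoricalNB:
    """Laplace-smoothed categorical naive Bayes on level codes."""

    def fit(self, X_cat, y, feature_idx):
        self.features_ = list(feature_idx)
        self.log_prior_ = np.log([max(1 - np.mean(y), 1e-9), max(np.mean(y), 1e-9)])
        self.tables_ = []
        for j in self.features_:
            n_levels = int(X_cat[:, j].max()) + 1
            table = np.ones((n_levels, 2))  # Laplace
            np.add.at(table, (X_cat[:, j], y), 1)
            self.tables_.append(np.log(table / table.sum(axis=0)))
        return self

    def log_likelihood(self, X_cat) -> np.ndarray:
        ll = np.zeros((len(X_cat), 2))
        for table, j in zip(self.tables_, self.features_):
            codes = np.clip(X_cat[:, j], 0, table.shape[0] - 1)
            ll += table[codes]
        return ll

    def predict_proba_pos(self, X_cat) -> np.ndarray:
        logp = self.log_likelihood(X_cat) + self.log_prior_
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p[:, 1] / p.sum(axis=1)


class _DTNB(_BaseLearner):
    """Decision table / naive Bayes hybrid on complementary attribute sets.

    The table's greedily selected attributes contribute a table conditional;
    all remaining attributes contribute naive-Bayes likelihoods; the two are
    combined assuming conditional independence between the blocks.
    """

    def fit(self, X_num, X_cat, y):
        self.table_ = _DecisionTable(max_features=4).fit(X_num, X_cat, y)
        rest = [j for j in range(X_cat.shape[1]) if j not in self.table_.features_]
        self.nb_ = _SmoothedCategoricalNB().fit(X_cat, y, rest) if rest else None
        self.prior_ = float(np.mean(y))
        return self

    def predict_proba(self, X_num, X_cat):
        p_table = self.table_.predict_proba(X_num, X_cat)
        p_table = np.clip(p_table, 1e-9, 1 - 1e-9)
        if self.nb_ is None:
            return p_table
        ll = self.nb_.log_likelihood(X_cat)
        log_odds = (np.log(p_table) - np.log1p(-p_table)) + (ll[:, 1] - ll[:, 0])
        return 1.0 / (1.0 + np.exp(-log_odds))


class _LocallyWeighted(_BaseLearner):
    """Distance-weighted nearest-neighbour learner on the numeric encoding."""

    def __init__(self, k: int = 50):
        self.k = k

    def fit(self, X_num, X_cat, y):
        self.X_ = np.asarray(X_num, dtype=float)
        self.y_ = np.asarray(y)
        self.prior_ = float(np.mean(y))
        return self

    def predict_proba(self, X_num, X_cat):
        from scipy.spatial.distance import cdist

        k = min(self.k, len(self.y_))
        dist = cdist(np.asarray(X_num, dtype=float), self.X_)
        out = np.empty(len(X_num))
        for i in range(len(X_num)):
            idx = np.argsort(dist[i], kind="stable")[:k]
            w = 1.0 / (dist[i, idx] + 1e-6)
            out[i] = float(np.sum(w * self.y_[idx]) / np.sum(w))
        return out


class _TanBayesNet(_BaseLearner):
    """Tree-augmented naive Bayes on discretized codes.

    Feature-feature edges are a maximum spanning tree of class-conditional
    mutual information; each feature's CPT conditions on the class and its
    tree parent, with Laplace smoothing.
    """

    def _cmi(self, a, b, y) -> float:
        total = 0.0
        n = len(y)
        for cls in (0, 1):
            mask = y == cls
            if not mask.any():
                continue
            na, nb = int(a.max()) + 1, int(b.max()) + 1
            joint = np.zeros((na, nb))
            np.add.at(joint, (a[mask], b[mask]), 1)
            pj = joint / mask.sum()
            pa = pj.sum(axis=1, keepdims=True)
            pb = pj.sum(axis=0, keepdims=True)
            nz = pj > 0
            total += (mask.sum() / n) * float((pj[nz] * np.log(pj[nz] / (pa @ pb)[nz])).sum())
        return total

    def fit(self, X_num, X_cat, y):
        n_attr = X_cat.shape[1]
        self.n_attr_ = n_attr
        self.log_prior_ = np.log([max(1 - np.mean(y), 1e-9), max(np.mean(y), 1e-9)])
        cmi = np.zeros((n_attr, n_attr))
        for j in range(n_attr):
            for k in range(j + 1, n_attr):
                cmi[j, k] = cmi[k, j] = self._cmi(X_cat[:, j], X_cat[:, k], y)
        mst = minimum_spanning_tree(-(cmi + 1e-12)).toarray()
        # orient edges away from attribute 0
        adjacency = (mst != 0) | (mst.T != 0)
        self.parent_ = np.full(n_attr, -1)
        stack, seen = [0], {0}
        while stack:
            node = stack.pop()
            for nxt in np.where(adjacency[node])[0]:
                if nxt not in seen:
                    seen.add(nxt)
                    self.parent_[nxt] = node
                    stack.append(nxt)
        self.cpts_ = []
        for j in range(n_attr):
            nj = int(X_cat[:, j].max()) + 1
            parent = self.parent_[j]
            if parent < 0:
                table = np.ones((1, nj, 2))
                np.add.at(table, (0, X_cat[:, j], y), 1)
            else:
                npar = int(X_cat[:, parent].max()) + 1
                table = np.ones((npar, nj, 2))
                np.add.at(table, (X_cat[:, parent], X_cat[:, j], y), 1)
            self.cpts_.append(np.log(table / table.sum(axis=1, keepdims=True)))
        return self

    def predict_proba(self, X_num, X_cat):
        logp = np.tile(self.log_prior_, (len(X_cat), 1))
        for j in range(self.n_attr_):
            table = self.cpts_[j]
            parent = self.parent_[j]
            pcodes = (np.zeros(len(X_cat), dtype=int) if parent < 0
                      else np.clip(X_cat[:, parent], 0, table.shape[0] - 1))
            jcodes = np.clip(X_cat[:, j], 0, table.shape[1] - 1)
            logp += table[pcodes, jcodes]
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p[:, 1] / p.sum(axis=1)


def make_learner(spec: ClassifierSpec, seed: int) -> _BaseLearner:
    """Instantiate the roster member named in ``spec`` with a derived seed."""
    name, params = spec.name, spec.params
    if name == "J48 (Tree)":
        return _SklearnLearner(DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=params.get("min_samples_leaf", 2),
            random_state=seed))
    if name == "Random Forest":
        return _SklearnLearner(RandomForestClassifier(
            n_estimators=params.get("n_estimators", 100), random_state=seed))
    if name == "NB Tree":
        return _TreeWithLeafModels("nb", seed=seed)
    if name == "Functional Tree":
        return _TreeWithLeafModels("logistic", seed=seed)
    if name == "Decision Table":
        return _DecisionTable(max_features=params.get("max_features", 5))
    if name == "DTNB":
        return _DTNB()
    if name == "LWL(J48+KNN)":
        return _LocallyWeighted(k=params.get("k", 50))
    if name == "Bayes Net":
        return _TanBayesNet()
    if name == "Naive Bayes":
        return _SklearnLearner(GaussianNB())
    if name == "SVM":
        from sklearn.calibration import CalibratedClassifierCV

        # sigmoid (Platt) calibration fitted within the training data turns
        # the SVM margin into P(disease | x)
        return _SklearnLearner(CalibratedClassifierCV(
            SVC(kernel="rbf", C=params.get("C", 1.0), random_state=seed),
            method="sigmoid", cv=3))
    if name == "Neural Network":
        return _SklearnLearner(MLPClassifier(
            hidden_layer_sizes=params.get("hidden", (16,)), max_iter=500,
            random_state=seed))
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class TrainedModel:
    """A roster member refit on the full training data, ready to score new data."""

    spec: ClassifierSpec
    learner: _BaseLearner
    encoder: NumericEncoder
    discretizer: Discretizer
    cv_accuracy: float
    schema: tuple

    def predict_proba(self, matrix: FeatureMatrix) -> np.ndarray:
        if matrix.attribute_names != self.schema:
            raise ValueError("feature matrix schema does not match the trained model")
        return np.clip(self.learner.predict_proba(
            self.encoder.transform(matrix), self.discretizer.transform(matrix)), 0.0, 1.0)

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        """Cost-adjusted binary call: 1 = disease."""
        return (self.predict_proba(matrix) >= self.spec.threshold).astype(int)


def cross_validate(spec: ClassifierSpec, matrix: FeatureMatrix, k: int = 10,
                   seed: int = 0):
    """Stratified k-fold evaluation of one roster member.

    Returns ``(ConfusionMatrix, MetricReport, TrainedModel, oof_proba)``: the
    confusion matrix summed over the k test folds, its metrics, the model
    refit on all data, and the out-of-fold P(disease) per instance.
    """
    if not matrix.has_class:
        raise ValueError("labeled feature matrix required")
    y = matrix.y()
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if k > min(n_pos, n_neg):
        raise ValueError(f"k={k} exceeds minority class size {min(n_pos, n_neg)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=derive_seed(seed, "folds"))
    oof = np.full(len(y), np.nan)
    threshold = spec.threshold
    for fold_no, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train = matrix.subset_rows(train_idx)
        test = matrix.subset_rows(test_idx)
        encoder = NumericEncoder(matrix.attributes).fit(train)
        disc = Discretizer(matrix.attributes).fit(train)
        learner = make_learner(spec, derive_seed(seed, f"{spec.name}:{fold_no}"))
        learner.fit(encoder.transform(train), disc.transform(train), y[train_idx])
        oof[test_idx] = np.clip(
            learner.predict_proba(encoder.transform(test), disc.transform(test)), 0, 1)
    pred = (oof >= threshold).astype(int)
    cm = ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()), fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()), fp=int(((pred == 1) & (y == 0)).sum()))
    report = metrics_from_confusion(cm)
    encoder = NumericEncoder(matrix.attributes).fit(matrix)
    disc = Discretizer(matrix.attributes).fit(matrix)
    learner = make_learner(spec, derive_seed(seed, f"{spec.name}:full"))
    learner.fit(encoder.transform(matrix), disc.transform(matrix), y)
    model = TrainedModel(spec=spec, learner=learner, encoder=encoder,
                         discretizer=disc, cv_accuracy=report.accuracy,
                         schema=matrix.attribute_names)
    return cm, report, model, oof
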