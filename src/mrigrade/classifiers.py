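"""Classical severity classifiers with hyperparameter search.

Six model families, each exposed as a scikit-learn-style estimator:
a decision tree with the CART twoing (or Gini) split criterion, a
correlation-distance k-nearest-neighbour classifier, linear discriminant
analysis with a pooled ridge-stabilised covariance, Gaussian naive
Bayes, a linear SVM (one-vs-one), and tree ensembles (bagging,
multiclass AdaBoost/SAMME, and RUSBoost with per-round class
rebalancing).  ``optimize_hyperparameters`` runs a seeded random search
with stratified cross-validation over documented per-family grids.

Tie conventions, shared everywhere: equal votes or scores resolve to the
lowest class label; equal distances resolve to the lower training index.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class TreeSpec:
    criterion: str = "twoing"  # or "gini"
    max_splits: int = 138      # reported optimum of the reference study's search
    min_leaf: int = 1

    def __post_init__(self):
        if self.criterion not in ("twoing", "gini"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.max_splits < 1:
            raise ValueError("max_splits must be >= 1")


@dataclass
class EnsembleSpec:
    method: str = "AdaBoost"  # AdaBoost | Bag | RUSBoost
    n_learners: int = 50
    learning_rate: float = 0.1
    learner: TreeSpec = field(default_factory=lambda: TreeSpec(max_splits=10))

    def __post_init__(self):
        if self.method not in ("AdaBoost", "Bag", "RUSBoost"):
            raise ValueError(f"unknown ensemble method {self.method!r}")
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")


@dataclass
class KNNSpec:
    k: int = 12
    metric: str = "correlation"  # or "euclidean"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in ("euclidean", "correlation"):
            raise ValueError(f"unknown metric {self.metric!r}")


# ---------------------------------------------------------------------------
# Twoing criterion and decision tree
# ---------------------------------------------------------------------------

def twoing_score(left_counts, right_counts) -> float:
    """CART twoing split criterion.

    score = (P_L * P_R / 4) * (sum_c |p(c|L) - p(c|R)|)^2, where P_L and
    P_R are the side proportions.  Bounded by 0.25, maximised by balanced
    class-separating splits.
    """
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    nl, nr = left.sum(), right.sum()
    if nl <= 0 or nr <= 0:
        raise ValueError("both split sides must be nonempty")
    pl, pr = nl / (nl + nr), nr / (nl + nr)
    return float(pl * pr / 4.0 * np.sum(np.abs(left / nl - right / nr)) ** 2)


def _gini_gain(left, right):
    nl, nr = left.sum(), right.sum()
    n = nl + nr
    parent = left + right

    def impurity(c, tot):
        p = c / tot
        return 1.0 - np.sum(p * p)

    return impurity(parent, n) - nl / n * impurity(left, nl) - nr / n * impurity(right, nr)


def _best_split(X, w_counts, criterion):
    """Best axis-aligned threshold split of a node.

    ``w_counts`` is an (n, C) one-hot (or weighted) class indicator.
    Thresholds are midpoints between consecutive distinct sorted values.
    Returns (score, feature, threshold) or None if no valid split exists.
    """
    n, d = X.shape
    total = w_counts.sum(axis=0)
    best = None
    for f in range(d):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        cum = np.cumsum(w_counts[order], axis=0)
        # split after position i (0-based): left = rows 0..i
        distinct = np.flatnonzero(xs[:-1] < xs[1:])
        for i in distinct:
            left = cum[i]
            right = total - left
            if left.sum() <= 0 or right.sum() <= 0:
                continue
            if criterion == "twoing":
                s = twoing_score(left, right)
            else:
                s = _gini_gain(left, right)
            if best is None or s > best[0] + 1e-15:
                best = (s, f, 0.5 * (xs[i] + xs[i + 1]))
    return best


class TwoingDecisionTreeClassifier(BaseEstimator, ClassifierMixin):
    """Greedy binary decision tree with the twoing or Gini criterion.

    Growth is best-first: the split with the globally highest criterion
    score is applied next, until ``max_splits`` internal nodes, node
    purity, or the ``min_leaf`` floor stop it.  Leaves predict the
    majority class (ties to the lowest label).
    """

    def __init__(self, criterion: str = "twoing", max_splits: int = 138,
                 min_leaf: int = 1):
        self.criterion = criterion
        self.max_splits = max_splits
        self.min_leaf = min_leaf

    def fit(self, X, y, sample_weight=None):
        spec = TreeSpec(self.criterion, self.max_splits, self.min_leaf)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        self.classes_ = np.unique(y)
        ci = np.searchsorted(self.classes_, y)
        C = len(self.classes_)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        wc = np.zeros((len(y), C))
        wc[np.arange(len(y)), ci] = w

        # nodes: dict id -> (feature, threshold, left_id, right_id) internal
        #        or ('leaf', class_index) terminal
        self.nodes_ = {}
        next_id = [0]

        def new_node():
            i = next_id[0]
            next_id[0] += 1
            return i

        root = new_node()
        counter = [0]
        heap = []  # (-score, tiebreak, node_id, idx, split)
        push_seq = [0]

        def consider(node_id, idx):
            node_counts = wc[idx].sum(axis=0)
            self.nodes_[node_id] = ("leaf", int(np.argmax(node_counts)))
            if len(idx) < 2 * spec.min_leaf or np.count_nonzero(node_counts) <= 1:
                return
            split = _best_split(X[idx], wc[idx], spec.criterion)
            if split is None:
                return
            s, f, t = split
            left_mask = X[idx, f] <= t
            if left_mask.sum() < spec.min_leaf or (~left_mask).sum() < spec.min_leaf:
                return
            heapq.heappush(heap, (-s, push_seq[0], node_id, idx, (f, t, left_mask)))
            push_seq[0] += 1

        consider(root, np.arange(len(y)))
        while heap and counter[0] < spec.max_splits:
            _, _, node_id, idx, (f, t, left_mask) = heapq.heappop(heap)
            lid, rid = new_node(), new_node()
            self.nodes_[node_id] = (f, float(t), lid, rid)
            counter[0] += 1
            consider(lid, idx[left_mask])
            consider(rid, idx[~left_mask])
        self.n_splits_ = counter[0]
        self.root_ = root
        return self

    def _predict_one(self, x):
        node = self.nodes_[self.root_]
        while node[0] != "leaf":
            f, t, lid, rid = node
            node = self.nodes_[lid] if x[f] <= t else self.nodes_[rid]
        return node[1]

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.classes_[[self._predict_one(x) for x in X]]


# ---------------------------------------------------------------------------
# Correlation-distance KNN
# ---------------------------------------------------------------------------

def correlation_distance(A, B):
    """Pairwise 1 - Pearson r between rows of A and rows of B.

    Constant vectors are uncorrelatable and get distance 1 against
    everything.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ Bc.T) / np.outer(na, nb)
    d = 1.0 - r
    d[~np.isfinite(d)] = 1.0
    return d


class CorrelationKNNClassifier(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbour majority vote with correlation or Euclidean
    distance; distance ties break to the lower training index and vote
    ties to the lowest label."""

    def __init__(self, k: int = 12, metric: str = "correlation"):
        self.k = k
        self.metric = metric

    def fit(self, X, y):
        KNNSpec(self.k, self.metric)
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y)
        self.classes_ = np.unique(self.y_)
        if self.k > len(self.y_):
            raise ValueError("k exceeds number of training samples")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.metric == "correlation":
            D = correlation_distance(X, self.X_)
        else:
            D = np.linalg.norm(X[:, None, :] - self.X_[None, :, :], axis=2)
        # stable argsort => distance ties resolve to lower training index
        nn = np.argsort(D, axis=1, kind="stable")[:, :self.k]
        out = np.empty(len(X), dtype=self.y_.dtype)
        for i, idx in enumerate(nn):
            labels, counts = np.unique(self.y_[idx], return_counts=True)
            out[i] = labels[np.argmax(counts)]  # ties -> lowest label (sorted)
        return out


# ---------------------------------------------------------------------------
# LDA and Gaussian naive Bayes
# ---------------------------------------------------------------------------

class PooledLDAClassifier(BaseEstimator, ClassifierMixin):
    """Linear discriminant analysis with a shared within-class covariance.

    The pooled covariance gets a ridge of 1e-6 * trace/d so collinear
    features never break the solve; priors are empirical.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n, d = X.shape
        means, priors = [], []
        S = np.zeros((d, d))
        for c in self.classes_:
            Xc = X[y == c]
            if len(Xc) < 2:
                raise ValueError(f"class {c} has fewer than 2 samples")
            mu = Xc.mean(axis=0)
            means.append(mu)
            priors.append(len(Xc) / n)
            S += (Xc - mu).T @ (Xc - mu)
        S /= (n - len(self.classes_))
        S += self.ridge * (np.trace(S) / d if np.trace(S) > 0 else 1.0) * np.eye(d)
        self.means_ = np.array(means)
        self.priors_ = np.array(priors)
        self.cov_inv_ = np.linalg.inv(S)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.empty((len(X), len(self.classes_)))
        for i, (mu, pi) in enumerate(zip(self.means_, self.priors_)):
            w = self.cov_inv_ @ mu
            b = -0.5 * mu @ w + np.log(pi)
            scores[:, i] = X @ w + b
        return scores

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class GaussianNBClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian naive Bayes with per-class diagonal covariances.

    Variances are floored at ``var_floor`` so constant features cannot
    produce infinite log-likelihoods.
    """

    def __init__(self, var_floor: float = 1e-9):
        self.var_floor = var_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.theta_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        self.var_ = np.array([np.maximum(X[y == c].var(axis=0), self.var_floor)
                              for c in self.classes_])
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = np.empty((len(X), len(self.classes_)))
        for i in range(len(self.classes_)):
            ll = -0.5 * np.sum(np.log(2 * np.pi * self.var_[i])
                               + (X - self.theta_[i]) ** 2 / self.var_[i], axis=1)
            jll[:, i] = ll + np.log(self.priors_[i])
        return jll

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        p = np.exp(jll - jll.max(axis=1, keepdims=True))
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


# ---------------------------------------------------------------------------
# Linear SVM (one-vs-one hinge)
# ---------------------------------------------------------------------------

class LinearSVMClassifier(BaseEstimator, ClassifierMixin):
    """Multiclass linear SVM via one-vs-one voting over class pairs.

    Each binary problem is solved to the hinge-loss optimum (SMO,
    tolerance 1e-4); the one-vs-one vote resolves ties to the lowest
    label.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-4):
        self.C = C
        self.tol = tol

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes")
        self.svc_ = SVC(kernel="linear", C=self.C, tol=self.tol,
                        decision_function_shape="ovr", break_ties=False)
        self.svc_.fit(np.asarray(X, dtype=float), y)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, X):
        """Per-class decision values (one-vs-one votes folded to one
        column per class); for 2-class fits, the signed margin."""
        return self.svc_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.svc_.predict(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Tree ensembles: Bag, AdaBoost (SAMME), RUSBoost
# ---------------------------------------------------------------------------

class TreeEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Bagging / AdaBoost-SAMME / RUSBoost over twoing decision trees.

    * Bag: bootstrap-resampled trees, unweighted majority vote.
    * AdaBoost: discrete SAMME reweighting with the given learning rate.
    * RUSBoost: SAMME where each round first undersamples every class to
      the minority-class count (weight-proportional, without
      replacement) before fitting; errors and weight updates use the
      full training set.

    ``resample_counts_`` records the per-round class counts actually fed
    to each learner (the RUSBoost balancing instrumentation).
    """

    def __init__(self, method: str = "AdaBoost", n_learners: int = 50,
                 learning_rate: float = 0.1, max_splits: int = 10,
                 criterion: str = "twoing", min_leaf: int = 1, seed: int = 0):
        self.method = method
        self.n_learners = n_learners
        self.learning_rate = learning_rate
        self.max_splits = max_splits
        self.criterion = criterion
        self.min_leaf = min_leaf
        self.seed = seed

    def _new_tree(self):
        return TwoingDecisionTreeClassifier(self.criterion, self.max_splits, self.min_leaf)

    def fit(self, X, y):
        EnsembleSpec(self.method, self.n_learners, self.learning_rate,
                     TreeSpec(self.criterion, self.max_splits, self.min_leaf))
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n = len(y)
        rng = np.random.default_rng(self.seed)
        self.classes_ = np.unique(y)
        K = len(self.classes_)
        self.estimators_ = []
        self.alphas_ = []
        self.resample_counts_ = []

        if self.method == "Bag":
            for _ in range(self.n_learners):
                idx = rng.integers(0, n, size=n)
                self.estimators_.append(self._new_tree().fit(X[idx], y[idx]))
                self.alphas_.append(1.0)
                self.resample_counts_.append(
                    {int(c): int(np.sum(y[idx] == c)) for c in self.classes_})
            return self

        w = np.full(n, 1.0 / n)
        min_count = min(int(np.sum(y == c)) for c in self.classes_)
        for _ in range(self.n_learners):
            if self.method == "RUSBoost":
                idx = []
                for c in self.classes_:
                    ci = np.flatnonzero(y == c)
                    p = w[ci] / w[ci].sum()
                    take = min(min_count, len(ci))
                    idx.extend(rng.choice(ci, size=take, replace=False, p=p))
                idx = np.array(idx)
                tree = self._new_tree().fit(X[idx], y[idx], sample_weight=w[idx])
            else:
                idx = np.arange(n)
                tree = self._new_tree().fit(X, y, sample_weight=w)
            self.resample_counts_.append(
                {int(c): int(np.sum(y[idx] == c)) for c in self.classes_})
            pred = tree.predict(X)
            miss = pred != y
            err = float(np.sum(w * miss) / np.sum(w))
            if err >= 1.0 - 1.0 / K:  # no better than chance: skip round
                continue
            err = max(err, 1e-12)
            alpha = self.learning_rate * (np.log((1 - err) / err) + np.log(K - 1))
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            w = w * np.exp(alpha * miss)
            w /= w.sum()
            if err <= 1e-12:
                break
        if not self.estimators_:  # degenerate data: fall back to one tree
            self.estimators_ = [self._new_tree().fit(X, y)]
            self.alphas_ = [1.0]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros((len(X), len(self.classes_)))
        for alpha, est in zip(self.alphas_, self.estimators_):
            pred = est.predict(X)
            votes[np.arange(len(X)), np.searchsorted(self.classes_, pred)] += alpha
        return self.classes_[np.argmax(votes, axis=1)]


# ---------------------------------------------------------------------------
# Registry, fit wrappers, serialization, hyperparameter search
# ---------------------------------------------------------------------------

def make_classifier(family: str, seed: int = 0, **params):
    """Instantiate a classifier by family name (dt, knn, lda, nb, svm,
    adaboost, bag, rusboost)."""
    family = family.lower()
    if family == "dt":
        return TwoingDecisionTreeClassifier(**params)
    if family == "knn":
        return CorrelationKNNClassifier(**params)
    if family == "lda":
        return PooledLDAClassifier(**params)
    if family == "nb":
        return GaussianNBClassifier(**params)
    if family == "svm":
        return LinearSVMClassifier(**params)
    if family in ("adaboost", "bag", "rusboost"):
        method = {"adaboost": "AdaBoost", "bag": "Bag", "rusboost": "RUSBoost"}[family]
        return TreeEnsembleClassifier(method=method, seed=seed, **params)
    raise ValueError(f"unknown classifier family {family!r}")


CLASSIFIER_FAMILIES = ("dt", "knn", "lda", "nb", "svm", "adaboost", "bag", "rusboost")


def fit_decision_tree(X, y, spec: TreeSpec = TreeSpec()):
    return TwoingDecisionTreeClassifier(spec.criterion, spec.max_splits, spec.min_leaf).fit(X, y)


def predict_knn(Xtrain, ytrain, Xtest, spec: KNNSpec = KNNSpec()):
    return CorrelationKNNClassifier(spec.k, spec.metric).fit(Xtrain, ytrain).predict(Xtest)


def fit_lda(X, y):
    return PooledLDAClassifier().fit(X, y)


def fit_gaussian_nb(X, y):
    return GaussianNBClassifier().fit(X, y)


def fit_linear_svm(X, y, C: float = 1.0):
    return LinearSVMClassifier(C=C).fit(X, y)


def fit_ensemble(X, y, spec: EnsembleSpec = EnsembleSpec(), seed: int = 0):
    return TreeEnsembleClassifier(
        method=spec.method, n_learners=spec.n_learners,
        learning_rate=spec.learning_rate, max_splits=spec.learner.max_splits,
        criterion=spec.learner.criterion, min_leaf=spec.learner.min_leaf,
        seed=seed).fit(X, y)


def _sample_params(family: str, rng) -> dict:
    family = family.lower()
    if family == "dt":
        return {"max_splits": int(rng.integers(1, 200)),
                "criterion": str(rng.choice(["twoing", "gini"]))}
    if family == "knn":
        return {"k": int(rng.integers(1, 31)),
                "metric": str(rng.choice(["euclidean", "correlation"]))}
    if family == "svm":
        return {"C": float(10.0 ** rng.uniform(-3, 3))}
    if family == "nb":
        return {}
    if family in ("adaboost", "bag", "rusboost"):
        return {"n_learners": int(rng.integers(5, 100)),
                "learning_rate": float(10.0 ** rng.uniform(-3, 0)),
                "max_splits": int(rng.integers(1, 50))}
    if family == "lda":
        return {}
    raise ValueError(f"unknown classifier family {family!r}")


def cross_val_error(clf, X, y, n_folds: int = 5, seed: int = 0) -> float:
    """Stratified k-fold misclassification rate."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_folds = min(n_folds, int(min(np.bincount(np.searchsorted(np.unique(y), y)))))
    if n_folds < 2:
        raise ValueError("cross-validation needs at least 2 samples per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        model = clone(clf).fit(X[tr], y[tr])
        errs.append(float(np.mean(model.predict(X[te]) != y[te])))
    return float(np.mean(errs))


def optimize_hyperparameters(X, y, family: str, budget: int = 20, seed: int = 0,
                             n_folds: int = 5):
    """Seeded random search minimising stratified-CV misclassification.

    Returns ``(best_params, best_cv_error)``; ties keep the first
    candidate found.  Families without tunable parameters (nb, lda) are
    evaluated once.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    best_params, best_err = None, np.inf
    seen = set()
    if family.lower() in ("nb", "lda"):
        budget = 1
    y_arr = np.asarray(y)
    counts = np.bincount(np.searchsorted(np.unique(y_arr), y_arr))
    folds = min(n_folds, int(counts.min()))
    min_train = len(y_arr) - int(np.ceil(len(y_arr) / max(folds, 2)))
    for _ in range(budget):
        params = _sample_params(family, rng)
        key = tuple(sorted(params.items()))
        if key in seen:
            continue
        seen.add(key)
        if params.get("k", 1) > min_train:
            continue
        clf = make_classifier(family, seed=seed, **params)
        err = cross_val_error(clf, X, y, n_folds=n_folds, seed=seed)
        if err < best_err:
            best_params, best_err = params, err
    if best_params is None:  # every candidate infeasible at this n
        best_params = {"k": 1} if family.lower() == "knn" else {}
        best_err = cross_val_error(make_classifier(family, seed=seed, **best_params),
                                   X, y, n_folds=n_folds, seed=seed)
    return best_params, float(best_err)


def classifier_to_json(clf) -> str:
    """Portable summary of a fitted model (family + hyperparameters).

    Full fitted state is pickleable via joblib; the JSON form exists for
    reports and reproducibility records.
    """
    return json.dumps({
        "family": type(clf).__name__,
        "hyperparameters": clf.get_params(),
        "classes": np.asarray(clf.classes_).tolist(),
    }, default=str)
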