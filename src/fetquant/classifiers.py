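"""Published decision rules and a CART trainer for tumor vs astrogliosis.

The published rules are fixed-threshold classifiers on TBR features: the
standard 1.6x-brain rule, single plexus thresholds (>1.0 early / >1.2 late),
their disjunctive dual-acquisition combination, thalamus rules (absolute and
relative), and a two-feature decision tree on the late plexus TBR and the
between-timepoint plexus-TBR difference ("module").

The CART trainer performs binary recursive partitioning with exhaustive
Gini-impurity split search over all features and all midpoints between
sorted distinct values, a minimum-node-fraction direct stop, per-node Fisher
exact p-values for class membership (descriptive only; splits use Gini), and
reports resubstitution and V-fold cross-validation misclassification costs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .fixtures import PUBLISHED_TREE, THALAMUS_THRESHOLDS

__all__ = [
    "TUMOR",
    "ASTROGLIOSIS",
    "ThresholdRule",
    "apply_threshold_rule",
    "dual_plexus_rule",
    "published_tree_classify",
    "thalamus_rule",
    "CartParams",
    "CartNode",
    "CartTree",
    "fit_cart",
    "predict_cart",
    "CartClassifier",
    "ThresholdClassifier",
    "DualPlexusClassifier",
    "PublishedTreeClassifier",
    "ThalamusRuleClassifier",
]

TUMOR = "tumor"
ASTROGLIOSIS = "astrogliosis"


# ---------------------------------------------------------------------------
# fixed threshold rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdRule:
    """Single-feature cutoff, oriented higher-is-tumor.

    ``inclusive`` decides whether a value exactly at the cutoff is tumor
    (published TBR cutoffs are strict '>'; thalamus relative cutoffs are
    inclusive '>=').
    """

    feature: str
    cutoff: float
    inclusive: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def _rule_value(row, feature: str) -> float:
    if np.isscalar(row):
        return float(row)
    if isinstance(row, dict):
        if feature not in row:
            raise KeyError(f"unknown feature {feature!r}")
        return float(row[feature])
    if feature not in row.index if isinstance(row, pd.Series) else feature not in row:
        raise KeyError(f"unknown feature {feature!r}")
    return float(row[feature])


def apply_threshold_rule(row, rule: ThresholdRule) -> str:
    """Label a sample tumor iff its feature exceeds the cutoff."""
    value = _rule_value(row, rule.feature)
    hit = value >= rule.cutoff if rule.inclusive else value > rule.cutoff
    return TUMOR if hit else ASTROGLIOSIS


def dual_plexus_rule(row, early_cutoff: float = 1.0, late_cutoff: float = 1.2) -> str:
    """Dual-acquisition plexus rule: tumor iff the early plexus TBR exceeds
    ``early_cutoff`` OR the late plexus TBR exceeds ``late_cutoff``.

    The disjunction raises sensitivity and lowers specificity relative to the
    single late-acquisition threshold.
    """
    early = _rule_value(row, "tbr_plexus_10")
    late = _rule_value(row, "tbr_plexus_60")
    return TUMOR if (early > early_cutoff or late > late_cutoff) else ASTROGLIOSIS


def published_tree_classify(tbr_plexus_60: float, module: float) -> str:
    """The published two-feature tree.

    Tumor iff (tbr_plexus_60 > 1.77 and module > 1.11) or
    (1.05 < tbr_plexus_60 <= 1.77 and module < 3.19); astrogliosis
    otherwise.  The boundary value 1.77 belongs to the second branch.
    """
    if tbr_plexus_60 < 0 or module < 0:
        raise ValueError("inputs must be non-negative")
    c = PUBLISHED_TREE
    if tbr_plexus_60 > c.t_hi:
        return TUMOR if module > c.m_hi else ASTROGLIOSIS
    if tbr_plexus_60 > c.t_lo:
        return TUMOR if module < c.m_lo_cap else ASTROGLIOSIS
    return ASTROGLIOSIS


def thalamus_rule(value: float, timepoint: int, mode: str = "absolute") -> str:
    """Call uptake in the thalamus pathological or normal.

    Absolute mode thresholds the SUV itself (> 1.0 early, > 1.1 late,
    strict); relative mode thresholds the ratio to the contralateral
    thalamus (>= 1.7 early, >= 1.6 late, inclusive).
    """
    if value < 0:
        raise ValueError("value must be non-negative")
    key = (mode, int(timepoint))
    if key not in THALAMUS_THRESHOLDS:
        raise ValueError(f"unknown mode/timepoint {key}")
    cutoff = THALAMUS_THRESHOLDS[key]
    hit = value >= cutoff if mode == "relative" else value > cutoff
    return "pathological" if hit else "normal"


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CartParams:
    """CART training parameters.

    ``min_node_fraction`` is the direct stop: a node holding less than this
    fraction of the training rows is not split further.  Splits always use
    the Gini impurity; ``cv_folds``-fold cross-validation reports the
    predictive cost alongside the resubstitution cost.
    """

    min_node_fraction: float = 0.05
    max_depth: int | None = None
    cv_folds: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.min_node_fraction < 1.0:
            raise ValueError("min_node_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class CartNode:
    counts: list[int]
    prediction: str
    p_value: float = float("nan")
    feature: str | None = None
    threshold: float | None = None
    left: "CartNode | None" = None
    right: "CartNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return int(sum(self.counts))


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(X: np.ndarray, y_codes: np.ndarray, n_classes: int):
    """Exhaustive Gini split search.

    Returns ``(feature_index, threshold, decrease)`` or ``None`` if no split
    reduces impurity.  Ties break toward the lower feature index, then the
    lower threshold.
    """
    n = y_codes.size
    parent = _gini(np.bincount(y_codes, minlength=n_classes).astype(float))
    best = None
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        ys = y_codes[order]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        left_counts = np.cumsum(onehot, axis=0)  # counts with value <= xs[i]
        total = left_counts[-1]
        # candidate cuts between distinct consecutive values
        distinct = np.flatnonzero(xs[:-1] < xs[1:])
        for i in distinct:
            lc = left_counts[i]
            rc = total - lc
            nl, nr = lc.sum(), rc.sum()
            dec = parent - (nl / n) * _gini(lc) - (nr / n) * _gini(rc)
            thr = (xs[i] + xs[i + 1]) / 2.0
            if best is None or dec > best[2] + 1e-12:
                best = (f, thr, dec)
    if best is None or best[2] <= 1e-12:
        return None
    return best


def _node_p_value(counts: np.ndarray, totals: np.ndarray) -> float:
    """Fisher exact test of class membership in-node vs out-of-node (binary
    classes only; descriptive)."""
    if counts.size != 2:
        return float("nan")
    table = np.array([counts, totals - counts])
    try:
        return float(stats.fisher_exact(table)[1])
    except ValueError:
        return float("nan")


@dataclass
class CartTree:
    root: CartNode
    feature_names: list[str]
    classes: list[str]
    resubstitution_cost: float = float("nan")
    cv_cost: float = float("nan")
    cv_cost_se: float = float("nan")
    fold_costs: list[float] = field(default_factory=list)
    params: CartParams | None = None

    def to_json(self) -> str:
        def node_dict(node: CartNode):
            d = {
                "counts": node.counts,
                "prediction": node.prediction,
                "p_value": node.p_value,
            }
            if not node.is_leaf:
                d.update(
                    feature=node.feature,
                    threshold=node.threshold,
                    left=node_dict(node.left),
                    right=node_dict(node.right),
                )
            return d

        payload = {
            "feature_names": self.feature_names,
            "classes": self.classes,
            "resubstitution_cost": self.resubstitution_cost,
            "cv_cost": self.cv_cost,
            "cv_cost_se": self.cv_cost_se,
            "fold_costs": self.fold_costs,
            "params": asdict(self.params) if self.params else None,
            "root": node_dict(self.root),
        }
        return json.dumps(payload, indent=2, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "CartTree":
        payload = json.loads(text)

        def build(d):
            node = CartNode(
                counts=d["counts"], prediction=d["prediction"], p_value=d["p_value"]
            )
            if "feature" in d:
                node.feature = d["feature"]
                node.threshold = d["threshold"]
                node.left = build(d["left"])
                node.right = build(d["right"])
            return node

        params = CartParams(**payload["params"]) if payload.get("params") else None
        return cls(
            root=build(payload["root"]),
            feature_names=payload["feature_names"],
            classes=payload["classes"],
            resubstitution_cost=payload["resubstitution_cost"],
            cv_cost=payload["cv_cost"],
            cv_cost_se=payload["cv_cost_se"],
            fold_costs=payload.get("fold_costs", []),
            params=params,
        )


def _as_matrix(features, feature_names=None):
    if isinstance(features, pd.DataFrame):
        names = [c for c in features.columns if features[c].dtype.kind in "fiu"]
        if feature_names is not None:
            names = list(feature_names)
        return features[names].to_numpy(dtype=float), names
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


def _grow(X, y_codes, classes, params, total_n, totals, depth=0) -> CartNode:
    counts = np.bincount(y_codes, minlength=len(classes))
    node = CartNode(
        counts=counts.tolist(),
        prediction=classes[int(np.argmax(counts))],
        p_value=_node_p_value(counts.astype(float), totals.astype(float)),
    )
    pure = np.count_nonzero(counts) <= 1
    too_small = y_codes.size < params.min_node_fraction * total_n
    too_deep = params.max_depth is not None and depth >= params.max_depth
    if pure or too_small or too_deep:
        return node
    split = _best_split(X, y_codes, len(classes))
    if split is None:
        return node
    f, thr, _ = split
    mask = X[:, f] <= thr
    node.feature = f  # index for now; renamed by caller
    node.threshold = float(thr)
    node.left = _grow(X[mask], y_codes[mask], classes, params, total_n, totals, depth + 1)
    node.right = _grow(X[~mask], y_codes[~mask], classes, params, total_n, totals, depth + 1)
    return node


def _name_features(node: CartNode, names: list[str]) -> None:
    if not node.is_leaf:
        node.feature = names[node.feature]
        _name_features(node.left, names)
        _name_features(node.right, names)


def _route(node: CartNode, getter) -> str:
    while not node.is_leaf:
        node = node.left if getter(node.feature) <= node.threshold else node.right
    return node.prediction


def fit_cart(features, labels, params: CartParams | None = None, feature_names=None) -> CartTree:
    """Train a CART tree; see module docstring for the algorithm.

    Single-class input yields a degenerate single-leaf tree.  Empty input is
    an error.
    """
    params = params or CartParams()
    X, names = _as_matrix(features, feature_names)
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    if X.shape[0] != y.size:
        raise ValueError("features and labels length mismatch")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing values in features; apply complete-case filtering first")
    classes = sorted(str(c) for c in np.unique(y))
    y_codes = np.array([classes.index(str(v)) for v in y])
    totals = np.bincount(y_codes, minlength=len(classes))

    root = _grow(X, y_codes, classes, params, X.shape[0], totals)
    _name_features(root, names)
    tree = CartTree(root=root, feature_names=names, classes=classes, params=params)

    preds = predict_cart(tree, pd.DataFrame(X, columns=names))
    tree.resubstitution_cost = float(np.mean(preds != np.array([str(v) for v in y])))

    if len(classes) > 1 and X.shape[0] >= params.cv_folds:
        kf = KFold(n_splits=params.cv_folds, shuffle=True, random_state=params.seed)
        errors = 0
        fold_costs = []
        for train_idx, test_idx in kf.split(X):
            sub_params = CartParams(
                min_node_fraction=params.min_node_fraction,
                max_depth=params.max_depth,
                cv_folds=params.cv_folds,
                seed=params.seed,
            )
            sub_classes = sorted(str(c) for c in np.unique(y[train_idx]))
            sub_codes = np.array([sub_classes.index(str(v)) for v in y[train_idx]])
            sub_totals = np.bincount(sub_codes, minlength=len(sub_classes))
            sub_root = _grow(
                X[train_idx], sub_codes, sub_classes, sub_params, train_idx.size, sub_totals
            )
            _name_features(sub_root, names)
            sub_tree = CartTree(root=sub_root, feature_names=names, classes=sub_classes)
            fold_pred = predict_cart(sub_tree, pd.DataFrame(X[test_idx], columns=names))
            fold_err = int(np.sum(fold_pred != np.array([str(v) for v in y[test_idx]])))
            errors += fold_err
            fold_costs.append(fold_err / test_idx.size)
        n = X.shape[0]
        c = errors / n
        tree.cv_cost = float(c)
        tree.cv_cost_se = float(math.sqrt(c * (1.0 - c) / n))
        tree.fold_costs = fold_costs
    return tree


def predict_cart(tree: CartTree, rows) -> np.ndarray:
    """Route rows through the tree; left branch is value <= threshold."""

    def predict_one(getter):
        return _route(tree.root, getter)

    def getter_for(mapping):
        def get(feature):
            if feature not in mapping:
                raise KeyError(f"missing split feature {feature!r}")
            v = mapping[feature]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"missing value for split feature {feature!r}")
            return float(v)

        return get

    if isinstance(rows, pd.DataFrame):
        return np.array([predict_one(getter_for(r)) for r in rows.to_dict("records")])
    if isinstance(rows, (dict, pd.Series)):
        return np.array([predict_one(getter_for(dict(rows)))])
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    frame = pd.DataFrame(X, columns=tree.feature_names)
    return predict_cart(tree, frame)


# ---------------------------------------------------------------------------
# scikit-learn estimator facades
# ---------------------------------------------------------------------------


class CartClassifier(ClassifierMixin, BaseEstimator):
    """CART with Gini splitting, minimum-node-fraction stop and CV cost
    reporting, as an sklearn-compatible classifier.

    Fitted attributes: ``tree_`` (the :class:`CartTree`), ``classes_``,
    ``resubstitution_cost_``, ``cv_cost_``, ``cv_cost_se_``.
    """

    def __init__(self, min_node_fraction=0.05, max_depth=None, cv_folds=10, random_state=None):
        self.min_node_fraction = min_node_fraction
        self.max_depth = max_depth
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y):
        params = CartParams(
            min_node_fraction=self.min_node_fraction,
            max_depth=self.max_depth,
            cv_folds=self.cv_folds,
            seed=self.random_state,
        )
        self.tree_ = fit_cart(X, y, params)
        self.classes_ = np.array(self.tree_.classes)
        self.feature_names_in_ = np.array(self.tree_.feature_names)
        self.n_features_in_ = len(self.tree_.feature_names)
        self.resubstitution_cost_ = self.tree_.resubstitution_cost
        self.cv_cost_ = self.tree_.cv_cost
        self.cv_cost_se_ = self.tree_.cv_cost_se
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        return predict_cart(self.tree_, X)


class _RuleClassifierBase(ClassifierMixin, BaseEstimator):
    """Common plumbing for the fixed published rules: fit is (mostly) a
    no-op, predict applies the rule row-wise to a feature DataFrame."""

    def fit(self, X, y=None):
        self.classes_ = np.array([ASTROGLIOSIS, TUMOR])
        return self

    def _rows(self, X):
        if isinstance(X, pd.DataFrame):
            return X.to_dict("records")
        if isinstance(X, (dict, pd.Series)):
            return [dict(X)]
        raise TypeError("rule classifiers require a DataFrame or mapping of named features")


class ThresholdClassifier(_RuleClassifierBase):
    """Single-feature cutoff classifier.

    With ``cutoff=None`` the cutoff is estimated on ``fit`` as the
    Youden-optimal operating point of the feature's ROC curve; otherwise
    ``fit`` is a no-op and the published cutoff is applied as given.
    """

    def __init__(self, feature="tbr_brain_60", cutoff=1.6, inclusive=False):
        self.feature = feature
        self.cutoff = cutoff
        self.inclusive = inclusive

    def fit(self, X, y=None):
        super().fit(X, y)
        if self.cutoff is None:
            if y is None:
                raise ValueError("labels required to estimate a cutoff")
            from .diagnostics import roc_analysis

            scores = X[self.feature] if isinstance(X, pd.DataFrame) else np.asarray(X, float)
            roc = roc_analysis(np.asarray(scores, float), y, positive_label=TUMOR)
            self.cutoff_ = float(roc.youden_cutoff)
        else:
            self.cutoff_ = float(self.cutoff)
        return self

    def predict(self, X):
        check_is_fitted(self, "cutoff_")
        rule = ThresholdRule(self.feature, self.cutoff_, self.inclusive)
        return np.array([apply_threshold_rule(r, rule) for r in self._rows(X)])


class DualPlexusClassifier(_RuleClassifierBase):
    """Disjunctive dual-acquisition plexus rule (>1.0 early OR >1.2 late)."""

    def __init__(self, early_cutoff=1.0, late_cutoff=1.2):
        self.early_cutoff = early_cutoff
        self.late_cutoff = late_cutoff

    def predict(self, X):
        return np.array(
            [dual_plexus_rule(r, self.early_cutoff, self.late_cutoff) for r in self._rows(X)]
        )


class PublishedTreeClassifier(_RuleClassifierBase):
    """The published two-feature tree on ``tbr_plexus_60`` and ``module``."""

    def predict(self, X):
        return np.array(
            [published_tree_classify(r["tbr_plexus_60"], r["module"]) for r in self._rows(X)]
        )


class ThalamusRuleClassifier(_RuleClassifierBase):
    """Pathological-vs-normal thalamus uptake rule."""

    def __init__(self, mode="absolute", timepoint=60, feature=None):
        self.mode = mode
        self.timepoint = timepoint
        self.feature = feature

    def fit(self, X, y=None):
        self.classes_ = np.array(["normal", "pathological"])
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame) and self.feature is not None:
            values = X[self.feature].to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float).ravel()
        return np.array([thalamus_rule(v, self.timepoint, self.mode) for v in values])
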