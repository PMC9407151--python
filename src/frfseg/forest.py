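"""Fast-random-forest pixel classifier and its performance indicators.

An ensemble of CART-style decision trees is trained on the feature vectors
of sparsely annotated pixels of the *same* image it will classify (no
held-out image exists by design: the annotator circles a few clusters per
class and the forest propagates those classes to every pixel).  Each tree
grows on a bootstrap resample of the labeled pixels; at every node a random
subset of features is drawn and the Gini-optimal axis-aligned split is
chosen, growing to purity.  Per-pixel class probabilities are the average
of the leaf class-frequency vectors over trees, which makes the ensemble
map exactly the arithmetic mean of its single-tree maps.

Ties are always broken toward the lowest index (feature, threshold, class)
so that a fixed seed reproduces the model bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import ConfigurationError, EvaluationError, TrainingError
from .features import FeatureStack
from .io import LabelSet

_SEED_CAP = 2**31


@dataclass
class DecisionTree:
    """Flat-array CART tree: feature[i] == -1 marks node i as a leaf."""

    feature: np.ndarray       # (n_nodes,) int, -1 for leaves
    threshold: np.ndarray     # (n_nodes,) float; x[f] <= thr goes left
    left: np.ndarray          # (n_nodes,) int child index
    right: np.ndarray         # (n_nodes,) int child index
    value: np.ndarray         # (n_nodes, n_classes) class frequencies

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index reached by each row of X (vectorized traversal)."""
        node = np.zeros(len(X), dtype=np.intp)
        while True:
            feat = self.feature[node]
            active = np.nonzero(feat >= 0)[0]
            if not len(active):
                return node
            cur = node[active]
            go_left = X[active, feat[active]] <= self.threshold[cur]
            node[active] = np.where(go_left, self.left[cur], self.right[cur])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.apply(X)]


@dataclass
class ProbabilityMap:
    """Per-class probability planes (n_classes, H, W); planes sum to 1 per pixel."""

    planes: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 3 or self.planes.shape[0] != len(self.class_names):
            raise ConfigurationError("probability map must be (n_classes, H, W)")
        total = self.planes.sum(axis=0)
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ConfigurationError("per-pixel class probabilities must sum to 1")

    def plane(self, class_name: str) -> np.ndarray:
        try:
            return self.planes[self.class_names.index(class_name)]
        except ValueError:
            raise ConfigurationError(f"unknown class {class_name!r}") from None

    def at(self, coords: np.ndarray) -> np.ndarray:
        """(n, n_classes) probabilities at (row, col) coordinates."""
        coords = np.asarray(coords, dtype=np.intp).reshape(-1, 2)
        return self.planes[:, coords[:, 0], coords[:, 1]].T


@dataclass
class PerformanceCurve:
    """Precision/recall versus training-instance count, plus optional ROC."""

    instances: list[int] = field(default_factory=list)
    precision: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    per_class: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    unseen_classes: list[list[str]] = field(default_factory=list)
    roc_points: np.ndarray | None = None   # (n, 2) columns (fpr, tpr)
    auc: float | None = None

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        if self.roc_points is not None:
            df = pd.DataFrame(self.roc_points, columns=["fpr", "tpr"])
            df["auc"] = self.auc
        else:
            df = pd.DataFrame(
                {"instances": self.instances, "precision": self.precision, "recall": self.recall}
            )
            for name, vals in self.per_class.items():
                df[f"precision_{name}"] = vals["precision"]
                df[f"recall_{name}"] = vals["recall"]
        df.to_csv(path, index=False)


@dataclass
class FRFModel:
    """Trained forest: trees + hyperparameters + the seeds that grew them."""

    trees: list[DecisionTree]
    n_trees: int
    features_per_split: int
    seed: int
    tree_seeds: list[int]
    class_names: list[str]
    n_features: int

    def predict_proba_samples(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) ensemble-averaged class probabilities."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features:
            raise ConfigurationError(
                f"stack has {X.shape[1]} features, model expects {self.n_features}"
            )
        out = np.zeros((len(X), len(self.class_names)))
        for tree in self.trees:
            out += tree.predict_proba(X)
        return out / len(self.trees)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_trees": self.n_trees,
            "features_per_split": self.features_per_split,
            "seed": self.seed,
            "tree_seeds": self.tree_seeds,
            "class_names": self.class_names,
            "n_features": self.n_features,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                }
                for t in self.trees
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FRFModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        data = json.loads(text)
        trees = [
            DecisionTree(
                feature=np.asarray(t["feature"], dtype=np.intp),
                threshold=np.asarray(t["threshold"], dtype=np.float64),
                left=np.asarray(t["left"], dtype=np.intp),
                right=np.asarray(t["right"], dtype=np.intp),
                value=np.asarray(t["value"], dtype=np.float64),
            )
            for t in data["trees"]
        ]
        return cls(
            trees=trees,
            n_trees=data["n_trees"],
            features_per_split=data["features_per_split"],
            seed=data["seed"],
            tree_seeds=list(data["tree_seeds"]),
            class_names=list(data["class_names"]),
            n_features=data["n_features"],
        )


def _split_score(values: np.ndarray, y: np.ndarray, n_classes: int) -> tuple[float, float] | None:
    """Best threshold for one feature by Gini impurity decrease.

    Returns (score, threshold) where score = sum over children of
    (sum_k count_k^2) / n_child — maximizing it minimizes the weighted
    Gini impurity.  Threshold ties resolve to the lowest threshold.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    if v[0] == v[-1]:
        return None
    onehot = np.zeros((len(v), n_classes))
    onehot[np.arange(len(v)), y[order]] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    n_left = np.arange(1, len(v), dtype=np.float64)
    left = cum[:-1]
    right = total[None, :] - left
    score = (left**2).sum(axis=1) / n_left + (right**2).sum(axis=1) / (len(v) - n_left)
    score[v[:-1] == v[1:]] = -np.inf  # cannot split between equal values
    best = int(np.argmax(score))      # first max -> lowest threshold
    return float(score[best]), float((v[best] + v[best + 1]) / 2.0)


def _grow_tree(
    X: np.ndarray, y: np.ndarray, n_classes: int, features_per_split: int, rng: np.random.Generator
) -> DecisionTree:
    """Grow one CART tree to purity on a bootstrap resample of (X, y)."""
    n, n_features = X.shape
    boot = rng.integers(0, n, size=n)
    Xb, yb = X[boot], y[boot]

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[np.ndarray] = []

    def _leaf_value(idx: np.ndarray) -> np.ndarray:
        counts = np.bincount(yb[idx], minlength=n_classes).astype(np.float64)
        return counts / counts.sum()

    # LIFO stack of (sample indices, slot to patch with this node's id)
    stack: list[tuple[np.ndarray, int | None, bool]] = [(np.arange(n), None, False)]
    while stack:
        idx, parent, is_right = stack.pop()
        node_id = len(feature)
        if parent is not None:
            (right if is_right else left)[parent] = node_id

        classes_here = np.unique(yb[idx])
        best: tuple[float, int, float] | None = None
        if len(classes_here) > 1:
            m = min(features_per_split, n_features)
            candidates = np.sort(rng.choice(n_features, size=m, replace=False))
            for f in candidates:  # ascending -> strict '>' keeps lowest index on ties
                res = _split_score(Xb[idx, f], yb[idx], n_classes)
                if res is not None and (best is None or res[0] > best[0]):
                    best = (res[0], int(f), res[1])

        if best is None:
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            value.append(_leaf_value(idx))
            continue

        _, f, thr = best
        go_left = Xb[idx, f] <= thr
        feature.append(f)
        threshold.append(thr)
        left.append(-1)
        right.append(-1)
        value.append(_leaf_value(idx))
        stack.append((idx[~go_left], node_id, True))
        stack.append((idx[go_left], node_id, False))

    return DecisionTree(
        feature=np.asarray(feature, dtype=np.intp),
        threshold=np.asarray(threshold, dtype=np.float64),
        left=np.asarray(left, dtype=np.intp),
        right=np.asarray(right, dtype=np.intp),
        value=np.asarray(value, dtype=np.float64),
    )


def _derive_tree_seeds(seed: int, n_trees: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, _SEED_CAP, size=n_trees)]


def _fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    class_names: list[str],
    n_trees: int,
    features_per_split: int | None,
    seed: int,
    tree_seeds: list[int] | None = None,
) -> FRFModel:
    n_features = X.shape[1]
    m = features_per_split or max(1, int(np.floor(np.sqrt(n_features))))
    if tree_seeds is None:
        tree_seeds = _derive_tree_seeds(seed, n_trees)
    trees = [
        _grow_tree(X, y, len(class_names), m, np.random.default_rng(ts)) for ts in tree_seeds
    ]
    return FRFModel(
        trees=trees,
        n_trees=len(trees),
        features_per_split=m,
        seed=seed,
        tree_seeds=tree_seeds,
        class_names=list(class_names),
        n_features=n_features,
    )


def train(
    stack: FeatureStack,
    labels: LabelSet,
    n_trees: int = 200,
    features_per_split: int | None = None,
    seed: int = 0,
    tree_seeds: list[int] | None = None,
) -> FRFModel:
    """Train the forest on the labeled pixels of ``stack``.

    ``features_per_split`` defaults to floor(sqrt(n_features)).  The master
    ``seed`` derives one sub-seed per tree; passing ``tree_seeds``
    explicitly reproduces any single tree of a larger ensemble.
    """
    if len(labels.classes) < 2:
        raise TrainingError("training requires at least 2 annotated classes")
    for name, count in labels.class_counts().items():
        if count == 0:
            raise TrainingError(f"class {name!r} has no labeled pixels")
    labels.validate_bounds(stack.source_dims)
    coords, y = labels.stacked()
    X = stack.sample(coords).astype(np.float64)
    return _fit_forest(X, y, labels.classes, n_trees, features_per_split, seed, tree_seeds)


def predict(model: FRFModel, stack: FeatureStack) -> tuple[np.ndarray, ProbabilityMap]:
    """Classify every pixel; returns (class-index map, probability map).

    Argmax ties resolve to the lowest class index.
    """
    h, w = stack.source_dims
    proba = model.predict_proba_samples(stack.flat())
    planes = proba.T.reshape(len(model.class_names), h, w)
    class_map = np.argmax(proba, axis=1).reshape(h, w)
    return class_map, ProbabilityMap(planes=planes, class_names=model.class_names)


def _precision_recall(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Micro and per-class precision/recall; absent denominators give 0."""
    tp = np.zeros(n_classes)
    fp = np.zeros(n_classes)
    fn = np.zeros(n_classes)
    for k in range(n_classes):
        tp[k] = np.sum((y_pred == k) & (y_true == k))
        fp[k] = np.sum((y_pred == k) & (y_true != k))
        fn[k] = np.sum((y_pred != k) & (y_true == k))
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec_c = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    micro_p = tp.sum() / max(tp.sum() + fp.sum(), 1)
    micro_r = tp.sum() / max(tp.sum() + fn.sum(), 1)
    return float(micro_p), float(micro_r), prec_c, rec_c


def evaluate(model: FRFModel, stack: FeatureStack, labels: LabelSet) -> dict:
    """Training-set performance on the annotated pixels (same-image protocol)."""
    coords, y = labels.stacked()
    proba = model.predict_proba_samples(stack.sample(coords).astype(np.float64))
    y_pred = np.argmax(proba, axis=1)
    micro_p, micro_r, prec_c, rec_c = _precision_recall(y, y_pred, len(labels.classes))
    return {
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "per_class": {
            name: {"precision": float(prec_c[k]), "recall": float(rec_c[k])}
            for k, name in enumerate(labels.classes)
        },
    }


def learning_curve(
    stack: FeatureStack,
    labels: LabelSet,
    schedule: list[int],
    n_trees: int = 200,
    features_per_split: int | None = None,
    seed: int = 0,
) -> PerformanceCurve:
    """Training-set precision/recall as annotated instances accumulate.

    The labeled samples are put in a seeded random order; for each count n
    in ``schedule`` the forest is trained on the first n samples of that
    order (restored to canonical order, so n = total reproduces ``train``
    exactly) and evaluated on those same n samples, mirroring the
    same-image train/test protocol.  A class absent from the first n
    samples is flagged and its precision/recall reported as 0.
    """
    if not schedule:
        raise ConfigurationError("schedule must be non-empty")
    schedule = sorted(int(n) for n in schedule)
    coords, y = labels.stacked()
    if schedule[-1] > len(y):
        raise ConfigurationError("schedule exceeds the number of labeled pixels")
    if schedule[0] < 1:
        raise ConfigurationError("instance counts must be positive")
    X = stack.sample(coords).astype(np.float64)
    order = np.random.default_rng(seed).permutation(len(y))

    curve = PerformanceCurve(
        per_class={name: {"precision": [], "recall": []} for name in labels.classes}
    )
    for n in schedule:
        subset = np.sort(order[:n])
        Xn, yn = X[subset], y[subset]
        seen = np.unique(yn)
        model = _fit_forest(
            Xn, yn, labels.classes, n_trees, features_per_split, seed
        )
        y_pred = np.argmax(model.predict_proba_samples(Xn), axis=1)
        micro_p, micro_r, prec_c, rec_c = _precision_recall(yn, y_pred, len(labels.classes))
        curve.instances.append(n)
        curve.precision.append(micro_p)
        curve.recall.append(micro_r)
        for k, name in enumerate(labels.classes):
            curve.per_class[name]["precision"].append(float(prec_c[k]))
            curve.per_class[name]["recall"].append(float(rec_c[k]))
        curve.unseen_classes.append(
            [name for k, name in enumerate(labels.classes) if k not in seen]
        )
    return curve


def roc(prob: ProbabilityMap, truth: LabelSet, positive_class: str) -> PerformanceCurve:
    """ROC of one class's probability plane against annotated truth.

    Thresholds sweep the unique probability values at the annotated pixels;
    AUC is the trapezoid-rule area.  A perfect separation yields the ideal
    classifier curve through (0, 1) with AUC 1.
    """
    if positive_class not in truth.classes:
        raise EvaluationError(f"unknown positive class {positive_class!r}")
    coords, y = truth.stacked()
    if len(y) == 0:
        raise EvaluationError("truth set is empty")
    pos_idx = truth.classes.index(positive_class)
    y_bin = (y == pos_idx).astype(int)
    if y_bin.all() or not y_bin.any():
        raise EvaluationError("truth must contain positive and negative pixels")
    scores = prob.at(coords)[:, pos_idx]
    fpr, tpr, _ = _roc_curve(y_bin, scores, drop_intermediate=False)
    return PerformanceCurve(
        roc_points=np.column_stack([fpr, tpr]), auc=float(_trapezoid_auc(fpr, tpr))
    )
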