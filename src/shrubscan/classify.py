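"""Fuzzy tree-based classification of shrub-layer points.

Reference labels are attached to shrub-layer points by gathering returns
within each surveyed object's size-specific radius; a pruned CART then
learns the taxa from the structural features. The tree is grown by greedy
binary Gini splits and pruned with the classical complexity-parameter rule:
a split (with its subtree) is retained only if it improves the overall
misclassification risk by more than ``cp`` times the root risk. Leaves carry
class-proportion probability vectors, so predictions are fuzzy memberships
rather than hard labels; the hard label is the argmax (ties resolved to the
class earlier in schema order).

Accuracy is assessed over repeated stratified train/validation splits
(default 100 iterations of a 90/10 split) with overall accuracy, Cohen's
kappa and per-class precision/recall/F1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pointcloud import PointCloud, ReferenceRecord

__all__ = [
    "LabeledFeatureSet", "FuzzyTreeModel", "AccuracyReport",
    "ValidationSummary", "assemble_reference", "stratified_split",
    "train_tree", "predict_fuzzy", "evaluate", "repeated_validation",
    "confusion_matrix", "drop_singleton_classes",
]


@dataclass
class LabeledFeatureSet:
    """Feature rows with class labels against an ordered class schema."""

    features: np.ndarray  # (n, p)
    labels: np.ndarray  # (n,) int indices into schema
    schema: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[0] != self.labels.size:
            raise ValueError("features must be (n, p) with n matching labels")
        if self.labels.size == 0:
            raise ValueError("labelled set is empty")
        if np.any(self.labels < 0) or np.any(self.labels >= len(self.schema)):
            raise ValueError("label outside the class schema")

    def __len__(self) -> int:
        return int(self.labels.size)

    def subset(self, idx: np.ndarray) -> "LabeledFeatureSet":
        return LabeledFeatureSet(self.features[idx], self.labels[idx],
                                 self.schema, self.feature_names)


def assemble_reference(cloud: PointCloud, features: pd.DataFrame,
                       refs: list[ReferenceRecord], schema: tuple[str, ...],
                       feature_names: tuple[str, ...] | None = None,
                       ) -> LabeledFeatureSet:
    """Label shrub-layer feature rows from the surveyed reference objects.

    Every shrub-layer point within a vertical cylinder of ``object_radius``
    around a record's (x, y) takes that record's class; a point claimed by
    several records goes to the planar-nearest one. Records that gather no
    points (e.g. a shrub browsed away between survey and flight) are
    skipped with a warning.
    """
    from .features import FEATURE_NAMES
    if feature_names is None:
        feature_names = FEATURE_NAMES
    px = features["x"].to_numpy()
    py = features["y"].to_numpy()
    best_d2 = np.full(px.size, np.inf)
    best_label = np.full(px.size, -1, dtype=np.int64)
    for rec in refs:
        d2 = (px - rec.x) ** 2 + (py - rec.y) ** 2
        inside = d2 <= rec.object_radius ** 2 + 1e-12
        if not inside.any():
            warnings.warn(
                f"reference {rec.ref_id} ({schema[rec.class_id]}) gathered "
                "no shrub-layer points; record skipped", stacklevel=2)
            continue
        take = inside & (d2 < best_d2)
        best_d2[take] = d2[take]
        best_label[take] = rec.class_id
    keep = best_label >= 0
    if not keep.any():
        raise ValueError("no reference record gathered any shrub-layer points")
    X = features.loc[keep, list(feature_names)].to_numpy(dtype=np.float64)
    return LabeledFeatureSet(X, best_label[keep], schema, tuple(feature_names))


def drop_singleton_classes(data: LabeledFeatureSet) -> LabeledFeatureSet:
    """Remove rows of classes with a single labelled point.

    A one-point class cannot be stratified into train and test; dropping
    it (with a warning) mirrors field practice, where a class observed
    once cannot be validated. The schema is kept intact so class indices
    and probability columns stay stable."""
    classes, counts = np.unique(data.labels, return_counts=True)
    single = classes[counts < 2]
    if single.size == 0:
        return data
    for cls in single:
        warnings.warn(f"class {data.schema[cls]!r} has a single labelled "
                      "point and is dropped from validation", stacklevel=2)
    keep = ~np.isin(data.labels, single)
    return data.subset(np.flatnonzero(keep))


def stratified_split(data: LabeledFeatureSet, train_frac: float, seed: int,
                     ) -> tuple[LabeledFeatureSet, LabeledFeatureSet]:
    """Per-class random split: floor(n * train_frac) rows to train, with at
    least one row on each side when a class has n >= 2. ``train_frac=1.0``
    sends everything to train (the final full-data model used to print the
    classification into the full cloud) and returns the training set itself
    as the resubstitution test set. A class with a single row cannot be
    stratified and is an error."""
    if not (0 < train_frac <= 1):
        raise ValueError("train_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(data.labels):
        rows = np.flatnonzero(data.labels == cls)
        if train_frac < 1.0 and rows.size < 2:
            raise ValueError(
                f"class {data.schema[cls]!r} has a single row and cannot be "
                "stratified into train and test")
        perm = rng.permutation(rows)
        if train_frac == 1.0:
            n_train = rows.size
        else:
            n_train = int(np.floor(rows.size * train_frac))
            n_train = min(max(n_train, 1), rows.size - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = data.subset(np.concatenate(train_idx))
    if train_frac == 1.0:
        return train, train
    return train, data.subset(np.concatenate(test_idx))


# ---------------------------------------------------------------------------
# CART


@dataclass
class _Node:
    counts: np.ndarray  # per-class training counts at this node
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int,
                w: np.ndarray) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gini gain) over all axis-aligned splits.

    Features are scanned in column order and candidate thresholds in
    ascending order, and strictly better gain is required to displace the
    incumbent — so equal-gain ties resolve to the earlier feature, then the
    smaller threshold. Split rule: left = (x <= threshold), thresholds are
    midpoints between consecutive distinct values.
    """
    n = y.size
    root_counts = np.zeros(n_classes)
    np.add.at(root_counts, y, w[y])
    parent = _gini(root_counts) * root_counts.sum()
    best = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = w[ys]
        left_counts = np.cumsum(onehot, axis=0)  # counts after first i+1 rows
        total = left_counts[-1]
        # candidate cut after row i where the value changes
        cut = np.flatnonzero(xs[:-1] < xs[1:])
        if cut.size == 0:
            continue
        lc = left_counts[cut]
        rc = total - lc
        nl = lc.sum(axis=1)
        nr = rc.sum(axis=1)
        gl = 1.0 - np.sum((lc / nl[:, None]) ** 2, axis=1)
        gr = 1.0 - np.sum((rc / nr[:, None]) ** 2, axis=1)
        gains = parent - (nl * gl + nr * gr)
        k = int(np.argmax(gains))  # first max -> smaller threshold
        gain = float(gains[k])
        if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
            thr = float((xs[cut[k]] + xs[cut[k] + 1]) / 2.0)
            best = (j, thr, gain)
    return best


def _grow(X: np.ndarray, y: np.ndarray, n_classes: int, depth: int,
          max_depth: int, w: np.ndarray) -> _Node:
    counts = np.zeros(n_classes)
    np.add.at(counts, y, w[y])
    node = _Node(counts=counts)
    if depth >= max_depth or np.count_nonzero(counts) < 2:
        return node
    found = _best_split(X, y, n_classes, w)
    if found is None:
        return node
    j, thr, _ = found
    mask = X[:, j] <= thr
    node.feature, node.threshold = j, thr
    node.left = _grow(X[mask], y[mask], n_classes, depth + 1, max_depth, w)
    node.right = _grow(X[~mask], y[~mask], n_classes, depth + 1,
                       max_depth, w)
    return node


def _prune(node: _Node, cp_times_root_risk: float) -> float:
    """Bottom-up complexity pruning; returns the subtree's
    misclassification count after pruning. A node keeps its split only if
    the subtree's risk undercuts the node-as-leaf risk by strictly more
    than cp x root risk."""
    leaf_risk = float(node.counts.sum() - node.counts.max())
    if node.is_leaf:
        return leaf_risk
    subtree_risk = (_prune(node.left, cp_times_root_risk)
                    + _prune(node.right, cp_times_root_risk))
    if leaf_risk - subtree_risk > cp_times_root_risk + 1e-12:
        return subtree_risk
    node.feature = node.threshold = node.left = node.right = None
    return leaf_risk


@dataclass
class FuzzyTreeModel:
    """Pruned binary decision tree with class-proportion leaves.

    ``predict_proba`` routes each row to its leaf and returns the leaf's
    training class proportions; ``predict`` takes the argmax with ties
    resolved to the class earlier in schema order (numpy argmax).
    """

    root: _Node
    schema: tuple[str, ...]
    feature_names: tuple[str, ...]
    cp: float

    @property
    def n_leaves(self) -> int:
        def count(n: _Node) -> int:
            return 1 if n.is_leaf else count(n.left) + count(n.right)
        return count(self.root)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.empty((X.shape[0], len(self.schema)))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold \
                    else node.right
            out[i] = node.probs
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def enc(n: _Node) -> dict:
            d: dict = {"counts": n.counts.tolist()}
            if not n.is_leaf:
                d.update(feature=n.feature, threshold=n.threshold,
                         left=enc(n.left), right=enc(n.right))
            return d
        return json.dumps({
            "schema": list(self.schema),
            "feature_names": list(self.feature_names),
            "cp": self.cp,
            "tree": enc(self.root),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FuzzyTreeModel":
        obj = json.loads(text)

        def dec(d: dict) -> _Node:
            node = _Node(counts=np.asarray(d["counts"], dtype=np.float64))
            if "feature" in d:
                node.feature = int(d["feature"])
                node.threshold = float(d["threshold"])
                node.left = dec(d["left"])
                node.right = dec(d["right"])
            return node
        return cls(root=dec(obj["tree"]), schema=tuple(obj["schema"]),
                   feature_names=tuple(obj["feature_names"]),
                   cp=float(obj["cp"]))


def train_tree(train: LabeledFeatureSet, cp: float = 0.001,
               max_depth: int = 25,
               class_weight: np.ndarray | None = None) -> FuzzyTreeModel:
    """Grow a Gini CART on the training rows and prune it with the
    complexity-parameter rule (strict improvement > cp x root risk).

    ``class_weight`` (one value per schema class) rescales each class's
    contribution to the split criterion, the pruning risk and the leaf
    proportions; the default leaves imbalance as-is, matching the
    reference protocol."""
    if np.unique(train.labels).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    if class_weight is None:
        w = np.ones(len(train.schema))
    else:
        w = np.asarray(class_weight, dtype=np.float64)
        if w.shape != (len(train.schema),) or np.any(w <= 0):
            raise ValueError("class_weight needs one positive value per "
                             "schema class")
    root = _grow(train.features, train.labels, len(train.schema), 0,
                 max_depth, w)
    root_risk = float(root.counts.sum() - root.counts.max())
    _prune(root, cp * root_risk)
    return FuzzyTreeModel(root=root, schema=train.schema,
                          feature_names=train.feature_names, cp=cp)


def predict_fuzzy(model: FuzzyTreeModel, X: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy memberships and hard labels for the rows of ``X``."""
    probs = model.predict_proba(X)
    return probs, np.argmax(probs, axis=1)


# ---------------------------------------------------------------------------
# accuracy assessment


def confusion_matrix(pred: np.ndarray, true: np.ndarray,
                     n_classes: int) -> np.ndarray:
    """Counts with reference classes as rows and predictions as columns."""
    pred = np.asarray(pred, dtype=np.int64)
    true = np.asarray(true, dtype=np.int64)
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (true, pred), 1)
    return m


@dataclass
class AccuracyReport:
    """Confusion matrix plus overall and per-class agreement measures."""

    matrix: np.ndarray
    overall_accuracy: float
    kappa: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    def to_frame(self, schema: tuple[str, ...]) -> pd.DataFrame:
        return pd.DataFrame({"precision": self.precision,
                             "recall": self.recall, "f1": self.f1},
                            index=list(schema))


def evaluate(pred: np.ndarray, true: np.ndarray,
             n_classes: int) -> AccuracyReport:
    """Overall accuracy, Cohen's kappa and per-class precision/recall/F1.

    kappa = (po - pe) / (1 - pe) with chance agreement
    pe = sum_i row_i * col_i / total^2. Per-class measures are nan when
    their denominator is zero (class absent from reference or prediction).
    """
    m = confusion_matrix(pred, true, n_classes)
    total = m.sum()
    if total == 0:
        raise ValueError("cannot evaluate an empty validation set")
    po = np.trace(m) / total
    pe = float(np.sum(m.sum(axis=1) * m.sum(axis=0))) / total ** 2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    tp = np.diag(m).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(m.sum(axis=0) > 0, tp / m.sum(axis=0), np.nan)
        recall = np.where(m.sum(axis=1) > 0, tp / m.sum(axis=1), np.nan)
        f1 = np.where((precision + recall) > 0,
                      2 * precision * recall / (precision + recall), np.nan)
    return AccuracyReport(matrix=m, overall_accuracy=float(po),
                          kappa=float(kappa), precision=precision,
                          recall=recall, f1=f1)


@dataclass
class ValidationSummary:
    """Mean and standard deviation over repeated stratified splits."""

    n_iter: int
    oa_mean: float
    oa_sd: float
    kappa_mean: float
    kappa_sd: float
    f1_mean: np.ndarray  # per class
    f1_sd: np.ndarray
    reports: list[AccuracyReport] = field(repr=False, default_factory=list)


def repeated_validation(data: LabeledFeatureSet, train_frac: float = 0.9,
                        n_iter: int = 100, base_seed: int = 0,
                        cp: float = 0.001) -> ValidationSummary:
    """Train and evaluate over ``n_iter`` independent stratified splits
    (seeds ``base_seed .. base_seed + n_iter - 1``)."""
    oas, kappas, f1s, reports = [], [], [], []
    for it in range(n_iter):
        train, test = stratified_split(data, train_frac, base_seed + it)
        model = train_tree(train, cp=cp)
        rep = evaluate(model.predict(test.features), test.labels,
                       len(data.schema))
        oas.append(rep.overall_accuracy)
        kappas.append(rep.kappa)
        f1s.append(rep.f1)
        reports.append(rep)
    f1_arr = np.asarray(f1s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan classes
        f1_mean = np.nanmean(f1_arr, axis=0)
        f1_sd = np.nanstd(f1_arr, axis=0)
    return ValidationSummary(
        n_iter=n_iter,
        oa_mean=float(np.mean(oas)), oa_sd=float(np.std(oas)),
        kappa_mean=float(np.mean(kappas)), kappa_sd=float(np.std(kappas)),
        f1_mean=f1_mean, f1_sd=f1_sd, reports=reports)
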