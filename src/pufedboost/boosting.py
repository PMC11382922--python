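"""Centralized histogram-based gradient-boosted trees (second-order logistic objective).

This is the computation that the federated protocol distributes, and the oracle
the federated trainer must reproduce bit-for-bit: quantile binning computed once
per training set, per-node (G, H, count) histograms, exhaustive left-scan split
search with the regularized second-order gain

    gain = 1/2 [ G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda) - (G_L+G_R)^2/(H_L+H_R+lambda) ] - gamma

and leaf weight w = -G/(H+lambda). Trees grow breadth-first to a fixed depth.
Ties in the split search break lexicographically by (feature index, bin index),
which is what makes federated and centralized training identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import DataError, ParameterError, WorkingLabels

MARGIN_CLIP = 36.0  # sigmoid saturates around exp(+-36); keeps h strictly positive


@dataclass(frozen=True)
class BoostConfig:
    n_trees: int = 30
    max_depth: int = 3
    learning_rate: float = 0.3
    reg_lambda: float = 1.0
    gamma: float = 0.0
    n_bins: int = 32
    min_child_samples: int = 1
    base_margin: float = 0.0

    def validate(self) -> None:
        if self.n_trees < 0:
            raise ParameterError("n_trees must be >= 0")
        if self.max_depth < 1:
            raise ParameterError("max_depth must be >= 1")
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if self.reg_lambda < 0 or self.gamma < 0:
            raise ParameterError("regularization terms must be >= 0")
        if self.min_child_samples < 1:
            raise ParameterError("min_child_samples must be >= 1")


# ---------------------------------------------------------------------------
# Binning


def quantile_bin(
    values: np.ndarray, n_bins: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-feature quantile bin edges and integer bin codes.

    Edges sit at the empirical i/n_bins quantiles (deduplicated). When a feature
    has at most ``n_bins`` distinct values, the edges are the distinct values
    themselves (minus the smallest), so binning is lossless. The bin code of a
    value is the count of edges <= value; a constant feature yields one bin.
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    if values.size and not np.isfinite(values).all():
        raise DataError("binning requires finite feature values (missing not supported)")
    edges_per_feature: list[np.ndarray] = []
    codes = np.empty(values.shape, dtype=np.int32)
    for k in range(values.shape[1]):
        col = values[:, k]
        uniq = np.unique(col)
        if uniq.size <= n_bins:
            edges = uniq[1:]
        else:
            qs = np.quantile(col, np.arange(1, n_bins) / n_bins)
            edges = np.unique(qs)
        edges_per_feature.append(edges)
        codes[:, k] = np.searchsorted(edges, col, side="right")
    return edges_per_feature, codes


def bin_transform(edges_per_feature: Sequence[np.ndarray], values: np.ndarray) -> np.ndarray:
    """Apply fitted edges to new values (code = count of edges <= value)."""
    values = np.asarray(values, dtype=np.float64)
    codes = np.empty(values.shape, dtype=np.int32)
    for k, edges in enumerate(edges_per_feature):
        codes[:, k] = np.searchsorted(edges, values[:, k], side="right")
    return codes


# ---------------------------------------------------------------------------
# Gradients


@dataclass
class GradientPair:
    g: np.ndarray
    h: np.ndarray


def compute_gradients(working_labels: WorkingLabels | np.ndarray, margins: np.ndarray) -> GradientPair:
    """Logistic-loss derivatives w.r.t. the previous-round margin.

    p = sigmoid(margin), g = p - y~, h = p(1-p). Margins are clipped to +-36 so
    h stays strictly positive.
    """
    y = working_labels.y_tilde if isinstance(working_labels, WorkingLabels) else np.asarray(working_labels)
    margins = np.asarray(margins, dtype=np.float64)
    if y.shape != margins.shape:
        raise DataError("labels and margins must be aligned")
    m = np.clip(margins, -MARGIN_CLIP, MARGIN_CLIP)
    p = 1.0 / (1.0 + np.exp(-m))
    return GradientPair(g=p - y, h=p * (1.0 - p))


# ---------------------------------------------------------------------------
# Histograms


@dataclass
class Histogram:
    """Per-feature, per-bin (sum g, sum h, count) over one node's sample set."""

    G: list[np.ndarray]
    H: list[np.ndarray]
    count: list[np.ndarray]

    def __add__(self, other: "Histogram") -> "Histogram":
        return Histogram(
            G=[a + b for a, b in zip(self.G, other.G)],
            H=[a + b for a, b in zip(self.H, other.H)],
            count=[a + b for a, b in zip(self.count, other.count)],
        )


def build_histogram(
    codes: np.ndarray,
    grads: GradientPair,
    node_samples: np.ndarray,
    n_bins_per_feature: Sequence[int],
) -> Histogram:
    """Exact per-bin gradient sums for one node (additive over disjoint nodes)."""
    idx = np.asarray(node_samples, dtype=np.intp)
    sub = codes[idx]
    g, h = grads.g[idx], grads.h[idx]
    G, H, C = [], [], []
    for k, nb in enumerate(n_bins_per_feature):
        c = sub[:, k]
        G.append(np.bincount(c, weights=g, minlength=nb))
        H.append(np.bincount(c, weights=h, minlength=nb))
        C.append(np.bincount(c, minlength=nb).astype(np.int64))
    return Histogram(G=G, H=H, count=C)


# ---------------------------------------------------------------------------
# Split search


@dataclass(frozen=True)
class SplitCandidate:
    feature: int  # global feature index
    bin: int  # last bin index going left
    gain: float
    g_left: float
    h_left: float
    n_left: int


def _leaf_objective(G: float, H: float, lam: float) -> float:
    return G * G / (H + lam)


def find_best_split(
    hist: Histogram,
    parent_g: float,
    parent_h: float,
    parent_count: int,
    config: BoostConfig,
) -> SplitCandidate | None:
    """Scan all (feature, boundary) candidates; return the gain maximizer.

    The left child takes bin codes <= q. Ties break toward the lowest
    (feature, bin) pair because only strictly larger gains replace the
    incumbent. Returns None when no candidate has positive gain or every
    candidate violates min_child_samples.
    """
    lam, gam = config.reg_lambda, config.gamma
    parent_obj = _leaf_objective(parent_g, parent_h, lam)
    best: SplitCandidate | None = None
    for k in range(len(hist.G)):
        nb = len(hist.G[k])
        if nb < 2:
            continue
        gl = np.cumsum(hist.G[k])[:-1]
        hl = np.cumsum(hist.H[k])[:-1]
        cl = np.cumsum(hist.count[k])[:-1]
        for q in range(nb - 1):
            n_left = int(cl[q])
            n_right = parent_count - n_left
            if n_left < config.min_child_samples or n_right < config.min_child_samples:
                continue
            g_l, h_l = float(gl[q]), float(hl[q])
            g_r, h_r = parent_g - g_l, parent_h - h_l
            gain = 0.5 * (
                _leaf_objective(g_l, h_l, lam)
                + _leaf_objective(g_r, h_r, lam)
                - parent_obj
            ) - gam
            if gain > 0 and (best is None or gain > best.gain):
                best = SplitCandidate(
                    feature=k, bin=q, gain=gain, g_left=g_l, h_left=h_l, n_left=n_left
                )
    return best


# ---------------------------------------------------------------------------
# Trees and models


@dataclass
class TreeNode:
    id: int
    is_leaf: bool
    n_samples: int
    cover: float  # sum of h over the node's samples
    gain: float = 0.0
    feature: str | None = None  # split feature name (internal nodes)
    bin: int | None = None  # last bin index routed left
    threshold: float | None = None  # edge value; route left iff value < threshold
    left: int | None = None
    right: int | None = None
    weight: float = 0.0  # leaf weight (before learning rate)


@dataclass
class Tree:
    nodes: list[TreeNode] = field(default_factory=list)

    def predict_margin(self, X: np.ndarray, feature_index: dict[str, int]) -> np.ndarray:
        # node ids increase from parent to child, so one ordered pass routes all rows
        n = X.shape[0]
        assign = np.zeros(n, dtype=np.intp)
        out = np.zeros(n, dtype=np.float64)
        for node in self.nodes:
            mask = assign == node.id
            if not mask.any():
                continue
            if node.is_leaf:
                out[mask] = node.weight
            else:
                v = X[mask, feature_index[node.feature]]
                assign[mask] = np.where(v < node.threshold, node.left, node.right)
        return out


@dataclass
class BoostedModel:
    """Ordered trees + binning + config; predictions are name-based."""

    feature_names: list[str]
    edges: list[np.ndarray]
    config: BoostConfig
    trees: list[Tree] = field(default_factory=list)

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise DataError(f"prediction input missing feature: {missing[0]!r}")
            return X[self.feature_names].to_numpy(dtype=np.float64)
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.feature_names):
            raise DataError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def margins(self, X) -> np.ndarray:
        Xm = self._matrix(X)
        out = np.full(Xm.shape[0], self.config.base_margin, dtype=np.float64)
        fidx = {f: i for i, f in enumerate(self.feature_names)}
        for tree in self.trees:
            out += self.config.learning_rate * tree.predict_margin(Xm, fidx)
        return out

    def predict_proba(self, X) -> np.ndarray:
        m = np.clip(self.margins(X), -MARGIN_CLIP, MARGIN_CLIP)
        return 1.0 / (1.0 + np.exp(-m))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "feature_names": self.feature_names,
            "edges": [e.tolist() for e in self.edges],
            "config": asdict(self.config),
            "trees": [[asdict(n) for n in t.nodes] for t in self.trees],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BoostedModel":
        payload = json.loads(text)
        model = cls(
            feature_names=payload["feature_names"],
            edges=[np.asarray(e, dtype=np.float64) for e in payload["edges"]],
            config=BoostConfig(**payload["config"]),
        )
        model.trees = [
            Tree(nodes=[TreeNode(**n) for n in nodes]) for nodes in payload["trees"]
        ]
        return model


def assign_leaf_weights(
    tree: Tree, leaf_of: np.ndarray, grads: GradientPair, config: BoostConfig
) -> None:
    """Closed-form leaf weights w = -G/(H+lambda) from a sample→leaf assignment.

    Shared by the centralized and federated trainers so accumulation order (and
    hence every float) is identical in both.
    """
    g_sum = np.bincount(leaf_of, weights=grads.g, minlength=len(tree.nodes))
    h_sum = np.bincount(leaf_of, weights=grads.h, minlength=len(tree.nodes))
    for node in tree.nodes:
        if node.is_leaf:
            node.weight = float(-g_sum[node.id] / (h_sum[node.id] + config.reg_lambda))


def _grow_tree(
    codes: np.ndarray,
    edges: Sequence[np.ndarray],
    feature_names: Sequence[str],
    grads: GradientPair,
    config: BoostConfig,
) -> tuple[Tree, np.ndarray]:
    """One breadth-first tree on precomputed bin codes; returns (tree, leaf_of)."""
    n_bins_per_feature = [len(e) + 1 for e in edges]
    tree = Tree()
    n = codes.shape[0]
    root_idx = np.arange(n, dtype=np.intp)
    g_root, h_root = float(grads.g.sum()), float(grads.h.sum())
    tree.nodes.append(TreeNode(id=0, is_leaf=True, n_samples=n, cover=h_root))
    leaf_of = np.zeros(n, dtype=np.intp)
    # frontier entries: (node_id, sample idx, G, H)
    frontier = [(0, root_idx, g_root, h_root)]
    for _depth in range(config.max_depth):
        next_frontier = []
        for node_id, idx, g_tot, h_tot in frontier:
            hist = build_histogram(codes, grads, idx, n_bins_per_feature)
            best = find_best_split(hist, g_tot, h_tot, idx.size, config)
            if best is None:
                continue
            node = tree.nodes[node_id]
            go_left = codes[idx, best.feature] <= best.bin
            left_idx, right_idx = idx[go_left], idx[~go_left]
            left = TreeNode(
                id=len(tree.nodes), is_leaf=True,
                n_samples=left_idx.size, cover=best.h_left,
            )
            tree.nodes.append(left)
            right = TreeNode(
                id=len(tree.nodes), is_leaf=True,
                n_samples=right_idx.size, cover=h_tot - best.h_left,
            )
            tree.nodes.append(right)
            node.is_leaf = False
            node.feature = feature_names[best.feature]
            node.bin = best.bin
            node.threshold = float(edges[best.feature][best.bin])
            node.gain = best.gain
            node.left, node.right = left.id, right.id
            leaf_of[left_idx] = left.id
            leaf_of[right_idx] = right.id
            next_frontier.append((left.id, left_idx, best.g_left, best.h_left))
            next_frontier.append(
                (right.id, right_idx, g_tot - best.g_left, h_tot - best.h_left)
            )
        frontier = next_frontier
        if not frontier:
            break
    assign_leaf_weights(tree, leaf_of, grads, config)
    return tree, leaf_of


def fit_boosting(
    X,
    working_labels: WorkingLabels | np.ndarray,
    config: BoostConfig | None = None,
) -> BoostedModel:
    """Train the centralized ensemble on a feature matrix and working labels."""
    config = config or BoostConfig()
    config.validate()
    if isinstance(X, pd.DataFrame):
        feature_names = [str(c) for c in X.columns]
        values = X.to_numpy(dtype=np.float64)
    else:
        values = np.asarray(X, dtype=np.float64)
        if values.ndim == 1:
            values = values[:, None]
        feature_names = [f"f{i}" for i in range(values.shape[1])]
    if values.shape[0] < 1:
        raise DataError("training requires at least one sample")
    if not np.isfinite(values).all():
        raise DataError("training features must be finite (missing values rejected)")
    y = (
        working_labels.y_tilde
        if isinstance(working_labels, WorkingLabels)
        else np.asarray(working_labels)
    )
    if y.shape[0] != values.shape[0]:
        raise DataError("labels and features must be aligned")
    edges, codes = quantile_bin(values, config.n_bins)
    model = BoostedModel(feature_names=feature_names, edges=edges, config=config)
    margins = np.full(values.shape[0], config.base_margin, dtype=np.float64)
    for _t in range(config.n_trees):
        grads = compute_gradients(y, margins)
        tree, leaf_of = _grow_tree(codes, edges, feature_names, grads, config)
        weights = np.array([node.weight for node in tree.nodes])
        margins += config.learning_rate * weights[leaf_of]
        model.trees.append(tree)
    return model


class BoostedTreesClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper over :func:`fit_boosting`.

    Parameters mirror :class:`BoostConfig`; the fitted ensemble is ``booster_``.
    """

    def __init__(
        self,
        n_trees: int = 30,
        max_depth: int = 3,
        learning_rate: float = 0.3,
        reg_lambda: float = 1.0,
        gamma: float = 0.0,
        n_bins: int = 32,
        min_child_samples: int = 1,
        base_margin: float = 0.0,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.reg_lambda = reg_lambda
        self.gamma = gamma
        self.n_bins = n_bins
        self.min_child_samples = min_child_samples
        self.base_margin = base_margin

    def _config(self) -> BoostConfig:
        return BoostConfig(
            n_trees=self.n_trees,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            reg_lambda=self.reg_lambda,
            gamma=self.gamma,
            n_bins=self.n_bins,
            min_child_samples=self.min_child_samples,
            base_margin=self.base_margin,
        )

    def fit(self, X, y):
        y = np.asarray(y)
        if not np.isin(y, (0, 1)).all():
            raise DataError("labels must be binary in {0,1}")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.booster_ = fit_boosting(X, y, self._config())
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "booster_")
        return self.booster_.margins(X)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "booster_")
        p1 = self.booster_.predict_proba(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
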