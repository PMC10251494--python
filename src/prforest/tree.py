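"""Probabilistic decision trees.

Two growth engines produce the same tree structure:

* a *reference* engine (this module) that carries per-sample arrival
  masses through dual-child propagation and calls the split-search
  primitives in :mod:`prforest.splitting` directly — correct for any
  feature uncertainty, written for clarity; and
* a *fast* engine (:mod:`prforest._fast`) used automatically when every
  feature uncertainty is zero, where propagation is deterministic and
  the tree reduces to a weighted-Gini CART over soft class masses.

Trees are stored in flat arrays (one row per node) for cheap batch
prediction and JSON serialization; :attr:`ProbTree.root` exposes the
conventional linked :class:`TreeNode` view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .splitting import (
    TIE_TOL,
    SplitSpec,
    find_best_split,
    gaussian_right_probability,
    node_class_distribution,
    right_probabilities,
    modified_gini,
)

__all__ = ["TreeNode", "ProbTree", "grow_tree_reference", "predict_proba_tree"]

LEAF = -1


@dataclass
class TreeNode:
    """Linked-node view of a tree node.

    ``split`` is present iff both children are present (internal node);
    a node with neither is terminal.  ``effective_mass`` is the summed
    arrival probability of the training samples that reached the node.
    """

    class_distribution: np.ndarray
    effective_mass: float
    split: Optional[SplitSpec] = None
    left_child: Optional["TreeNode"] = None
    right_child: Optional["TreeNode"] = None
    feature_subset: Optional[np.ndarray] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


class ProbTree:
    """A grown probabilistic tree in flat-array form.

    Parameters are parallel arrays indexed by node id; node 0 is the
    root.  ``feature[i] == -1`` marks a terminal node.  ``subsets``
    records the feature subset drawn at each node (``None`` where no
    draw happened, e.g. pure nodes), enabling exact replay by reference
    implementations.
    """

    def __init__(
        self,
        feature: np.ndarray,
        threshold: np.ndarray,
        left: np.ndarray,
        right: np.ndarray,
        dist: np.ndarray,
        mass: np.ndarray,
        subsets: list | None = None,
        bootstrap_indices: np.ndarray | None = None,
    ) -> None:
        self.feature = np.asarray(feature, dtype=np.int32)
        self.threshold = np.asarray(threshold, dtype=float)
        self.left = np.asarray(left, dtype=np.int32)
        self.right = np.asarray(right, dtype=np.int32)
        self.dist = np.asarray(dist, dtype=float)
        self.mass = np.asarray(mass, dtype=float)
        self.subsets = subsets if subsets is not None else [None] * len(self.feature)
        self.bootstrap_indices = bootstrap_indices

    @property
    def n_nodes(self) -> int:
        return int(self.feature.size)

    @property
    def n_classes(self) -> int:
        return int(self.dist.shape[1])

    @property
    def root(self) -> TreeNode:
        """Build the linked :class:`TreeNode` view (cheap, done on demand)."""
        return self._build(0)

    def _build(self, i: int) -> TreeNode:
        subset = self.subsets[i] if i < len(self.subsets) else None
        if self.feature[i] == LEAF:
            return TreeNode(
                class_distribution=self.dist[i].copy(),
                effective_mass=float(self.mass[i]),
                feature_subset=subset,
            )
        return TreeNode(
            class_distribution=self.dist[i].copy(),
            effective_mass=float(self.mass[i]),
            split=SplitSpec(int(self.feature[i]), float(self.threshold[i])),
            left_child=self._build(int(self.left[i])),
            right_child=self._build(int(self.right[i])),
            feature_subset=subset,
        )

    def split_sequence(self) -> list[tuple[int, int, float]]:
        """Preorder list of ``(node_id, feature, threshold)`` for internal nodes."""
        out: list[tuple[int, int, float]] = []

        def walk(i: int) -> None:
            if self.feature[i] != LEAF:
                out.append((i, int(self.feature[i]), float(self.threshold[i])))
                walk(int(self.left[i]))
                walk(int(self.right[i]))

        walk(0)
        return out

    def feature_importance(self, n_features: int) -> np.ndarray:
        """Mass-weighted impurity decrease per feature (unnormalized)."""
        imp = np.zeros(n_features)
        gini = 1.0 - np.einsum("ij,ij->i", self.dist, self.dist)
        internal = np.flatnonzero(self.feature != LEAF)
        for i in internal:
            l, r = int(self.left[i]), int(self.right[i])
            dec = (
                self.mass[i] * gini[i]
                - self.mass[l] * gini[l]
                - self.mass[r] * gini[r]
            )
            imp[self.feature[i]] += dec
        return imp


def _resolve_max_features(spec, d: int) -> int:
    """Number of features drawn per node from a strategy spec."""
    if isinstance(spec, (int, np.integer)):
        k = int(spec)
    elif spec in (None, "all"):
        k = d
    elif spec == "sqrt":
        k = max(1, int(np.sqrt(d)))
    elif spec == "log2":
        k = max(1, int(np.log2(d)))
    else:
        raise ValueError(f"unknown max_features strategy {spec!r}")
    if not 1 <= k <= d:
        raise ValueError(f"max_features={k} outside [1, {d}]")
    return k


class _TreeBuilder:
    """Accumulates node rows during recursive reference growth."""

    def __init__(self, K: int):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.dist: list[np.ndarray] = []
        self.mass: list[float] = []
        self.subsets: list = []

    def new_node(self, dist: np.ndarray, mass: float) -> int:
        i = len(self.feature)
        self.feature.append(LEAF)
        self.threshold.append(np.nan)
        self.left.append(LEAF)
        self.right.append(LEAF)
        self.dist.append(dist)
        self.mass.append(mass)
        self.subsets.append(None)
        return i


def grow_tree_reference(
    X: np.ndarray,
    DX: np.ndarray,
    PMF: np.ndarray,
    arrival: np.ndarray,
    class_weights: np.ndarray,
    *,
    min_samples_split: float = 2.0,
    min_samples_leaf: float = 1.0,
    keep_probability: float = 0.05,
    max_depth: int | None = None,
    max_features="all",
    rng: np.random.Generator | None = None,
) -> ProbTree:
    """Grow a probabilistic tree with explicit dual-child propagation.

    ``arrival`` holds each training row's initial mass (bootstrap
    multiplicity; rows with zero mass are ignored).  At every split each
    surviving sample sends ``mass * P(x > t)`` to the right child and the
    complement to the left; a path is dropped at a child when its mass
    there falls below ``keep_probability`` (dropped mass is simply
    excluded, no renormalization).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n, d = X.shape
    if arrival.shape != (n,):
        raise ValueError("arrival must be one mass per row")
    live = np.flatnonzero(arrival > 0)
    if live.size == 0:
        raise ValueError("empty bootstrap: no row has positive arrival mass")
    k_feats = _resolve_max_features(max_features, d)
    b = _TreeBuilder(PMF.shape[1])

    def build(idx: np.ndarray, mass: np.ndarray, depth: int) -> int:
        dist = node_class_distribution(mass, PMF[idx], class_weights)
        m = float(mass.sum())
        node = b.new_node(dist, m)
        gini = modified_gini(dist)
        if (
            m < min_samples_split
            or gini <= TIE_TOL
            or (max_depth is not None and depth >= max_depth)
            or idx.size < 2
        ):
            return node
        if k_feats == d:
            subset = np.arange(d)
        else:
            subset = np.sort(rng.choice(d, size=k_feats, replace=False))
        b.subsets[node] = subset
        found = find_best_split(
            X[idx],
            DX[idx],
            mass,
            PMF[idx],
            subset,
            class_weights,
            min_samples_leaf=min_samples_leaf,
            keep_probability=keep_probability,
        )
        if found is None:
            return node
        spec, _cost = found
        p_right = right_probabilities(
            X[idx, spec.feature_index], DX[idx, spec.feature_index], spec.threshold
        )
        right_mass = mass * p_right
        left_mass = mass - right_mass
        keep_l = (left_mass > 0) & (left_mass >= keep_probability)
        keep_r = (right_mass > 0) & (right_mass >= keep_probability)
        if not keep_l.any() or not keep_r.any():
            return node  # pruning emptied a child; treat as unsplittable
        b.feature[node] = spec.feature_index
        b.threshold[node] = spec.threshold
        b.left[node] = build(idx[keep_l], left_mass[keep_l], depth + 1)
        b.right[node] = build(idx[keep_r], right_mass[keep_r], depth + 1)
        return node

    build(live, arrival[live].astype(float), 0)
    return ProbTree(
        np.array(b.feature),
        np.array(b.threshold),
        np.array(b.left),
        np.array(b.right),
        np.stack(b.dist),
        np.array(b.mass),
        subsets=b.subsets,
    )


def predict_proba_tree(
    tree: ProbTree,
    x: np.ndarray,
    dx: np.ndarray | None = None,
    *,
    prune: bool = False,
    keep_probability: float = 0.05,
) -> np.ndarray:
    """Class probabilities for one point by probability-weighted leaf averaging.

    The point reaches every leaf with the product of per-node crossing
    probabilities along the path; the output is the arrival-weighted
    mean of the leaf class distributions.  Without pruning the arrival
    probabilities sum to exactly 1.  With ``prune=True``, paths whose
    arrival mass drops below ``keep_probability`` are discarded (faster,
    approximate) and the result is renormalized.
    """
    x = np.asarray(x, dtype=float)
    if dx is None:
        dx = np.zeros_like(x)
    else:
        dx = np.asarray(dx, dtype=float)
    if x.shape != dx.shape:
        raise ValueError("x and dx must have the same shape")
    acc = np.zeros(tree.n_classes)
    stack = [(0, 1.0)]
    while stack:
        i, mass = stack.pop()
        f = int(tree.feature[i])
        if f == LEAF:
            acc += mass * tree.dist[i]
            continue
        if f >= x.size:
            raise ValueError("feature vector shorter than the tree expects")
        p = gaussian_right_probability(float(x[f]), float(dx[f]), float(tree.threshold[i]))
        right_mass = mass * p
        left_mass = mass - right_mass
        for child, m in ((int(tree.right[i]), right_mass), (int(tree.left[i]), left_mass)):
            if m > 0 and (not prune or m >= keep_probability):
                stack.append((child, m))
    if prune:
        s = acc.sum()
        if s > 0:
            acc = acc / s
    return acc
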