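"""Probabilistic random forest: fitting, prediction, importances, JSON I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np

from . import _fast
from .dataset import UncertainDataset
from .tree import ProbTree, _resolve_max_features, grow_tree_reference, predict_proba_tree

__all__ = [
    "Hyperparameters",
    "PRForestModel",
    "compute_class_weights",
    "fit_forest",
    "predict_proba_forest",
    "predict_labels",
    "feature_importances",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Forest hyperparameters.

    ``min_samples_split`` and ``min_samples_leaf`` are *effective
    probability masses* (sums of arrival probabilities), which reduce to
    ordinary sample counts when all feature uncertainties are zero.
    ``max_features`` is one of ``"sqrt"``, ``"log2"``, ``"all"`` or an
    explicit integer.
    """

    n_trees: int = 100
    max_features: str | int = "sqrt"
    min_samples_split: float = 10.0
    min_samples_leaf: float = 5.0
    keep_probability: float = 0.05
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be a positive integer")
        if not 0.0 <= self.keep_probability <= 1.0:
            raise ValueError("keep_probability must lie in [0, 1]")
        if self.min_samples_leaf > self.min_samples_split:
            raise ValueError("min_samples_leaf must not exceed min_samples_split")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be positive or None")

    def with_seed(self, seed: int) -> "Hyperparameters":
        return replace(self, seed=int(seed))


def compute_class_weights(label_pmfs: np.ndarray) -> np.ndarray:
    """Balanced inverse effective-frequency weights over soft labels.

    The effective count of class ``c`` is ``m_c = sum_i pmf[i][c]``; the
    weight is ``n / (K * m_c)``, so perfectly balanced data yields all
    ones.
    """
    pmfs = np.asarray(label_pmfs, dtype=float)
    n, K = pmfs.shape
    if n < 1:
        raise ValueError("need at least one sample")
    m = pmfs.sum(axis=0)
    if np.any(m <= 0):
        empty = [str(c) for c in np.flatnonzero(m <= 0)]
        raise ValueError(
            f"class(es) {', '.join(empty)} have zero effective count; "
            "cannot compute balanced class weights"
        )
    return n / (K * m)


@dataclass
class PRForestModel:
    """A fitted probabilistic random forest."""

    trees: list
    hyperparameters: Hyperparameters
    feature_names: list
    class_names: list
    class_weights: np.ndarray
    bootstrap_sample_ids: list  # per tree, the drawn sample ids (with repeats)
    engine: str  # "fast" or "reference"

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    # -- serialization (documented JSON schema, no binary formats) -------

    SCHEMA_VERSION = 1

    def to_dict(self) -> dict:
        return {
            "schema_version": self.SCHEMA_VERSION,
            "hyperparameters": {
                **asdict(self.hyperparameters),
            },
            "feature_names": list(self.feature_names),
            "class_names": list(self.class_names),
            "class_weights": list(map(float, self.class_weights)),
            "engine": self.engine,
            "bootstrap_sample_ids": [list(ids) for ids in self.bootstrap_sample_ids],
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": [
                        None if np.isnan(x) else float(x) for x in t.threshold
                    ],
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "class_distribution": t.dist.tolist(),
                    "effective_mass": t.mass.tolist(),
                    "feature_subsets": [
                        None if s is None else [int(v) for v in s] for s in t.subsets
                    ],
                }
                for t in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PRForestModel":
        if d.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        trees = []
        for td in d["trees"]:
            trees.append(
                ProbTree(
                    np.array(td["feature"], dtype=np.int32),
                    np.array(
                        [np.nan if x is None else x for x in td["threshold"]], dtype=float
                    ),
                    np.array(td["left"], dtype=np.int32),
                    np.array(td["right"], dtype=np.int32),
                    np.array(td["class_distribution"], dtype=float),
                    np.array(td["effective_mass"], dtype=float),
                    subsets=[
                        None if s is None else np.array(s, dtype=np.int64)
                        for s in td["feature_subsets"]
                    ],
                )
            )
        hp = Hyperparameters(**d["hyperparameters"])
        return cls(
            trees=trees,
            hyperparameters=hp,
            feature_names=list(d["feature_names"]),
            class_names=list(d["class_names"]),
            class_weights=np.array(d["class_weights"], dtype=float),
            bootstrap_sample_ids=[list(ids) for ids in d["bootstrap_sample_ids"]],
            engine=d["engine"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PRForestModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _select_engine(dataset: UncertainDataset, hp: Hyperparameters, engine: str) -> str:
    if engine == "auto":
        # The fast path is exact whenever propagation is deterministic:
        # all uncertainties zero means every arrival mass stays at its
        # bootstrap count (>= 1), so keep_probability (< 1) never fires.
        if not dataset.DX.any() and hp.keep_probability < 1.0:
            return "fast"
        return "reference"
    if engine in ("fast", "reference"):
        return engine
    raise ValueError(f"unknown engine {engine!r}")


def fit_forest(
    dataset: UncertainDataset,
    hyperparameters: Hyperparameters,
    *,
    engine: str = "auto",
) -> PRForestModel:
    """Fit a probabilistic random forest.

    Bootstraps (with replacement, size n) and per-node feature subsets
    are drawn from a stream seeded by ``hyperparameters.seed``; fitting
    is fully deterministic given the seed.
    """
    n, d = dataset.X.shape
    if n == 0:
        raise ValueError("cannot fit on an empty dataset")
    hp = hyperparameters
    class_weights = compute_class_weights(dataset.PMF)
    chosen = _select_engine(dataset, hp, engine)
    k_feats = _resolve_max_features(hp.max_features, d)
    rng = np.random.default_rng(hp.seed)
    M = dataset.PMF * class_weights[None, :]
    trees: list[ProbTree] = []
    boot_ids: list[list[str]] = []
    for _ in range(hp.n_trees):
        boot = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, 2**32))
        counts = np.bincount(boot, minlength=n).astype(float)
        if chosen == "fast":
            sel = np.flatnonzero(counts)
            tree = grow_tree_fast_rows(
                dataset.X[sel], counts[sel], M[sel], hp, k_feats, tree_seed
            )
        else:
            tree = grow_tree_reference(
                dataset.X,
                dataset.DX,
                dataset.PMF,
                counts,
                class_weights,
                min_samples_split=hp.min_samples_split,
                min_samples_leaf=hp.min_samples_leaf,
                keep_probability=hp.keep_probability,
                max_depth=hp.max_depth,
                max_features=hp.max_features,
                rng=np.random.default_rng(tree_seed),
            )
        tree.bootstrap_indices = boot
        trees.append(tree)
        boot_ids.append([dataset.sample_ids[i] for i in boot])
    return PRForestModel(
        trees=trees,
        hyperparameters=hp,
        feature_names=list(dataset.feature_names),
        class_names=list(dataset.class_names),
        class_weights=class_weights,
        bootstrap_sample_ids=boot_ids,
        engine=chosen,
    )


def grow_tree_fast_rows(Xs, counts, Ms, hp: Hyperparameters, k_feats: int, seed: int):
    return _fast.grow_tree_fast(
        Xs,
        counts,
        Ms,
        min_samples_split=hp.min_samples_split,
        min_samples_leaf=hp.min_samples_leaf,
        max_depth=hp.max_depth,
        k_feats=k_feats,
        seed=seed,
    )


def predict_proba_forest(
    model: PRForestModel,
    X: np.ndarray,
    DX: np.ndarray | None = None,
) -> np.ndarray:
    """Mean over trees of per-tree class probabilities; rows sum to 1.

    With no (or all-zero) test-time uncertainties each point follows a
    single root-to-leaf path per tree; otherwise it is propagated to all
    leaves with Gaussian crossing probabilities (no pruning, so the
    arrival masses sum to exactly 1).
    """
    if not model.trees:
        raise RuntimeError("model has no trees; fit it first")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.n_features}"
        )
    if DX is None or not np.asarray(DX).any():
        return _fast.predict_dense_forest(model.trees, X, model.n_classes)
    DX = np.atleast_2d(np.asarray(DX, dtype=float))
    if DX.shape != X.shape:
        raise ValueError("DX must match the shape of X")
    out = np.zeros((X.shape[0], model.n_classes))
    for tree in model.trees:
        for i in range(X.shape[0]):
            out[i] += predict_proba_tree(tree, X[i], DX[i])
    out /= len(model.trees)
    return out


def predict_labels(
    model: PRForestModel,
    X: np.ndarray,
    DX: np.ndarray | None = None,
) -> np.ndarray:
    """Hard labels by argmax; exact probability ties go to the lower class index."""
    proba = predict_proba_forest(model, X, DX)
    return np.argmax(proba, axis=1)


def feature_importances(model: PRForestModel) -> np.ndarray:
    """Mean over trees of normalized mass-weighted impurity decrease.

    Non-negative, sums to 1.  A forest in which no tree ever split
    (e.g. pure training data) returns the uniform vector.
    """
    d = model.n_features
    acc = np.zeros(d)
    n_used = 0
    for tree in model.trees:
        imp = tree.feature_importance(d)
        s = imp.sum()
        if s > 0:
            acc += imp / s
            n_used += 1
    if n_used == 0:
        return np.full(d, 1.0 / d)
    acc /= n_used
    return acc / acc.sum()
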