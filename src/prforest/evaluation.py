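"""Nested stratified k-fold cross-validation and policy comparison.

The outer loop estimates generalization performance on held-out test
folds; the inner loop, run on each outer training split, selects
hyperparameters by grid search.  All folds are stratified on the
nominal class labels.  Test metrics are computed on samples with
confirmed labels only, and the same fold plan (and the same tree seeds)
is shared by every label policy so the comparison is exactly paired.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._version import __version__ as _pkg_version
from .dataset import UncertainDataset
from .forest import Hyperparameters, PRForestModel, fit_forest, predict_proba_forest
from .metrics import precision_recall_f1, roc_auc
from .policies import LabelPolicy, apply_policy

__all__ = [
    "FoldPlan",
    "HyperparameterGrid",
    "MetricsReport",
    "stratified_kfold",
    "build_fold_plan",
    "select_hyperparameters",
    "evaluate_fold",
    "run_comparison",
    "DEFAULT_FPR_GRID_POINTS",
]

DEFAULT_FPR_GRID_POINTS = 101
POSITIVE_CLASS = "new_disease_activity"


def stratified_kfold(nominal_labels: np.ndarray, k: int, seed) -> np.ndarray:
    """Assign each sample to one of ``k`` folds, stratified by label.

    Within each class the (seeded-shuffled) members are distributed so
    every fold gets either ``floor(n_c/k)`` or one more; the classes'
    remainders are rotated across folds so total fold sizes also differ
    by at most the number of classes' imbalance (20 or 21 for the
    142-subject default).  Deterministic given ``seed``.
    """
    labels = np.asarray(nominal_labels)
    n = labels.size
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    fold_id = np.full(n, -1, dtype=np.int64)
    offset = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise ValueError(
                f"class {c!r} has only {idx.size} members, fewer than k={k}"
            )
        rng.shuffle(idx)
        base, extra = divmod(idx.size, k)
        sizes = np.full(k, base)
        for j in range(extra):
            sizes[(offset + j) % k] += 1
        offset = (offset + extra) % k
        stops = np.cumsum(sizes)
        starts = stops - sizes
        for f in range(k):
            fold_id[idx[starts[f]:stops[f]]] = f
    return fold_id


@dataclass
class FoldPlan:
    """Nested stratified CV index structure over a dataset.

    ``outer[i]`` is ``(train_idx, test_idx)``; ``inner[i][j]`` is
    ``(train_idx, val_idx)`` over the i-th outer training set.  All
    indices refer to the dataset the plan was built on.  The plan is
    reconstructible from ``(labels, k, seed)`` alone.
    """

    k: int
    seed: int
    outer: list
    inner: list

    @property
    def n_samples(self) -> int:
        return sum(len(t) for _, t in self.outer)


def build_fold_plan(nominal_labels: np.ndarray, k: int, seed: int) -> FoldPlan:
    labels = np.asarray(nominal_labels)
    outer_fold = stratified_kfold(labels, k, seed)
    outer, inner = [], []
    for i in range(k):
        test_idx = np.flatnonzero(outer_fold == i)
        train_idx = np.flatnonzero(outer_fold != i)
        outer.append((train_idx, test_idx))
        inner_fold = stratified_kfold(labels[train_idx], k, [seed, 1 + i])
        folds_i = []
        for j in range(k):
            val_idx = train_idx[inner_fold == j]
            tr_idx = train_idx[inner_fold != j]
            folds_i.append((tr_idx, val_idx))
        inner.append(folds_i)
    return FoldPlan(k=k, seed=seed, outer=outer, inner=inner)


@dataclass(frozen=True)
class HyperparameterGrid:
    """Candidate values for the searched hyperparameter fields.

    Expansion order (and therefore the grid-order tie-break) is the
    cartesian product in field order: n_trees, max_features,
    min_samples_split, min_samples_leaf.
    """

    n_trees: tuple = (50, 100, 250)
    max_features: tuple = ("sqrt", "log2", "all")
    min_samples_split: tuple = (10.0,)
    min_samples_leaf: tuple = (5.0,)

    def __post_init__(self) -> None:
        for name in ("n_trees", "max_features", "min_samples_split", "min_samples_leaf"):
            if not getattr(self, name):
                raise ValueError(f"grid field {name} must be non-empty")

    def candidates(self, base: Hyperparameters) -> list[Hyperparameters]:
        out = []
        for nt, mf, ms, ml in itertools.product(
            self.n_trees, self.max_features, self.min_samples_split, self.min_samples_leaf
        ):
            out.append(
                replace(
                    base,
                    n_trees=int(nt),
                    max_features=mf,
                    min_samples_split=float(ms),
                    min_samples_leaf=float(ml),
                )
            )
        return out

    def to_dict(self) -> dict:
        return {
            "n_trees": list(self.n_trees),
            "max_features": list(self.max_features),
            "min_samples_split": list(self.min_samples_split),
            "min_samples_leaf": list(self.min_samples_leaf),
        }


# ---------------------------------------------------------------------------
# policy views

def _policy_view(dataset: UncertainDataset, policy: LabelPolicy):
    """Aligned (full-length) training view of a policy plus a usability mask.

    ``apply_policy`` is called first so its validation and contracts
    hold; the returned dataset keeps full-dataset alignment (so fold
    indices remain valid) and ``mask`` marks the rows the policy allows
    into training.
    """
    apply_policy(dataset, policy)  # validation (raises on emptied classes)
    n, K = dataset.PMF.shape
    PMF = np.zeros((n, K))
    PMF[np.arange(n), dataset.nominal] = 1.0
    if policy.name == "probabilistic":
        post = ~dataset.confirmed
        p = policy.posthoc_probability
        off = (1.0 - p) / (K - 1)
        soft = np.full((int(post.sum()), K), off)
        soft[np.arange(soft.shape[0]), dataset.nominal[post]] = p
        PMF[post] = soft
    aligned = dataset.replace_pmf(PMF)
    mask = dataset.confirmed.copy() if policy.name == "exclude" else np.ones(n, dtype=bool)
    return aligned, mask


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0])


# ---------------------------------------------------------------------------
# fold evaluation

@dataclass
class FoldEval:
    """Confirmed-label-only evaluation of one model on one test fold."""

    tp: int
    fp: int
    fn: int
    tn: int
    scores: np.ndarray  # predicted positive-class probability, confirmed only
    labels: np.ndarray  # true positive indicator, confirmed only

    @property
    def n_confirmed(self) -> int:
        return int(self.labels.size)


def evaluate_fold(
    model: PRForestModel,
    dataset: UncertainDataset,
    test_idx: np.ndarray,
    positive_index: int,
    threshold: float = 0.5,
) -> FoldEval | None:
    """Confusion counts and scores on the confirmed samples of a test fold.

    Post hoc samples are excluded from the counts entirely.  Hard
    predictions call a sample positive when its predicted positive-class
    probability exceeds ``threshold``.  Returns ``None`` when the fold
    contains no confirmed sample (the caller flags and skips it).
    """
    test_idx = np.asarray(test_idx, dtype=np.int64)
    conf = test_idx[dataset.confirmed[test_idx]]
    if conf.size == 0:
        return None
    proba = predict_proba_forest(model, dataset.X[conf])
    scores = proba[:, positive_index]
    pred_pos = scores > threshold
    true_pos = dataset.nominal[conf] == positive_index
    tp = int(np.sum(pred_pos & true_pos))
    fp = int(np.sum(pred_pos & ~true_pos))
    fn = int(np.sum(~pred_pos & true_pos))
    tn = int(np.sum(~pred_pos & ~true_pos))
    return FoldEval(tp, fp, fn, tn, scores=scores, labels=true_pos)


def _fold_scores(ev: FoldEval) -> tuple[float, float]:
    """(F1 %, AUC) of a fold evaluation; non-finite values become 0 / NaN."""
    prf = precision_recall_f1(ev.tp, ev.fp, ev.fn)
    f1 = prf.f1 if math.isfinite(prf.f1) else 0.0
    if ev.labels.all() or not ev.labels.any():
        auc = np.nan
    else:
        _, _, auc = roc_auc(ev.scores, ev.labels)
    return f1, auc


def select_hyperparameters(
    dataset: UncertainDataset,
    inner_folds: Sequence[tuple],
    grid: HyperparameterGrid,
    policy: LabelPolicy,
    base: Hyperparameters,
    seed_parts: tuple[int, ...],
    *,
    metric: str = "f1",
    threshold: float = 0.5,
) -> Hyperparameters:
    """Full grid search over the inner folds of one outer training set.

    Each candidate is scored by its mean selection metric (default F1 on
    confirmed validation samples) over the inner folds; ties break by
    higher mean AUC, then smaller ``n_trees``, then grid order.  Tree
    seeds depend only on ``seed_parts`` and the fold index, so every
    candidate (and every policy) trains with the same random streams.
    """
    if metric not in ("f1", "auc"):
        raise ValueError("selection metric must be 'f1' or 'auc'")
    aligned, mask = _policy_view(dataset, policy)
    positive_index = _positive_index(dataset)
    candidates = grid.candidates(base)
    best = None  # (mean_metric, mean_auc, -n_trees, -order_rank, hp)
    any_trained = False
    for rank, cand in enumerate(candidates):
        f1s, aucs = [], []
        for j, (tr_idx, val_idx) in enumerate(inner_folds):
            tr = tr_idx[mask[tr_idx]]
            hp = cand.with_seed(_derive_seed(*seed_parts, j))
            try:
                model = fit_forest(aligned.subset(tr), hp)
            except ValueError:
                continue
            ev = evaluate_fold(model, dataset, val_idx, positive_index, threshold)
            if ev is None:
                continue
            f1, auc = _fold_scores(ev)
            f1s.append(f1)
            aucs.append(auc)
        if not f1s:
            continue
        any_trained = True
        mean_f1 = float(np.mean(f1s))
        mean_auc = float(np.nanmean(aucs)) if not np.all(np.isnan(aucs)) else 0.0
        mean_metric = mean_f1 if metric == "f1" else mean_auc
        key = (mean_metric, mean_auc, -cand.n_trees, -rank)
        if best is None or key > best[0]:
            best = (key, cand)
    if not any_trained:
        raise ValueError("no hyperparameter candidate could be trained and scored")
    return best[1]


# ---------------------------------------------------------------------------
# reporting

_METRICS = ("auc", "recall", "precision", "f1")


@dataclass
class MetricsReport:
    """Per-fold and aggregated results for one policy.

    ``folds`` holds one dict per outer fold (confusion counts, metrics,
    the selected hyperparameters and the ROC curve); ``summary`` maps
    each metric to ``(mean, sd)`` over the folds where it was defined
    (sample SD, ddof=1).  Everything in ``summary`` is recomputable from
    ``folds``.
    """

    policy: str
    posthoc_probability: float
    k: int
    seed: int
    folds: list
    summary: dict
    mean_roc: dict
    manifest: dict

    def to_dict(self) -> dict:
        return {
            "policy": self.policy,
            "posthoc_probability": self.posthoc_probability,
            "k": self.k,
            "seed": self.seed,
            "folds": self.folds,
            "summary": self.summary,
            "mean_roc": self.mean_roc,
            "manifest": self.manifest,
        }

    def metric_mean(self, name: str) -> float:
        return self.summary[name]["mean"]

    def metric_sd(self, name: str) -> float:
        return self.summary[name]["sd"]


def _positive_index(dataset: UncertainDataset) -> int:
    if POSITIVE_CLASS in dataset.class_names:
        return dataset.class_names.index(POSITIVE_CLASS)
    if dataset.n_classes == 2:
        return 1
    raise ValueError(
        f"cannot infer positive class; expected {POSITIVE_CLASS!r} in class names"
    )


def _aggregate(values: list[float]) -> dict:
    vals = np.array([v for v in values if math.isfinite(v)], dtype=float)
    if vals.size == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n_folds": 0}
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return {"mean": float(vals.mean()), "sd": sd, "n_folds": int(vals.size)}


def _vertical_mean_roc(curves: list, n_points: int = DEFAULT_FPR_GRID_POINTS) -> dict:
    grid = np.linspace(0.0, 1.0, n_points)
    if not curves:
        return {"fpr": grid.tolist(), "tpr": [float("nan")] * n_points}
    tprs = [np.interp(grid, fpr, tpr) for fpr, tpr in curves]
    return {"fpr": grid.tolist(), "tpr": np.mean(tprs, axis=0).tolist()}


def run_comparison(
    dataset: UncertainDataset,
    policies: Sequence[LabelPolicy],
    grid: HyperparameterGrid | dict,
    k: int = 7,
    seed: int = 0,
    *,
    base: Hyperparameters | None = None,
    selection_metric: str = "f1",
    threshold: float = 0.5,
    fold_plan: FoldPlan | None = None,
) -> list[MetricsReport]:
    """Nested-CV comparison of label policies on one dataset.

    A single fold plan (and a single family of tree seeds, derived from
    ``seed`` and fold indices only) is shared by all policies, so the
    policies see identical outer test samples and identical random
    streams — the comparison is exactly paired, and a policy that
    produces identical training data (e.g. ``probabilistic`` with
    ``posthoc_probability=1`` vs ``naive``) produces an identical
    report.

    ``grid`` may be a single :class:`HyperparameterGrid` shared by all
    policies or a mapping from policy name to grid.
    """
    if base is None:
        base = Hyperparameters()
    plan = fold_plan if fold_plan is not None else build_fold_plan(dataset.nominal, k, seed)
    positive_index = _positive_index(dataset)
    reports = []
    for policy in policies:
        pol_grid = grid[policy.name] if isinstance(grid, dict) else grid
        aligned, mask = _policy_view(dataset, policy)
        folds = []
        curves = []
        for i, (train_idx, test_idx) in enumerate(plan.outer):
            chosen = select_hyperparameters(
                dataset,
                plan.inner[i],
                pol_grid,
                policy,
                base,
                (seed, 2, i),
                metric=selection_metric,
                threshold=threshold,
            )
            tr = train_idx[mask[train_idx]]
            hp = chosen.with_seed(_derive_seed(seed, 3, i))
            model = fit_forest(aligned.subset(tr), hp)
            ev = evaluate_fold(model, dataset, test_idx, positive_index, threshold)
            if ev is None:
                folds.append({"fold": i, "skipped": True,
                              "reason": "no confirmed samples in test fold"})
                continue
            prf = precision_recall_f1(ev.tp, ev.fp, ev.fn)
            if ev.labels.any() and not ev.labels.all():
                fpr, tpr, auc = roc_auc(ev.scores, ev.labels)
                curves.append((fpr, tpr))
                roc_dict = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
            else:
                auc, roc_dict = float("nan"), None
            folds.append(
                {
                    "fold": i,
                    "skipped": False,
                    "tp": ev.tp, "fp": ev.fp, "fn": ev.fn, "tn": ev.tn,
                    "n_test_confirmed": ev.n_confirmed,
                    "auc": auc,
                    "recall": prf.recall,
                    "precision": prf.precision,
                    "f1": prf.f1,
                    "degenerate_f1": prf.degenerate,
                    "selected_hyperparameters": {
                        "n_trees": chosen.n_trees,
                        "max_features": chosen.max_features,
                        "min_samples_split": chosen.min_samples_split,
                        "min_samples_leaf": chosen.min_samples_leaf,
                    },
                    "roc": roc_dict,
                }
            )
        summary = {
            m: _aggregate([f[m] for f in folds if not f.get("skipped")])
            for m in _METRICS
        }
        reports.append(
            MetricsReport(
                policy=policy.name,
                posthoc_probability=policy.posthoc_probability,
                k=plan.k,
                seed=seed,
                folds=folds,
                summary=summary,
                mean_roc=_vertical_mean_roc(curves),
                manifest={
                    "package": "prforest",
                    "version": _pkg_version,
                    "grid": pol_grid.to_dict(),
                    "selection_metric": selection_metric,
                    "threshold": threshold,
                },
            )
        )
    return reports
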