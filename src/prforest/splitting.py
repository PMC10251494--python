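"""Split-search primitives for probabilistic trees.

These routines operate on a *node*: a set of training samples together
with the probability mass with which each has arrived there.  A split on
feature ``j`` at threshold ``t`` sends each sample to the right child
with the probability that a Gaussian centred on its feature value (std =
its uncertainty) exceeds ``t``, and to the left child with the
complement; samples therefore populate both children fractionally.  When
all uncertainties are zero the propagation degenerates to deterministic
CART routing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

__all__ = [
    "SplitSpec",
    "gaussian_right_probability",
    "right_probabilities",
    "node_class_distribution",
    "modified_gini",
    "split_cost",
    "candidate_thresholds",
    "find_best_split",
]

_SQRT2 = math.sqrt(2.0)

#: Cost differences below this are ties.  Candidates whose cost lies
#: within TIE_TOL of the minimum are considered equal-cost and the one
#: with the lowest (feature index, threshold) wins; a split must beat
#: the parent impurity by more than TIE_TOL to count as an improvement.
#: Exactly equal real-arithmetic costs (e.g. two features inducing the
#: same sample partition) then resolve identically regardless of
#: floating-point summation order, so independent implementations agree
#: on whole split sequences.
TIE_TOL = 1e-10


@dataclass(frozen=True)
class SplitSpec:
    """A binary decision rule: route right iff ``x[feature_index] > threshold``."""

    feature_index: int
    threshold: float


def gaussian_right_probability(x: float, dx: float, t: float) -> float:
    """P(X > t) for X ~ Normal(mean ``x``, std ``dx``).

    With ``dx == 0`` this is the step function used by deterministic
    trees: 1 if ``x > t`` else 0.

    Raises
    ------
    ValueError
        If ``dx`` is negative.
    """
    if dx < 0:
        raise ValueError("feature uncertainty dx must be non-negative")
    if dx == 0:
        return 1.0 if x > t else 0.0
    return 0.5 * math.erfc((t - x) / (dx * _SQRT2))


def right_probabilities(x: np.ndarray, dx: np.ndarray, t: float) -> np.ndarray:
    """Vectorized :func:`gaussian_right_probability` over samples."""
    x = np.asarray(x, dtype=float)
    dx = np.asarray(dx, dtype=float)
    if np.any(dx < 0):
        raise ValueError("feature uncertainty dx must be non-negative")
    out = (x > t).astype(float)
    soft = dx > 0
    if soft.any():
        out[soft] = 0.5 * erfc((t - x[soft]) / (dx[soft] * _SQRT2))
    return out


def node_class_distribution(
    arrival_probs: np.ndarray,
    label_pmfs: np.ndarray,
    class_weights: np.ndarray,
) -> np.ndarray:
    """Class distribution of a node from soft labels and arrival masses.

    Each sample contributes ``arrival * class_weight[c] * pmf[c]`` to
    class ``c``; the result is normalized to sum to 1.

    Raises
    ------
    ValueError
        If the total contributed mass is zero (a degenerate node the
        caller must never have created).
    """
    arrival = np.asarray(arrival_probs, dtype=float)
    pmfs = np.asarray(label_pmfs, dtype=float)
    w = np.asarray(class_weights, dtype=float)
    mass = arrival @ pmfs * w
    total = mass.sum()
    if total <= 0:
        raise ValueError("degenerate node: zero total class mass")
    return mass / total


def modified_gini(class_distribution: np.ndarray) -> float:
    """Gini impurity ``1 - sum_c p_c^2`` of a (soft) class distribution."""
    p = np.asarray(class_distribution, dtype=float)
    return float(1.0 - np.dot(p, p))


def _child_masses(
    X_col: np.ndarray,
    DX_col: np.ndarray,
    arrival: np.ndarray,
    threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample arrival masses in the (left, right) children."""
    p_right = right_probabilities(X_col, DX_col, threshold)
    right = arrival * p_right
    left = arrival - right
    return left, right


def split_cost(
    X_col: np.ndarray,
    DX_col: np.ndarray,
    arrival: np.ndarray,
    label_pmfs: np.ndarray,
    threshold: float,
    class_weights: np.ndarray,
) -> float:
    """Mass-weighted mean Gini impurity of the two children of a split.

    The children's class distributions are formed with
    :func:`node_class_distribution`; the mixing weights are the
    children's effective (arrival) masses divided by the parent mass.
    A candidate that sends all mass to one side returns the parent
    impurity, a no-gain sentinel the search treats as non-improving.
    """
    left, right = _child_masses(X_col, DX_col, arrival, threshold)
    m_left = left.sum()
    m_right = right.sum()
    m_parent = m_left + m_right
    if m_parent <= 0:
        raise ValueError("split_cost requires positive arrival mass")
    parent_gini = modified_gini(
        node_class_distribution(arrival, label_pmfs, class_weights)
    )
    if m_left <= 0 or m_right <= 0:
        return parent_gini
    g_left = modified_gini(node_class_distribution(left, label_pmfs, class_weights))
    g_right = modified_gini(node_class_distribution(right, label_pmfs, class_weights))
    return (m_left * g_left + m_right * g_right) / m_parent


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted feature values.

    If a midpoint is not strictly between its neighbours (adjacent
    floats), the lower value itself is used so that routing by
    ``x > t`` always realizes the intended partition.
    """
    v = np.unique(np.asarray(values, dtype=float))
    if v.size < 2:
        return np.empty(0)
    mid = 0.5 * (v[:-1] + v[1:])
    bad = ~((v[:-1] < mid) & (mid < v[1:]))
    mid[bad] = v[:-1][bad]
    return mid


def find_best_split(
    X: np.ndarray,
    DX: np.ndarray,
    arrival: np.ndarray,
    label_pmfs: np.ndarray,
    feature_subset: np.ndarray,
    class_weights: np.ndarray,
    *,
    min_samples_leaf: float = 1.0,
    keep_probability: float = 0.0,
) -> tuple[SplitSpec, float] | None:
    """Best (lowest-cost) split of a node over a feature subset.

    Candidate thresholds per feature are midpoints between consecutive
    distinct values among the samples whose arrival mass exceeds
    ``keep_probability``.  Both children must retain effective mass of
    at least ``min_samples_leaf``.  All candidates whose cost lies
    within :data:`TIE_TOL` of the minimum are ties, broken by lower
    feature index then lower threshold.  Returns ``(spec, cost)`` or
    ``None`` when no candidate reduces the parent impurity by more than
    :data:`TIE_TOL`.
    """
    feature_subset = np.asarray(feature_subset, dtype=np.int64)
    if feature_subset.size == 0:
        raise ValueError("feature_subset must not be empty")
    parent_gini = modified_gini(
        node_class_distribution(arrival, label_pmfs, class_weights)
    )
    visible = arrival > keep_probability
    scored: list[tuple[float, int, float]] = []  # canonical candidate order
    for j in np.sort(feature_subset):
        for t in candidate_thresholds(X[visible, j]):
            left, right = _child_masses(X[:, j], DX[:, j], arrival, float(t))
            m_left, m_right = left.sum(), right.sum()
            if m_left < min_samples_leaf or m_right < min_samples_leaf:
                continue
            if m_left <= 0 or m_right <= 0:
                continue
            g_left = modified_gini(
                node_class_distribution(left, label_pmfs, class_weights)
            )
            g_right = modified_gini(
                node_class_distribution(right, label_pmfs, class_weights)
            )
            cost = (m_left * g_left + m_right * g_right) / (m_left + m_right)
            scored.append((cost, int(j), float(t)))
    if not scored:
        return None
    min_cost = min(c for c, _, _ in scored)
    if min_cost >= parent_gini - TIE_TOL:
        return None
    for cost, j, t in scored:
        if cost <= min_cost + TIE_TOL:
            return SplitSpec(j, t), cost
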