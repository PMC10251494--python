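"""Numba kernels for the zero-feature-uncertainty training path.

When every feature uncertainty is zero the Gaussian crossing
probability is a step function, each training sample travels to exactly
one child with its full mass, and the ``keep_probability`` rule can
never fire.  Tree growth then reduces to a greedy weighted-Gini CART
over per-sample soft class masses, which these kernels implement over
flat node arrays.  The kernels mirror the reference engine's candidate
set (midpoints of consecutive distinct values), leaf-mass constraint,
cost formula, improvement threshold and tie-breaking exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .tree import LEAF, ProbTree

__all__ = ["grow_tree_fast", "predict_dense_tree", "predict_dense_forest"]

_TIE_TOL = 1e-10  # keep equal to splitting.TIE_TOL


@njit(fastmath=False)
def _scan_splits(
    X, w, M, idx, start, end, subset_row, k_feats,
    tot, m_count, min_leaf, pass2, target_cost,
):
    """One canonical-order scan over the node's split candidates.

    With ``pass2`` false, returns ``(min_cost, -1, 0.0)``.  With
    ``pass2`` true, returns the first candidate whose cost is within
    the tie tolerance of ``target_cost`` as ``(cost, feature,
    threshold)`` — i.e. the lowest-(feature, threshold) tie.
    """
    K = M.shape[1]
    m_node = end - start
    Lc = np.empty(K)
    best_cost = np.inf
    for jj in range(k_feats):
        f = subset_row[jj]
        vals = np.empty(m_node)
        for p in range(m_node):
            vals[p] = X[idx[start + p], f]
        # stable sort: tied values keep row order, so scalar reference
        # implementations can reproduce costs bit-for-bit
        order = np.argsort(vals, kind="mergesort")
        wL = 0.0
        for c in range(K):
            Lc[c] = 0.0
        for p in range(m_node - 1):
            i = idx[start + order[p]]
            wL += w[i]
            for c in range(K):
                Lc[c] += w[i] * M[i, c]
            v1 = vals[order[p]]
            v2 = vals[order[p + 1]]
            if v1 >= v2:
                continue
            wR = m_count - wL
            if wL < min_leaf or wR < min_leaf:
                continue
            t = 0.5 * (v1 + v2)
            if not (v1 < t < v2):
                t = v1
            sL = 0.0
            sR = 0.0
            for c in range(K):
                sL += Lc[c]
                sR += tot[c] - Lc[c]
            gL = 1.0
            gR = 1.0
            for c in range(K):
                qL = Lc[c] / sL
                qR = (tot[c] - Lc[c]) / sR
                gL -= qL * qL
                gR -= qR * qR
            cost = (wL * gL + wR * gR) / m_count
            if pass2:
                if cost <= target_cost + _TIE_TOL:
                    return cost, f, t
            elif cost < best_cost:
                best_cost = cost
    return best_cost, -1, 0.0


@njit(fastmath=False)
def _grow_kernel(
    X, w, M,
    min_split, min_leaf, max_depth, k_feats, seed,
    feature, threshold, left, right, dist, mass,
    subset_buf, subset_len,
):
    m_rows, d = X.shape
    K = M.shape[1]
    np.random.seed(seed)

    idx = np.arange(m_rows)
    tmp = np.empty(m_rows, dtype=np.int64)
    perm = np.empty(d, dtype=np.int64)
    tot = np.empty(K)

    # explicit stack: (node_id, start, end, depth)
    cap = feature.shape[0]
    stack = np.empty((cap, 4), dtype=np.int64)
    top = 0
    n_nodes = 1
    stack[top, 0] = 0
    stack[top, 1] = 0
    stack[top, 2] = m_rows
    stack[top, 3] = 0
    top += 1

    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        depth = stack[top, 3]

        m_count = 0.0
        for c in range(K):
            tot[c] = 0.0
        for p in range(start, end):
            i = idx[p]
            m_count += w[i]
            for c in range(K):
                tot[c] += w[i] * M[i, c]
        wsum = 0.0
        for c in range(K):
            wsum += tot[c]
        gini = 1.0
        for c in range(K):
            q = tot[c] / wsum
            dist[node, c] = q
            gini -= q * q
        mass[node] = m_count
        feature[node] = LEAF
        subset_len[node] = -1

        if (
            m_count < min_split
            or gini <= _TIE_TOL
            or (max_depth >= 0 and depth >= max_depth)
            or end - start < 2
        ):
            continue

        # draw the per-node feature subset (partial Fisher-Yates), sorted
        if k_feats == d:
            for j in range(d):
                subset_buf[node, j] = j
        else:
            for j in range(d):
                perm[j] = j
            for j in range(k_feats):
                r = j + np.random.randint(0, d - j)
                t = perm[j]
                perm[j] = perm[r]
                perm[r] = t
            sub = np.sort(perm[:k_feats])
            for j in range(k_feats):
                subset_buf[node, j] = sub[j]
        subset_len[node] = k_feats

        min_cost, _, _ = _scan_splits(
            X, w, M, idx, start, end, subset_buf[node], k_feats,
            tot, m_count, min_leaf, False, 0.0,
        )
        if min_cost == np.inf or min_cost >= gini - _TIE_TOL:
            continue
        _, best_f, best_t = _scan_splits(
            X, w, M, idx, start, end, subset_buf[node], k_feats,
            tot, m_count, min_leaf, True, min_cost,
        )

        # partition idx[start:end] into (<= t | > t) around the split
        nl = 0
        nr = 0
        for p in range(start, end):
            i = idx[p]
            if X[i, best_f] > best_t:
                tmp[nr] = i
                nr += 1
            else:
                idx[start + nl] = i
                nl += 1
        for p in range(nr):
            idx[start + nl + p] = tmp[p]

        feature[node] = best_f
        threshold[node] = best_t
        l_id = n_nodes
        r_id = n_nodes + 1
        n_nodes += 2
        left[node] = l_id
        right[node] = r_id
        stack[top, 0] = l_id
        stack[top, 1] = start
        stack[top, 2] = start + nl
        stack[top, 3] = depth + 1
        top += 1
        stack[top, 0] = r_id
        stack[top, 1] = start + nl
        stack[top, 2] = end
        stack[top, 3] = depth + 1
        top += 1

    return n_nodes


@njit(fastmath=False)
def _predict_kernel(feature, threshold, left, right, dist, X, out):
    n = X.shape[0]
    K = dist.shape[1]
    for i in range(n):
        node = 0
        while feature[node] != LEAF:
            if X[i, feature[node]] > threshold[node]:
                node = right[node]
            else:
                node = left[node]
        for c in range(K):
            out[i, c] += dist[node, c]


def grow_tree_fast(
    X: np.ndarray,
    counts: np.ndarray,
    M: np.ndarray,
    *,
    min_samples_split: float,
    min_samples_leaf: float,
    max_depth: int | None,
    k_feats: int,
    seed: int,
) -> ProbTree:
    """Grow one deterministic-propagation tree.

    ``X``/``counts``/``M`` cover only rows with positive bootstrap
    count; ``M`` holds each row's class-weighted label mass
    (``pmf * class_weight``).
    """
    m, d = X.shape
    cap = 2 * m + 1
    K = M.shape[1]
    feature = np.empty(cap, dtype=np.int32)
    threshold = np.full(cap, np.nan)
    left = np.full(cap, LEAF, dtype=np.int32)
    right = np.full(cap, LEAF, dtype=np.int32)
    dist = np.empty((cap, K))
    mass = np.empty(cap)
    subset_buf = np.empty((cap, k_feats), dtype=np.int32)
    subset_len = np.empty(cap, dtype=np.int32)
    n_nodes = _grow_kernel(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(counts, dtype=np.float64),
        np.ascontiguousarray(M, dtype=np.float64),
        float(min_samples_split),
        float(min_samples_leaf),
        -1 if max_depth is None else int(max_depth),
        int(k_feats),
        np.uint32(seed),
        feature, threshold, left, right, dist, mass,
        subset_buf, subset_len,
    )
    subsets = [
        subset_buf[i, : subset_len[i]].astype(np.int64) if subset_len[i] >= 0 else None
        for i in range(n_nodes)
    ]
    return ProbTree(
        feature[:n_nodes].copy(),
        threshold[:n_nodes].copy(),
        left[:n_nodes].copy(),
        right[:n_nodes].copy(),
        dist[:n_nodes].copy(),
        mass[:n_nodes].copy(),
        subsets=subsets,
    )


def predict_dense_tree(tree: ProbTree, X: np.ndarray) -> np.ndarray:
    """Batch class probabilities of one tree for exactly-known points."""
    out = np.zeros((X.shape[0], tree.n_classes))
    _predict_kernel(
        tree.feature, tree.threshold, tree.left, tree.right, tree.dist,
        np.ascontiguousarray(X, dtype=np.float64), out,
    )
    return out


def predict_dense_forest(trees, X: np.ndarray, K: int) -> np.ndarray:
    """Mean over trees of batch per-tree probabilities (dx = 0 path)."""
    Xc = np.ascontiguousarray(X, dtype=np.float64)
    out = np.zeros((X.shape[0], K))
    for tree in trees:
        _predict_kernel(
            tree.feature, tree.threshold, tree.left, tree.right, tree.dist, Xc, out
        )
    out /= len(trees)
    return out
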