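"""Independent brute-force oracles used by the test suite.

Nothing here calls package internals for its computations: the CART
oracle re-derives every node statistic with scalar arithmetic from raw
arrays, the split oracle enumerates thresholds with scipy's normal
survival function, and the AUC oracle counts concordant pairs.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

TIE_TOL = 1e-10


# ---------------------------------------------------------------------------
# greedy weighted-Gini CART (hard labels), co-walking a fitted tree


class CartOracle:
    """An independently grown greedy weighted-Gini CART.

    Grows itself by *co-walking* a fitted tree: at every node it
    receives only the recorded per-node feature subset (the shared
    randomness), recomputes the best split from scratch with scalar
    arithmetic, and asserts that its own decision matches the fitted
    tree's.  Leaf class distributions are recomputed independently and
    used for :meth:`predict`.
    """

    def __init__(self, X, y, counts, n_classes, min_split, min_leaf, max_depth=None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.counts = np.asarray(counts, dtype=float)
        self.K = int(n_classes)
        self.min_split = float(min_split)
        self.min_leaf = float(min_leaf)
        self.max_depth = max_depth
        n = len(self.y)
        # balanced inverse effective-frequency class weights
        m_c = [0.0] * self.K
        for i in range(n):
            m_c[self.y[i]] += 1.0
        self.cw = [n / (self.K * m) for m in m_c]
        self.leaf_dist: dict[int, list[float]] = {}

    # -- node statistics (scalar, in node row order) ---------------------

    def _node_stats(self, rows):
        m_count = 0.0
        tot = [0.0] * self.K
        for i in rows:
            m_count += self.counts[i]
            for c in range(self.K):
                pmf = 1.0 if self.y[i] == c else 0.0
                tot[c] += self.counts[i] * (pmf * self.cw[c])
        wsum = 0.0
        for c in range(self.K):
            wsum += tot[c]
        gini = 1.0
        dist = [0.0] * self.K
        for c in range(self.K):
            q = tot[c] / wsum
            dist[c] = q
            gini -= q * q
        return m_count, tot, dist, gini

    def _scan(self, rows, subset, m_count, tot):
        """All admissible candidates in canonical order as (cost, f, t)."""
        out = []
        for f in subset:
            vals = [self.X[i, f] for i in rows]
            order = sorted(range(len(rows)), key=lambda p: vals[p])  # stable
            wL = 0.0
            Lc = [0.0] * self.K
            for p in range(len(rows) - 1):
                i = rows[order[p]]
                wL += self.counts[i]
                for c in range(self.K):
                    pmf = 1.0 if self.y[i] == c else 0.0
                    Lc[c] += self.counts[i] * (pmf * self.cw[c])
                v1, v2 = vals[order[p]], vals[order[p + 1]]
                if v1 >= v2:
                    continue
                wR = m_count - wL
                if wL < self.min_leaf or wR < self.min_leaf:
                    continue
                t = 0.5 * (v1 + v2)
                if not (v1 < t < v2):
                    t = v1
                sL = 0.0
                sR = 0.0
                for c in range(self.K):
                    sL += Lc[c]
                    sR += tot[c] - Lc[c]
                gL = 1.0
                gR = 1.0
                for c in range(self.K):
                    qL = Lc[c] / sL
                    qR = (tot[c] - Lc[c]) / sR
                    gL -= qL * qL
                    gR -= qR * qR
                out.append(((wL * gL + wR * gR) / m_count, int(f), float(t)))
        return out

    def check_tree(self, tree) -> int:
        """Co-walk ``tree`` (a ProbTree); returns the number of verified splits."""
        rows0 = [i for i in range(len(self.y)) if self.counts[i] > 0]
        return self._walk(tree, 0, rows0, 0)

    def _walk(self, tree, node, rows, depth) -> int:
        m_count, tot, dist, gini = self._node_stats(rows)
        assert abs(m_count - tree.mass[node]) <= 1e-9 * max(1.0, m_count)
        for c in range(self.K):
            assert abs(dist[c] - tree.dist[node, c]) <= 1e-9
        is_leaf = tree.feature[node] == -1
        stop = (
            m_count < self.min_split
            or gini <= TIE_TOL
            or len(rows) < 2
            or (self.max_depth is not None and depth >= self.max_depth)
        )
        if stop:
            assert is_leaf, "tree split a node the oracle says must stop"
            self.leaf_dist[node] = dist
            return 0
        subset = tree.subsets[node]
        assert subset is not None, "node attempted no split but was splittable"
        cands = self._scan(rows, [int(f) for f in subset], m_count, tot)
        if not cands or min(c for c, _, _ in cands) >= gini - TIE_TOL:
            assert is_leaf, "tree split where the oracle finds no improvement"
            self.leaf_dist[node] = dist
            return 0
        min_cost = min(c for c, _, _ in cands)
        chosen = next(ct for ct in cands if ct[0] <= min_cost + TIE_TOL)
        assert not is_leaf, "oracle finds an improving split but tree stopped"
        assert chosen[1] == int(tree.feature[node]), (
            f"split feature mismatch at node {node}: "
            f"oracle {chosen[1]}, tree {int(tree.feature[node])}"
        )
        assert chosen[2] == float(tree.threshold[node]), (
            f"threshold mismatch at node {node}"
        )
        f, t = chosen[1], chosen[2]
        left_rows = [i for i in rows if self.X[i, f] <= t]
        right_rows = [i for i in rows if self.X[i, f] > t]
        n = 1
        n += self._walk(tree, int(tree.left[node]), left_rows, depth + 1)
        n += self._walk(tree, int(tree.right[node]), right_rows, depth + 1)
        return n

    def predict(self, tree, x) -> np.ndarray:
        node = 0
        while tree.feature[node] != -1:
            f, t = int(tree.feature[node]), float(tree.threshold[node])
            node = int(tree.right[node]) if x[f] > t else int(tree.left[node])
        return np.array(self.leaf_dist[node])


# ---------------------------------------------------------------------------
# exhaustive probabilistic split search (soft labels, Gaussian features)


def right_prob(x, dx, t):
    if dx == 0:
        return 1.0 if x > t else 0.0
    return float(norm.sf(t, loc=x, scale=dx))


def exhaustive_best_split(X, DX, arrival, PMF, class_weights, subset,
                          min_leaf=1.0, keep_probability=0.0):
    """Enumerate every candidate split and apply the documented tie rule.

    Returns ``(spec_feature, spec_threshold, cost)`` or ``None``.  All
    arithmetic is scalar per candidate; the Gaussian tail comes from
    scipy, an independent route from the implementation's erfc.
    """
    n, _ = X.shape
    K = PMF.shape[1]
    parent = _soft_gini(arrival, PMF, class_weights)
    cands = []
    for f in sorted(int(j) for j in subset):
        vis = sorted(set(float(X[i, f]) for i in range(n)
                         if arrival[i] > keep_probability))
        for v1, v2 in zip(vis[:-1], vis[1:]):
            t = 0.5 * (v1 + v2)
            if not (v1 < t < v2):
                t = v1
            right = np.array([arrival[i] * right_prob(X[i, f], DX[i, f], t)
                              for i in range(n)])
            left = arrival - right
            mL, mR = float(left.sum()), float(right.sum())
            if mL < min_leaf or mR < min_leaf or mL <= 0 or mR <= 0:
                continue
            gL = _soft_gini(left, PMF, class_weights)
            gR = _soft_gini(right, PMF, class_weights)
            cands.append(((mL * gL + mR * gR) / (mL + mR), f, t))
    if not cands:
        return None
    min_cost = min(c for c, _, _ in cands)
    if min_cost >= parent - TIE_TOL:
        return None
    cost, f, t = next(ct for ct in cands if ct[0] <= min_cost + TIE_TOL)
    return f, t, cost


def _soft_gini(arrival, PMF, class_weights):
    K = PMF.shape[1]
    mass = [0.0] * K
    for i in range(len(arrival)):
        for c in range(K):
            mass[c] += arrival[i] * PMF[i, c] * class_weights[c]
    tot = sum(mass)
    return 1.0 - sum((m / tot) ** 2 for m in mass)


# ---------------------------------------------------------------------------
# AUC by pair counting (Mann-Whitney concordance, ties = 1/2)


def concordance_auc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
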