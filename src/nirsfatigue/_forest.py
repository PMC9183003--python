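"""Compact random-forest engine for small windowed-biosignal datasets.

Implements the classical bagged-CART ensemble exactly as configured for this
pipeline — bootstrap resampling, Gini split criterion, a random sqrt(p)
feature subset per node, ``min_samples_split`` = 2 (trees grown to purity),
majority vote across trees — with impurity-based feature importances
(mean decrease in impurity, per-tree normalised).  The per-subject feature
selection loop refits a forest after every single-feature elimination inside
every cross-validation fold (thousands of fits per subject on ~20-sample
training sets), so the hot path is compiled with numba; the result is
algorithmically interchangeable with a conventional random-forest
implementation and is cross-checked against one in the test suite.

Tie-breaking conventions (pinned for bit-reproducibility): candidate
features are drawn by partial Fisher-Yates shuffle; among equal-gain splits
the first examined wins; a leaf with a tied class count predicts class 0.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _fit_forest_impl(X, y, n_trees, max_features, min_samples_split, seed):
    n, p = X.shape
    max_nodes = 2 * n + 1
    feat = np.full((n_trees, max_nodes), -1, np.int64)
    thr = np.zeros((n_trees, max_nodes))
    left = np.full((n_trees, max_nodes), -1, np.int64)
    right = np.full((n_trees, max_nodes), -1, np.int64)
    leaf = np.zeros((n_trees, max_nodes), np.int64)
    importances = np.zeros(p)

    np.random.seed(seed)
    featbuf = np.empty(p, np.int64)
    samp = np.empty(n, np.int64)
    part = np.empty(n, np.int64)
    vals = np.empty(n)
    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)

    for t in range(n_trees):
        for i in range(n):
            samp[i] = np.random.randint(0, n)
        imp_t = np.zeros(p)
        n_nodes = 1
        top = 0
        stack_node[top] = 0
        stack_lo[top] = 0
        stack_hi[top] = n
        top = 1
        while top > 0:
            top -= 1
            node = stack_node[top]
            lo = stack_lo[top]
            hi = stack_hi[top]
            m = hi - lo
            c1 = 0
            for i in range(lo, hi):
                c1 += y[samp[i]]
            c0 = m - c1
            if c0 == 0 or c1 == 0 or m < min_samples_split:
                leaf[t, node] = 1 if c1 > c0 else 0
                continue
            gini = 1.0 - (c0 / m) ** 2 - (c1 / m) ** 2

            for j in range(p):
                featbuf[j] = j
            best_gain = -1.0
            best_f = -1
            best_thr = 0.0
            tried = 0
            j = 0
            # draw features without replacement; keep drawing past
            # max_features only while no valid split has been found
            while j < p:
                k = j + np.random.randint(0, p - j)
                tmp = featbuf[j]
                featbuf[j] = featbuf[k]
                featbuf[k] = tmp
                f = featbuf[j]
                j += 1
                tried += 1
                for i in range(m):
                    vals[i] = X[samp[lo + i], f]
                order = np.argsort(vals[:m], kind="mergesort")
                left_c1 = 0
                for i in range(1, m):
                    left_c1 += y[samp[lo + order[i - 1]]]
                    vprev = vals[order[i - 1]]
                    vcur = vals[order[i]]
                    if vprev < vcur:
                        nl = i
                        nr = m - i
                        l1 = left_c1
                        l0 = nl - l1
                        r1 = c1 - l1
                        r0 = nr - r1
                        g = (
                            gini
                            - (nl / m) * (1.0 - (l0 / nl) ** 2 - (l1 / nl) ** 2)
                            - (nr / m) * (1.0 - (r0 / nr) ** 2 - (r1 / nr) ** 2)
                        )
                        if g > best_gain + 1e-15:
                            best_gain = g
                            best_f = f
                            best_thr = 0.5 * (vprev + vcur)
                if tried >= max_features and best_f >= 0:
                    break
            if best_f < 0:
                # all features constant on this node's samples
                leaf[t, node] = 1 if c1 > c0 else 0
                continue

            # stable partition of samp[lo:hi] around the chosen threshold
            nl = 0
            for i in range(lo, hi):
                if X[samp[i], best_f] <= best_thr:
                    part[nl] = samp[i]
                    nl += 1
            nr = nl
            for i in range(lo, hi):
                if X[samp[i], best_f] > best_thr:
                    part[nr] = samp[i]
                    nr += 1
            for i in range(m):
                samp[lo + i] = part[i]

            feat[t, node] = best_f
            thr[t, node] = best_thr
            left[t, node] = n_nodes
            right[t, node] = n_nodes + 1
            imp_t[best_f] += (m / n) * best_gain
            stack_node[top] = n_nodes
            stack_lo[top] = lo
            stack_hi[top] = lo + nl
            top += 1
            stack_node[top] = n_nodes + 1
            stack_lo[top] = lo + nl
            stack_hi[top] = hi
            top += 1
            n_nodes += 2

        s = imp_t.sum()
        if s > 0:
            importances += imp_t / s
    importances /= n_trees
    return feat, thr, left, right, leaf, importances


@njit(cache=True)
def _vote_fractions_impl(feat, thr, left, right, leaf, X):
    n_trees = feat.shape[0]
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        v = 0
        for t in range(n_trees):
            node = 0
            while feat[t, node] >= 0:
                if X[i, feat[t, node]] <= thr[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            v += leaf[t, node]
        out[i] = v / n_trees
    return out


class RandomForest:
    """Bagged Gini decision trees with random feature subsets at each node.

    Parameters mirror the conventional configuration: ``n_trees`` estimators,
    ``max_features='sqrt'`` candidate features per split, Gini criterion,
    ``min_samples_split=2``.  ``vote_fractions`` returns, per sample, the
    fraction of trees voting for the positive class; ``predict`` is the
    majority vote (ties -> class 0).
    """

    def __init__(self, n_trees: int = 10, min_samples_split: int = 2, seed: int = 0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        self.n_trees = int(n_trees)
        self.min_samples_split = int(min_samples_split)
        self.seed = int(seed)
        self._trees = None
        self.feature_importances_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.int64)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_samples, n_features) matching y")
        if X.shape[0] < 1:
            raise ValueError("cannot fit on an empty training set")
        max_features = max(1, int(np.sqrt(X.shape[1])))
        *trees, imp = _fit_forest_impl(
            X, y, self.n_trees, max_features, self.min_samples_split, self.seed
        )
        self._trees = tuple(trees)
        self.feature_importances_ = imp
        return self

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        if self._trees is None:
            raise RuntimeError("forest is not fitted")
        X = np.ascontiguousarray(X, dtype=np.float64)
        return _vote_fractions_impl(*self._trees, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.vote_fractions(X) > 0.5).astype(np.int64)
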