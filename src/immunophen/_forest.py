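"""Small CART regression forest with out-of-bag permutation importance.

Purpose-built for per-gene models with two predictors: every predictor
is a split candidate at every node (no feature subsampling), trees are
grown on bootstrap resamples of the samples, and importances are the
percent increase in out-of-bag MSE when one predictor's values are
permuted among each tree's OOB set. Implemented with numba because the
pipeline fits one forest per gene (thousands of forests per run) and a
general-purpose library forest is orders of magnitude too slow for
that, and does not expose OOB permutation importance.

Trees use variance-reduction (SSE) splits with midpoint thresholds and
a minimum leaf size; ties between equally good splits resolve to the
first (lowest feature index, lowest threshold) candidate, which keeps
results deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LEAF = -1


@njit(cache=True)
def _build_tree(X, y, min_leaf):
    """Grow one CART regression tree; returns flat node arrays.

    X : (n, p) float64, y : (n,) float64 (bootstrap sample).
    """
    n, p = X.shape
    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, _LEAF, dtype=np.int64)
    threshold = np.zeros(max_nodes, dtype=np.float64)
    left = np.zeros(max_nodes, dtype=np.int64)
    right = np.zeros(max_nodes, dtype=np.int64)
    value = np.zeros(max_nodes, dtype=np.float64)

    idx = np.arange(n)
    # stack of (start, end, node_id) over idx, partitioned in place
    stack_start = np.empty(max_nodes, dtype=np.int64)
    stack_end = np.empty(max_nodes, dtype=np.int64)
    stack_node = np.empty(max_nodes, dtype=np.int64)
    stack_start[0], stack_end[0], stack_node[0] = 0, n, 0
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        start, end, node = stack_start[top], stack_end[top], stack_node[top]
        m = end - start
        ysum = 0.0
        for i in range(start, end):
            ysum += y[idx[i]]
        value[node] = ysum / m
        if m < 2 * min_leaf:
            continue

        best_cost = np.inf
        best_f = -1
        best_thr = 0.0
        for f in range(p):
            xv = np.empty(m, dtype=np.float64)
            for i in range(m):
                xv[i] = X[idx[start + i], f]
            order = np.argsort(xv, kind="mergesort")
            ys = np.empty(m, dtype=np.float64)
            xs = np.empty(m, dtype=np.float64)
            for i in range(m):
                ys[i] = y[idx[start + order[i]]]
                xs[i] = xv[order[i]]
            csum = 0.0
            csum2 = 0.0
            tot = 0.0
            tot2 = 0.0
            for i in range(m):
                tot += ys[i]
                tot2 += ys[i] * ys[i]
            for i in range(m - 1):
                csum += ys[i]
                csum2 += ys[i] * ys[i]
                nl = i + 1
                if nl < min_leaf or (m - nl) < min_leaf:
                    continue
                if xs[i + 1] <= xs[i]:
                    continue
                nr = m - nl
                sse = (csum2 - csum * csum / nl) + (
                    (tot2 - csum2) - (tot - csum) * (tot - csum) / nr
                )
                if sse < best_cost - 1e-12:
                    best_cost = sse
                    best_f = f
                    best_thr = 0.5 * (xs[i] + xs[i + 1])
        if best_f < 0:
            continue

        # partition idx[start:end] by the chosen split
        lo = start
        hi = end - 1
        while lo <= hi:
            if X[idx[lo], best_f] <= best_thr:
                lo += 1
            else:
                tmp = idx[lo]
                idx[lo] = idx[hi]
                idx[hi] = tmp
                hi -= 1
        mid = lo
        if mid == start or mid == end:
            continue

        feature[node] = best_f
        threshold[node] = best_thr
        left[node] = n_nodes
        right[node] = n_nodes + 1
        stack_start[top], stack_end[top], stack_node[top] = start, mid, n_nodes
        top += 1
        stack_start[top], stack_end[top], stack_node[top] = mid, end, n_nodes + 1
        top += 1
        n_nodes += 2

    return feature[:n_nodes], threshold[:n_nodes], left[:n_nodes], right[:n_nodes], value[:n_nodes]


@njit(cache=True)
def _predict_one(feature, threshold, left, right, value, x):
    node = 0
    while feature[node] != _LEAF:
        if x[feature[node]] <= threshold[node]:
            node = left[node]
        else:
            node = right[node]
    return value[node]


@njit(cache=True)
def forest_oob_importance(X, y, boot, perms, min_leaf):
    """Fit a forest and compute OOB error and permutation importances.

    Parameters
    ----------
    X : (n, p) float64
    y : (n,) float64
    boot : (T, n) int64
        Bootstrap sample indices per tree.
    perms : (T, p, n) int64
        Random permutations of ``range(n)`` per tree and predictor;
        their restriction to each tree's OOB set defines the shuffle.
    min_leaf : int

    Returns
    -------
    oob_mse : float
        MSE of per-sample OOB-averaged predictions.
    inc_mse : (p,) float64
        100 * (permuted OOB MSE - OOB MSE) / OOB MSE per predictor,
        averaged over trees.
    """
    n, p = X.shape
    T = boot.shape[0]
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    mse0_tot = 0.0
    msep_tot = np.zeros(p)
    used = 0

    inbag = np.zeros(n, dtype=np.bool_)
    for t in range(T):
        Xb = np.empty((n, p), dtype=np.float64)
        yb = np.empty(n, dtype=np.float64)
        for i in range(n):
            Xb[i] = X[boot[t, i]]
            yb[i] = y[boot[t, i]]
        feature, threshold, left, right, value = _build_tree(Xb, yb, min_leaf)

        inbag[:] = False
        for i in range(n):
            inbag[boot[t, i]] = True
        n_oob = 0
        for i in range(n):
            if not inbag[i]:
                n_oob += 1
        if n_oob == 0:
            continue
        oob_idx = np.empty(n_oob, dtype=np.int64)
        j = 0
        for i in range(n):
            if not inbag[i]:
                oob_idx[j] = i
                j += 1

        mse0 = 0.0
        for i in range(n_oob):
            s = oob_idx[i]
            pred = _predict_one(feature, threshold, left, right, value, X[s])
            oob_sum[s] += pred
            oob_cnt[s] += 1.0
            d = y[s] - pred
            mse0 += d * d
        mse0 /= n_oob

        # shuffled OOB ordering per predictor, from the supplied permutation
        xrow = np.empty(p, dtype=np.float64)
        for f in range(p):
            shuffled = np.empty(n_oob, dtype=np.int64)
            j = 0
            for i in range(n):
                cand = perms[t, f, i]
                if not inbag[cand]:
                    shuffled[j] = cand
                    j += 1
                    if j == n_oob:
                        break
            msep = 0.0
            for i in range(n_oob):
                s = oob_idx[i]
                for q in range(p):
                    xrow[q] = X[s, q]
                xrow[f] = X[shuffled[i], f]
                pred = _predict_one(feature, threshold, left, right, value, xrow)
                d = y[s] - pred
                msep += d * d
            msep_tot[f] += msep / n_oob
        mse0_tot += mse0
        used += 1

    oob_mse = 0.0
    n_seen = 0
    for i in range(n):
        if oob_cnt[i] > 0:
            d = y[i] - oob_sum[i] / oob_cnt[i]
            oob_mse += d * d
            n_seen += 1
    oob_mse = oob_mse / n_seen if n_seen > 0 else np.nan

    inc = np.zeros(p)
    if used > 0 and mse0_tot > 0:
        for f in range(p):
            inc[f] = 100.0 * (msep_tot[f] - mse0_tot) / mse0_tot
    return oob_mse, inc


def fit_forest_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    min_leaf: int = 5,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, np.ndarray]:
    """Convenience wrapper: draws bootstrap/permutation randomness from a
    seeded Generator and calls the compiled kernel."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    boot = rng.integers(0, n, size=(n_trees, n), dtype=np.int64)
    perms = np.empty((n_trees, p, n), dtype=np.int64)
    for t in range(n_trees):
        for f in range(p):
            perms[t, f] = rng.permutation(n)
    return forest_oob_importance(X, y, boot, perms, min_leaf)
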