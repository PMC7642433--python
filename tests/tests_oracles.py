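"""Independent brute-force oracles shared by the test suite.

These deliberately re-derive quantities from their definitions without
importing the implementation paths they are used to check.
"""

import numpy as np
import pandas as pd


def nearest_centroid_posteriors(
    expr: pd.DataFrame, labels: pd.Series, X_new: np.ndarray
):
    """Plain standardized nearest-centroid posteriors (no shrinkage).

    delta_k(x) = sum_i (x_i - xbar_ik)^2 / (s_i + s0)^2 - 2 log pi_k,
    with pooled within-class sd s_i, s0 = median(s_i), observed priors;
    posteriors proportional to exp(-delta_k / 2).
    """
    X = expr.to_numpy(dtype=float)
    y = labels.to_numpy()
    classes = sorted(set(y))
    n, K = X.shape[1], len(classes)
    cents = np.column_stack([X[:, y == c].mean(axis=1) for c in classes])
    ssw = np.zeros(X.shape[0])
    for j, c in enumerate(classes):
        ssw += ((X[:, y == c] - cents[:, j : j + 1]) ** 2).sum(axis=1)
    s = np.sqrt(ssw / (n - K))
    s0 = np.median(s)
    priors = np.array([(y == c).mean() for c in classes])
    scores = np.empty((X_new.shape[1], K))
    for j in range(K):
        d = X_new - cents[:, j : j + 1]
        scores[:, j] = (d**2 / (s + s0)[:, None] ** 2).sum(axis=0) - 2 * np.log(
            priors[j]
        )
    logp = -scores / 2
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True), classes
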