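"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimized code paths: modularity by
exhaustive enumeration of joint partitions, LMG by explicit averaging over
orderings, Wilks selection by exhaustive entry orders.
"""

from itertools import product

import numpy as np


def brute_force_barber_q(A: np.ndarray) -> float:
    """Maximum Barber modularity over ALL joint partitions.

    Rows are assigned every labeling into at most ``min(r, c)`` modules (more
    effective modules than that cannot exist in a bipartite partition); for a
    fixed row labeling each column independently joins its best module, or
    stays alone (contribution zero).
    """
    A = np.asarray(A, dtype=float)
    r, c = A.shape
    F = A.sum()
    k, d = A.sum(axis=1), A.sum(axis=0)
    B = A - np.outer(k, d) / F
    n_mod = min(r, c)
    best = -np.inf
    for labels in product(range(n_mod), repeat=r):
        rl = np.array(labels)
        G = np.zeros((n_mod, c))
        for m in range(n_mod):
            G[m] = B[rl == m].sum(axis=0)
        best = max(best, G.max(axis=0).clip(min=0).sum() / F)
    return best


def ols_r2(X: np.ndarray, y: np.ndarray, cols) -> float:
    design = np.column_stack([np.ones(len(y))] +
                             [X[:, j] for j in cols])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = ((y - design @ coef) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - rss / tss
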