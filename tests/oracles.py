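"""Independent reference implementations used only to cross-check the
library. Deliberately naive (loops, brute force) and written against the
mathematical definitions, not against the library code."""

from __future__ import annotations

import numpy as np


def glasso_coordinate_descent(S: np.ndarray, lam: float, n_sweeps: int = 2000, tol: float = 1e-12) -> np.ndarray:
    """Graphical lasso via block coordinate descent on the covariance.

    Textbook algorithm with the L1 penalty on off-diagonal precision
    entries only (so the working covariance keeps W_jj = S_jj): each
    column's off-diagonal block solves a lasso by cyclic coordinate
    descent; the precision is recovered from the final W and the lasso
    coefficients.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))  # lasso coefficients per column
    for _ in range(n_sweeps):
        W_old = W.copy()
        for j in range(p):
            idx = [i for i in range(p) if i != j]
            W11 = W[np.ix_(idx, idx)]
            s12 = S[idx, j]
            beta = B[idx, j].copy()
            for _ in range(200):
                beta_old = beta.copy()
                for k in range(p - 1):
                    r = s12[k] - W11[k] @ beta + W11[k, k] * beta[k]
                    beta[k] = np.sign(r) * max(abs(r) - lam, 0.0) / W11[k, k]
                if np.max(np.abs(beta - beta_old)) < tol:
                    break
            B[idx, j] = beta
            W[idx, j] = W11 @ beta
            W[j, idx] = W[idx, j]
        if np.max(np.abs(W - W_old)) < tol:
            break
    theta = np.zeros((p, p))
    for j in range(p):
        idx = [i for i in range(p) if i != j]
        theta[j, j] = 1.0 / (W[j, j] - W[idx, j] @ B[idx, j])
        theta[idx, j] = -B[idx, j] * theta[j, j]
    return 0.5 * (theta + theta.T)


def partial_correlations_by_regression(X: np.ndarray) -> np.ndarray:
    """Partial correlation of columns i, j as the correlation of the
    residuals after OLS-regressing each on all remaining columns."""
    n, p = X.shape
    rho = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            Z = np.column_stack([np.ones(n), X[:, others]])
            ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
            rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
            rho[i, j] = rho[j, i] = np.corrcoef(ri, rj)[0, 1]
    return rho


def connected_components_union_find(n_nodes: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    parent = list(range(n_nodes))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, set[int]] = {}
    for v in range(n_nodes):
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())


def nc_score_pairwise(x, y) -> float:
    """(C - D) / (C + D) by explicit enumeration of all sample pairs."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    c = d = 0
    for s1 in range(n):
        for s2 in range(s1 + 1, n):
            prod = (x[s1] - x[s2]) * (y[s1] - y[s2])
            if prod > 0:
                c += 1
            elif prod < 0:
                d += 1
    if c + d == 0:
        return 0.0
    return (c - d) / (c + d)


def bh_adjust_min_over_tail(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        q[i] = min(running_min, 1.0)
    return q


def quantile_bins_by_sorting(values, n_bins: int) -> np.ndarray:
    """Quantile levels computed from an explicit sort (type-7 quantiles)."""
    v = np.asarray(values, dtype=float)
    srt = np.sort(v)
    n = len(v)
    cuts = []
    for j in range(1, n_bins):
        h = (n - 1) * j / n_bins
        lo = int(np.floor(h))
        cuts.append(srt[lo] + (h - lo) * (srt[min(lo + 1, n - 1)] - srt[lo]))
    levels = np.ones(n, dtype=int)
    for cut in cuts:
        levels += v > cut
    return levels
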