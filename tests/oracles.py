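"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: dense matrix powers for
the penalized CCA eigenproblem, a triple-loop topological overlap, an
exhaustive GSEA running sum, and an indicator-matrix CA via plain SVD.
"""

import numpy as np
import pandas as pd
from scipy import linalg


def dense_grcca_oracle(X, Y, groups, lam, mu):
    """maximize w_x' C_xy w_y s.t. w_x' R w_x = 1, w_y' C_yy w_y = 1 (dense)."""
    n = X.shape[0]
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    Cxy = Xs.T @ Ys / (n - 1)
    Cyy = Ys.T @ Ys / (n - 1)
    p = X.shape[1]
    R = np.zeros((p, p))
    for g in np.unique(groups):
        idx = np.nonzero(np.asarray(groups) == g)[0]
        B = np.ones((len(idx), len(idx))) / len(idx)
        R[np.ix_(idx, idx)] = lam * (np.eye(len(idx)) - B) + mu * B
    R_m = linalg.fractional_matrix_power(R, -0.5).real
    C_m = linalg.fractional_matrix_power(Cyy, -0.5).real
    U, s, Vt = np.linalg.svd(R_m @ Cxy @ C_m)
    wx = R_m @ U[:, 0]
    wy = C_m @ Vt[0]
    lc = abs(np.corrcoef(Xs @ wx, Ys @ wy)[0, 1])
    return wx, wy, lc


def tom_loop_oracle(A):
    n = A.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            out[i, j] = (l + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
    return out


def brute_force_es(ranked: pd.Series, gene_set) -> float:
    hits = set(gene_set)
    total = sum(abs(v) for g, v in ranked.items() if g in hits)
    n = len(ranked)
    nh = len([g for g in ranked.index if g in hits])
    running, best = 0.0, 0.0
    for g, v in ranked.items():
        if g in hits:
            running += abs(v) / total
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def indicator_ca_oracle(table: pd.DataFrame):
    cols, names = [], []
    for var in table.columns:
        for lvl in sorted(table[var].astype(str).unique()):
            names.append(f"{var}={lvl}")
            cols.append((table[var].astype(str) == lvl).astype(float).to_numpy())
    Z = np.column_stack(cols)
    P = Z / Z.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = np.diag(r**-0.5) @ (P - np.outer(r, c)) @ np.diag(c**-0.5)
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    keep = s > 1e-12
    rows = np.diag(r**-0.5) @ U[:, keep] * s[keep]
    loadings = np.diag(c**-0.5) @ Vt[keep].T * s[keep]
    return rows, loadings, s[keep] ** 2
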