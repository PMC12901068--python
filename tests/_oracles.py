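"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — nested loops, exhaustive enumeration,
direct normal-equations algebra — and shares no code with the library paths
it checks.
"""

from __future__ import annotations

import numpy as np

from edgedyn.extrema import _passes


def edge_pairs_nested_loop(n_nodes: int) -> list[tuple[int, int]]:
    pairs = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i < j:
                pairs.append((i, j))
    return pairs


def rss_explicit_loop(z: np.ndarray) -> np.ndarray:
    """RSS per timepoint by explicit python loop over every node pair."""
    T, n = z.shape
    out = np.zeros(T)
    for t in range(T):
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                total += (z[t, i] * z[t, j]) ** 2
        out[t] = np.sqrt(total)
    return out


def troughs_neighbor_scan(v: np.ndarray) -> list[int]:
    """Every interior index strictly below both neighbours."""
    return [t for t in range(1, len(v) - 1) if v[t] < v[t - 1] and v[t] < v[t + 1]]


def interval_max_peaks(v: np.ndarray, troughs) -> list[tuple[int, float]]:
    """Earliest maximum in each open inter-trough interval."""
    out = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        best_idx = a + 1
        for t in range(a + 1, b):
            if v[t] > v[best_idx]:
                best_idx = t
        out.append((best_idx, v[best_idx]))
    return out


def adjacent_peak_max_subsets(v: np.ndarray, base_troughs, theta: float) -> list[tuple]:
    """All maximum-cardinality trough subsets satisfying the flanking-peak
    percent test, by exhaustive enumeration (feasible for <= 12 troughs)."""
    best: list[tuple] = []
    best_k = -1
    n = len(base_troughs)
    for mask in range(1 << n):
        sel = [base_troughs[i] for i in range(n) if mask >> i & 1]
        bounds = [-1] + sel + [len(v)]
        ok = True
        for j, t in enumerate(sel):
            left = v[bounds[j] + 1 : t]
            right = v[t + 1 : bounds[j + 2]]
            ref = min(
                left.max() if left.size else -np.inf,
                right.max() if right.size else -np.inf,
            )
            if not _passes(v[t], ref, theta):
                ok = False
                break
        if ok:
            if len(sel) > best_k:
                best, best_k = [tuple(sel)], len(sel)
            elif len(sel) == best_k:
                best.append(tuple(sel))
    return best


def ancova_normal_equations(y, group01, age, volume):
    """From-scratch OLS via normal equations: coefficients, group F (extra sum
    of squares), and grand-mean adjusted group means with SEs."""
    n = len(y)
    X = np.column_stack([np.ones(n), group01, age, volume])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    ssr_full = float(resid @ resid)
    df_den = n - 4

    Xr = np.delete(X, 1, axis=1)
    beta_r = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
    resid_r = y - Xr @ beta_r
    ssr_red = float(resid_r @ resid_r)
    f = (ssr_red - ssr_full) / (ssr_full / df_den)

    sigma2 = ssr_full / df_den
    cov = sigma2 * np.linalg.inv(XtX)
    means = {}
    for g, ind in ((0, 0.0), (1, 1.0)):
        c = np.array([1.0, ind, age.mean(), volume.mean()])
        means[g] = (float(c @ beta), float(np.sqrt(c @ cov @ c)))
    return {"beta": beta, "f": f, "df_den": df_den, "adjusted": means}
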