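"""Numba kernels for weighted graph metrics.

These inner loops (all-pairs shortest paths, neighborhood local
efficiency, Brandes betweenness) dominate the cost of sweeping the
density grid over whole cohorts, so they are jitted. Lengths use
``np.inf`` for absent edges and 0 on the diagonal. Tie comparisons use a
small absolute tolerance so exact-arithmetic ties (binary graphs) are
shared fractionally while float ties in continuous data remain
effectively impossible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TIE_TOL = 1e-12


@njit(cache=True)
def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances; input is not modified."""
    D = lengths.copy()
    n = D.shape[0]
    for k in range(n):
        for i in range(n):
            dik = D[i, k]
            if dik == np.inf:
                continue
            for j in range(n):
                alt = dik + D[k, j]
                if alt < D[i, j]:
                    D[i, j] = alt
    return D


@njit(cache=True)
def floyd_warshall_predecessors(lengths: np.ndarray):
    """Distances plus a predecessor matrix (-1 marks unreachable/self)."""
    D = lengths.copy()
    n = D.shape[0]
    pred = np.full((n, n), -1, dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i != j and D[i, j] != np.inf:
                pred[i, j] = i
    for k in range(n):
        for i in range(n):
            dik = D[i, k]
            if dik == np.inf:
                continue
            for j in range(n):
                alt = dik + D[k, j]
                if alt < D[i, j]:
                    D[i, j] = alt
                    pred[i, j] = pred[k, j]
    return D, pred


@njit(cache=True)
def local_efficiency_nodes(w: np.ndarray) -> np.ndarray:
    """Per-node weighted local efficiency (connectivity-toolbox form).

    For node u with neighbors V: the numerator sums
    (w_ua w_ub)^(1/3) / d_ab over ordered neighbor pairs, where d_ab are
    shortest paths within the neighborhood subgraph on cube-root
    lengths; the denominator is k_u (k_u - 1). Nodes with fewer than two
    neighbors score 0.
    """
    n = w.shape[0]
    out = np.zeros(n)
    L3 = np.empty_like(w)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                L3[i, j] = (1.0 / w[i, j]) ** (1.0 / 3.0)
            else:
                L3[i, j] = np.inf
    for u in range(n):
        k = 0
        for v in range(n):
            if w[u, v] > 0:
                k += 1
        if k < 2:
            continue
        nbrs = np.empty(k, dtype=np.int64)
        k = 0
        for v in range(n):
            if w[u, v] > 0:
                nbrs[k] = v
                k += 1
        D = np.empty((k, k))
        for a in range(k):
            for b in range(k):
                D[a, b] = 0.0 if a == b else L3[nbrs[a], nbrs[b]]
        for m in range(k):
            for a in range(k):
                dam = D[a, m]
                if dam == np.inf:
                    continue
                for b in range(k):
                    alt = dam + D[m, b]
                    if alt < D[a, b]:
                        D[a, b] = alt
        sw = np.empty(k)
        for a in range(k):
            sw[a] = w[u, nbrs[a]] ** (1.0 / 3.0)
        num = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and D[a, b] != np.inf and D[a, b] > 0:
                    num += sw[a] * sw[b] / D[a, b]
        out[u] = num / (k * (k - 1))
    return out


@njit(cache=True)
def betweenness_nodes(lengths: np.ndarray) -> np.ndarray:
    """Brandes betweenness on a weighted length matrix.

    Shortest-path multiplicity is shared fractionally across equal-length
    paths. Output is normalized by (N-1)(N-2), i.e. the fraction of
    ordered source-target pairs (excluding the node itself) whose
    shortest paths pass through each node.
    """
    n = lengths.shape[0]
    bc = np.zeros(n)
    if n < 3:
        return bc
    dist = np.empty(n)
    sigma = np.empty(n)
    visited = np.empty(n, dtype=np.bool_)
    order = np.empty(n, dtype=np.int64)
    preds = np.empty((n, n), dtype=np.int64)
    npred = np.empty(n, dtype=np.int64)
    delta = np.empty(n)
    for s in range(n):
        for v in range(n):
            dist[v] = np.inf
            sigma[v] = 0.0
            visited[v] = False
            npred[v] = 0
            delta[v] = 0.0
        dist[s] = 0.0
        sigma[s] = 1.0
        n_order = 0
        while True:
            u = -1
            best = np.inf
            for v in range(n):
                if not visited[v] and dist[v] < best:
                    best = dist[v]
                    u = v
            if u == -1:
                break
            visited[u] = True
            order[n_order] = u
            n_order += 1
            du = dist[u]
            for v in range(n):
                if visited[v] or v == u:
                    continue
                luv = lengths[u, v]
                if luv == np.inf:
                    continue
                alt = du + luv
                if alt < dist[v] - _TIE_TOL:
                    dist[v] = alt
                    sigma[v] = sigma[u]
                    preds[v, 0] = u
                    npred[v] = 1
                elif abs(alt - dist[v]) <= _TIE_TOL:
                    sigma[v] += sigma[u]
                    preds[v, npred[v]] = u
                    npred[v] += 1
        for idx in range(n_order - 1, -1, -1):
            wnode = order[idx]
            coeff = (1.0 + delta[wnode]) / sigma[wnode]
            for pi in range(npred[wnode]):
                v = preds[wnode, pi]
                delta[v] += sigma[v] * coeff
            if wnode != s:
                bc[wnode] += delta[wnode]
    return bc / ((n - 1.0) * (n - 2.0))
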