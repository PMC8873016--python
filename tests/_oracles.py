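"""Independent brute-force reference implementations used only by tests.

Everything here is written for clarity, not speed: pure-python triple
loops, exhaustive triangle and path enumeration. These serve as oracles
for the package's vectorized/jitted metric implementations and must stay
independent of them.
"""

from __future__ import annotations

import math

import numpy as np

INF = math.inf


def lengths_of(w: np.ndarray) -> list[list[float]]:
    n = w.shape[0]
    return [
        [0.0 if i == j else (1.0 / w[i][j] if w[i][j] > 0 else INF)
         for j in range(n)]
        for i in range(n)
    ]


def floyd_ref(L: list[list[float]]) -> list[list[float]]:
    n = len(L)
    D = [row[:] for row in L]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]
    return D


def global_eff_ref(w: np.ndarray) -> float:
    D = floyd_ref(lengths_of(w))
    n = len(D)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and D[i][j] < INF:
                total += 1.0 / D[i][j]
    return total / (n * (n - 1))


def nodal_eff_ref(w: np.ndarray) -> list[float]:
    D = floyd_ref(lengths_of(w))
    n = len(D)
    out = []
    for i in range(n):
        s = sum(1.0 / D[i][j] for j in range(n) if j != i and D[i][j] < INF)
        out.append(s / (n - 1))
    return out


def path_length_ref(w: np.ndarray) -> tuple[float, int]:
    D = floyd_ref(lengths_of(w))
    n = len(D)
    finite = [D[i][j] for i in range(n) for j in range(n)
              if i != j and D[i][j] < INF]
    n_inf = n * (n - 1) - len(finite)
    return sum(finite) / len(finite), n_inf


def clustering_ref(w: np.ndarray) -> float:
    """Onnela weighted clustering via explicit triangle enumeration."""
    n = w.shape[0]
    mx = w.max()
    what = w / mx if mx > 0 else w
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        tri = 0.0
        for a in range(k):
            for b in range(k):
                j, l = nbrs[a], nbrs[b]
                if j != l and w[j][l] > 0:
                    tri += (what[i][j] * what[j][l] * what[l][i]) ** (1 / 3)
        cs.append(tri / (k * (k - 1)))
    return sum(cs) / n


def local_eff_ref(w: np.ndarray) -> float:
    """Direct summation of the weighted neighborhood-efficiency formula."""
    n = w.shape[0]
    es = []
    for u in range(n):
        nbrs = [v for v in range(n) if w[u][v] > 0]
        k = len(nbrs)
        if k < 2:
            es.append(0.0)
            continue
        sub = [[0.0 if a == b else
                ((1.0 / w[nbrs[a]][nbrs[b]]) ** (1 / 3)
                 if w[nbrs[a]][nbrs[b]] > 0 else INF)
                for b in range(k)] for a in range(k)]
        D = floyd_ref(sub)
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and 0 < D[a][b] < INF:
                    total += (w[u][nbrs[a]] * w[u][nbrs[b]]) ** (1 / 3) / D[a][b]
        es.append(total / (k * (k - 1)))
    return sum(es) / n


def _all_shortest_paths(L, D, s, t, tol=1e-9):
    """Enumerate every shortest s->t path by pruned depth-first search."""
    n = len(L)
    paths = []
    target = D[s][t]

    def extend(node, dist, path):
        if node == t:
            paths.append(path[:])
            return
        for v in range(n):
            if L[node][v] < INF and v not in path:
                nd = dist + L[node][v]
                if nd + D[v][t] <= target + tol:
                    path.append(v)
                    extend(v, nd, path)
                    path.pop()

    extend(s, 0.0, [s])
    return paths


def betweenness_ref(w: np.ndarray) -> list[float]:
    """Betweenness by exhaustive shortest-path enumeration.

    Fractional sharing over equal-length paths; normalized by
    (N-1)(N-2) ordered source-target pairs.
    """
    L = lengths_of(w)
    D = floyd_ref(L)
    n = len(L)
    bc = [0.0] * n
    for s in range(n):
        for t in range(n):
            if s == t or D[s][t] == INF:
                continue
            paths = _all_shortest_paths(L, D, s, t)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return [b / ((n - 1) * (n - 2)) for b in bc]


def threshold_ref(z: np.ndarray, kappa: float) -> set[tuple[int, int]]:
    """Sort-and-cut reference for proportional thresholding."""
    n = z.shape[0]
    edges = [(float(z[i][j]), i, j) for i in range(n) for j in range(i + 1, n)
             if z[i][j] > 0]
    K = int(np.round(kappa * n * (n - 1) / 2))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    return {(i, j) for _, i, j in edges[: min(K, len(edges))]}


def bh_ref(pvals, level):
    """Benjamini-Hochberg step-up: returns boolean rejections."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * level / m:
            k_max = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_max:
            reject[idx] = True
    return reject
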