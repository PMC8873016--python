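"""Weighted graph topology over a density (sparsity) grid.

A Fisher-z connectivity matrix is reduced to a sequence of weighted
graphs by proportional thresholding across a grid of edge densities
(default 10%-34% in 1% steps), global and nodal metrics are computed at
every density, and each metric's curve is summarized by its area under
the curve (AUC) over the grid — the subject-level outcome used for
group inference, chosen to avoid committing to a single arbitrary
threshold.

Conventions (documented, configurable where noted):

- negative and zero Fisher-z edges are removed before thresholding
  (``edge_sign="positive"``; ``"absolute"`` keeps |z| instead);
- metrics run on the raw retained Fisher-z weights by default;
  per-subject max-normalization to (0, 1] is available as an option
  (it discards overall-strength differences, keeping pure topology);
- edge weight w maps to length 1/w for path-based metrics;
- "degree" is the binary count of suprathreshold edges (weighted
  strength exposed separately);
- disconnected pairs contribute 0 to efficiencies and are excluded
  (but counted) in the characteristic path length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .connectome import ConnectivityMatrix

__all__ = [
    "DensityGrid",
    "WeightedGraph",
    "MetricCurves",
    "proportional_threshold",
    "to_length_matrix",
    "shortest_path_matrix",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "characteristic_path_length",
    "clustering_coefficient",
    "nodal_degree",
    "nodal_strength",
    "betweenness",
    "metric_curves",
    "auc",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]

GLOBAL_METRICS = ("E_glob", "E_loc", "L_p", "C_p")
NODAL_METRICS = ("degree", "E_nodal", "betweenness")


@dataclass(frozen=True)
class DensityGrid:
    """Inclusive grid of edge densities kappa_min, kappa_min+step, ..., kappa_max."""

    kappa_min: float = 0.10
    kappa_max: float = 0.34
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.kappa_min < self.kappa_max < 1):
            raise ValueError("require 0 < kappa_min < kappa_max < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")
        n = round((self.kappa_max - self.kappa_min) / self.step)
        last = self.kappa_min + n * self.step
        if abs(last - self.kappa_max) > 1e-12:
            raise ValueError("kappa_max must be reachable from kappa_min in whole steps")

    @property
    def values(self) -> np.ndarray:
        n = round((self.kappa_max - self.kappa_min) / self.step)
        return self.kappa_min + self.step * np.arange(n + 1)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class WeightedGraph:
    """Non-negative symmetric weight matrix produced by thresholding."""

    w: np.ndarray
    kappa: float | None = None
    n_edges_target: int | None = None
    all_positive_retained: bool = False

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")
        if np.max(np.abs(self.w - self.w.T)) > 1e-12:
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.w, k=1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def normalized(self) -> "WeightedGraph":
        """Weights rescaled by the maximum to (0, 1]."""
        mx = self.w.max()
        w = self.w / mx if mx > 0 else self.w.copy()
        return WeightedGraph(w=w, kappa=self.kappa,
                             n_edges_target=self.n_edges_target,
                             all_positive_retained=self.all_positive_retained)


def _as_weights(graph) -> np.ndarray:
    return graph.w if isinstance(graph, WeightedGraph) else np.asarray(graph, float)


def proportional_threshold(
    fc: ConnectivityMatrix | np.ndarray,
    kappa: float,
    edge_sign: str = "positive",
) -> WeightedGraph:
    """Keep the K = round(kappa * N(N-1)/2) strongest edges.

    Negative and zero z values are removed first (``edge_sign="positive"``)
    or replaced by their magnitude (``"absolute"``); the K largest
    remaining upper-triangular weights are retained, ties broken by
    lexicographic (i, j) order so the retained set is deterministic. If
    fewer than K positive edges exist, all of them are kept and a
    warning is recorded on the graph.
    """
    if not 0 < kappa < 1:
        raise ValueError("kappa must lie in (0, 1)")
    z = fc.z if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    n = z.shape[0]
    if edge_sign == "absolute":
        z = np.abs(z)
    elif edge_sign != "positive":
        raise ValueError("edge_sign must be 'positive' or 'absolute'")
    n_pairs = n * (n - 1) // 2
    K = int(np.round(kappa * n_pairs))
    if K == 0:
        raise ValueError(f"kappa={kappa} yields zero edges for N={n}")
    iu, ju = np.triu_indices(n, k=1)
    wvals = z[iu, ju]
    pos = wvals > 0
    iu, ju, wvals = iu[pos], ju[pos], wvals[pos]
    short = wvals.size < K
    if short:
        warnings.warn(
            f"only {wvals.size} positive edges available for target {K}; "
            "retaining all of them", stacklevel=2,
        )
        keep = np.arange(wvals.size)
    else:
        # stable ranking: strongest first, ties by (i, j)
        order = np.lexsort((ju, iu, -wvals))
        keep = order[:K]
    w = np.zeros_like(z)
    w[iu[keep], ju[keep]] = wvals[keep]
    w = w + w.T
    return WeightedGraph(w=w, kappa=kappa, n_edges_target=K,
                         all_positive_retained=short)


def to_length_matrix(graph) -> np.ndarray:
    """Reciprocal weight-to-length map: 1/w, absent edges +inf, diagonal 0."""
    w = _as_weights(graph)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_path_matrix(lengths: np.ndarray, return_predecessors: bool = False):
    """All-pairs shortest path distances on a non-negative length matrix.

    Unreachable pairs come back as +inf. With ``return_predecessors``
    also returns the predecessor matrix (enough to reconstruct one
    shortest path per pair; fractional multiplicities for betweenness
    are handled by :func:`betweenness`).
    """
    L = np.asarray(lengths, dtype=float)
    if np.any(L[np.isfinite(L)] < 0):
        raise ValueError("lengths must be non-negative")
    if return_predecessors:
        return _kernels.floyd_warshall_predecessors(L)
    return _kernels.floyd_warshall(L)


def _distances(graph) -> np.ndarray:
    return shortest_path_matrix(to_length_matrix(graph))


def global_efficiency(graph, distances: np.ndarray | None = None) -> float:
    """E_glob = mean over ordered pairs of 1/d_ij, with 1/inf = 0."""
    D = _distances(graph) if distances is None else distances
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(D)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(graph, node: int | None = None,
                     distances: np.ndarray | None = None):
    """E_nodal(i) = mean over j != i of 1/d_ij (vector if node is None)."""
    D = _distances(graph) if distances is None else distances
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(D)] = 0.0
    e = inv.sum(axis=1) / (n - 1)
    return e if node is None else float(e[node])


def local_efficiency(graph, per_node: bool = False):
    """Mean (or per-node) neighborhood efficiency, weighted toolbox form."""
    w = _as_weights(graph)
    if w.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    e = _kernels.local_efficiency_nodes(np.ascontiguousarray(w))
    return e if per_node else float(e.mean())


def characteristic_path_length(graph, distances: np.ndarray | None = None
                               ) -> tuple[float, int]:
    """Mean finite shortest-path distance over connected ordered pairs.

    Returns ``(L_p, n_infinite_pairs)``; raises when no pair is
    connected.
    """
    D = _distances(graph) if distances is None else distances
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    vals = D[off]
    finite = np.isfinite(vals)
    n_inf = int((~finite).sum())
    if not finite.any():
        raise ValueError("graph has no connected pair; path length undefined")
    return float(vals[finite].mean()), n_inf


def clustering_coefficient(graph, per_node: bool = False):
    """Weighted clustering via cube-root geometric-mean triangle weights.

    Weights are max-normalized; node i scores the sum over triangles of
    (w_ij w_jk w_ki)^(1/3) divided by k_i (k_i - 1); nodes with fewer
    than two neighbors score 0. Returns the mean over nodes by default.
    """
    w = _as_weights(graph)
    n = w.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    mx = w.max()
    what = np.cbrt(w / mx) if mx > 0 else w.copy()
    cyc3 = np.diag(what @ what @ what)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.divide(cyc3, denom, out=np.zeros(n), where=denom > 0)
    return c if per_node else float(c.mean())


def nodal_degree(graph, node: int | None = None):
    """Binary count of suprathreshold edges incident to each node."""
    w = _as_weights(graph)
    k = (w > 0).sum(axis=1)
    return k if node is None else int(k[node])


def nodal_strength(graph, node: int | None = None):
    """Weighted degree (sum of incident edge weights)."""
    w = _as_weights(graph)
    s = w.sum(axis=1)
    return s if node is None else float(s[node])


def betweenness(graph, node: int | None = None):
    """Fraction of shortest paths between other pairs passing through a node.

    Normalized by (N-1)(N-2) ordered pairs; equal-length shortest paths
    share their contribution fractionally.
    """
    lengths = to_length_matrix(graph)
    b = _kernels.betweenness_nodes(np.ascontiguousarray(lengths))
    return b if node is None else float(b[node])


@dataclass
class MetricCurves:
    """Per-subject metric values across the density grid."""

    grid: DensityGrid
    global_curves: dict[str, np.ndarray]
    nodal_curves: dict[str, np.ndarray]  # (n_nodes, n_kappa)
    disconnected_pairs: np.ndarray = field(default_factory=lambda: np.array([]))
    node_ids: list[str] | None = None

    def auc_frame(self, subject_id: str = "sub") -> pd.DataFrame:
        """Tidy AUC table: one row per global metric and per node x metric."""
        kap = self.grid.values
        rows = []
        for name, curve in self.global_curves.items():
            rows.append((subject_id, name, "GLOBAL", auc(curve, self.grid)))
        for name, mat in self.nodal_curves.items():
            ids = self.node_ids or [f"n{i:04d}" for i in range(mat.shape[0])]
            aucs = np.trapezoid(mat, kap, axis=1)
            rows.extend((subject_id, name, nid, a) for nid, a in zip(ids, aucs))
        return pd.DataFrame(rows, columns=["subject_id", "metric", "node_id", "value"])

    def curve_frame(self, subject_id: str = "sub") -> pd.DataFrame:
        """Tidy curve table: subject_id, metric, node_id-or-GLOBAL, kappa, value."""
        kap = self.grid.values
        rows = []
        for name, curve in self.global_curves.items():
            rows.extend((subject_id, name, "GLOBAL", k, v) for k, v in zip(kap, curve))
        for name, mat in self.nodal_curves.items():
            ids = self.node_ids or [f"n{i:04d}" for i in range(mat.shape[0])]
            for ni, nid in enumerate(ids):
                rows.extend((subject_id, name, nid, k, v)
                            for k, v in zip(kap, mat[ni]))
        return pd.DataFrame(
            rows, columns=["subject_id", "metric", "node_id", "kappa", "value"]
        )


def metric_curves(
    fc: ConnectivityMatrix,
    grid: DensityGrid,
    global_metrics: tuple[str, ...] = GLOBAL_METRICS,
    nodal_metrics: tuple[str, ...] = NODAL_METRICS,
    edge_sign: str = "positive",
    normalize: bool = False,
) -> MetricCurves:
    """Sweep the density grid and compute all requested metrics.

    By default metrics run on the raw Fisher-z weights, so that overall
    connectivity-strength differences between subjects carry through to
    the path-based metrics; ``normalize=True`` max-normalizes weights to
    (0, 1] per thresholded graph instead (the pure-topology convention,
    which discards strength differences). Per-density counts of
    disconnected ordered pairs are recorded alongside the curves.
    """
    unknown = (set(global_metrics) - set(GLOBAL_METRICS)) | (
        set(nodal_metrics) - set(NODAL_METRICS))
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    kap = grid.values
    nk = len(kap)
    n = fc.n_nodes
    gcurves = {m: np.zeros(nk) for m in global_metrics}
    ncurves = {m: np.zeros((n, nk)) for m in nodal_metrics}
    disc = np.zeros(nk, dtype=int)
    for qi, kappa in enumerate(kap):
        g = proportional_threshold(fc, kappa, edge_sign=edge_sign)
        if normalize:
            g = g.normalized()
        need_dist = bool({"E_glob", "L_p"} & set(global_metrics)) or (
            "E_nodal" in nodal_metrics)
        D = _distances(g) if need_dist else None
        if D is not None:
            off = ~np.eye(n, dtype=bool)
            disc[qi] = int(np.isinf(D[off]).sum())
        if "E_glob" in gcurves:
            gcurves["E_glob"][qi] = global_efficiency(g, distances=D)
        if "E_loc" in gcurves:
            gcurves["E_loc"][qi] = local_efficiency(g)
        if "L_p" in gcurves:
            gcurves["L_p"][qi] = characteristic_path_length(g, distances=D)[0]
        if "C_p" in gcurves:
            gcurves["C_p"][qi] = clustering_coefficient(g)
        if "degree" in ncurves:
            ncurves["degree"][:, qi] = nodal_degree(g)
        if "E_nodal" in ncurves:
            ncurves["E_nodal"][:, qi] = nodal_efficiency(g, distances=D)
        if "betweenness" in ncurves:
            ncurves["betweenness"][:, qi] = betweenness(g)
    return MetricCurves(
        grid=grid, global_curves=gcurves, nodal_curves=ncurves,
        disconnected_pairs=disc, node_ids=fc.node_ids,
    )


def auc(curve: np.ndarray, grid: DensityGrid) -> float:
    """Trapezoidal area under a metric curve over the density grid."""
    curve = np.asarray(curve, dtype=float)
    kap = grid.values
    if curve.shape[0] != kap.shape[0]:
        raise ValueError(
            f"curve length {curve.shape[0]} does not match grid length {kap.shape[0]}"
        )
    if curve.shape[0] < 2:
        raise ValueError("need at least 2 grid points for an AUC")
    return float(np.trapezoid(curve, kap))
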