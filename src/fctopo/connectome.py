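"""Functional connectome construction.

Node time series (optionally extracted from a 4D NIfTI image through
5-mm spherical regions of interest) are turned into symmetric Fisher-z
connectivity matrices: Pearson correlation between every pair of node
signals, then z = arctanh(r). Motion scrubbing (dropping time points
whose framewise displacement exceeds a threshold) and an overall
connectivity-strength summary are provided for validation-style
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nodes import NodeSet

__all__ = [
    "ConnectivityMatrix",
    "extract_sphere_timeseries",
    "scrub_timepoints",
    "correlation_matrix",
    "fisher_z",
    "overall_fc_strength",
]

#: |r| is clipped here before arctanh so z stays finite at r = +/-1
R_CLIP = 1 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix bound to a node order.

    Invariants enforced at construction: symmetry within 1e-12, exactly
    zero diagonal, finite entries.
    """

    z: np.ndarray
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity matrix contains non-finite values")
        if np.max(np.abs(self.z - self.z.T)) > 1e-12:
            raise ValueError("connectivity matrix must be symmetric within 1e-12")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("diagonal must be exactly zero")
        if self.node_ids is not None and len(self.node_ids) != n:
            raise ValueError("node_ids length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def to_csv(self, path) -> None:
        """Write as delimited text with node ids as header row and column."""
        ids = self.node_ids or [f"n{i:04d}" for i in range(self.n_nodes)]
        df = pd.DataFrame(self.z, index=ids, columns=ids)
        # repr-precision floats so the round-trip is lossless
        df.to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        z = df.to_numpy(dtype=float)
        z = (z + z.T) / 2  # absorb decimal round-trip asymmetry
        np.fill_diagonal(z, 0.0)
        return cls(z=z, node_ids=[str(c) for c in df.columns])


def extract_sphere_timeseries(
    image_4d,
    affine: np.ndarray | None = None,
    node_set: NodeSet | None = None,
    radius_mm: float = 5.0,
) -> np.ndarray:
    """Average the BOLD signal over a sphere around each node coordinate.

    A voxel belongs to a node's sphere when its center lies within
    ``radius_mm`` (Euclidean distance in millimeter space, inclusive
    boundary) of the node's MNI coordinate; the node signal is the
    unweighted mean over those voxels.

    Parameters
    ----------
    image_4d : ndarray, nibabel image, or path
        Functional image: a ``(nx, ny, nz, t)`` data array (then
        ``affine`` is required), an in-memory NIfTI image, or a path to
        one (the affine is then taken from the image).
    affine : (4, 4) ndarray, optional
        Voxel-to-millimeter affine; required for plain arrays.
    node_set : NodeSet
        Node coordinates in MNI millimeters; output row order follows it.
    radius_mm : float
        Sphere radius, default 5 mm.

    Returns
    -------
    (n_nodes, t) ndarray

    Raises
    ------
    ValueError
        If any node has no voxel within its sphere (bad coverage), the
        error lists the offending node ids.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if isinstance(image_4d, (str, Path)):
        import nibabel as nib

        image_4d = nib.load(str(image_4d))
    if hasattr(image_4d, "get_fdata"):  # nibabel image
        if affine is None:
            affine = image_4d.affine
        image_4d = image_4d.get_fdata()
    if affine is None:
        raise ValueError("affine is required when passing a plain array")
    if node_set is None:
        raise ValueError("node_set is required")
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    nx, ny, nz, nt = image_4d.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    mm = vox @ affine[:3, :3].T + affine[:3, 3]
    flat = image_4d.reshape(-1, nt)

    out = np.empty((node_set.n_nodes, nt))
    empty: list[str] = []
    for i, center in enumerate(node_set.coordinates):
        d2 = np.sum((mm - center) ** 2, axis=1)
        mask = d2 <= radius_mm**2 + 1e-9
        if not mask.any():
            empty.append(node_set.node_ids[i])
            continue
        out[i] = flat[mask].mean(axis=0)
    if empty:
        raise ValueError(f"nodes with no in-sphere voxels (bad coverage): {empty}")
    return out


def scrub_timepoints(
    timeseries: np.ndarray,
    fd_series: np.ndarray,
    fd_threshold_mm: float = 0.2,
    min_timepoints: int = 3,
) -> tuple[np.ndarray, int]:
    """Drop time points with framewise displacement above threshold.

    A column is removed when FD is *strictly* greater than
    ``fd_threshold_mm`` (a point exactly at the threshold is kept);
    surviving columns keep their order. Returns the scrubbed series and
    the number of columns removed.
    """
    ts = np.asarray(timeseries, dtype=float)
    fd = np.asarray(fd_series, dtype=float)
    if fd.shape[0] != ts.shape[1]:
        raise ValueError("fd_series length must equal number of timepoints")
    keep = fd <= fd_threshold_mm
    n_removed = int((~keep).sum())
    if keep.sum() < min_timepoints:
        raise ValueError(
            f"only {int(keep.sum())} timepoints survive scrubbing "
            f"(minimum {min_timepoints}); correlation would be degenerate"
        )
    return ts[:, keep], n_removed


def correlation_matrix(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation between all node pairs.

    Requires at least 3 time points and nonzero temporal variance at
    every node; a flat node is reported by index.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a nodes x time matrix with >= 3 timepoints")
    sd = ts.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        raise ValueError(f"zero-variance node(s): {flat.tolist()}")
    r = np.corrcoef(ts)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r_matrix: np.ndarray, node_ids: list[str] | None = None) -> ConnectivityMatrix:
    """Fisher r-to-z transform, z = arctanh(r), with the diagonal zeroed.

    |r| is clipped to 1 - 1e-7 first so perfectly (anti)correlated pairs
    map to a large finite z rather than infinity.
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, node_ids=node_ids)


def overall_fc_strength(fc: ConnectivityMatrix, positive_only: bool = False) -> float:
    """Mean upper-triangular Fisher-z value (signed by default).

    With ``positive_only`` the mean runs over positive edges only — an
    alternative reading of "overall connectivity strength" kept behind a
    flag.
    """
    iu = np.triu_indices(fc.n_nodes, k=1)
    vals = fc.z[iu]
    if positive_only:
        vals = vals[vals > 0]
        if vals.size == 0:
            return 0.0
    return float(vals.mean())
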