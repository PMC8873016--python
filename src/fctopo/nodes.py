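"""Node definitions for whole-brain functional networks.

A node set binds node identifiers to MNI millimeter coordinates and to a
functional-network label drawn from a fixed seven-network vocabulary
(six cortical networks of the Yeo parcellation plus a subcortical
network), with ``other`` available for unassigned nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed network vocabulary: somatomotor, ventral attention, visual,
#: dorsal attention, default mode, frontoparietal, subcortical.
NETWORK_LABELS = ("SMN", "VAN", "VN", "DAN", "DMN", "FPN", "subcortical", "other")


@dataclass
class NodeSet:
    """Ordered set of network nodes with coordinates and network labels.

    Parameters
    ----------
    node_ids : list of str
        Unique node identifiers; order defines row/column order of every
        matrix bound to this node set.
    coordinates : (n, 3) ndarray
        MNI coordinates in millimeters.
    network_labels : list of str
        One label per node, from :data:`NETWORK_LABELS`.
    """

    node_ids: list[str]
    coordinates: np.ndarray
    network_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not self.network_labels:
            self.network_labels = ["other"] * len(self.node_ids)
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        if self.coordinates.shape != (len(self.node_ids), 3):
            raise ValueError(
                f"coordinates must be ({len(self.node_ids)}, 3), "
                f"got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        bad = sorted(set(self.network_labels) - set(NETWORK_LABELS))
        if bad:
            raise ValueError(f"unknown network labels: {bad}")
        if len(self.network_labels) != len(self.node_ids):
            raise ValueError("one network label per node required")

    def __len__(self) -> int:
        return len(self.node_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "x_mm": self.coordinates[:, 0],
                "y_mm": self.coordinates[:, 1],
                "z_mm": self.coordinates[:, 2],
                "network_label": self.network_labels,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NodeSet":
        return cls(
            node_ids=[str(s) for s in df["node_id"]],
            coordinates=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            network_labels=[str(s) for s in df["network_label"]],
        )

    @classmethod
    def from_csv(cls, path) -> "NodeSet":
        return cls.from_frame(pd.read_csv(path))
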