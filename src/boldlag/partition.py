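"""Network partition: voxel -> resting-state-network labels.

The partition defines the block structure of time-delay and functional
connectivity matrices. With ``m`` networks there are ``m (m + 1) / 2``
unique blocks (including the diagonal), of which ``m (m - 1) / 2`` are
off-diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetworkPartition", "DEFAULT_NETWORK_NAMES"]

# Canonical 7-network cortical parcellation used for block analyses.
DEFAULT_NETWORK_NAMES = ["DAN", "VAN", "SMN", "VIS", "FPC", "LAN", "DMN"]


@dataclass
class NetworkPartition:
    """Per-voxel integer network labels with network names.

    ``labels[v]`` indexes into ``names``; every analyzed voxel must be
    labeled and every network must contain at least two voxels.
    """

    labels: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D per-voxel array")
        if self.labels.min(initial=0) < 0 or (
            self.labels.size and self.labels.max() >= len(self.names)
        ):
            raise ValueError("labels must index into names")
        counts = np.bincount(self.labels, minlength=len(self.names))
        if (counts < 2).any():
            small = [self.names[i] for i in np.flatnonzero(counts < 2)]
            raise ValueError(f"networks with fewer than 2 voxels: {small}")

    @property
    def n_voxels(self) -> int:
        return self.labels.size

    @property
    def n_networks(self) -> int:
        return len(self.names)

    def members(self, network: int) -> np.ndarray:
        return np.flatnonzero(self.labels == network)

    def block_pairs(self, include_diagonal: bool = True) -> list[tuple[int, int]]:
        """Unique (a, b) network pairs with a <= b (or a < b)."""
        m = self.n_networks
        return [
            (a, b)
            for a in range(m)
            for b in range(a if include_diagonal else a + 1, m)
        ]

    def block_indices(self, a: int, b: int) -> tuple[np.ndarray, np.ndarray]:
        """Row/column voxel indices of the unique entries of block (a, b).

        For a diagonal block (a == b) only the upper-triangle pairs i < j
        are returned; for an off-diagonal block (a < b) all (i in a,
        j in b) pairs are unique. Entries are oriented so that a positive
        matrix value means "network-a voxel late relative to network-b
        voxel" under the package sign convention.
        """
        if a > b:
            raise ValueError("block_indices requires a <= b")
        va, vb = self.members(a), self.members(b)
        if a == b:
            ii, jj = np.meshgrid(va, vb, indexing="ij")
            keep = ii < jj
            return ii[keep], jj[keep]
        ii, jj = np.meshgrid(va, vb, indexing="ij")
        return ii.ravel(), jj.ravel()
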