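"""Per-epoch time-series container.

A :class:`TimeSeriesEpoch` is the unit of computation throughout the
package: an ``n_voxels x n_frames`` real matrix sampled every ``tr``
seconds, together with a boolean per-frame validity mask (frames flagged
by censoring are invalid but remain in place, so frame indices always
correspond to acquisition times).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TimeSeriesEpoch"]


@dataclass
class TimeSeriesEpoch:
    """Voxels-by-frames BOLD-like time series for one subject epoch.

    Parameters
    ----------
    data : ndarray, shape (n_voxels, n_frames)
        Signal in arbitrary intensity units.
    tr : float
        Repetition time (sampling interval) in seconds.
    valid : ndarray of bool, shape (n_frames,), optional
        Per-frame validity mask; defaults to all frames valid.
    subject_id, state_label, epoch_id : str
        Identifiers used for grouping in group-level operations.
    """

    data: np.ndarray
    tr: float
    valid: np.ndarray | None = None
    subject_id: str = ""
    state_label: str = ""
    epoch_id: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_voxels, n_frames) array")
        if not np.isfinite(self.data).all():
            raise ValueError("data must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (self.data.shape[1],):
                raise ValueError("valid mask length must equal n_frames")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def has_valid_frames(self) -> bool:
        return bool(self.valid.any())

    def with_data(self, data: np.ndarray) -> "TimeSeriesEpoch":
        """Copy of this epoch with replaced data, same mask and labels."""
        return replace(self, data=np.array(data, dtype=float), valid=self.valid.copy())

    def with_mask(self, valid: np.ndarray) -> "TimeSeriesEpoch":
        """Copy of this epoch with a replaced validity mask."""
        return replace(self, data=self.data.copy(), valid=np.asarray(valid, dtype=bool).copy())

    def copy(self) -> "TimeSeriesEpoch":
        return replace(self, data=self.data.copy(), valid=self.valid.copy())
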