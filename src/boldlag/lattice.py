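"""Voxel lattice geometry: coordinates, adjacency, and a simple smoother.

Synthetic voxels live on an explicit 3-D rectangular lattice so that the
cluster-extent statistics have a well-defined neighbor structure and a
Gaussian lattice smoother is available. Voxels are flattened x-fastest
(Fortran order), 0-based, matching the NIfTI reader.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp

__all__ = ["LatticeGeometry", "lattice_adjacency", "gaussian_lattice_smooth"]


@dataclass(frozen=True)
class LatticeGeometry:
    """Shape of the voxel lattice and its physical spacing (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (6.0, 6.0, 6.0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def coordinates(self) -> np.ndarray:
        """(n_voxels, 3) integer lattice coordinates, x-fastest order."""
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        return np.column_stack(
            [ix.ravel(order="F"), iy.ravel(order="F"), iz.ravel(order="F")]
        )

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Flatten a (nx, ny, nz[, t]) volume to voxel-major order."""
        if volume.shape[:3] != self.shape:
            raise ValueError("volume shape does not match lattice")
        if volume.ndim == 3:
            return volume.reshape(-1, order="F")
        return volume.reshape(self.n_voxels, -1, order="F")

    def unflatten(self, values: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`flatten` for per-voxel vectors or matrices."""
        values = np.asarray(values)
        if values.ndim == 1:
            return values.reshape(self.shape, order="F")
        return values.reshape((*self.shape, values.shape[1]), order="F")


def lattice_adjacency(geometry: LatticeGeometry) -> sp.csr_matrix:
    """Sparse 6-connectivity (face-neighbor) adjacency for a 3-D lattice."""
    nx, ny, nz = geometry.shape
    idx = np.arange(geometry.n_voxels).reshape((nx, ny, nz), order="F")
    rows, cols = [], []
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(0, -1)
        b[axis] = slice(1, None)
        rows.append(idx[tuple(a)].ravel())
        cols.append(idx[tuple(b)].ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    n = geometry.n_voxels
    adj = sp.coo_matrix(
        (np.ones(rows.size, dtype=bool), (rows, cols)), shape=(n, n)
    )
    adj = adj + adj.T
    return adj.tocsr()


def label_clusters(mask: np.ndarray, geometry: LatticeGeometry) -> tuple[np.ndarray, int]:
    """Connected components (6-connectivity) of a boolean voxel mask.

    Returns per-voxel integer labels (0 = background) and the component
    count; a thin wrapper over ``scipy.ndimage.label`` on the lattice.
    """
    vol = geometry.unflatten(mask.astype(np.int8))
    structure = ndi.generate_binary_structure(3, 1)
    labeled, n = ndi.label(vol, structure=structure)
    return geometry.flatten(labeled), int(n)


def gaussian_lattice_smooth(
    values: np.ndarray, geometry: LatticeGeometry, fwhm_mm: float = 6.0
) -> np.ndarray:
    """Gaussian smoothing of per-voxel data on the lattice.

    ``values`` may be a per-voxel vector or an (n_voxels, n_frames)
    matrix (smoothed frame by frame). FWHM is converted to sigma in
    voxel units per axis using the lattice spacing.
    """
    sigma_vox = [
        fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / s for s in geometry.spacing
    ]
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return geometry.flatten(
            ndi.gaussian_filter(geometry.unflatten(values), sigma=sigma_vox)
        )
    out = np.empty_like(values)
    for t in range(values.shape[1]):
        out[:, t] = geometry.flatten(
            ndi.gaussian_filter(geometry.unflatten(values[:, t]), sigma=sigma_vox)
        )
    return out
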