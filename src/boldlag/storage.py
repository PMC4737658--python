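"""Study container (HDF5) and NIfTI interoperability.

The hierarchical container stores epochs (matrix, TR, mask, labels),
derived TD/amplitude matrices, maps, and a provenance record (config
hash and seed) so every derived object is traceable to its inputs.
NIfTI-1 4-D volumes plus an integer label volume serve as the real-data
entry point; voxels are flattened 0-based, x-fastest.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import nibabel as nib
import numpy as np

from .epoch import TimeSeriesEpoch
from .lagcore import TimeDelayMatrix
from .lattice import LatticeGeometry
from .partition import NetworkPartition

__all__ = [
    "save_study",
    "load_study",
    "save_td_matrices",
    "load_td_matrices",
    "write_nifti_series",
    "read_nifti_series",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _epoch_key(epoch: TimeSeriesEpoch, i: int) -> str:
    return f"{epoch.subject_id or 'sub'}_{epoch.state_label or 'state'}_" \
           f"{epoch.epoch_id or f'ep{i:03d}'}"


def save_study(
    path,
    epochs: list[TimeSeriesEpoch],
    partition: NetworkPartition | None = None,
    geometry: LatticeGeometry | None = None,
    provenance: dict | None = None,
) -> None:
    """Write epochs (and optional partition/geometry) to an HDF5 container."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("epochs")
        for i, ep in enumerate(epochs):
            g = grp.create_group(f"{i:04d}_{_epoch_key(ep, i)}")
            g.create_dataset("data", data=ep.data)
            g.create_dataset("valid", data=ep.valid)
            g.attrs["tr"] = ep.tr
            g.attrs["subject_id"] = ep.subject_id
            g.attrs["state_label"] = ep.state_label
            g.attrs["epoch_id"] = ep.epoch_id
        if partition is not None:
            g = f.create_group("partition")
            g.create_dataset("labels", data=partition.labels)
            g.attrs["names"] = json.dumps(partition.names)
        if geometry is not None:
            g = f.create_group("geometry")
            g.attrs["shape"] = geometry.shape
            g.attrs["spacing"] = geometry.spacing
        if provenance:
            g = f.create_group("provenance")
            for k, v in provenance.items():
                g.attrs[k] = v


def load_study(path):
    """Read a study container; returns (epochs, partition, geometry)."""
    epochs: list[TimeSeriesEpoch] = []
    partition = geometry = None
    with h5py.File(path, "r") as f:
        for key in sorted(f["epochs"]):
            g = f["epochs"][key]
            epochs.append(
                TimeSeriesEpoch(
                    data=g["data"][...],
                    tr=float(g.attrs["tr"]),
                    valid=g["valid"][...].astype(bool),
                    subject_id=str(g.attrs["subject_id"]),
                    state_label=str(g.attrs["state_label"]),
                    epoch_id=str(g.attrs["epoch_id"]),
                )
            )
        if "partition" in f:
            partition = NetworkPartition(
                labels=f["partition"]["labels"][...],
                names=json.loads(f["partition"].attrs["names"]),
            )
        if "geometry" in f:
            geometry = LatticeGeometry(
                shape=tuple(int(x) for x in f["geometry"].attrs["shape"]),
                spacing=tuple(float(x) for x in f["geometry"].attrs["spacing"]),
            )
    return epochs, partition, geometry


def save_td_matrices(path, tds: list[TimeDelayMatrix], keys: list[str]) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("td")
        for key, td in zip(keys, tds):
            g = grp.create_group(key)
            g.create_dataset("td", data=td.td)
            g.create_dataset("amp", data=td.amp)
            g.create_dataset("validity", data=td.validity)
            g.attrs["tr"] = td.tr
            g.create_dataset("excluded", data=td.excluded)


def load_td_matrices(path) -> tuple[list[TimeDelayMatrix], list[str]]:
    tds, keys = [], []
    with h5py.File(path, "r") as f:
        for key in sorted(f["td"]):
            g = f["td"][key]
            tds.append(
                TimeDelayMatrix(
                    td=g["td"][...],
                    amp=g["amp"][...],
                    validity=g["validity"][...].astype(bool),
                    tr=float(g.attrs["tr"]),
                    excluded=g["excluded"][...].astype(int),
                )
            )
            keys.append(key)
    return tds, keys


def write_nifti_series(
    path,
    epoch: TimeSeriesEpoch,
    geometry: LatticeGeometry,
    label_path=None,
    partition: NetworkPartition | None = None,
) -> None:
    """Write an epoch as a 4-D NIfTI (and labels as a 3-D int volume)."""
    vol = geometry.unflatten(epoch.data)
    affine = np.diag([*geometry.spacing, 1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((*geometry.spacing, epoch.tr))
    nib.save(img, str(path))
    if label_path is not None and partition is not None:
        lab = geometry.unflatten(partition.labels.astype(np.int16) + 1)
        nib.save(nib.Nifti1Image(lab, affine), str(label_path))


def read_nifti_series(
    path, label_path=None, tr: float | None = None
) -> tuple[TimeSeriesEpoch, LatticeGeometry, NetworkPartition | None]:
    """Read a 4-D NIfTI (+ optional aligned label volume).

    Voxels are flattened x-fastest with 0-based coordinates; the TR is
    taken from the header's 4th zoom unless overridden. Label volumes
    use 0 for unlabeled; labels 1..m map to networks 0..m-1.
    """
    img = nib.load(str(path))
    data4d = np.asarray(img.dataobj, dtype=float)
    if data4d.ndim != 4:
        raise ValueError("expected a 4-D volume")
    zooms = img.header.get_zooms()
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.0
        if tr <= 0:
            raise ValueError("TR missing from header; pass tr explicitly")
    geometry = LatticeGeometry(
        shape=data4d.shape[:3],
        spacing=tuple(float(z) for z in zooms[:3]),
    )
    epoch = TimeSeriesEpoch(data=geometry.flatten(data4d), tr=tr)
    partition = None
    if label_path is not None:
        lab_img = nib.load(str(label_path))
        lab = np.asarray(lab_img.dataobj).astype(int)
        if lab.shape != data4d.shape[:3]:
            raise ValueError("label volume shape does not match series")
        flat = geometry.flatten(lab)
        n_names = int(flat.max())
        partition = NetworkPartition(
            labels=np.clip(flat - 1, 0, None),
            names=[f"NET{i}" for i in range(n_names)],
        )
    return epoch, geometry, partition
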