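"""Tractogram and volume I/O.

TCK and TRK files are read and written through ``nibabel.streamlines``; both
are converted to world-mm (RAS) coordinates on read, so the rest of the
package never sees voxel-space points.  Scalar and integer label volumes use
NIfTI via nibabel.  Cluster labelings are serialized as a two-column TSV
(streamline_index, cluster_label) with a JSON sidecar recording the method
and its parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines import Field
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.tractogram import Tractogram as NibTractogram
from nibabel.streamlines.trk import TrkFile

from .geometry import Tractogram

__all__ = [
    "read_tractogram",
    "write_tractogram",
    "read_volume",
    "write_volume",
    "write_labels",
    "read_labels",
]


def read_tractogram(path, shape=None, affine=None) -> Tractogram:
    """Load a TCK or TRK file into a world-mm :class:`Tractogram`.

    TRK headers carry their own grid; TCK does not, so ``shape``/``affine``
    (defaults: unit grid) describe the reference space for downstream voxel
    operations.
    """
    path = Path(path)
    tf = nib.streamlines.load(str(path))  # applies affine_to_rasmm -> world mm
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    hdr = tf.header
    if affine is None:
        aff = hdr.get(Field.VOXEL_TO_RASMM) if isinstance(hdr, dict) else None
        affine = np.asarray(aff, dtype=float) if aff is not None else np.eye(4)
    if shape is None:
        dims = hdr.get(Field.DIMENSIONS) if isinstance(hdr, dict) else None
        shape = tuple(int(d) for d in dims) if dims is not None else (1, 1, 1)
    return Tractogram(streamlines, shape, affine)


def write_tractogram(t: Tractogram, path) -> None:
    """Write a tractogram as TCK or TRK depending on the file suffix.

    Round-trips: coordinates survive write/read within 1e-4 mm (TRK stores
    float32).
    """
    path = Path(path)
    nt = NibTractogram([np.asarray(s) for s in t.streamlines], affine_to_rasmm=np.eye(4))
    header = {
        Field.VOXEL_TO_RASMM: np.asarray(t.affine, dtype=np.float32),
        Field.DIMENSIONS: np.asarray(t.shape, dtype=np.int16),
        Field.VOXEL_SIZES: np.linalg.norm(np.asarray(t.affine)[:3, :3], axis=0).astype(
            np.float32
        ),
    }
    if path.suffix == ".tck":
        TckFile(nt, header={}).save(str(path))
    elif path.suffix == ".trk":
        TrkFile(nt, header=header).save(str(path))
    else:
        raise ValueError(f"unsupported tractogram format: {path.suffix}")


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data array, voxel-to-world affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def write_labels(labels, path, sidecar: dict | None = None) -> None:
    """Serialize per-streamline labels as TSV (+ optional JSON sidecar)."""
    path = Path(path)
    labels = np.asarray(labels, dtype=int)
    with open(path, "w") as fh:
        fh.write("streamline_index\tcluster_label\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{int(lab)}\n")
    if sidecar is not None:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)
            fh.write("\n")


def read_labels(path) -> np.ndarray:
    rows = np.loadtxt(path, skiprows=1, dtype=int, ndmin=2)
    order = np.argsort(rows[:, 0])
    return rows[order, 1]
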