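"""Readers and writers for the formats the pipeline consumes and produces.

Connectome matrices travel as dense CSV with a node-id header row and column
(values round-trip bit-identically).  Volumes are NIfTI with their affine;
tractograms are TCK or TRK, with TRK's voxel-corner convention converted to
world mm by nibabel on read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import Cohort, LabelVolume, ScalarVolume, Tractogram, WeightedConnectome

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix", "write_matrix",
    "read_scalar_volume", "read_label_volume", "write_volume",
    "read_tractogram", "write_tractogram",
    "read_class_table", "write_class_table",
    "read_cohort", "write_cohort",
]

_SYM_ATOL = 1e-9


def read_matrix(path, kind: str = "nos") -> WeightedConnectome:
    """Read a square symmetric CSV matrix with node ids as header/index."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0, comment="#",
                     float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path.name}: matrix is not square {df.shape}")
    w = df.to_numpy(dtype=float)
    asym = np.abs(w - w.T)
    if asym.max(initial=0.0) > _SYM_ATOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"{path.name}: asymmetric beyond {_SYM_ATOL} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}")
    try:
        nodes = df.index.astype(int).to_numpy()
    except (TypeError, ValueError):
        nodes = df.index.to_numpy()
    return WeightedConnectome(nodes, w, kind=kind)


def write_matrix(path, connectome: WeightedConnectome,
                 config_hash: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(connectome.weights, index=connectome.nodes,
                      columns=connectome.nodes)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        # shortest-repr floats so values round-trip bit-identically
        df.to_csv(fh, float_format=lambda v: repr(float(v)))


def read_scalar_volume(path) -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(np.asanyarray(img.dataobj, dtype=float), img.affine)


def read_label_volume(path, label_table: dict | None = None) -> LabelVolume:
    img = nib.load(str(path))
    grid = np.asanyarray(img.dataobj)
    return LabelVolume(np.rint(grid).astype(np.int32), img.affine,
                       label_table=label_table or {})


def write_volume(path, volume) -> None:
    grid = volume.grid
    if isinstance(volume, LabelVolume):
        grid = grid.astype(np.int32)
    nib.save(nib.Nifti1Image(grid, volume.affine), str(path))


def read_tractogram(path) -> Tractogram:
    """Load TCK or TRK; streamlines come back in world mm (RAS+)."""
    tf = nib.streamlines.load(str(path))  # applies TRK's voxel→rasmm transform
    return Tractogram([np.asarray(s, dtype=float) for s in tf.streamlines])


def write_tractogram(path, tractogram: Tractogram,
                     reference: LabelVolume | ScalarVolume | None = None) -> None:
    """Save as TCK or TRK (by extension). TRK needs a reference volume for
    its header (dimensions, voxel sizes, voxel-to-world affine)."""
    path = Path(path)
    sl = [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines]
    t = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".trk":
        if reference is None:
            raise ValueError("TRK output needs a reference volume for its header")
        header = {
            nib.streamlines.Field.VOXEL_TO_RASMM: reference.affine.astype(np.float32),
            nib.streamlines.Field.VOXEL_SIZES: np.sqrt(
                (reference.affine[:3, :3] ** 2).sum(axis=0)).astype(np.float32),
            nib.streamlines.Field.DIMENSIONS: np.asarray(reference.grid.shape,
                                                         dtype=np.int16),
        }
        nib.streamlines.save(t, str(path), header=header)
    else:
        nib.streamlines.save(t, str(path))


def read_class_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, comment="#")
    for col in ("functional", "cytoarchitectonic"):
        if col not in df.columns:
            raise ValueError(f"class table missing column {col!r}")
    return df


def write_class_table(path, classes: pd.DataFrame) -> None:
    classes.to_csv(path)


def write_cohort(directory, cohort: Cohort,
                 config_hash: str | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s, (nos, sca) in enumerate(cohort.subjects):
        write_matrix(directory / f"subject_{s:03d}_nos.csv", nos,
                     config_hash=config_hash)
        write_matrix(directory / f"subject_{s:03d}_scalar.csv", sca,
                     config_hash=config_hash)


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    nos_files = sorted(directory.glob("subject_*_nos.csv"))
    if not nos_files:
        raise FileNotFoundError(f"no subject_*_nos.csv matrices in {directory}")
    subjects = []
    for nf in nos_files:
        sf = directory / nf.name.replace("_nos.csv", "_scalar.csv")
        if not sf.exists():
            raise FileNotFoundError(f"missing scalar matrix for {nf.name}")
        subjects.append((read_matrix(nf, kind="nos"),
                         read_matrix(sf, kind="scalar")))
    return Cohort(subjects)
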