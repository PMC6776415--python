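"""File formats: NIfTI volumes, TCK streamlines, delimited-text matrices,
cohort CSV tables and JSON results.  All round-trips are lossless to 1e-12
(float text formats use repr-precision)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .netbuild import Connectome, Parcellation
from .tracking import Streamline, StreamlineSet, TensorField

__all__ = [
    "write_tensor_field", "read_tensor_field",
    "write_labels", "read_labels",
    "write_tck", "read_tck",
    "write_matrix", "read_matrix",
    "write_connectome", "read_connectome",
    "write_cohort", "read_cohort",
    "write_json", "read_json",
]

# lower-triangular component order used in the 6-volume tensor NIfTI
_LT = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]


# -- NIfTI volumes ----------------------------------------------------------

def write_tensor_field(fld: TensorField, path) -> None:
    comp = np.stack([fld.tensors[..., i, j] for i, j in _LT], axis=-1)
    nib.save(nib.Nifti1Image(comp.astype(np.float64), fld.affine), str(path))
    mpath = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz/.nii
    nib.save(nib.Nifti1Image(fld.mask.astype(np.uint8), fld.affine),
             str(mpath) + "_mask.nii.gz")


def read_tensor_field(path, mask_path=None) -> TensorField:
    img = nib.load(str(path))
    comp = np.asarray(img.dataobj, dtype=float)
    if comp.ndim != 4 or comp.shape[-1] != 6:
        raise ValueError(f"{path}: expected a 4-D volume with 6 components")
    tensors = np.zeros(comp.shape[:3] + (3, 3))
    for k, (i, j) in enumerate(_LT):
        tensors[..., i, j] = comp[..., k]
        tensors[..., j, i] = comp[..., k]
    affine = img.affine
    mask = None
    if mask_path is None:
        guess = Path(str(path))
        guess = Path(str(guess).replace(".nii.gz", "").replace(".nii", "")
                     + "_mask.nii.gz")
        if guess.exists():
            mask_path = guess
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    voxel_size = float(np.abs(affine[0, 0])) or 1.0
    return TensorField(tensors, voxel_size=voxel_size, affine=affine, mask=mask)


def write_labels(parc: Parcellation, path) -> None:
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int32), parc.affine),
             str(path))


def read_labels(path, voxel_size: Optional[float] = None) -> Parcellation:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    vs = voxel_size or float(np.abs(img.affine[0, 0])) or 1.0
    return Parcellation(labels=labels, affine=img.affine, voxel_size=vs)


# -- TCK streamlines --------------------------------------------------------

def write_tck(tracks: StreamlineSet, path) -> None:
    tractogram = nib.streamlines.Tractogram(
        [s.points for s in tracks], affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))


def read_tck(path) -> StreamlineSet:
    tck = nib.streamlines.load(str(path))
    sls = [Streamline(np.asarray(pts, dtype=float))
           for pts in tck.tractogram.streamlines]
    return StreamlineSet(sls)


# -- delimited-text matrices ------------------------------------------------

def write_matrix(M: np.ndarray, path, delimiter: str = "\t") -> None:
    np.savetxt(str(path), np.asarray(M, dtype=float),
               delimiter=delimiter, fmt="%.17g")


def read_matrix(path, delimiter: str = "\t") -> np.ndarray:
    try:
        return np.loadtxt(str(path), delimiter=delimiter, ndmin=2)
    except ValueError as err:
        raise ValueError(f"malformed matrix file {path}: {err}") from err


def write_connectome(conn: Connectome, outdir) -> None:
    """Connectome as counts + weights matrices, a node-volume column file and
    a JSON sidecar carrying strategy and provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(conn.counts, outdir / "counts.tsv")
    if conn.weights is not None:
        write_matrix(conn.weights, outdir / "weights.tsv")
    if conn.node_volumes is not None:
        np.savetxt(outdir / "node_volumes.csv", conn.node_volumes, fmt="%.17g")
    sidecar = {"strategy": conn.strategy, "subject_id": conn.subject_id,
               "n_nodes": conn.n_nodes, **conn.meta}
    (outdir / "connectome.json").write_text(json.dumps(sidecar, indent=2))


def read_connectome(outdir) -> Connectome:
    outdir = Path(outdir)
    counts = read_matrix(outdir / "counts.tsv").astype(np.int64)
    weights = None
    if (outdir / "weights.tsv").exists():
        weights = read_matrix(outdir / "weights.tsv")
    volumes = None
    if (outdir / "node_volumes.csv").exists():
        volumes = np.loadtxt(outdir / "node_volumes.csv")
    meta = json.loads((outdir / "connectome.json").read_text())
    return Connectome(counts=counts, weights=weights, node_volumes=volumes,
                      strategy=meta.get("strategy", "none"),
                      subject_id=meta.get("subject_id", ""))


# -- cohort tables and results ----------------------------------------------

def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" in df.columns and df["id"].duplicated().any():
        raise ValueError("duplicate subject ids in cohort table")
    return df


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def read_json(path):
    return json.loads(Path(path).read_text())
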