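"""Readers/writers for every on-disk format the pipeline touches.

Volumes (DWI, masks, densities, warps) are NIfTI-1 via :mod:`nibabel`;
gradient tables are FSL-style ``.bval``/``.bvec`` text; streamlines are TCK
or TRK via :mod:`nibabel.streamlines`.  All streamline coordinates exposed by
this module are world millimetres regardless of the on-disk convention (TRK
stores voxel-order coordinates; the dialect is hidden here).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "DWIVolume",
    "Tractogram",
    "MaskSet",
    "MASK_NAMES",
    "read_dwi",
    "write_dwi",
    "read_tractogram",
    "write_tractogram",
    "read_mask_set",
    "read_nifti_volume",
    "write_nifti_volume",
]

#: canonical waypoint mask names (left/right dentate nucleus, red nucleus,
#: precentral gyrus, superior cerebellar peduncle, Vim, plus white matter);
#: ``EXCL_*`` names are free-form exclusion masks.
MASK_NAMES = (
    "DN_L", "DN_R", "RN_L", "RN_R", "PG_L", "PG_R",
    "SCP_L", "SCP_R", "VIM_L", "VIM_R", "WM",
)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class DWIVolume:
    """A 4D diffusion-weighted acquisition.

    Attributes
    ----------
    data : ndarray, shape (X, Y, Z, N)
        Non-negative signal.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm map (invertible).
    bvals : ndarray, shape (N,)
        b-values in s/mm^2; at least one must be 0.
    bvecs : ndarray, shape (N, 3)
        Gradient directions; unit norm wherever the b-value is positive.
    """

    data: np.ndarray
    affine: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got shape {self.data.shape}")
        n = self.data.shape[3]
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise ValueError(
                f"gradient table mismatch: {n} volumes, {len(self.bvals)} b-values, "
                f"bvecs shape {self.bvecs.shape}"
            )
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if not np.any(self.bvals == 0):
            raise ValueError("no b=0 volume present")
        if np.any(self.data < 0):
            raise ValueError("DWI signal contains negative values")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError("non-unit gradient direction for a b>0 volume")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])


@dataclass
class Tractogram:
    """An ordered collection of streamlines in world mm.

    Every streamline is an (P, 3) float array with P >= 2 and finite
    coordinates.  ``space_tag`` records whether the coordinates live in a
    subject's native frame or the template frame; ``provenance`` names the
    method that produced them (e.g. ``"fact"``, ``"ifod2"``).
    """

    streamlines: List[np.ndarray]
    space_tag: str = "native"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.space_tag not in ("native", "template"):
            raise ValueError(f"space_tag must be native|template, got {self.space_tag!r}")
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            arr = np.asarray(sl, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(f"streamline {i} is not an (P>=2, 3) array")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class MaskSet:
    """Named binary volumes on one shared grid."""

    masks: Dict[str, np.ndarray]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        shape = None
        for name, m in self.masks.items():
            arr = np.asarray(m)
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask {name!r} is not binary (values {vals[:5]}...)")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"mask {name!r} shape {arr.shape} differs from {shape}"
                )
            self.masks[name] = arr.astype(bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> List[str]:
        return list(self.masks)

    @property
    def shape(self):
        return next(iter(self.masks.values())).shape

    def exclusion_names(self) -> List[str]:
        return [n for n in self.masks if n.startswith("EXCL")]


# ---------------------------------------------------------------------------
# DWI
# ---------------------------------------------------------------------------

def _load_bval_bvec(bval_path, bvec_path):
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(1, -1)
    # FSL convention is 3 rows x N columns; accept N x 3 as well
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise ValueError(f"bvec table has shape {bvecs.shape}, expected 3xN or Nx3")
    return bvals, bvecs


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    """Load a 4D DWI NIfTI together with its FSL-style gradient table.

    Gradient vectors with a positive b-value are normalised to unit length;
    a zero-norm vector paired with b>0 is an error, as is any count mismatch
    between the NIfTI and the b-value/b-vector tables, or a missing b=0.
    """
    img = nib.load(os.fspath(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected 4D volume, got {data.ndim}D")
    n = data.shape[3]
    bvals, bvecs = _load_bval_bvec(bval_path, bvec_path)
    if len(bvals) != n or bvecs.shape[0] != n:
        raise ValueError(
            f"gradient table mismatch: NIfTI has {n} volumes but "
            f"{len(bvals)} b-values / {bvecs.shape[0]} b-vectors"
        )
    bvecs = bvecs.astype(float).copy()
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(norms == 0):
        raise ValueError("zero gradient vector paired with b>0")
    bvecs[dw] /= norms[:, None]
    return DWIVolume(data=data, affine=img.affine, bvals=bvals, bvecs=bvecs)


def write_dwi(dwi: DWIVolume, nifti_path, bval_path, bvec_path) -> None:
    """Write a :class:`DWIVolume` as NIfTI + FSL-style .bval/.bvec (3xN)."""
    nib.save(nib.Nifti1Image(dwi.data.astype(np.float32), dwi.affine),
             os.fspath(nifti_path))
    np.savetxt(bval_path, dwi.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, dwi.bvecs.T, fmt="%.8f")


# ---------------------------------------------------------------------------
# tractograms
# ---------------------------------------------------------------------------

def read_tractogram(path, space_tag: str = "native") -> Tractogram:
    """Read a .tck or .trk file; coordinates are returned in world mm.

    TRK's on-disk voxel-order storage is converted on load (nibabel applies
    the header affine); TCK already stores world mm and passes through.
    """
    path = Path(path)
    if path.suffix.lower() not in (".tck", ".trk"):
        raise ValueError(f"unsupported tractogram extension: {path.suffix!r}")
    tf = nib.streamlines.load(os.fspath(path))  # always loaded to RAS+ mm
    sls = [np.asarray(s, dtype=float) for s in tf.streamlines]
    return Tractogram(streamlines=sls, space_tag=space_tag, provenance=path.stem)


def write_tractogram(tractogram: Tractogram, path,
                     reference_affine: Optional[np.ndarray] = None,
                     reference_shape: Optional[Sequence[int]] = None) -> None:
    """Write streamlines as .tck or .trk.

    TRK stores coordinates in voxel-order space and therefore needs a
    reference grid; pass ``reference_affine`` (and optionally
    ``reference_shape``) when writing .trk.  TCK needs neither.
    """
    path = Path(path)
    sls = [s.astype(np.float32) for s in tractogram.streamlines]
    new = nib.streamlines.Tractogram(sls, affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".tck":
        nib.streamlines.save(new, os.fspath(path))
    elif path.suffix.lower() == ".trk":
        if reference_affine is None:
            raise ValueError("writing .trk requires reference_affine")
        from nibabel.streamlines.trk import TrkFile
        header = {
            nib.streamlines.Field.VOXEL_TO_RASMM: np.asarray(reference_affine, float),
            nib.streamlines.Field.VOXEL_SIZES:
                np.sqrt((np.asarray(reference_affine)[:3, :3] ** 2).sum(0)),
            nib.streamlines.Field.DIMENSIONS:
                tuple(reference_shape) if reference_shape is not None else (1, 1, 1),
        }
        TrkFile(new, header=header).save(os.fspath(path))
    else:
        raise ValueError(f"unsupported tractogram extension: {path.suffix!r}")


# ---------------------------------------------------------------------------
# masks and plain volumes
# ---------------------------------------------------------------------------

def read_nifti_volume(path):
    """Load a 3D (or 4D) NIfTI; returns ``(data, affine)``."""
    img = nib.load(os.fspath(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_nifti_volume(data, affine, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                             np.asarray(affine, float)), os.fspath(path))


def read_mask_set(source: Union[str, os.PathLike, Mapping[str, str]]) -> MaskSet:
    """Load named binary masks sharing one grid.

    ``source`` is either a YAML manifest mapping mask names to NIfTI paths, a
    directory containing ``<NAME>.nii[.gz]`` files, or an in-memory mapping.
    Non-binary volumes are rejected (never silently thresholded) and a grid
    mismatch names the offending file.
    """
    if isinstance(source, Mapping):
        entries = {str(k): Path(v) for k, v in source.items()}
    else:
        src = Path(source)
        if src.is_dir():
            entries = {}
            for p in sorted(src.iterdir()):
                if p.name.endswith(".nii.gz"):
                    entries[p.name[:-7]] = p
                elif p.suffix == ".nii":
                    entries[p.stem] = p
        else:
            with open(src) as fh:
                manifest = yaml.safe_load(fh)
            if not isinstance(manifest, Mapping):
                raise ValueError(f"{src}: manifest must map mask names to paths")
            entries = {str(k): (src.parent / v) for k, v in manifest.items()}
    if not entries:
        raise ValueError("no masks found")

    masks: Dict[str, np.ndarray] = {}
    affine = None
    ref_name = None
    shape = None
    for name, p in entries.items():
        data, aff = read_nifti_volume(p)
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask {name!r} ({p}) is not binary")
        if affine is None:
            affine, shape, ref_name = aff, data.shape, name
        else:
            if data.shape != shape or not np.allclose(aff, affine, atol=1e-4):
                raise ValueError(
                    f"grid mismatch: mask {name!r} ({p}) does not match {ref_name!r}"
                )
        masks[name] = data.astype(bool)
    return MaskSet(masks=masks, affine=affine)
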