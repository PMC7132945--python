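"""Core containers and file I/O for the virtual-dissection pipeline.

Geometric conventions used throughout the package:

* voxel indices are 0-based and index *centers*: integer index ``i`` maps to
  the center of voxel ``i`` under the dataset affine;
* streamline vertices are stored in world millimetres.  Per-format
  conventions (e.g. the TRK corner offset) are normalised at the I/O
  boundary so that everything downstream speaks one language.

Volumes and masks are NIfTI-1 (``.nii``/``.nii.gz``), gradient tables are
FSL-style ``bvals``/``bvecs`` text files, tractograms are TRK or TCK.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger("commissura")

__all__ = [
    "FormatError",
    "GeometryError",
    "ValidationError",
    "GradientTable",
    "DwiDataset",
    "ScalarMap",
    "Tractogram",
    "voxel_to_world",
    "world_to_voxel",
    "read_dwi_dataset",
    "write_dwi_dataset",
    "read_tractogram",
    "write_tractogram",
]

#: b-values below this (s/mm^2) are treated as b=0 acquisitions.
B0_THRESHOLD = 50.0


class FormatError(ValueError):
    """A file or in-memory object violates a format contract."""


class GeometryError(ValueError):
    """Inconsistent spatial metadata (affines, shapes, out-of-grid objects)."""


class ValidationError(ValueError):
    """A parameter or specification is out of its legal range."""


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (…,3) to world mm through ``affine`` (voxel-center)."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map world-mm points (…,3) to continuous voxel coordinates."""
    inv = np.linalg.inv(affine)
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine is not invertible (singular 3x3 block)")
    return affine


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GradientTable:
    """Diffusion gradient scheme: one (b, g) row per acquired volume.

    ``bvals`` are in s/mm^2 and ``bvecs`` are unit 3-vectors for every
    diffusion-weighted row; vectors on b=0 rows are ignored.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (n, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise FormatError(
                f"bval count ({len(self.bvals)}) != bvec count ({len(self.bvecs)})"
            )
        dw = self.bvals > B0_THRESHOLD
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(norms < 1e-12):
            raise FormatError("zero-length bvec on a diffusion-weighted row")
        self.bvecs = self.bvecs.copy()
        self.bvecs[dw] /= norms[:, None]
        if not np.any(~dw):
            raise FormatError("gradient table has no b=0 row (needed for S0)")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def shells(self) -> np.ndarray:
        """Unique nonzero b-values, rounded to the nearest 10 s/mm^2."""
        b = self.bvals[~self.b0_mask]
        return np.unique(np.round(b, -1))


@dataclass
class DwiDataset:
    """A 4-D diffusion-weighted acquisition with its gradient scheme."""

    signal: np.ndarray
    affine: np.ndarray
    gradients: GradientTable
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise FormatError(f"signal must be 4-D, got shape {self.signal.shape}")
        if self.signal.shape[3] != len(self.gradients):
            raise FormatError(
                f"signal has {self.signal.shape[3]} volumes but gradient table "
                f"has {len(self.gradients)} rows"
            )
        self.affine = _check_affine(self.affine)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.signal.shape[:3]:
            raise FormatError(
                f"brain mask shape {self.brain_mask.shape} != spatial shape "
                f"{self.signal.shape[:3]}"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class ScalarMap:
    """A 3-D scalar field (e.g. FA or MD) sharing a grid with its source DWI."""

    values: np.ndarray
    affine: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise FormatError(f"scalar map must be 3-D, got {self.values.shape}")
        self.affine = _check_affine(self.affine)


@dataclass
class Tractogram:
    """A list of streamlines (each an (n_i, 3) float array of world-mm vertices).

    ``affine`` and ``grid_shape`` record the reference grid the streamlines
    were tracked on; they are only needed to write TRK headers and to gate
    against voxel masks.
    """

    streamlines: list = field(default_factory=list)
    affine: np.ndarray | None = None
    grid_shape: tuple | None = None
    space: str = "world-mm"

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float).reshape(-1, 3) for s in self.streamlines]
        for s in self.streamlines:
            if not np.all(np.isfinite(s)):
                raise FormatError("streamline contains non-finite vertices")
        if self.affine is not None:
            self.affine = _check_affine(self.affine)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


# ---------------------------------------------------------------------------
# DWI reading / writing
# ---------------------------------------------------------------------------

def _read_gradient_files(bval_path: str, bvec_path: str) -> GradientTable:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2:
        raise FormatError(f"bvec file {bvec_path!r} is not a 2-D table")
    # FSL convention stores bvecs as 3 rows x N columns; accept either layout.
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    return GradientTable(bvals, bvecs)


def read_dwi_dataset(
    image_path: str,
    bval_path: str,
    bvec_path: str,
    mask_path: str | None = None,
) -> DwiDataset:
    """Load a 4-D NIfTI plus FSL-style bvals/bvecs (and optional brain mask).

    Without a mask, voxels whose mean b=0 signal is positive form the brain
    mask.  Vectors are renormalised to unit length on load.
    """
    img = nib.load(image_path)
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{image_path!r} is {data.ndim}-D; expected a 4-D DWI")
    gradients = _read_gradient_files(bval_path, bvec_path)
    if data.shape[3] != len(gradients):
        raise FormatError(
            f"{image_path!r} has {data.shape[3]} volumes but the gradient "
            f"files list {len(gradients)} entries"
        )
    affine = _check_affine(img.affine)
    if mask_path is not None:
        mimg = nib.load(mask_path)
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise FormatError(
                f"mask shape {mask.shape} != image spatial shape {data.shape[:3]}"
            )
    else:
        mask = data[..., gradients.b0_mask].mean(axis=3) > 0
    ds = DwiDataset(data, affine, gradients, mask)
    logger.info(
        "read DWI %s: shape %s, %d gradients, %d mask voxels",
        image_path, data.shape, len(gradients), int(mask.sum()),
    )
    return ds


def write_dwi_dataset(d: DwiDataset, image_path: str, bval_path: str, bvec_path: str,
                      mask_path: str | None = None) -> None:
    """Write a dataset back to NIfTI + bvals/bvecs (inverse of read_dwi_dataset)."""
    nib.save(nib.Nifti1Image(np.asarray(d.signal), d.affine), image_path)
    np.savetxt(bval_path, d.gradients.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, d.gradients.bvecs.T, fmt="%.17g")
    if mask_path is not None:
        nib.save(nib.Nifti1Image(d.brain_mask.astype(np.uint8), d.affine), mask_path)


def write_scalar_map(m: ScalarMap, path: str) -> None:
    nib.save(nib.Nifti1Image(m.values.astype(np.float32), m.affine), path)


def read_scalar_map(path: str, label: str = "") -> ScalarMap:
    img = nib.load(path)
    return ScalarMap(np.asarray(img.dataobj, dtype=float), img.affine, label=label)


# ---------------------------------------------------------------------------
# tractogram reading / writing
# ---------------------------------------------------------------------------

def write_tractogram(t: Tractogram, path: str, allow_empty: bool = False) -> None:
    """Write a tractogram to TRK or TCK; vertices are stored as float32 mm."""
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".trk", ".tck"):
        raise FormatError(f"unknown tractogram extension {ext!r} (use .trk or .tck)")
    if len(t) == 0 and not allow_empty:
        raise ValidationError("refusing to write an empty tractogram "
                              "(pass allow_empty=True to override)")
    nt = nib.streamlines.Tractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    if ext == ".trk":
        hdr = {}
        if t.affine is not None and t.grid_shape is not None:
            hdr["voxel_to_rasmm"] = t.affine.astype(np.float32)
            hdr["voxel_sizes"] = np.sqrt((t.affine[:3, :3] ** 2).sum(axis=0)).astype(np.float32)
            hdr["dimensions"] = np.asarray(t.grid_shape, dtype=np.int16)
        nib.streamlines.TrkFile(nt, header=hdr).save(path)
    else:
        nib.streamlines.TckFile(nt).save(path)
    logger.info("wrote %d streamlines to %s", len(t), path)


def read_tractogram(path: str) -> Tractogram:
    """Read TRK/TCK; vertices are returned in world mm whatever the on-disk space."""
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".trk", ".tck"):
        raise FormatError(f"unknown tractogram extension {ext!r} (use .trk or .tck)")
    try:
        tf = nib.streamlines.load(path)
    except Exception as exc:  # nibabel raises various header errors
        raise FormatError(f"could not parse tractogram {path!r}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    affine = None
    shape = None
    if isinstance(tf, nib.streamlines.TrkFile):
        affine = np.asarray(tf.header["voxel_to_rasmm"], dtype=float)
        shape = tuple(int(v) for v in tf.header["dimensions"])
    return Tractogram(streamlines, affine=affine, grid_shape=shape)
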