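"""Per-voxel diffusion tensor fitting and derived maps.

The tensor is estimated by ordinary least squares on the log-signal
(Stejskal-Tanner model ``S = S0 exp(-b g' D g)``), which is exact on
noise-free data.  FA and MD follow the standard Basser-Pierpaoli
definitions:

    MD = (l1 + l2 + l3) / 3
    FA = sqrt(3/2) * ||l - MD|| / ||l||

A single-peak orientation field (principal eigenvector, FA amplitude) is
derived for the deterministic tracker; it plays the role that a fibre
orientation distribution would on multi-fibre data, and the synthetic
phantom can supply multi-peak fields directly through the same container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import B0_THRESHOLD, DwiDataset, GeometryError, ScalarMap, ValidationError

logger = logging.getLogger("commissura")

__all__ = [
    "TensorField",
    "OrientationField",
    "InsufficientDataError",
    "fit_tensor_lls",
    "compute_fa_md",
    "fa_from_eigenvalues",
    "md_from_eigenvalues",
    "derive_peak_field",
    "write_orientation_field",
    "read_orientation_field",
]


class InsufficientDataError(ValueError):
    """Too few usable volumes to constrain the six tensor elements."""


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors (mm^2/s) with estimated S0.

    ``tensors`` is (X, Y, Z, 3, 3); voxels outside ``mask`` or where the fit
    produced non-finite values are flagged in ``failed`` rather than zeroed.
    """

    tensors: np.ndarray
    s0: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    failed: np.ndarray

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (descending) and matching eigenvectors per voxel.

        Returns ``(evals, evecs)`` with shapes (X,Y,Z,3) and (X,Y,Z,3,3);
        ``evecs[..., i]`` is the eigenvector of ``evals[..., i]``.
        """
        evals, evecs = np.linalg.eigh(self.tensors)
        order = np.argsort(evals, axis=-1)[..., ::-1]
        evals = np.take_along_axis(evals, order, axis=-1)
        evecs = np.take_along_axis(evecs, order[..., None, :], axis=-1)
        return evals, evecs


@dataclass
class OrientationField:
    """Per-voxel unit peak directions with amplitudes over a support mask.

    ``peaks`` is (X, Y, Z, P, 3); ``n_peaks`` gives the number of valid
    entries per voxel and ``support`` the voxels where tracking may live.
    """

    peaks: np.ndarray
    amplitudes: np.ndarray
    n_peaks: np.ndarray
    support: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.n_peaks = np.asarray(self.n_peaks, dtype=np.int64)
        self.support = np.asarray(self.support, dtype=bool)
        if self.peaks.ndim != 5 or self.peaks.shape[-1] != 3:
            raise ValidationError(f"peaks must be (X,Y,Z,P,3), got {self.peaks.shape}")
        if np.any(self.amplitudes < 0):
            raise ValidationError("peak amplitudes must be >= 0")
        if np.any(self.support & (self.n_peaks == 0)):
            raise ValidationError("support voxels must carry at least one peak")
        # unit-norm check over valid entries only
        p_idx = np.arange(self.peaks.shape[3])
        valid = p_idx[None, None, None, :] < self.n_peaks[..., None]
        norms = np.linalg.norm(self.peaks, axis=-1)
        if np.any(np.abs(norms[valid] - 1.0) > 1e-6):
            raise ValidationError("peak directions must be unit-norm (tol 1e-6)")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.peaks.shape[:3]

    def peaks_at(self, ijk) -> tuple[np.ndarray, np.ndarray]:
        """(directions, amplitudes) of the peaks resident in voxel ``ijk``."""
        i, j, k = ijk
        n = int(self.n_peaks[i, j, k])
        return self.peaks[i, j, k, :n], self.amplitudes[i, j, k, :n]


# ---------------------------------------------------------------------------
# tensor fit
# ---------------------------------------------------------------------------

def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx,
        -b * gy * gy,
        -b * gz * gz,
        -2 * b * gx * gy,
        -2 * b * gx * gz,
        -2 * b * gy * gz,
    ])


def fit_tensor_lls(d: DwiDataset, shell_selection=None) -> TensorField:
    """Ordinary least-squares tensor fit over the brain mask.

    ``shell_selection`` is a predicate on b-values choosing which volumes
    enter the fit; b=0 volumes are always kept.  The human-study default is
    ``lambda b: b <= 1000`` (tensor metrics from the b=1000 shell only).
    Non-positive signals are floored at a tiny positive value before the log.
    """
    bvals = d.gradients.bvals
    keep = bvals <= B0_THRESHOLD
    if shell_selection is not None:
        keep = keep | np.array([bool(shell_selection(b)) for b in bvals])
    else:
        keep = np.ones_like(keep)
    n_b0 = int(np.sum(bvals[keep] <= B0_THRESHOLD))
    n_dw = int(keep.sum()) - n_b0
    if n_b0 < 1 or n_dw < 6:
        raise InsufficientDataError(
            f"need >= 1 b0 and >= 6 DW volumes after shell selection, "
            f"got {n_b0} b0 + {n_dw} DW"
        )
    X = _design_matrix(bvals[keep], d.gradients.bvecs[keep])
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise GeometryError(
            f"singular tensor design matrix (condition number {cond:.3g}); "
            "gradient directions are degenerate"
        )
    signal = np.asarray(d.signal, dtype=float)[..., keep]
    mask = d.brain_mask
    vox = signal[mask]
    floor = np.finfo(float).tiny
    logs = np.log(np.maximum(vox, floor))
    coeffs = logs @ np.linalg.pinv(X).T  # (n_vox, 7)

    shape = d.spatial_shape
    tensors = np.zeros(shape + (3, 3), dtype=float)
    s0 = np.zeros(shape, dtype=float)
    failed = np.zeros(shape, dtype=bool)

    dxx, dyy, dzz = coeffs[:, 1], coeffs[:, 2], coeffs[:, 3]
    dxy, dxz, dyz = coeffs[:, 4], coeffs[:, 5], coeffs[:, 6]
    t = np.empty((len(coeffs), 3, 3))
    t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = dxx, dyy, dzz
    t[:, 0, 1] = t[:, 1, 0] = dxy
    t[:, 0, 2] = t[:, 2, 0] = dxz
    t[:, 1, 2] = t[:, 2, 1] = dyz
    bad = ~np.isfinite(coeffs).all(axis=1)
    t[bad] = 0.0

    tensors[mask] = t
    s0[mask] = np.exp(coeffs[:, 0])
    fl = np.zeros(shape, dtype=bool)
    fl[mask] = bad
    failed = fl
    logger.info("tensor fit: %d voxels, %d volumes, %d failed",
                int(mask.sum()), int(keep.sum()), int(bad.sum()))
    return TensorField(tensors, s0, d.affine, mask.copy(), failed)


# ---------------------------------------------------------------------------
# scalar maps
# ---------------------------------------------------------------------------

def md_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    return np.mean(evals, axis=-1)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Basser-Pierpaoli FA; negative eigenvalues are clamped to 0 first."""
    ev = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    md = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt((np.square(ev - md)).sum(axis=-1))
    den = np.sqrt(np.square(ev).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_fa_md(t: TensorField) -> tuple[ScalarMap, ScalarMap]:
    """FA and MD maps from a fitted tensor field.

    MD uses the raw eigenvalues (so noise-free recovery is exact); FA clamps
    negative eigenvalues to zero, and such voxels are flagged in the field.
    """
    evals, _ = t.eigensystem()
    neg = np.any(evals < 0, axis=-1) & t.mask
    if np.any(neg):
        t.failed = t.failed | neg
        logger.debug("FA: %d voxels had negative eigenvalues (clamped)", int(neg.sum()))
    md = np.where(t.mask, md_from_eigenvalues(evals), 0.0)
    fa = np.where(t.mask, fa_from_eigenvalues(evals), 0.0)
    return (ScalarMap(fa, t.affine, label="FA"),
            ScalarMap(md, t.affine, label="MD"))


def derive_peak_field(t: TensorField, fa_floor: float = 0.1) -> OrientationField:
    """Single-peak orientation field: principal eigenvector, FA amplitude.

    Support is the set of mask voxels with FA >= ``fa_floor`` and a
    successful fit.
    """
    evals, evecs = t.eigensystem()
    fa = fa_from_eigenvalues(evals)
    support = t.mask & ~t.failed & (fa >= fa_floor)
    e1 = evecs[..., 0]
    norms = np.linalg.norm(e1, axis=-1, keepdims=True)
    e1 = np.where(norms > 0, e1 / np.maximum(norms, 1e-30), 0.0)
    shape = t.tensors.shape[:3]
    peaks = np.zeros(shape + (1, 3))
    amps = np.zeros(shape + (1,))
    n_peaks = np.zeros(shape, dtype=np.int64)
    peaks[support, 0] = e1[support]
    amps[support, 0] = fa[support]
    n_peaks[support] = 1
    return OrientationField(peaks, amps, n_peaks, support, t.affine)


def write_orientation_field(field: OrientationField, prefix: str) -> None:
    """Persist a peak field as NIfTI volumes (``<prefix>_peaks/_amps/_npeaks``).

    Peak directions are flattened to an (X, Y, Z, 3P) volume so that
    multi-peak fields (e.g. phantom crossings) survive the round trip.
    """
    import nibabel as nib

    shape = field.spatial_shape
    p = field.peaks.shape[3]
    nib.save(nib.Nifti1Image(field.peaks.reshape(shape + (3 * p,)).astype(np.float32),
                             field.affine), f"{prefix}_peaks.nii.gz")
    nib.save(nib.Nifti1Image(field.amplitudes.astype(np.float32), field.affine),
             f"{prefix}_amps.nii.gz")
    nib.save(nib.Nifti1Image(field.n_peaks.astype(np.int16), field.affine),
             f"{prefix}_npeaks.nii.gz")


def read_orientation_field(prefix: str) -> OrientationField:
    """Inverse of :func:`write_orientation_field`."""
    import nibabel as nib

    pk = nib.load(f"{prefix}_peaks.nii.gz")
    peaks = np.asarray(pk.dataobj, dtype=float)
    shape = peaks.shape[:3]
    peaks = peaks.reshape(shape + (-1, 3))
    amps = np.asarray(nib.load(f"{prefix}_amps.nii.gz").dataobj, dtype=float)
    if amps.ndim == 3:
        amps = amps[..., None]
    n_peaks = np.asarray(nib.load(f"{prefix}_npeaks.nii.gz").dataobj,
                         dtype=np.int64)
    # re-normalise against float32 round-off so the unit-norm invariant holds
    norms = np.linalg.norm(peaks, axis=-1, keepdims=True)
    peaks = np.where(norms > 1e-6, peaks / np.maximum(norms, 1e-30), 0.0)
    return OrientationField(peaks, amps, n_peaks, n_peaks > 0, pk.affine)
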