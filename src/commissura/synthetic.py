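"""Synthetic inputs: multi-bundle DWI phantoms with ground truth, protocol
ROI presets in phantom space, and statistical cohorts with planted effects.

The phantom emulates the geometry the dissection pipeline was designed for:

* a commissural arc ("dhc_like") running between two bilateral seed blobs,
  crossing the grid's central sagittal plane (the phantom "midline");
* a straight decoy bundle ("fornix_like") that clips one seed blob — like
  the fornix sharing the alveus with commissural fibres — and runs
  anterior-posterior through the exclusion slabs, so raw tractography picks
  it up and only the boolean gates remove it;
* isotropic background everywhere else.

Voxel signals follow the single-tensor Stejskal-Tanner model; where bundles
overlap, the signal is an equal-weight multi-tensor mixture and the
orientation field carries one peak per resident bundle.

Two flavors mirror the two acquisition regimes: ``human`` (48x58x48 grid at
1.25 mm) and ``ex_vivo`` (60x72x60 at 0.5 mm); all phantom geometry scales
with the field of view.  Diffusivities are kept at in vivo tissue scale in
both flavors and the default b-value is 1000 s/mm^2, so the attenuation
(b*MD ~ 1.5) is well conditioned for the tensor fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .dissection import GateProtocol, RoiSpec, Slab, rasterize_roi
from .io import DwiDataset, GeometryError, GradientTable, ValidationError, voxel_to_world
from .tensor import OrientationField, fa_from_eigenvalues, md_from_eigenvalues

logger = logging.getLogger("commissura")

__all__ = [
    "BundleSpec",
    "PhantomTruth",
    "CohortSpec",
    "prolate_eigenvalues",
    "make_gradient_table",
    "arc_centerline",
    "line_centerline",
    "build_phantom",
    "add_rician_noise",
    "make_cohort",
]

#: default non-diffusion-weighted signal amplitude
S0_DEFAULT = 100.0
#: isotropic background diffusivity (mm^2/s), typical deep gray/mixed tissue
BACKGROUND_DIFFUSIVITY = 0.7e-3

_FLAVOR_GRID = {
    "human": ((48, 58, 48), 1.25),
    "ex_vivo": ((60, 72, 60), 0.5),
}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """A tube of coherent fibres: a centerline, a radius and a tensor shape.

    ``eigenvalues`` (mm^2/s, descending) orient lambda_1 along the local
    centerline tangent.
    """

    name: str
    centerline: np.ndarray
    radius_mm: float
    eigenvalues: tuple

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValidationError(f"bundle {self.name!r}: centerline must be (K,3)")
        if len(self.centerline) < 3:
            raise ValidationError(f"bundle {self.name!r}: centerline needs >= 3 points")
        if not self.radius_mm > 0:
            raise ValidationError(f"bundle {self.name!r}: radius must be > 0")
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValidationError(
                f"bundle {self.name!r}: eigenvalues must satisfy l1 >= l2 >= l3 > 0"
            )

    @property
    def fa(self) -> float:
        return float(fa_from_eigenvalues(np.asarray(self.eigenvalues)))

    @property
    def md(self) -> float:
        return float(md_from_eigenvalues(np.asarray(self.eigenvalues)))


@dataclass
class PhantomTruth:
    """Everything a test needs to score the pipeline against ground truth."""

    bundle_masks: dict
    centerlines: dict
    bundle_fa: dict
    bundle_md: dict
    rois: dict
    protocol: GateProtocol
    background_diffusivity: float
    affine: np.ndarray
    grid_shape: tuple
    seed_names: tuple = ()


@dataclass
class CohortSpec:
    """Generator settings for a synthetic study cohort.

    The planted effect is the correlation between the commissural-tract MD
    and the word-recognition memory score; regional volumes are confounded
    with intracranial volume through ``volume_icv_corr``.  Defaults follow
    the human study's observed scales (tract MD ~1.478e-3 mm^2/s etc.).
    """

    n_subjects: int = 95
    true_corr_md_memory: float = -0.269
    md_mean: float = 1.478e-3
    md_sd: float = 0.163e-3
    score_mean: float = 35.79
    score_sd: float = 2.78
    icv_mean: float = 1_587_548.46
    icv_sd: float = 176_651.55
    volume_icv_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.true_corr_md_memory) < 1:
            raise ValidationError("|true_corr_md_memory| must be < 1")
        for name in ("md_sd", "score_sd", "icv_sd"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not -1 < self.volume_icv_corr < 1:
            raise ValidationError("|volume_icv_corr| must be < 1")
        if self.n_subjects < 4:
            raise ValidationError("need n_subjects >= 4 for correlations")


# secondary cohort columns: (mean, sd) at the human study's scale
_COHORT_MARGINALS = {
    "dhc_fa": (0.318, 0.059),
    "ac_fa": (0.439, 0.050),
    "ac_md": (0.854e-3, 0.051e-3),
    "psmt": (112.15, 14.34),
    "lswmt": (110.15, 11.49),
}
_REGION_VOLUMES = {
    "hippocampus": (8856.07, 663.78),
    "amygdala": (3210.26, 310.89),
    "entorhinal": (3460.21, 575.65),
    "parahippocampal": (4391.78, 523.85),
    "temporal_pole": (4682.52, 490.93),
}


# ---------------------------------------------------------------------------
# small constructors
# ---------------------------------------------------------------------------

def prolate_eigenvalues(md: float, fa: float) -> tuple:
    """Axially symmetric eigenvalues (l1, l2, l2) with the requested MD and FA.

    Closed form: l1 = MD + 2 d, l2 = l3 = MD - d with
    d = FA * MD / sqrt(3 - 2 FA^2).
    """
    if not 0 <= fa < 1:
        raise ValidationError("fa must be in [0, 1)")
    if not md > 0:
        raise ValidationError("md must be > 0")
    d = fa * md / np.sqrt(3.0 - 2.0 * fa**2)
    l1, l2 = md + 2 * d, md - d
    if l2 <= 0:
        raise ValidationError(f"fa={fa} too high for a prolate tensor at md={md}")
    return (float(l1), float(l2), float(l2))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def make_gradient_table(n_dirs: int = 90, bval: float = 1000.0,
                        n_b0: int = 9) -> GradientTable:
    """A single-shell scheme with quasi-uniform (Fibonacci) directions."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    bvecs = np.vstack([np.tile([1.0, 0.0, 0.0], (n_b0, 1)), _fibonacci_sphere(n_dirs)])
    return GradientTable(bvals, bvecs)


def arc_centerline(radius: float, center, theta_start_deg: float,
                   theta_end_deg: float, n: int = 200) -> np.ndarray:
    """Circular arc in the x-z plane at fixed y (a commissural arch)."""
    th = np.deg2rad(np.linspace(theta_start_deg, theta_end_deg, n))
    cx, cy, cz = center
    return np.column_stack([cx + radius * np.cos(th),
                            np.full(n, cy),
                            cz + radius * np.sin(th)])


def line_centerline(start, end, n: int = 100) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return np.asarray(start) + t * (np.asarray(end) - np.asarray(start))


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _densify(polyline: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~``spacing`` and return (points, unit tangents)."""
    seg = np.diff(polyline, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    s = np.linspace(0.0, total, n)
    pts = np.column_stack([np.interp(s, arclen, polyline[:, k]) for k in range(3)])
    tan = np.gradient(pts, s, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return pts, tan


def _tensor_from_tangent(tangents: np.ndarray, eigenvalues) -> np.ndarray:
    """Rotate diag(eigenvalues) so lambda_1 lies along each tangent."""
    l1, l2, l3 = eigenvalues
    t = tangents
    helper = np.where(np.abs(t[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e2 = np.cross(t, helper)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(t, e2)
    return (l1 * t[:, :, None] * t[:, None, :]
            + l2 * e2[:, :, None] * e2[:, None, :]
            + l3 * e3[:, :, None] * e3[:, None, :])


def _center_affine(grid_shape, voxel_size: float) -> np.ndarray:
    """Axis-aligned affine putting the world origin at the grid center."""
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = -(np.asarray(grid_shape) - 1) / 2.0 * voxel_size
    return affine


def _sphere_mask(grid_shape, affine, center, radius) -> np.ndarray:
    idx = np.indices(grid_shape).reshape(3, -1).T
    xyz = voxel_to_world(affine, idx)
    d = np.linalg.norm(xyz - np.asarray(center), axis=1)
    return (d <= radius).reshape(grid_shape)


def _dhc_layout(scale: float) -> dict:
    """Geometry of the 'dhc_default' preset, in mm scaled to the field of view."""
    s = scale
    arc = arc_centerline(18 * s, (0.0, 0.0, -5 * s), 185.0, -5.0)
    decoy = line_centerline((-18 * s, -20 * s, 0.0), (-18 * s, 20 * s, 0.0))
    return {
        "bundles": [
            BundleSpec("dhc_like", arc, 5.0 * s,
                       prolate_eigenvalues(1.478e-3, 0.318)),
            BundleSpec("fornix_like", decoy, 4.0 * s,
                       prolate_eigenvalues(1.0e-3, 0.45)),
        ],
        "seed_centers": {"left_hippocampus": (-18 * s, 0.0, -5 * s),
                         "right_hippocampus": (18 * s, 0.0, -5 * s)},
        "seed_radius": 2.5 * s,
        "not_slabs": [
            ("not_anterior", Slab("coronal", position_mm=10 * s)),
            ("not_posterior", Slab("coronal", position_mm=-10 * s)),
            ("not_superior", Slab("axial", position_mm=26 * s)),
        ],
    }


def _ac_layout(scale: float) -> dict:
    s = scale
    arc = arc_centerline(12 * s, (0.0, -15 * s, -10 * s), 175.0, 5.0)
    box = {"y": (-19.5 * s, -10.5 * s), "z": (-5 * s, 5.5 * s)}
    return {
        "bundles": [
            BundleSpec("ac_like", arc, 4.0 * s,
                       prolate_eigenvalues(0.854e-3, 0.439)),
        ],
        "seed_slab": Slab("sagittal", position_mm=-6.25 * s, extent_mm=box),
        "and_slab": Slab("sagittal", position_mm=6.25 * s, extent_mm=box),
        "not_slabs": [
            ("not_superior", Slab("axial", position_mm=8 * s)),
            ("not_posterior", Slab("coronal", position_mm=-25 * s)),
            ("not_anterior", Slab("coronal", position_mm=-5 * s)),
        ],
    }


def _cut_planes(scale: float, voxel_size: float) -> tuple:
    # five sagittal slices either side of the midline, in native voxel units
    off = 5 * voxel_size
    return (-off, off)


def build_phantom(
    layout="dhc_default",
    flavor: str = "human",
    grid_shape=None,
    voxel_size_mm: float | None = None,
    gradients: GradientTable | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    s0: float = S0_DEFAULT,
    background_diffusivity: float = BACKGROUND_DIFFUSIVITY,
) -> tuple[DwiDataset, OrientationField, PhantomTruth]:
    """Build a multi-bundle DWI phantom with ground truth.

    ``layout`` is a named preset (``"dhc_default"`` or ``"ac_default"``) or a
    list of :class:`BundleSpec` (in which case no protocol ROIs are emitted
    and ``truth.protocol`` is None).  Returns the synthetic dataset, the
    ground-truth orientation field (one peak per resident bundle) and a
    :class:`PhantomTruth`.
    """
    if flavor not in _FLAVOR_GRID:
        raise ValidationError(f"unknown flavor {flavor!r}")
    default_shape, default_vox = _FLAVOR_GRID[flavor]
    grid_shape = tuple(grid_shape) if grid_shape is not None else default_shape
    voxel_size = float(voxel_size_mm) if voxel_size_mm is not None else default_vox
    affine = _center_affine(grid_shape, voxel_size)
    scale = voxel_size / 1.25  # geometry is authored at human scale
    gradients = gradients if gradients is not None else make_gradient_table()

    preset = None
    if isinstance(layout, str):
        preset = layout
        if layout == "dhc_default":
            lay = _dhc_layout(scale)
        elif layout == "ac_default":
            lay = _ac_layout(scale)
        else:
            raise ValidationError(f"unknown phantom preset {layout!r}")
        bundles = lay["bundles"]
    else:
        bundles = list(layout)
        lay = {"not_slabs": []}
    names = [b.name for b in bundles]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate bundle names: {names}")

    # rasterize bundles
    idx = np.indices(grid_shape).reshape(3, -1).T
    centers = voxel_to_world(affine, idx)
    half_fov = (np.asarray(grid_shape) - 1) / 2.0 * voxel_size
    masks, tangents, dense_lines = {}, {}, {}
    for b in bundles:
        if np.any(np.abs(b.centerline) > half_fov[None, :] + 1e-9):
            raise GeometryError(f"bundle {b.name!r} centerline leaves the grid")
        pts, tan = _densify(b.centerline, voxel_size / 3.0)
        tree = cKDTree(pts)
        dist, nearest = tree.query(centers, workers=-1)
        inside = dist <= b.radius_mm
        masks[b.name] = inside.reshape(grid_shape)
        tangents[b.name] = tan[nearest[inside]]
        dense_lines[b.name] = pts

    # signal synthesis
    bvals, bvecs = gradients.bvals, gradients.bvecs
    n_vol = len(gradients)
    signal = np.empty(grid_shape + (n_vol,), dtype=np.float32)
    iso_att = np.exp(-bvals * background_diffusivity)
    signal[:] = (s0 * iso_att).astype(np.float32)

    n_resident = np.zeros(grid_shape, dtype=np.int64)
    for b in bundles:
        n_resident += masks[b.name]
    flat_any = n_resident.reshape(-1) > 0
    att_sum = np.zeros((flat_any.sum(), n_vol))
    res_flat = n_resident.reshape(-1)[flat_any].astype(float)
    # map bundle voxels into the "any bundle" compressed index space
    any_index = -np.ones(np.prod(grid_shape), dtype=np.int64)
    any_index[flat_any] = np.arange(flat_any.sum())
    for b in bundles:
        flat = masks[b.name].reshape(-1)
        D = _tensor_from_tangent(tangents[b.name], b.eigenvalues)
        expo = np.einsum("ni,vij,nj->vn", bvecs, D, bvecs)
        att = np.exp(-bvals[None, :] * expo)
        att_sum[any_index[flat]] += att
    att_mix = att_sum / res_flat[:, None]
    sig_flat = signal.reshape(-1, n_vol)
    sig_flat[flat_any] = (s0 * att_mix).astype(np.float32)

    brain_mask = np.ones(grid_shape, dtype=bool)
    dataset = DwiDataset(signal, affine, gradients, brain_mask)
    if noise_sigma:
        dataset = add_rician_noise(dataset, noise_sigma, seed)

    # ground-truth orientation field: one peak per resident bundle
    max_p = max(1, int(n_resident.max()))
    peaks = np.zeros(grid_shape + (max_p, 3))
    amps = np.zeros(grid_shape + (max_p,))
    n_peaks = np.zeros(grid_shape, dtype=np.int64)
    for b in bundles:
        m = masks[b.name]
        slot = n_peaks[m]
        flat_ids = np.flatnonzero(m.reshape(-1))
        pk = peaks.reshape(-1, max_p, 3)
        am = amps.reshape(-1, max_p)
        pk[flat_ids, slot] = tangents[b.name]
        am[flat_ids, slot] = b.fa
        n_peaks[m] += 1
    support = n_peaks > 0
    ofield = OrientationField(peaks, amps, n_peaks, support, affine)

    # protocol ROIs
    rois: dict[str, RoiSpec] = {}
    protocol = None
    seed_names: tuple = ()
    if preset == "dhc_default":
        for name, c in lay["seed_centers"].items():
            role = "SEED" if name.startswith("left") else "AND"
            rois[name] = RoiSpec(name, role,
                                 mask=_sphere_mask(grid_shape, affine, c,
                                                   lay["seed_radius"]))
        for name, slab in lay["not_slabs"]:
            rois[name] = RoiSpec(name, "NOT", slab=slab)
        protocol = GateProtocol(
            "dhc_default",
            seed=rois["left_hippocampus"],
            ands=[rois["right_hippocampus"]],
            nots=[rois[n] for n, _ in lay["not_slabs"]],
            cut_planes=_cut_planes(scale, voxel_size),
        )
        seed_names = ("left_hippocampus", "right_hippocampus")
        _check_dhc_truth(masks, rois, grid_shape, affine)
    elif preset == "ac_default":
        rois["seed_left"] = RoiSpec("seed_left", "SEED", slab=lay["seed_slab"])
        rois["and_right"] = RoiSpec("and_right", "AND", slab=lay["and_slab"])
        for name, slab in lay["not_slabs"]:
            rois[name] = RoiSpec(name, "NOT", slab=slab)
        protocol = GateProtocol(
            "ac_default",
            seed=rois["seed_left"],
            ands=[rois["and_right"]],
            nots=[rois[n] for n, _ in lay["not_slabs"]],
            cut_planes=_cut_planes(scale, voxel_size),
        )
        seed_names = ("seed_left", "and_right")

    truth = PhantomTruth(
        bundle_masks=masks,
        centerlines=dense_lines,
        bundle_fa={b.name: b.fa for b in bundles},
        bundle_md={b.name: b.md for b in bundles},
        rois=rois,
        protocol=protocol,
        background_diffusivity=background_diffusivity,
        affine=affine,
        grid_shape=grid_shape,
        seed_names=seed_names,
    )
    logger.info("phantom %s/%s: grid %s, %d bundle voxels",
                preset or "custom", flavor, grid_shape, int((n_resident > 0).sum()))
    return dataset, ofield, truth


def _check_dhc_truth(masks, rois, grid_shape, affine) -> None:
    """Assert the preset honors its own ground-truth invariants."""
    left = rois["left_hippocampus"].mask
    right = rois["right_hippocampus"].mask
    dhc = masks["dhc_like"]
    decoy = masks["fornix_like"]
    if not ((dhc & left).any() and (dhc & right).any()):
        raise GeometryError("dhc_like bundle must intersect both seed blobs")
    if not (decoy & left).any() or (decoy & right).any():
        raise GeometryError("decoy must intersect exactly the left seed blob")
    hit_not = any(
        (decoy & rasterize_roi(rois[n], grid_shape, affine)).any()
        for n in rois if rois[n].role == "NOT"
    )
    if not hit_not:
        raise GeometryError("decoy must cross at least one NOT slab")


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_rician_noise(d: DwiDataset, sigma: float, seed: int = 0) -> DwiDataset:
    """Rician-corrupt every voxel/volume: sqrt((S+e1)^2 + e2^2), e ~ N(0, s^2)."""
    if sigma < 0:
        raise ValidationError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    s = np.asarray(d.signal, dtype=np.float64)
    e1 = rng.normal(0.0, sigma, size=s.shape)
    e2 = rng.normal(0.0, sigma, size=s.shape)
    noisy = np.sqrt((s + e1) ** 2 + e2**2).astype(d.signal.dtype)
    return DwiDataset(noisy, d.affine, d.gradients, d.brain_mask)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def make_cohort(spec: CohortSpec):
    """One row per subject: tract metrics, cognition scores, volumes, ICV.

    ``(dhc_md, cpwm)`` is drawn bivariate normal with the planted
    correlation; every regional volume is ``gamma * ICV`` plus independent
    noise, with ``gamma`` chosen so corr(volume, ICV) = ``volume_icv_corr``.
    Fully deterministic under ``spec.seed``.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    rho = spec.true_corr_md_memory
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    md = spec.md_mean + spec.md_sd * z1
    score = spec.score_mean + spec.score_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
    data = {
        "subject": [f"sub-{i:04d}" for i in range(n)],
        "dhc_md": md,
        "cpwm": score,
    }
    for col, (mean, sd) in _COHORT_MARGINALS.items():
        data[col] = mean + sd * rng.standard_normal(n)
    icv = spec.icv_mean + spec.icv_sd * rng.standard_normal(n)
    data["icv"] = icv
    c = spec.volume_icv_corr
    for col, (mean, sd) in _REGION_VOLUMES.items():
        gamma = c * sd / spec.icv_sd
        noise_sd = sd * np.sqrt(1 - c**2)
        data[col] = mean + gamma * (icv - spec.icv_mean) + noise_sd * rng.standard_normal(n)
    frame = pd.DataFrame(data)
    order = ["subject", "dhc_fa", "dhc_md", "ac_fa", "ac_md",
             "cpwm", "psmt", "lswmt",
             *list(_REGION_VOLUMES), "icv"]
    return frame[order]
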