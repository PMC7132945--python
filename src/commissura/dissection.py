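"""Virtual dissection: boolean ROI gating and transverse-segment extraction.

A tract protocol is a SEED region, one or more AND (waypoint) regions, any
number of NOT (exclusion) regions, plus a pair of sagittal cut planes that
straddle the midline.  Gating semantics:

* a streamline survives iff it has at least one vertex in *every* AND mask
  and no vertex in *any* NOT mask (vertex membership = nearest voxel);
* commissural protocols are run bilaterally: the second pass swaps the seed
  with the first (contralateral) AND region;
* the transverse segment keeps, per streamline, the maximal contiguous
  vertex runs lying strictly between the two cut planes.

The AND test is passage-through by default; termination-only (endpoints
inside the mask) is available via ``require_termination`` for protocols that
demand streamlines actually end in the waypoint region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GeometryError, Tractogram, ValidationError, world_to_voxel
from .tracking import TrackingParams, track_from_mask

logger = logging.getLogger("commissura")

__all__ = [
    "RoiSpec",
    "Slab",
    "GateProtocol",
    "TractSegment",
    "ReconstructionFailure",
    "rasterize_roi",
    "filter_by_gates",
    "run_bilateral_protocol",
    "cut_segment",
]

#: anatomical plane -> grid axis, assuming an RAS-like grid
#: (x: sagittal/left-right, y: coronal/posterior-anterior, z: axial/inferior-superior)
PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


class ReconstructionFailure(RuntimeError):
    """Both seeding directions of a bilateral protocol produced no survivors."""


@dataclass
class Slab:
    """A declarative one-slice ROI: a whole grid plane at a given position,
    optionally restricted to an in-plane mm box and/or with mm carve-out
    boxes subtracted (e.g. "whole section except the temporal lobes").

    ``position_mm`` locates the slab on its plane axis in world mm; use
    ``slice_index`` to pin a voxel slice directly instead.
    """

    plane: str
    position_mm: float | None = None
    slice_index: int | None = None
    extent_mm: dict | None = None          # {"y": (lo, hi), "z": (lo, hi)} style
    carve_out: list = field(default_factory=list)  # list of {"x": (lo,hi), ...}

    def __post_init__(self) -> None:
        if self.plane not in PLANE_AXIS:
            raise ValidationError(f"unknown plane {self.plane!r}")
        if (self.position_mm is None) == (self.slice_index is None):
            raise ValidationError("give exactly one of position_mm / slice_index")


@dataclass
class RoiSpec:
    """A named gating region: an explicit binary mask or a declarative slab."""

    name: str
    role: str
    mask: np.ndarray | None = None
    slab: Slab | None = None

    def __post_init__(self) -> None:
        if self.role not in ("SEED", "AND", "NOT"):
            raise ValidationError(f"ROI role must be SEED/AND/NOT, got {self.role!r}")
        if (self.mask is None) == (self.slab is None):
            raise ValidationError(f"ROI {self.name!r}: give exactly one of mask / slab")


@dataclass
class GateProtocol:
    """A full dissection plan for one tract."""

    name: str
    seed: RoiSpec
    ands: list
    nots: list = field(default_factory=list)
    cut_planes: tuple = (-6.25, 6.25)      # sagittal world-mm offsets
    bilateral: bool = True

    def __post_init__(self) -> None:
        if self.seed.role != "SEED":
            raise ValidationError("protocol seed ROI must have role SEED")
        if any(a.role != "AND" for a in self.ands):
            raise ValidationError("all waypoint ROIs must have role AND")
        if any(x.role != "NOT" for x in self.nots):
            raise ValidationError("all exclusion ROIs must have role NOT")
        if self.bilateral and len(self.ands) < 1:
            raise ValidationError("a commissural protocol needs >= 1 AND region")
        lo, hi = self.cut_planes
        if not (lo < 0 < hi):
            raise ValidationError(
                f"cut planes {self.cut_planes} must strictly straddle the midline"
            )


@dataclass
class TractSegment:
    """Contiguous vertex runs of a tractogram between the cut planes."""

    runs: list                       # list of (n_i, 3) world-mm arrays
    provenance: str = ""             # "seeded-from-left" | "seeded-from-right"

    @property
    def n_vertices(self) -> int:
        return int(sum(len(r) for r in self.runs))

    def vertices(self) -> np.ndarray:
        if not self.runs:
            return np.empty((0, 3))
        return np.vstack(self.runs)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _axis_coords(grid_shape, affine, axis: int) -> np.ndarray:
    """World coordinate along ``axis`` of every voxel center (1-D per index)."""
    idx = np.zeros((grid_shape[axis], 3))
    idx[:, axis] = np.arange(grid_shape[axis])
    # assumes axis-aligned affine for declarative slabs (true for phantoms);
    # oblique grids should supply explicit masks instead
    from .io import voxel_to_world
    return voxel_to_world(affine, idx)[:, axis]


def _box_mask(grid_shape, affine, box: dict) -> np.ndarray:
    mask = np.ones(grid_shape, dtype=bool)
    for ax_name, ax in (("x", 0), ("y", 1), ("z", 2)):
        if ax_name not in box:
            continue
        lo, hi = box[ax_name]
        coords = _axis_coords(grid_shape, affine, ax)
        sel = (coords >= lo) & (coords <= hi)
        shape = [1, 1, 1]
        shape[ax] = grid_shape[ax]
        mask &= sel.reshape(shape)
    return mask


def rasterize_roi(spec: RoiSpec, grid_shape, affine) -> np.ndarray:
    """Deterministic binary mask for an ROI spec on the given grid."""
    if spec.mask is not None:
        if spec.mask.shape != tuple(grid_shape):
            raise GeometryError(
                f"ROI {spec.name!r} mask shape {spec.mask.shape} != grid {tuple(grid_shape)}"
            )
        return spec.mask.astype(bool)
    slab = spec.slab
    axis = PLANE_AXIS[slab.plane]
    if slab.slice_index is not None:
        sl = int(slab.slice_index)
    else:
        coords = _axis_coords(grid_shape, affine, axis)
        sl = int(np.argmin(np.abs(coords - slab.position_mm)))
    if not 0 <= sl < grid_shape[axis]:
        raise GeometryError(f"ROI {spec.name!r}: slab slice {sl} outside grid")
    mask = np.zeros(grid_shape, dtype=bool)
    index = [slice(None)] * 3
    index[axis] = sl
    mask[tuple(index)] = True
    if slab.extent_mm:
        mask &= _box_mask(grid_shape, affine, slab.extent_mm)
    for box in slab.carve_out:
        mask &= ~_box_mask(grid_shape, affine, box)
    if not mask.any():
        raise ValidationError(f"ROI {spec.name!r} rasterizes to an empty mask")
    return mask


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def _vertex_voxels(streamline: np.ndarray, affine, grid_shape) -> np.ndarray:
    ijk = np.rint(world_to_voxel(affine, streamline)).astype(int)
    ijk = np.clip(ijk, 0, np.asarray(grid_shape) - 1)
    return ijk


def filter_by_gates(
    t: Tractogram,
    protocol: GateProtocol,
    grid_shape=None,
    affine=None,
    require_termination: bool = False,
) -> Tractogram:
    """Keep streamlines satisfying every AND and no NOT of the protocol.

    With ``require_termination`` the AND test only inspects the two endpoint
    vertices (the streamline must end inside the waypoint region).
    """
    grid_shape = grid_shape or t.grid_shape
    affine = affine if affine is not None else t.affine
    if grid_shape is None or affine is None:
        raise GeometryError("gating needs a reference grid (shape + affine)")
    and_masks = [rasterize_roi(a, grid_shape, affine) for a in protocol.ands]
    not_masks = [rasterize_roi(x, grid_shape, affine) for x in protocol.nots]
    kept = []
    reasons = {"and": 0, "not": 0}
    for s in t.streamlines:
        ijk = _vertex_voxels(s, affine, grid_shape)
        i, j, k = ijk[:, 0], ijk[:, 1], ijk[:, 2]
        if any(m[i, j, k].any() for m in not_masks):
            reasons["not"] += 1
            continue
        if require_termination:
            ends = ijk[[0, -1]]
            ok = all(m[ends[:, 0], ends[:, 1], ends[:, 2]].any() for m in and_masks)
        else:
            ok = all(m[i, j, k].any() for m in and_masks)
        if not ok:
            reasons["and"] += 1
            continue
        kept.append(s)
    logger.info("gating %s: %d in -> %d out (AND-fail %d, NOT-hit %d)",
                protocol.name, len(t), len(kept), reasons["and"], reasons["not"])
    return Tractogram(kept, affine=affine, grid_shape=grid_shape)


def run_bilateral_protocol(
    field,
    protocol: GateProtocol,
    params: TrackingParams,
    require_termination: bool = False,
) -> tuple[Tractogram, Tractogram]:
    """Seed from the SEED region, gate, then repeat with seed/first-AND swapped.

    Returns the left- and right-seeded gated tractograms.  Raises
    :class:`ReconstructionFailure` when both passes are empty (the tract
    could not be reconstructed in this subject/phantom).
    """
    if not protocol.bilateral:
        raise ValidationError("run_bilateral_protocol requires protocol.bilateral")
    grid_shape = field.spatial_shape
    affine = field.affine

    def one_pass(seed_spec: RoiSpec, and_specs: list, tag: str) -> Tractogram:
        seed_mask = rasterize_roi(seed_spec, grid_shape, affine)
        raw = track_from_mask(field, seed_mask, params)
        pass_protocol = GateProtocol(
            name=f"{protocol.name}[{tag}]",
            seed=seed_spec,
            ands=and_specs,
            nots=protocol.nots,
            cut_planes=protocol.cut_planes,
            bilateral=True,
        )
        return filter_by_gates(raw, pass_protocol, grid_shape, affine,
                               require_termination=require_termination)

    contralateral = protocol.ands[0]
    extra_ands = protocol.ands[1:]
    swapped_seed = RoiSpec(contralateral.name, "SEED",
                           mask=contralateral.mask, slab=contralateral.slab)
    swapped_and = RoiSpec(protocol.seed.name, "AND",
                          mask=protocol.seed.mask, slab=protocol.seed.slab)

    left = one_pass(protocol.seed, [contralateral] + extra_ands, "L")
    right = one_pass(swapped_seed, [swapped_and] + extra_ands, "R")
    if len(left) == 0 and len(right) == 0:
        raise ReconstructionFailure(
            f"protocol {protocol.name!r}: no surviving streamlines from either "
            "seeding direction"
        )
    return left, right


# ---------------------------------------------------------------------------
# transverse segment
# ---------------------------------------------------------------------------

def cut_segment(
    t: Tractogram,
    cut_planes: tuple,
    axis: int = 0,
    provenance: str = "",
) -> TractSegment:
    """Extract the maximal vertex runs strictly between two sagittal planes.

    ``cut_planes`` are world-mm positions on ``axis`` (default x/sagittal);
    boundary vertices are excluded so the cut is deterministic and
    side-symmetric.  Streamlines with no vertex in the slab contribute
    nothing; no resampling is performed.
    """
    lo, hi = cut_planes
    if not lo < hi:
        raise ValidationError(f"cut planes inverted: {cut_planes}")
    runs = []
    for s in t.streamlines:
        inside = (s[:, axis] > lo) & (s[:, axis] < hi)
        if not inside.any():
            continue
        # maximal contiguous runs of True
        padded = np.concatenate([[False], inside, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        stops = np.flatnonzero(~padded[1:] & padded[:-1])
        for a, b in zip(starts, stops):
            runs.append(s[a:b])
    seg = TractSegment(runs, provenance=provenance)
    logger.info("cut segment %s: %d runs, %d vertices", provenance or "-",
                len(runs), seg.n_vertices)
    return seg
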