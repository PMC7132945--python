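"""Tractometry: sampling scalar maps along tract segments and combining the
left- and right-seeded segment means into vertex-weighted tract metrics.

The combined statistic for a scalar M (FA or MD) is

    VWM(M) = (N_LR * mean(M_LR) + N_RL * mean(M_RL)) / (N_LR + N_RL)

where N_LR / N_RL count the vertices of the segments obtained by seeding
from the left and right hemisphere respectively.  Weighting by vertex count
absorbs any asymmetry in how many streamlines each seeding direction
produced.  Per-side means pool all retained vertices (not per-streamline
averages), which is what the vertex counts in the formula refer to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .dissection import TractSegment
from .io import GeometryError, ScalarMap, ValidationError, world_to_voxel

logger = logging.getLogger("commissura")

__all__ = ["SegmentMetrics", "UndefinedMetricError", "sample_scalar_along",
           "vertex_weighted_mean", "segment_metrics"]


class UndefinedMetricError(ValueError):
    """No vertices available on either side; the subject must be excluded."""


@dataclass
class SegmentMetrics:
    """Per-side and vertex-weighted combined FA/MD for one tract."""

    n_left: int
    n_right: int
    fa_left: float
    fa_right: float
    md_left: float
    md_right: float
    fa_vw: float
    md_vw: float

    def as_row(self) -> dict:
        """Flat mapping suitable for appending to a cohort table."""
        return {
            "n_L": self.n_left, "n_R": self.n_right,
            "fa_L": self.fa_left, "fa_R": self.fa_right,
            "md_L": self.md_left, "md_R": self.md_right,
            "fa_vw": self.fa_vw, "md_vw": self.md_vw,
        }


def sample_scalar_along(segment: TractSegment, smap: ScalarMap,
                        interp: str = "trilinear") -> np.ndarray:
    """One scalar value per retained vertex.

    ``interp`` is ``"trilinear"`` (default; exact on linear fields) or
    ``"nearest"`` for sensitivity checks.  A vertex outside the map extent is
    an error — gating should make that impossible.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValidationError(f"unknown interpolation {interp!r}")
    verts = segment.vertices()
    if len(verts) == 0:
        return np.empty(0)
    vox = world_to_voxel(smap.affine, verts)
    upper = np.asarray(smap.values.shape) - 1
    bad = np.flatnonzero(np.any((vox < -0.5) | (vox > upper + 0.5), axis=1))
    if len(bad):
        raise GeometryError(
            f"vertex {bad[0]} at {verts[bad[0]]} lies outside the scalar map extent"
        )
    order = 1 if interp == "trilinear" else 0
    return map_coordinates(smap.values, vox.T, order=order, mode="nearest")


def vertex_weighted_mean(n_left: int, mean_left: float,
                         n_right: int, mean_right: float) -> float:
    """(nL*mL + nR*mR) / (nL + nR); with one empty side, the other's mean."""
    if n_left < 0 or n_right < 0:
        raise ValidationError("vertex counts must be nonnegative")
    if n_left + n_right == 0:
        raise UndefinedMetricError("no vertices on either side")
    return float((n_left * mean_left + n_right * mean_right) / (n_left + n_right))


def segment_metrics(seg_left: TractSegment, seg_right: TractSegment,
                    fa: ScalarMap, md: ScalarMap,
                    interp: str = "trilinear") -> SegmentMetrics:
    """Per-side pooled-vertex means plus vertex-weighted combination."""
    n_l, n_r = seg_left.n_vertices, seg_right.n_vertices
    if n_l + n_r == 0:
        raise UndefinedMetricError(
            "both transverse segments are empty; tract metrics undefined"
        )

    def side(seg, smap):
        if seg.n_vertices == 0:
            return np.nan
        return float(np.mean(sample_scalar_along(seg, smap, interp=interp)))

    fa_l, fa_r = side(seg_left, fa), side(seg_right, fa)
    md_l, md_r = side(seg_left, md), side(seg_right, md)
    fa_vw = vertex_weighted_mean(n_l, 0.0 if n_l == 0 else fa_l,
                                 n_r, 0.0 if n_r == 0 else fa_r)
    md_vw = vertex_weighted_mean(n_l, 0.0 if n_l == 0 else md_l,
                                 n_r, 0.0 if n_r == 0 else md_r)
    m = SegmentMetrics(n_l, n_r, fa_l, fa_r, md_l, md_r, fa_vw, md_vw)
    logger.info("segment metrics: nL=%d nR=%d fa_vw=%.4f md_vw=%.4g",
                n_l, n_r, fa_vw, md_vw)
    return m
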