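"""ROI rasterization, boolean gating semantics, bilateral runs, segment cuts."""

import numpy as np
import pytest

import commissura as cm
from commissura.dissection import (GateProtocol, RoiSpec, Slab, cut_segment,
                                   filter_by_gates, rasterize_roi)
from commissura.io import Tractogram
from commissura.synthetic import arc_centerline


GRID = (20, 20, 20)
EYE = np.eye(4)


def straight_line(x0, x1, y, z, n=50):
    xs = np.linspace(x0, x1, n)
    return np.column_stack([xs, np.full(n, float(y)), np.full(n, float(z))])


class TestRasterize:
    def test_sagittal_slab_fills_one_slice(self):
        spec = RoiSpec("s", "NOT", slab=Slab("sagittal", slice_index=10))
        mask = rasterize_roi(spec, GRID, EYE)
        assert mask[10].all()
        assert mask.sum() == 20 * 20

    def test_whole_section_with_carve_out_set_algebra(self):
        carve = [{"x": (3.0, 8.0), "z": (2.0, 6.0)}]
        spec = RoiSpec("c", "NOT",
                       slab=Slab("coronal", position_mm=7.0, carve_out=carve))
        mask = rasterize_roi(spec, GRID, EYE)
        # independent oracle: plane minus box, voxel by voxel
        expected = np.zeros(GRID, bool)
        expected[:, 7, :] = True
        for i in range(20):
            for k in range(20):
                if 3 <= i <= 8 and 2 <= k <= 6:
                    expected[i, 7, k] = False
        np.testing.assert_array_equal(mask, expected)

    def test_carve_out_covering_plane_is_empty_roi(self):
        carve = [{"x": (-1.0, 30.0), "z": (-1.0, 30.0)}]
        spec = RoiSpec("c", "NOT",
                       slab=Slab("coronal", position_mm=7.0, carve_out=carve))
        with pytest.raises(cm.ValidationError, match="empty"):
            rasterize_roi(spec, GRID, EYE)

    def test_slab_outside_grid_rejected(self):
        spec = RoiSpec("s", "NOT", slab=Slab("axial", slice_index=25))
        with pytest.raises(cm.GeometryError):
            rasterize_roi(spec, GRID, EYE)

    def test_mm_position_resolves_to_nearest_slice(self):
        affine = np.diag([1.25, 1.25, 1.25, 1.0])
        spec = RoiSpec("s", "AND", slab=Slab("sagittal", position_mm=6.3))
        mask = rasterize_roi(spec, GRID, affine)
        assert mask[5].all() and mask.sum() == 400  # 6.3/1.25 ~ slice 5


def _protocol(ands, nots):
    seed = RoiSpec("seed", "SEED", mask=np.ones(GRID, bool))
    return GateProtocol("fixture", seed=seed, ands=ands, nots=nots,
                        cut_planes=(-5.0, 5.0))


@pytest.fixture(scope="module")
def masks():
    and_mask = np.zeros(GRID, bool)
    and_mask[15, 10, 10] = True
    not_mask = np.zeros(GRID, bool)
    not_mask[5, 10, 10] = True
    return (RoiSpec("a", "AND", mask=and_mask),
            RoiSpec("x", "NOT", mask=not_mask))


class TestGatingSemantics:
    def test_truth_table_exhaustive(self, masks):
        """Survivors are exactly the streamlines hitting the AND and missing
        the NOT, enumerated over all membership combinations."""
        roi_and, roi_not = masks
        cases = {
            "hits_and_only": straight_line(12, 18, 10, 10),
            "hits_not_only": straight_line(2, 8, 10, 10),
            "hits_both": straight_line(2, 18, 10, 10),
            "hits_neither": straight_line(2, 18, 3, 3),
        }
        t = Tractogram(list(cases.values()), affine=EYE, grid_shape=GRID)
        out = filter_by_gates(t, _protocol([roi_and], [roi_not]))
        survivors = [tuple(s[0]) for s in out.streamlines]
        assert len(out) == 1
        assert tuple(cases["hits_and_only"][0]) in survivors

    def test_not_dominates_and(self, masks):
        roi_and, roi_not = masks
        t = Tractogram([straight_line(2, 18, 10, 10)], affine=EYE,
                       grid_shape=GRID)
        assert len(filter_by_gates(t, _protocol([roi_and], [roi_not]))) == 0
        assert len(filter_by_gates(t, _protocol([roi_and], []))) == 1

    def test_gating_idempotent(self, masks):
        roi_and, roi_not = masks
        t = Tractogram([straight_line(12, 18, 10, 10),
                        straight_line(2, 18, 10, 10)], affine=EYE,
                       grid_shape=GRID)
        once = filter_by_gates(t, _protocol([roi_and], [roi_not]))
        twice = filter_by_gates(once, _protocol([roi_and], [roi_not]))
        assert len(once) == len(twice)
        for a, b in zip(once, twice):
            np.testing.assert_array_equal(a, b)

    def test_gating_monotone_in_rois(self, masks):
        roi_and, roi_not = masks
        extra_and = RoiSpec("a2", "AND", mask=np.roll(roi_and.mask, 1, axis=0))
        rng = np.random.default_rng(5)
        streams = [straight_line(2, 18, int(rng.integers(3, 17)),
                                 int(rng.integers(3, 17))) for _ in range(30)]
        streams += [straight_line(12, 18, 10, 10)]
        t = Tractogram(streams, affine=EYE, grid_shape=GRID)
        base = len(filter_by_gates(t, _protocol([roi_and], [])))
        with_not = len(filter_by_gates(t, _protocol([roi_and], [roi_not])))
        with_and = len(filter_by_gates(t, _protocol([roi_and, extra_and], [])))
        assert with_not <= base
        assert with_and <= base

    def test_termination_only_flag_restricts_to_endpoints(self, masks):
        roi_and, _ = masks
        passes_through = straight_line(2, 18, 10, 10)   # crosses the AND voxel
        t = Tractogram([passes_through], affine=EYE, grid_shape=GRID)
        assert len(filter_by_gates(t, _protocol([roi_and], []))) == 1
        assert len(filter_by_gates(t, _protocol([roi_and], []),
                                   require_termination=True)) == 0
        ends_inside = straight_line(2, 15, 10, 10)
        t2 = Tractogram([ends_inside], affine=EYE, grid_shape=GRID)
        assert len(filter_by_gates(t2, _protocol([roi_and], []),
                                   require_termination=True)) == 1


class TestBilateralProtocol:
    def test_phantom_passes_nonempty_and_decoy_free(self, phantom, bilateral):
        _, _, truth = phantom
        left, right = bilateral
        assert len(left) > 0 and len(right) > 0
        # no survivor may dwell in decoy-only territory
        decoy_only = truth.bundle_masks["fornix_like"] & \
            ~truth.bundle_masks["dhc_like"]
        from commissura.dissection import _vertex_voxels
        for t in (left, right):
            for s in t.streamlines:
                ijk = _vertex_voxels(s, truth.affine, truth.grid_shape)
                assert not decoy_only[ijk[:, 0], ijk[:, 1], ijk[:, 2]].any()

    def test_symmetric_phantom_counts_balance(self):
        arc = arc_centerline(18.0, (0.0, 0.0, -5.0), 185.0, -5.0)
        spec = cm.BundleSpec("arc", arc, 5.0,
                             cm.prolate_eigenvalues(1.478e-3, 0.318))
        _, field, truth = cm.build_phantom([spec], flavor="human")
        from commissura.synthetic import _sphere_mask
        left = RoiSpec("L", "SEED", mask=_sphere_mask(
            truth.grid_shape, truth.affine, (-18, 0, -5), 2.5))
        right = RoiSpec("R", "AND", mask=_sphere_mask(
            truth.grid_shape, truth.affine, (18, 0, -5), 2.5))
        proto = GateProtocol("sym", seed=left, ands=[right],
                             cut_planes=(-6.25, 6.25))
        tl, tr = cm.run_bilateral_protocol(field, proto, cm.TrackingParams())
        assert abs(len(tl) - len(tr)) / max(len(tl), len(tr)) < 0.10

    def test_ac_preset_crosses_midline_where_unblocked(self):
        _, field, truth = cm.build_phantom("ac_default", flavor="human")
        tl, tr = cm.run_bilateral_protocol(field, truth.protocol,
                                           cm.TrackingParams())
        assert len(tl) > 0 and len(tr) > 0
        for t in (tl, tr):
            for s in t.streamlines:
                assert s[:, 0].min() < 0 < s[:, 0].max()

    def test_failure_signal_when_nothing_survives(self, phantom):
        _, field, truth = phantom
        # an AND region in empty background is unreachable
        bad = np.zeros(truth.grid_shape, bool)
        bad[2, 2, 2] = True
        proto = GateProtocol(
            "doomed", seed=truth.rois["left_hippocampus"],
            ands=[RoiSpec("nowhere", "AND", mask=bad)],
            cut_planes=(-6.25, 6.25))
        with pytest.raises(cm.ReconstructionFailure):
            cm.run_bilateral_protocol(field, proto, cm.TrackingParams())


class TestCutSegment:
    def test_enumeration_oracle_integer_vertices(self):
        xs = np.arange(-12, 13, dtype=float)
        s = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
        t = Tractogram([s], affine=EYE, grid_shape=GRID)
        seg = cut_segment(t, (-6.25, 6.25))
        expected = [x for x in xs if -6.25 < x < 6.25]
        assert seg.n_vertices == len(expected)
        np.testing.assert_array_equal(sorted(seg.vertices()[:, 0]), expected)

    def test_crossing_both_planes_keeps_inner_run_only(self):
        s = straight_line(-15, 15, 0, 0, n=61)
        t = Tractogram([s], affine=EYE, grid_shape=GRID)
        seg = cut_segment(t, (-5.0, 5.0))
        assert len(seg.runs) == 1
        assert np.all(np.abs(seg.vertices()[:, 0]) < 5.0)

    def test_streamline_outside_slab_contributes_nothing(self):
        s = straight_line(8, 15, 0, 0)
        t = Tractogram([s], affine=EYE, grid_shape=GRID)
        assert cut_segment(t, (-5.0, 5.0)).n_vertices == 0

    def test_inverted_planes_rejected(self):
        t = Tractogram([straight_line(-5, 5, 0, 0)], affine=EYE,
                       grid_shape=GRID)
        with pytest.raises(cm.ValidationError):
            cut_segment(t, (5.0, -5.0))

    def test_segment_vertices_subset_of_original(self, bilateral, phantom):
        _, _, truth = phantom
        left, _ = bilateral
        seg = cut_segment(left, truth.protocol.cut_planes)
        all_orig = {tuple(np.round(v, 9)) for s in left.streamlines for v in s}
        sample = seg.vertices()[:: max(1, seg.n_vertices // 200)]
        for v in sample:
            assert tuple(np.round(v, 9)) in all_orig

    def test_mean_midline_crossing_near_true_apex(self, bilateral, phantom):
        _, _, truth = phantom
        left, right = bilateral
        apex_z = truth.centerlines["dhc_like"][
            np.argmin(np.abs(truth.centerlines["dhc_like"][:, 0])), 2]
        zs = []
        for t in (left, right):
            for s in t.streamlines:
                i = np.argmin(np.abs(s[:, 0]))
                zs.append(s[i, 2])
        assert abs(np.mean(zs) - apex_z) <= 1.25
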