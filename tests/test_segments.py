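"""Segment division, voxel assignment, native mapping and weighted profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alongtract.segments import (SegmentSet, TractProfile, VoxelInclusionMask,
                                 assign_voxels, build_profiles, divide_segments,
                                 include_voxels, to_native, weighted_metric)
from alongtract.skeleton import Skeleton, TractVolume


def straight_skeleton(length=24.2, n=200):
    s = np.linspace(0, length, n)
    curve = np.stack([s, np.zeros(n), np.zeros(n)], axis=1)
    return Skeleton(curve=curve, arclengths=s)


class TestDivide:
    def test_closed_form_length(self):
        segs = divide_segments(straight_skeleton(24.2), 30, 0.2)
        assert segs.segment_length == pytest.approx(1.0, abs=1e-9)
        assert segs.intervals[1, 0] - segs.intervals[0, 0] == pytest.approx(0.8)
        assert segs.intervals[-1, 1] == pytest.approx(24.2)

    def test_single_segment(self):
        segs = divide_segments(straight_skeleton(10), 1, 0.2)
        assert segs.intervals.tolist() == [[0, 10]]

    def test_disjoint_when_no_overlap(self):
        segs = divide_segments(straight_skeleton(10), 10, 0.0)
        assert np.allclose(segs.intervals[:, 1] - segs.intervals[:, 0], 1.0)
        assert np.allclose(segs.intervals[1:, 0], segs.intervals[:-1, 1])

    @given(st.integers(1, 60), st.floats(0.0, 0.9), st.floats(5.0, 300.0))
    @settings(max_examples=60, deadline=None)
    def test_length_identity(self, n, overlap, total):
        segs = divide_segments(straight_skeleton(total), n, overlap)
        ell = segs.segment_length
        assert ell * (1 + (n - 1) * (1 - overlap)) == pytest.approx(total, rel=1e-6)


class TestAssign:
    def test_exclusive_and_overlap_zones(self):
        # segment length 1.0 mm, stride 0.8 mm on a 24.2 mm skeleton
        skel = straight_skeleton(24.2)
        segs = divide_segments(skel, 30, 0.2)
        data = np.zeros((30, 3, 3))
        data[5, 1, 1] = 1.0   # arc 4.5 -> exclusive zone of segment 6 [4.0, 5.0]
        data[9, 1, 1] = 1.0   # arc 8.1 -> overlap of segments 10 and 11
        aff = np.diag([0.9, 1.0, 1.0, 1.0])  # voxel centers at 0.9*i mm
        vol = TractVolume(data, aff, threshold=0.5)
        out = assign_voxels(vol, skel, segs)
        assert [i for i in range(30) if out.labels[i][5, 1, 1]] == [5]
        assert len([i for i in range(30) if out.labels[i][9, 1, 1]]) == 2

    def test_interior_counts_balanced_on_tube(self, line_phantom, line_skeleton):
        _, vol, _, _ = line_phantom
        segs = assign_voxels(vol, line_skeleton,
                             divide_segments(line_skeleton, 30, 0.2))
        counts = np.array([segs.labels[i].sum() for i in range(30)])
        inner = counts[4:26]
        assert inner.std() / inner.mean() < 0.10

    def test_dual_label_fraction_matches_overlap(self, line_phantom, line_skeleton):
        _, vol, _, _ = line_phantom
        segs = assign_voxels(vol, line_skeleton,
                             divide_segments(line_skeleton, 30, 0.2))
        stack = np.stack([segs.labels[i] for i in range(30)])
        interior = stack[3:27].sum(0)
        frac = (interior[interior > 0] == 2).mean()
        assert frac == pytest.approx(0.2, abs=0.05)


class TestToNative:
    def _segs_with_labels(self, shape=(20, 20, 20)):
        skel = straight_skeleton(15)
        segs = divide_segments(skel, 5, 0.2)
        rng = np.random.default_rng(3)
        labels = {}
        for i in range(5):
            m = np.zeros(shape, bool)
            m[3 * i + 2:3 * i + 5, 8:13, 8:13] = True
            labels[i] = m
        return SegmentSet(5, 0.2, segs.intervals, labels)

    def test_identity_affine_preserves_labels(self):
        segs = self._segs_with_labels()
        out = to_native(segs, np.eye(4), np.eye(4), (20, 20, 20))
        for i in range(5):
            assert np.array_equal(out.labels[i], segs.labels[i])

    def test_translation_by_one_voxel(self):
        segs = self._segs_with_labels()
        native_affine = np.eye(4)
        native_affine[0, 3] = 1.0  # native voxel i maps to template i+1
        out = to_native(segs, np.eye(4), native_affine, (20, 20, 20))
        for i in range(5):
            assert np.array_equal(out.labels[i][:-1], segs.labels[i][1:])

    def test_roundtrip_small_affine(self):
        segs = self._segs_with_labels()
        rng = np.random.default_rng(7)
        ang = np.deg2rad(2.0)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        n2t = np.eye(4)
        n2t[:3, :3] = rot
        n2t[:3, 3] = [0.8, -0.5, 0.3]
        fwd = to_native(segs, np.eye(4), np.eye(4), (20, 20, 20),
                        world_native_to_template=n2t)
        back = to_native(fwd, np.eye(4), np.eye(4), (20, 20, 20),
                         world_native_to_template=np.linalg.inv(n2t))
        agree = 0
        total = 0
        for i in range(5):
            a, b = segs.labels[i], back.labels[i]
            agree += (a & b).sum()
            total += a.sum()
        assert agree / total >= 0.9

    def test_all_outside_raises(self):
        segs = self._segs_with_labels()
        n2t = np.eye(4)
        n2t[:3, 3] = [500, 500, 500]
        with pytest.raises(ValueError, match="outside"):
            to_native(segs, np.eye(4), np.eye(4), (20, 20, 20),
                      world_native_to_template=n2t)


class TestInclusion:
    def _mask(self, fa=0.5, prob=1e-3, wm=1):
        shape = (4, 4, 4)
        return VoxelInclusionMask(
            wm_mask=np.full(shape, wm), fa_map=np.full(shape, fa),
            tract_prob=np.full(shape, prob))

    def test_fa_threshold_is_strict(self):
        assert not self._mask(fa=0.2).gate().any()
        assert self._mask(fa=0.2000001).gate().all()

    def test_probability_threshold_is_inclusive(self):
        assert self._mask(prob=5e-5).gate().all()
        assert not self._mask(prob=4.9e-5).gate().any()

    def test_wm_mask_overrides(self):
        assert not self._mask(wm=0).gate().any()

    def test_filtering_applied_to_labels(self):
        segs = divide_segments(straight_skeleton(15), 5, 0.2)
        labels = {i: np.ones((4, 4, 4), bool) for i in range(5)}
        segs = SegmentSet(5, 0.2, segs.intervals, labels)
        out = include_voxels(self._mask(fa=0.1), segs)
        assert not any(m.any() for m in out.labels.values())


class TestWeightedMetric:
    def test_uniform_weights_reduce_to_mean(self):
        m = np.arange(27, dtype=float).reshape(3, 3, 3)
        w = np.ones((3, 3, 3))
        vox = np.ones((3, 3, 3), bool)
        assert weighted_metric(m, w, vox) == pytest.approx(m.mean())

    def test_hand_computed(self):
        m = np.array([[[0.2, 0.6]]])
        w = np.array([[[1.0, 3.0]]])
        vox = np.ones((1, 1, 2), bool)
        assert weighted_metric(m, w, vox) == pytest.approx(0.5)

    def test_single_voxel(self):
        m = np.full((2, 2, 2), 0.7)
        w = np.random.default_rng(0).random((2, 2, 2))
        vox = np.zeros((2, 2, 2), bool)
        vox[0, 0, 0] = True
        assert weighted_metric(m, w, vox) == pytest.approx(0.7)

    def test_empty_or_zero_weight_is_nan(self):
        m = np.ones((2, 2, 2))
        assert np.isnan(weighted_metric(m, np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool)))
        vox = np.ones((2, 2, 2), bool)
        assert np.isnan(weighted_metric(m, np.zeros((2, 2, 2)), vox))

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_weight_scale_invariance_and_bounds(self, c):
        rng = np.random.default_rng(17)
        m = rng.random((4, 4, 4))
        w = rng.random((4, 4, 4)) + 0.01
        vox = rng.random((4, 4, 4)) > 0.4
        if not vox.any():
            return
        v1 = weighted_metric(m, w, vox)
        v2 = weighted_metric(m, c * w, vox)
        assert v1 == pytest.approx(v2, rel=1e-9)
        assert m[vox].min() - 1e-12 <= v1 <= m[vox].max() + 1e-12


class TestProfiles:
    def _participant(self, ndi=0.6, shape=(10, 5, 5), n_seg=4):
        labels = {}
        for i in range(n_seg):
            m = np.zeros(shape, bool)
            m[2 * i:2 * i + 3, 1:4, 1:4] = True
            labels[i] = m
        segs = SegmentSet(n_seg, 0.2, np.zeros((n_seg, 2)), labels)
        vols = {name: np.full(shape, v) for name, v in
                [("NDI", ndi), ("ODI", 0.3), ("FA", 0.5), ("MD", 8e-4)]}
        return {"segments": segs, "tract_prob": np.full(shape, 0.5), **vols}

    def test_constant_metric_yields_constant_profile(self):
        prof = build_profiles([self._participant()])
        assert np.allclose(prof.values[0, :, 0], 0.6)

    def test_identical_participants_identical_rows(self):
        prof = build_profiles([self._participant(), self._participant()])
        assert np.array_equal(prof.values[0], prof.values[1])

    def test_missing_segment_flagged_not_zero(self):
        part = self._participant()
        part["segments"].labels[2][:] = False
        prof = build_profiles([part])
        assert np.isnan(prof.values[0, 2, 0])
        df = prof.to_dataframe()
        flags = df[(df.segment == 3)]["flag"].unique()
        assert list(flags) == ["missing"]

    def test_dataframe_roundtrip(self):
        prof = build_profiles([self._participant(0.55), self._participant(0.65)])
        back = TractProfile.from_dataframe(prof.to_dataframe())
        assert np.allclose(back.values, prof.values, equal_nan=True)

    def test_linear_gradient_recovered(self, line_phantom, line_skeleton):
        from alongtract.segments import assign_voxels, divide_segments
        _, vol, curve, arclen = line_phantom
        segs = assign_voxels(vol, line_skeleton, divide_segments(line_skeleton, 30, 0.2))
        # metric linear in arc position of each voxel's nearest curve point
        from scipy.spatial import cKDTree
        coords = np.indices(vol.data.shape).reshape(3, -1).T * 2.0
        d, idx = cKDTree(curve).query(coords)
        s = np.linspace(0, arclen[-1], len(curve))[idx].reshape(vol.data.shape)
        metric = 0.4 + 0.2 * s / arclen[-1]
        prob = vol.data.copy()
        parts = [{"segments": segs, "tract_prob": prob, "NDI": metric,
                  "ODI": metric, "FA": metric, "MD": metric}]
        prof = build_profiles(parts)
        # interior segments follow the gradient linearly (terminal segments
        # absorb the tube overhang beyond the clip window by design)
        vals = prof.values[0, 1:-1, 0]
        x = segs.intervals.mean(axis=1)[1:-1]
        coef = np.polyfit(x, vals, 1)
        resid = vals - np.polyval(coef, x)
        assert np.abs(resid).max() < 0.02 * 0.2
        assert coef[0] > 0
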