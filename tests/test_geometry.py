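import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elopath import (PhantomSpec, TrajectoryTube, extract_tissue, make_phantom,
                     point_in_tube, raw_damage, resample_polyline)
from elopath.geometry import point_segment_distance
from elopath.io_formats import Tractogram, ValidationError


def _tube(entry=(0, 0, 0), target=(20, 0, 0), radius=5.0, **kw):
    return TrajectoryTube(entry=np.array(entry, float),
                          target=np.array(target, float), radius=radius, **kw)


class TestTubeMembership:
    def test_axis_midpoint_inside(self):
        assert point_in_tube(np.array([10.0, 0.0, 0.0]), _tube())

    def test_radial_boundary(self):
        t = _tube()
        assert point_in_tube(np.array([10.0, 5.0, 0.0]), t)
        assert not point_in_tube(np.array([10.0, 5.0 + 1e-9, 0.0]), t)

    def test_round_caps_extend_beyond_endpoints(self):
        t = _tube()
        assert point_in_tube(np.array([-4.0, 0.0, 0.0]), t)       # in cap
        assert not point_in_tube(np.array([-5.1, 0.0, 0.0]), t)
        flat = _tube(cap="flat")
        assert not point_in_tube(np.array([-4.0, 0.0, 0.0]), flat)
        assert point_in_tube(np.array([0.0, 4.9, 0.0]), flat)

    def test_degenerate_tube_rejected(self):
        with pytest.raises(ValidationError):
            _tube(entry=(1, 2, 3), target=(1, 2, 3))
        with pytest.raises(ValidationError):
            _tube(radius=0.0)

    def test_agrees_with_sweeping_sphere_cloud(self):
        """The analytic capsule test must agree with the construction it
        models: a sphere of the tube radius swept densely along the axis
        (step radius/10). Verdicts match except within one sweep step of
        the boundary."""
        rng = np.random.default_rng(42)
        t = _tube(entry=(3, -2, 1), target=(25, 12, -6), radius=5.0)
        step = t.radius / 10.0
        n = int(np.ceil(t.length / step))
        centers = t.entry + np.linspace(0, 1, n + 1)[:, None] * (t.target - t.entry)
        pts = rng.uniform(-15, 40, size=(1000, 3))
        analytic = t.contains(pts)
        dmin = np.min(np.linalg.norm(pts[:, None, :] - centers[None, :, :],
                                     axis=2), axis=1)
        sphere = dmin <= t.radius
        boundary = np.abs(point_segment_distance(pts, t.entry, t.target)
                          - t.radius) < step
        assert np.array_equal(analytic[~boundary], sphere[~boundary])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_membership_symmetric_in_endpoints(self, p):
        """A capsule does not care which end is the entry."""
        p = np.array(p)
        a = _tube(entry=(0, 0, 0), target=(20, 5, -3))
        b = _tube(entry=(20, 5, -3), target=(0, 0, 0))
        assert point_in_tube(p, a) == point_in_tube(p, b)


class TestResampling:
    def test_step_bound_and_vertex_retention(self):
        line = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [10.0, 7.0, 0.0]])
        out = resample_polyline(line, 1.0)
        gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.all(gaps <= 1.0 + 1e-12)
        for v in line:
            assert np.any(np.all(np.isclose(out, v), axis=1))

    def test_zero_length_segment_no_blowup(self):
        line = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [2.0, 1.0, 1.0]])
        out = resample_polyline(line, 0.25)
        assert np.all(np.isfinite(out))
        assert np.any(np.all(out == [2.0, 1.0, 1.0], axis=1))


class TestExtractTissue:
    def test_tube_in_background_is_empty(self, small_phantom):
        parc = small_phantom.parcellation
        lo, _ = parc.world_bounds()
        far = lo - 50.0
        tube = TrajectoryTube(entry=far, target=far + [10, 0, 0], radius=3.0)
        inv = extract_tissue(tube, parc, small_phantom.tractogram)
        assert inv.gm_voxels_per_roi == {}
        assert inv.fiber_indices == frozenset()

    def test_counts_match_full_volume_scan(self, small_phantom):
        """Bounding-box-pruned extraction is bit-identical to scanning
        every voxel of the volume at the default 5 mm radius."""
        parc = small_phantom.parcellation
        tube = TrajectoryTube(entry=np.array([40.0, 3.0, -2.0]),
                              target=np.array([0.0, 0.0, 0.0]), radius=5.0)
        inv = extract_tissue(tube, parc, None)
        shape = parc.label_volume.shape
        idx = np.indices(shape).reshape(3, -1).T
        centers = parc.voxel_to_world(idx)
        inside = tube.contains(centers)
        labs = parc.label_volume.reshape(-1)[inside]
        expect = {int(l): int(c) for l, c in
                  zip(*np.unique(labs[labs > 0], return_counts=True))}
        assert inv.gm_voxels_per_roi == expect

    def test_fiber_detection_selects_crossing_bundle(self, block_parcellation):
        """One bundle threads the tube, another sits far away; only the
        first may appear, verified per fibre by a direct distance check."""
        crossing = [np.array([[5.0, -20.0, 5.0], [5.0, 30.0, 5.0]]),
                    np.array([[6.0, -20.0, 4.0], [4.0, 30.0, 6.0]])]
        distant = [np.array([[100.0, 0.0, 0.0], [100.0, 10.0, 0.0]])]
        tract = Tractogram(streamlines=crossing + distant)
        tube = TrajectoryTube(entry=np.array([5.0, 5.0, -20.0]),
                              target=np.array([5.0, 5.0, 20.0]), radius=4.0)
        inv = extract_tissue(tube, block_parcellation, tract)
        assert inv.fiber_indices == {0, 1}

    def test_radius_monotonicity(self, small_phantom, small_scene):
        ph, gm, fib = small_scene
        entry = np.array([50.0, 10.0, 5.0])
        target = np.zeros(3)
        prev_counts, prev_damage = None, None
        for r in (2.0, 5.0, 8.0, 10.0):
            tube = TrajectoryTube(entry=entry, target=target, radius=r)
            inv = extract_tissue(tube, ph.parcellation, ph.tractogram)
            dmg = raw_damage(inv, gm, fib).as_array()
            if prev_counts is not None:
                for k, v in prev_counts.items():
                    assert inv.gm_voxels_per_roi.get(k, 0) >= v
                assert np.all(dmg >= prev_damage - 1e-12)
            prev_counts, prev_damage = inv.gm_voxels_per_roi, dmg

    def test_translation_equivariance(self):
        """Shifting scene and tube together leaves the inventory unchanged."""
        from elopath import Parcellation

        vol = np.zeros((10, 10, 10), dtype=np.int32)
        vol[3:7, 3:7, 3:7] = 1
        a1 = np.diag([2.0, 2.0, 2.0, 1.0])
        a2 = a1.copy()
        shift = np.array([13.0, -4.0, 7.0])
        a2[:3, 3] += shift
        p1 = Parcellation(label_volume=vol, affine=a1)
        p2 = Parcellation(label_volume=vol.copy(), affine=a2)
        t1 = TrajectoryTube(entry=np.array([0.0, 8.0, 8.0]),
                            target=np.array([18.0, 8.0, 8.0]), radius=4.0)
        t2 = TrajectoryTube(entry=t1.entry + shift, target=t1.target + shift,
                            radius=4.0)
        assert (extract_tissue(t1, p1).gm_voxels_per_roi
                == extract_tissue(t2, p2).gm_voxels_per_roi)


class TestRawDamage:
    def test_empty_inventory_zero(self, small_scene):
        from elopath.geometry import TissueInventory

        _, gm, fib = small_scene
        inv = TissueInventory(gm_voxels_per_roi={}, voxel_volume=8.0,
                              fiber_indices=frozenset())
        assert raw_damage(inv, gm, fib).as_array().tolist() == [0, 0, 0, 0]

    def test_single_roi_product(self):
        from elopath.geometry import TissueInventory
        from elopath.scores import FiberScoreTable, GMScoreTable

        gm = GMScoreTable(fcgm={1: 2.0}, scgm={1: 0.25})
        fib = FiberScoreTable(rois=[], fcwm=np.empty(0), scwm=np.empty(0))
        inv = TissueInventory(gm_voxels_per_roi={1: 10}, voxel_volume=1.0,
                              fiber_indices=frozenset())
        dmg = raw_damage(inv, gm, fib)
        assert dmg.fcgm_path == pytest.approx(20.0)
        assert dmg.scgm_path == pytest.approx(2.5)

    def test_unknown_label_rejected(self, small_scene):
        from elopath.geometry import TissueInventory

        _, gm, fib = small_scene
        inv = TissueInventory(gm_voxels_per_roi={99: 1}, voxel_volume=8.0,
                              fiber_indices=frozenset())
        with pytest.raises(ValidationError, match="99"):
            raw_damage(inv, gm, fib)

    def test_matches_explicit_loop_on_phantom(self, small_scene):
        ph, gm, fib = small_scene
        tube = TrajectoryTube(entry=np.array([45.0, -5.0, 3.0]),
                              target=np.array([-2.0, 1.0, 0.0]), radius=6.0)
        inv = extract_tissue(tube, ph.parcellation, ph.tractogram)
        dmg = raw_damage(inv, gm, fib)
        fcgm = sum(vol * gm.fcgm[k] for k, vol in inv.gm_volume_per_roi.items())
        scgm = sum(vol * gm.scgm[k] for k, vol in inv.gm_volume_per_roi.items())
        fcwm = sum(fib.fcwm[p] for p in inv.fiber_indices)
        scwm = sum(fib.scwm[p] for p in inv.fiber_indices)
        assert dmg.fcgm_path == pytest.approx(fcgm, rel=1e-12)
        assert dmg.scgm_path == pytest.approx(scgm, rel=1e-12)
        assert dmg.fcwm_path == pytest.approx(fcwm, rel=1e-12)
        assert dmg.scwm_path == pytest.approx(scwm, rel=1e-12)
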