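"""Scene synthesis: geometry fidelity, electrode placement, perturbations."""

import numpy as np
import pytest
from scipy import ndimage

import ectplan as ep
from ectplan import scenes as S


def surface_gap_mm(mask_a, mask_b, spacing):
    """Minimum surface-to-surface distance between two voxel masks."""
    dist = ndimage.distance_transform_edt(~mask_a, sampling=spacing)
    return float(dist[mask_b].min())


class TestSimplifiedScene:
    def test_sphere_volume_matches_analytic(self):
        scene = ep.build_simplified_scene(10, spacing=0.5)
        vol = scene.mask("tumor").sum() * scene.voxel_volume
        assert vol == pytest.approx(4 / 3 * np.pi * 5**3, rel=0.05)

    def test_wall_is_tenth_of_outer_diameter(self):
        # 10 mm vessel -> 1 mm wall, 8 mm blood core
        scene = ep.build_simplified_scene(10, 10.0, 3.0, "parallel", spacing=0.5)
        blood = scene.mask("blood")
        iz = scene.labels.shape[2] // 2
        area = blood[:, :, iz].sum() * scene.spacing[0] * scene.spacing[1]
        d_core = 2 * np.sqrt(area / np.pi)
        assert d_core == pytest.approx(8.0, abs=2 * scene.spacing[0])
        wall = scene.mask("vessel_wall")
        area_out = (wall | blood)[:, :, iz].sum() * scene.spacing[0] ** 2
        d_out = 2 * np.sqrt(area_out / np.pi)
        assert d_out == pytest.approx(10.0, abs=2 * scene.spacing[0])

    @pytest.mark.parametrize("orientation", ["perpendicular", "parallel"])
    @pytest.mark.parametrize("distance", [0.0, 3.0])
    def test_tumor_vessel_gap(self, orientation, distance):
        scene = ep.build_simplified_scene(10, 5.0, distance, orientation, spacing=0.5)
        gap = surface_gap_mm(scene.vessel_mask(), scene.mask("tumor"), scene.spacing)
        # surface-to-surface gap within one voxel of the requested distance
        assert gap == pytest.approx(distance, abs=2 * 0.5)

    def test_thin_wall_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="wall"):
            scene = ep.build_simplified_scene(10, 1.0, 3.0, "parallel", spacing=0.5)
        assert scene.mask("vessel_wall").any()

    def test_geometry_errors(self):
        with pytest.raises(S.GeometryError):
            ep.build_simplified_scene(-5)
        with pytest.raises(S.GeometryError):
            ep.build_simplified_scene(10, 5.0, -1.0)
        with pytest.raises(S.ConfigError):
            ep.build_simplified_scene(10, 5.0, 0.0, "diagonal")

    def test_labels_partition_grid(self):
        scene = ep.build_simplified_scene(10, 7.0, 0.0, "perpendicular", spacing=1.0)
        sc = ep.rasterize_electrodes(scene, ep.place_electrodes(scene, "ECT", 10, 5))
        assert set(np.unique(sc.labels)) <= set(sc.role_map)


class TestElectrodePlacement:
    def test_box_ring_two_mm_from_tumor_edge(self):
        scene = ep.build_simplified_scene(10, spacing=1.0)
        el = ep.place_electrodes(scene, "ECT", 10, 4)
        radii = [np.hypot(e.x, e.y) for e in el]
        assert len(el) == 4
        assert radii == pytest.approx([7.0] * 4)  # tumor radius 5 + 2 mm
        # square symmetry: 90-degree rotation permutes the positions
        pos = {(round(e.x, 6), round(e.y, 6)) for e in el}
        rot = {(round(-y, 6), round(x, 6)) for x, y in pos}
        assert pos == rot

    def test_hexagon_inside_tumor_for_large_ire(self):
        scene = ep.build_simplified_scene(30, spacing=1.0)
        el = ep.place_electrodes(scene, "IRE", 30, 7)
        assert len(el) == 7
        radii = sorted(np.hypot(e.x, e.y) for e in el)
        assert radii[0] == pytest.approx(0.0)  # center electrode
        assert radii[1:] == pytest.approx([7.0] * 6)
        pos = {(round(e.x, 6), round(e.y, 6)) for e in el if np.hypot(e.x, e.y) > 1}
        c, s = np.cos(np.pi / 3), np.sin(np.pi / 3)
        rot = {(round(c * x - s * y, 6), round(s * x + c * y, 6)) for x, y in pos}
        assert pos == rot

    def test_center_electrode_only_where_configured(self):
        scene = ep.build_simplified_scene(10, spacing=1.0)
        assert len(ep.place_electrodes(scene, "ECT", 10, 5)) == 5
        with pytest.raises(S.ConfigError):
            ep.place_electrodes(scene, "ECT", 10, 6)
        with pytest.raises(S.ConfigError):
            ep.place_electrodes(scene, "IRE", 50, 7)

    def test_tumor_centered_on_active_tip_by_default(self):
        scene = ep.build_simplified_scene(30, spacing=1.0)
        el = ep.place_electrodes(scene, "ECT", 30, 5)
        for e in el:
            assert e.tip_bottom_z == -20.0
            assert e.tip_top_z == 20.0

    def test_depth_override_for_large_perpendicular_vessel(self):
        scene = ep.build_simplified_scene(10, 10.0, 0.0, "perpendicular", spacing=1.0)
        el = ep.place_electrodes(scene, "ECT", 10, 4)
        # tips stop 1 mm past the near tumor edge (z = -(5 + 1))
        assert all(e.tip_bottom_z == -6.0 for e in el)
        el5 = ep.place_electrodes(scene, "ECT", 10, 4, depth_beyond_edge=5.0)
        assert all(e.tip_bottom_z == -10.0 for e in el5)
        # parallel vessels and small vessels keep the centered depth
        par = ep.build_simplified_scene(10, 10.0, 0.0, "parallel", spacing=1.0)
        assert all(e.tip_bottom_z == -20.0 for e in ep.place_electrodes(par, "ECT", 10, 4))
        small = ep.build_simplified_scene(10, 5.0, 0.0, "perpendicular", spacing=1.0)
        assert all(e.tip_bottom_z == -20.0 for e in ep.place_electrodes(small, "ECT", 10, 4))


class TestRasterization:
    def test_zero_electrodes_identity(self):
        scene = ep.build_simplified_scene(10, spacing=1.0)
        out = ep.rasterize_electrodes(scene, [])
        np.testing.assert_array_equal(out.labels, scene.labels)

    def test_active_tip_is_connected_rod_of_right_length(self):
        scene = ep.build_simplified_scene(10, spacing=0.5)
        el = ep.place_electrodes(scene, "ECT", 10, 4)
        sc = ep.rasterize_electrodes(scene, el)
        tip = sc.electrode_active_mask(0)
        n_comp = ndimage.label(tip)[1]
        assert n_comp == 1
        zs = sc.axis_coords(2)[np.unique(np.argwhere(tip)[:, 2])]
        assert zs.max() - zs.min() == pytest.approx(40.0, abs=1.5 * 0.5)

    def test_idempotent(self):
        scene = ep.build_simplified_scene(10, spacing=1.0)
        el = ep.place_electrodes(scene, "ECT", 10, 5)
        once = ep.rasterize_electrodes(scene, el)
        twice = ep.rasterize_electrodes(once, el)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_electrode_outside_domain_rejected(self):
        scene = ep.build_simplified_scene(10, spacing=1.0)
        with pytest.raises(S.GeometryError):
            ep.rasterize_electrodes(scene, [S.ElectrodeSpec(x=500.0, y=0.0, tip_bottom_z=-20.0)])


class TestPerturbations:
    @pytest.fixture(scope="class")
    def vessel_scene(self):
        return ep.build_simplified_scene(10, 10.0, 3.0, "parallel", spacing=1.0)

    @pytest.mark.parametrize("kind", S.PerturbationSpec.KINDS)
    def test_zero_magnitude_is_identity(self, vessel_scene, kind):
        out = ep.perturb_vessel(vessel_scene, S.PerturbationSpec(kind, 0))
        np.testing.assert_array_equal(out.labels, vessel_scene.labels)

    def test_shift_left_then_right_restores_vessel(self, vessel_scene):
        spec_l = S.PerturbationSpec("shift_left", 3)
        spec_r = S.PerturbationSpec("shift_right", 3)
        back = ep.perturb_vessel(ep.perturb_vessel(vessel_scene, spec_l), spec_r)
        np.testing.assert_array_equal(back.vessel_mask(), vessel_scene.vessel_mask())

    def test_shift_moves_centroid_by_magnitude(self, vessel_scene):
        out = ep.perturb_vessel(vessel_scene, S.PerturbationSpec("shift_up", 2))
        c0 = ndimage.center_of_mass(vessel_scene.vessel_mask())
        c1 = ndimage.center_of_mass(out.vessel_mask())
        assert c1[1] - c0[1] == pytest.approx(2.0, abs=0.05)  # +y, 1 mm/px grid
        assert c1[0] == pytest.approx(c0[0], abs=0.05)

    def test_enlarge_then_shrink_close_to_original(self, vessel_scene):
        grown = ep.perturb_vessel(vessel_scene, S.PerturbationSpec("enlarge", 1))
        back = ep.perturb_vessel(grown, S.PerturbationSpec("shrink", 1))
        n0 = int(vessel_scene.vessel_mask().sum())
        n1 = int(back.vessel_mask().sum())
        # dilation+erosion = morphological closing; for a convex tube the
        # voxel count should agree within one boundary layer
        iz = vessel_scene.labels.shape[2] // 2
        perimeter_layer = int(
            (vessel_scene.vessel_mask()[:, :, iz].sum() * 4) ** 0.5
        ) * vessel_scene.labels.shape[2]
        assert abs(n1 - n0) <= perimeter_layer

    def test_enlarge_grows_and_shrink_shrinks(self, vessel_scene):
        n0 = int(vessel_scene.vessel_mask().sum())
        for mag in (1, 3):
            big = ep.perturb_vessel(vessel_scene, S.PerturbationSpec("enlarge", mag))
            small = ep.perturb_vessel(vessel_scene, S.PerturbationSpec("shrink", mag))
            assert small.vessel_mask().sum() < n0 < big.vessel_mask().sum()

    def test_vacated_voxels_become_liver(self, vessel_scene):
        out = ep.perturb_vessel(vessel_scene, S.PerturbationSpec("shift_right", 3))
        vacated = vessel_scene.vessel_mask() & ~out.vessel_mask()
        assert np.all(out.labels[vacated] == S.LIVER)

    def test_partition_preserved(self, vessel_scene):
        out = ep.perturb_vessel(vessel_scene, S.PerturbationSpec("enlarge", 3))
        assert set(np.unique(out.labels)) <= set(out.role_map)

    def test_erasing_vessel_is_degenerate(self):
        scene = ep.build_simplified_scene(10, 3.0, 3.0, "parallel", spacing=1.0)
        with pytest.raises(S.DegenerateGeometryError):
            ep.perturb_vessel(scene, S.PerturbationSpec("shrink", 3))

    def test_no_vessel_rejected(self):
        scene = ep.build_simplified_scene(10, spacing=1.5)
        with pytest.raises(S.GeometryError):
            ep.perturb_vessel(scene, S.PerturbationSpec("enlarge", 1))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            S.PerturbationSpec("stretch", 1)
        with pytest.raises(ValueError):
            S.PerturbationSpec("enlarge", -1)


class TestCollisionHandling:
    def test_no_intersection_unchanged(self):
        scene = ep.build_simplified_scene(10, 5.0, 3.0, "parallel", spacing=1.0)
        el = ep.place_electrodes(scene, "ECT", 10, 4)
        out, report = ep.resolve_electrode_vessel_collisions(scene, el)
        assert report == []
        assert [(e.x, e.y) for e in out] == [(e.x, e.y) for e in el]

    def test_clearable_crossing_gets_minimal_offset(self):
        # center electrode crosses a 5 mm perpendicular vessel below the
        # tumor; 2.5+0.6 mm of lateral clearance is available
        scene = ep.build_simplified_scene(10, 5.0, 1.0, "perpendicular", spacing=0.5)
        el = ep.place_electrodes(scene, "ECT", 10, 5)
        assert ep.detect_electrode_vessel_collisions(scene, el) == [4]
        out, report = ep.resolve_electrode_vessel_collisions(scene, el)
        assert len(report) == 1 and not report[0]["breach"]
        dx, dy = report[0]["offset"]
        assert 0 < np.hypot(dx, dy) <= 4.0
        assert ep.detect_electrode_vessel_collisions(scene, out) == []
        # minimality: every strictly smaller grid offset still collides
        e = el[4]
        for ddx in np.arange(-4, 4.5, 0.5):
            for ddy in np.arange(-4, 4.5, 0.5):
                if 0 < np.hypot(ddx, ddy) < np.hypot(dx, dy):
                    moved = [e.shifted(ddx, ddy)]
                    assert ep.detect_electrode_vessel_collisions(scene, moved) == [0]

    def test_unavoidable_breach_flagged_and_kept(self):
        # a 15 mm vessel right under a 10 mm tumor spans the whole box:
        # electrodes at centered depth cannot clear it laterally
        scene = ep.build_simplified_scene(10, 15.0, 0.0, "perpendicular", spacing=1.0)
        el = [S.ElectrodeSpec(x=e.x, y=e.y, tip_bottom_z=-20.0)
              for e in ep.place_electrodes(scene, "IRE", 10, 4)]
        out, report = ep.resolve_electrode_vessel_collisions(scene, el, max_offset=2.0)
        breached = [r for r in report if r["breach"]]
        assert breached
        for r in breached:
            e0, e1 = el[r["index"]], out[r["index"]]
            assert (e0.x, e0.y) == (e1.x, e1.y)


class TestPatientLikeScene:
    def test_deterministic_for_fixed_seed(self):
        a = ep.build_patient_like_scene(7, spacing=2.0)
        b = ep.build_patient_like_scene(7, spacing=2.0)
        np.testing.assert_array_equal(a.labels, b.labels)
        c = ep.build_patient_like_scene(8, spacing=2.0)
        assert not np.array_equal(a.labels, c.labels)

    def test_tumor_bounding_box_matches_extents(self):
        scene = ep.build_patient_like_scene(0, tumor_extents=(15, 11, 11), spacing=1.0)
        idx = np.argwhere(scene.mask("tumor"))
        for axis, extent in enumerate((15, 11, 11)):
            size = (idx[:, axis].max() - idx[:, axis].min() + 1) * scene.spacing[axis]
            assert size == pytest.approx(extent, abs=1.5 * scene.spacing[axis])

    def test_tumor_abuts_major_vessel(self):
        scene = ep.build_patient_like_scene(0, spacing=1.0)
        gap = surface_gap_mm(scene.vessel_mask(), scene.mask("tumor"), scene.spacing)
        assert gap <= 2.0

    def test_has_branching_vessel_tree(self):
        scene = ep.build_patient_like_scene(0, spacing=1.0)
        vessel = scene.vessel_mask()
        # one connected tree: trunk along z plus an oblique branch that
        # reaches beyond the trunk's lateral extent toward -x
        assert ndimage.label(vessel)[1] == 1
        xs = scene.axis_coords(0)[np.argwhere(vessel)[:, 0]]
        trunk_min_x = scene.meta["tumor_extents"][0] / 2 + scene.meta["gap"]
        assert xs.min() < trunk_min_x - 3.0
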