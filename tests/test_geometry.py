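"""Parametric solids, positioning and rigid discretization."""

import math

import numpy as np
import pytest

from cutsim import geometry as geo


class TestFemur:
    def test_dimensions_and_watertightness(self, assembly_spec):
        fem = geo.build_femur_surrogate(assembly_spec)
        assert fem.is_watertight
        b = fem.mesh.bounds
        assert b[1, 2] - b[0, 2] == pytest.approx(70.0)
        assert max(fem.mesh.extents[:2]) == pytest.approx(40.0, rel=1e-6)

    def test_degenerate_head_rejected(self):
        with pytest.raises(ValueError):
            geo.AssemblySpec(femur_length=70.0, head_diameter=0.0)

    def test_volume_matches_analytic_solid_of_revolution(self):
        spec = geo.AssemblySpec(femur_length=50.0, head_diameter=40.0)
        fem = geo.build_femur_surrogate(spec, sections=256)
        assert fem.volume == pytest.approx(geo.femur_analytic_volume(spec), rel=0.01)

    def test_voxelized_volume_matches_analytic(self):
        # fine-grid containment count against the closed-form volume
        spec = geo.AssemblySpec(femur_length=20.0, head_diameter=10.0)
        fem = geo.build_femur_surrogate(spec, sections=256)
        h = 0.2
        lo, hi = fem.mesh.bounds
        ax = [np.arange(lo[d] + h / 2, hi[d], h) for d in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        pts = np.column_stack([a.ravel() for a in g])
        vol = fem.contains(pts).sum() * h**3
        assert vol == pytest.approx(geo.femur_analytic_volume(spec), rel=0.01)


class TestImplantProxy:
    def test_screw_outer_diameter_in_thread_region(self):
        spec = geo.ImplantSpec(kind="screw", shaft_diameter=8.0,
                               thread_outer_diameter=12.0, thread_length=20.0)
        imp = geo.build_implant_proxy(spec)
        assert imp.is_watertight
        v = imp.mesh.vertices
        distal = v[v[:, 2] > spec.overall_length - spec.thread_length]
        assert np.hypot(distal[:, 0], distal[:, 1]).max() == pytest.approx(6.0)
        proximal = v[v[:, 2] < spec.overall_length - spec.thread_length - 1.0]
        assert np.hypot(proximal[:, 0], proximal[:, 1]).max() == pytest.approx(4.0)

    def test_straight_blade_is_watertight_limit_case(self):
        spec = geo.implant_preset("blade", helix_angle_deg=0.0)
        imp = geo.build_implant_proxy(spec)
        assert imp.is_watertight
        assert imp.volume > 0

    def test_helical_blade_watertight(self):
        imp = geo.build_implant_proxy(geo.implant_preset("blade"))
        assert imp.is_watertight

    def test_screw_volume_not_below_bare_shaft(self):
        # Boolean-union monotonicity via a containment-grid volume oracle
        spec = geo.implant_preset("screw")
        screw = geo.build_implant_proxy(spec)
        shaft = geo.build_implant_proxy(
            geo.ImplantSpec(kind="screw", shaft_diameter=spec.shaft_diameter,
                            thread_outer_diameter=spec.shaft_diameter,
                            thread_length=spec.thread_length,
                            overall_length=spec.overall_length)
        )
        h = 0.4
        lo, hi = screw.mesh.bounds
        ax = [np.arange(lo[d] + h / 2, hi[d], h) for d in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        pts = np.column_stack([a.ravel() for a in g])
        assert screw.contains(pts).sum() >= shaft.contains(pts).sum()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            geo.ImplantSpec(kind="staple")


class TestFixtures:
    def test_shell_leaves_distal_exposure(self, assembly_spec):
        shell, _, _, _ = geo.build_fixtures(assembly_spec)
        assert shell.is_watertight
        assert shell.mesh.bounds[0, 2] == pytest.approx(7.5)

    def test_base_top_normal_angle(self, assembly_spec):
        n = geo.base_top_normal(assembly_spec)
        angle = math.degrees(math.acos(n @ np.array([0.0, 0.0, 1.0])))
        assert angle == pytest.approx(28.0)

    def test_zero_angle_gives_horizontal_face(self):
        n = geo.base_top_normal(geo.AssemblySpec(base_angle_deg=1e-9))
        assert n[2] == pytest.approx(1.0)

    def test_all_fixtures_watertight(self, assembly_spec):
        for solid in geo.build_fixtures(assembly_spec):
            assert solid.is_watertight, solid.label
            assert solid.volume > 0


class TestPositioning:
    def test_tip_to_joint_distance(self, assembly_spec):
        fem = geo.build_femur_surrogate(assembly_spec)
        imp = geo.build_implant_proxy(geo.implant_preset("screw"))
        T = geo.position_implant(imp, fem, assembly_spec)
        posed = imp.apply_transform(T)
        tip = posed.point_world([0.0, 0.0, imp.mesh.bounds[1, 2]])
        apex = fem.point_world([0.0, 0.0, assembly_spec.femur_length])
        assert np.linalg.norm(apex - tip) == pytest.approx(15.0, abs=1e-9)

    def test_zero_distance_puts_tip_at_apex(self):
        spec = geo.AssemblySpec(tip_to_joint=0.0)
        fem = geo.build_femur_surrogate(spec)
        imp = geo.build_implant_proxy(geo.implant_preset("screw"))
        posed = imp.apply_transform(geo.position_implant(imp, fem, spec))
        tip = posed.point_world([0.0, 0.0, imp.mesh.bounds[1, 2]])
        assert np.allclose(tip, fem.point_world([0.0, 0.0, spec.femur_length]))

    def test_idempotence(self, assembly_spec):
        fem = geo.build_femur_surrogate(assembly_spec)
        imp = geo.build_implant_proxy(geo.implant_preset("screw"))
        posed = imp.apply_transform(geo.position_implant(imp, fem, assembly_spec))
        T2 = geo.position_implant(posed, fem, assembly_spec)
        assert np.allclose(T2, np.eye(4), atol=1e-9)

    def test_excessive_tip_distance_rejected(self, assembly_spec):
        fem = geo.build_femur_surrogate(assembly_spec)
        imp = geo.build_implant_proxy(geo.implant_preset("screw"))
        with pytest.raises(ValueError):
            geo.position_implant(imp, fem, assembly_spec, femur_length=10.0)

    def test_axis_inclination_complements_base_angle(self, assembly_spec):
        assert assembly_spec.implant_axis_from_vertical_deg == pytest.approx(62.0)


class TestDiscretization:
    def test_uniform_cube_lattice_count(self, cube10):
        d = geo.discretize_rigid(cube10, (1000.0, 1000.0))
        assert len(d.points) == 1000

    def test_surface_band_is_finer_than_interior(self, cube10):
        from scipy.spatial import cKDTree

        d = geo.discretize_rigid(cube10, (500.0, 1000.0))
        assert d.surface.any() and (~d.surface).any()
        tree = cKDTree(d.points)
        dist, _ = tree.query(d.points, k=2)
        nn = dist[:, 1]
        assert nn[d.surface].max() <= nn[~d.surface].min() + 1e-9

    def test_all_centroids_inside_by_independent_ray_oracle(self):
        spec = geo.AssemblySpec(femur_length=30.0, head_diameter=16.0)
        fem = geo.build_femur_surrogate(spec)
        d = geo.discretize_rigid(fem, (2000.0, 4000.0))
        inside = geo.points_in_mesh(fem.mesh, d.points)
        assert inside.mean() > 0.999  # tessellation-surface stragglers only

    def test_coarse_resolution_warns_not_errors(self, cube10):
        with pytest.warns(UserWarning):
            geo.discretize_rigid(cube10, (12000.0, 12000.0))


class TestSurfaceSampling:
    def test_samples_lie_on_surface(self, cube10):
        pts = geo.surface_points(cube10, 0.5)
        half = 5.0
        on_face = np.isclose(np.abs(pts), half, atol=1e-9).any(axis=1)
        assert on_face.all()

    def test_deterministic(self, cube10):
        a = geo.surface_points(cube10, 0.5)
        b = geo.surface_points(cube10, 0.5)
        assert np.array_equal(a, b)
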