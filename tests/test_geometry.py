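import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvmech.geometry import (
    LVGeometry,
    MaterialCoordinate,
    RigidPose,
    cavity_volume,
    chart_jacobian,
    chart_jacobian_analytic,
    classify_points,
    evaluate_profile,
    fiber_frame,
    make_quadrature,
    point,
    region_mask,
    voxelize,
    wall_volume,
)


@st.composite
def feasible_geometries(draw):
    R_b = draw(st.floats(25, 50))
    L = draw(st.floats(5, min(18, R_b - 8)))
    Z = draw(st.floats(35, 70))
    H = draw(st.floats(4, min(15, Z - 10)))
    e = draw(st.floats(0.4, 1.0))
    psi0 = draw(st.floats(math.radians(-85), math.radians(-25)))
    return LVGeometry(R_b=R_b, Z=Z, L=L, H=H, e=e, psi0=psi0)


class TestProfile:
    def test_apex_closes_both_surfaces(self, midsize_lv):
        p = evaluate_profile(midsize_lv, math.pi / 2)
        assert p.rho_epi == pytest.approx(0.0, abs=1e-9)
        assert p.zeta_epi == pytest.approx(0.0, abs=1e-9)
        assert p.rho_end == pytest.approx(0.0, abs=1e-9)
        assert p.zeta_end == pytest.approx(midsize_lv.H)

    def test_equator_values(self, midsize_lv):
        g = midsize_lv
        p = evaluate_profile(g, 0.0)
        assert (p.rho_epi, p.zeta_epi) == pytest.approx((g.R_b, g.Z))
        assert (p.rho_end, p.zeta_end) == pytest.approx((g.R_b - g.L, g.Z))

    def test_dilated_patient_row_endocardial_radius(self):
        g = LVGeometry(R_b=40, Z=53, L=10, H=5.9, e=0.65,
                       psi0=np.deg2rad(-75))
        assert evaluate_profile(g, 0.0).rho_end == pytest.approx(30.0)

    def test_psi_outside_range_rejected(self, midsize_lv):
        with pytest.raises(ValueError):
            evaluate_profile(midsize_lv, midsize_lv.psi0 - 0.1)

    @settings(max_examples=40, deadline=None)
    @given(g=feasible_geometries(), u=st.floats(0, 1))
    def test_wall_thickness_nonnegative_everywhere(self, g, u):
        psi = g.psi0 + u * (math.pi / 2 - g.psi0)
        p = evaluate_profile(g, psi)
        gap = p.rho_epi - p.rho_end
        factor = g.e * math.cos(psi) + (1 - g.e) * (1 - math.sin(psi))
        assert gap == pytest.approx(g.L * factor, abs=1e-9)
        assert gap >= -1e-12


class TestChart:
    @pytest.mark.parametrize("t,surface", [(0.0, "end"), (1.0, "epi")])
    def test_extreme_t_reproduces_profiles(self, midsize_lv, t, surface):
        psi = 0.3
        pos = point(midsize_lv, MaterialCoordinate(psi=psi, t=t, theta=0.0))
        p = evaluate_profile(midsize_lv, psi)
        rho, zeta = (p.rho_end, p.zeta_end) if surface == "end" else (
            p.rho_epi, p.zeta_epi)
        assert pos == pytest.approx([rho, 0.0, zeta])

    def test_midwall_blend(self, midsize_lv):
        g = midsize_lv
        pos = point(g, MaterialCoordinate(psi=0.0, t=0.5, theta=0.0))
        assert pos[0] == pytest.approx(g.R_b - g.L / 2)

    def test_out_of_range_coordinate_rejected(self, midsize_lv):
        with pytest.raises(ValueError):
            point(midsize_lv, MaterialCoordinate(psi=0.0, t=1.2, theta=0.0))

    def test_analytic_jacobian_matches_central_differences(self, midsize_lv):
        psi = np.linspace(midsize_lv.psi0 + 0.01, math.pi / 2 - 0.01, 9)
        t = np.linspace(0.05, 0.95, 9)
        theta = np.linspace(0.0, 6.0, 9)
        Ja = chart_jacobian_analytic(midsize_lv, psi, t, theta)
        Jf = chart_jacobian(midsize_lv, psi, t, theta)
        assert np.abs(Ja - Jf).max() < 1e-7


class TestVolumes:
    def test_ellipsoid_limit_closed_forms(self, ellipsoid_lv):
        g = ellipsoid_lv
        v_cav = 4 / 3 * math.pi * (g.R_b - g.L) ** 2 * (g.Z - g.H) / 1000
        v_wall = 4 / 3 * math.pi * (
            g.R_b**2 * g.Z - (g.R_b - g.L) ** 2 * (g.Z - g.H)
        ) / 1000
        assert cavity_volume(g) == pytest.approx(v_cav, rel=1e-9)
        assert wall_volume(g) == pytest.approx(v_wall, rel=1e-9)

    def test_thicker_wall_shrinks_cavity(self, midsize_lv):
        thicker = midsize_lv.replace(L=midsize_lv.L + 2)
        assert cavity_volume(thicker) < cavity_volume(midsize_lv)

    def test_voxel_counting_oracle(self, midsize_lv):
        img = voxelize(midsize_lv, spacing=0.5)
        assert img.label_volume(1) == pytest.approx(
            cavity_volume(midsize_lv), rel=0.01)
        assert img.label_volume(2) == pytest.approx(
            wall_volume(midsize_lv), rel=0.01)

    def test_quadrature_weights_sum_to_wall_volume(self, midsize_lv):
        grid = make_quadrature(midsize_lv)
        assert np.all(grid.weights > 0)
        assert grid.weights.sum() / 1000 == pytest.approx(
            wall_volume(midsize_lv), rel=0.005)

    @settings(max_examples=10, deadline=None)
    @given(g=feasible_geometries())
    def test_quadrature_volume_consistency_across_family(self, g):
        grid = make_quadrature(g, 16, 6, 16)
        assert grid.weights.sum() / 1000 == pytest.approx(
            wall_volume(g), rel=0.005)


class TestFiberField:
    def test_helix_angle_endpoints_and_zero_crossing(self, midsize_lv):
        q_endo = MaterialCoordinate(psi=0.2, t=0.0, theta=0.4)
        fr = fiber_frame(midsize_lv, q_endo)
        e_circ = np.array([-math.sin(0.4), math.cos(0.4), 0.0])
        # endocardium: fully longitudinal fiber (90 deg from circumferential)
        assert abs(fr.f @ e_circ) < 1e-9
        assert fr.f[2] > 0  # oriented apex -> base

        q_epi = MaterialCoordinate(psi=0.2, t=1.0, theta=0.4)
        fr_epi = fiber_frame(midsize_lv, q_epi)
        # epicardium: -60 deg helix angle
        assert fr_epi.f @ e_circ == pytest.approx(math.cos(math.radians(-60)),
                                                  abs=1e-9)
        q_mid = MaterialCoordinate(psi=0.2, t=0.6, theta=0.4)
        fr_mid = fiber_frame(midsize_lv, q_mid)
        assert fr_mid.f @ e_circ == pytest.approx(1.0, abs=1e-9)

    def test_frames_orthonormal_on_quadrature_grid(self, midsize_lv):
        grid = make_quadrature(midsize_lv)
        V = grid.frames
        gram = np.swapaxes(V, -1, -2) @ V
        assert np.abs(gram - np.eye(3)).max() < 1e-10
        # right-handed: det = +1
        assert np.linalg.det(V) == pytest.approx(1.0, abs=1e-10)

    def test_apex_uses_one_sided_limit(self, midsize_lv):
        fr = fiber_frame(
            midsize_lv, MaterialCoordinate(psi=math.pi / 2, t=0.5, theta=0.0)
        )
        assert np.isfinite(fr.f).all()
        assert np.linalg.norm(fr.f) == pytest.approx(1.0)


class TestVoxelize:
    def test_richardson_convergence_of_wall_volume(self, midsize_lv):
        errs = []
        for sp in (2.0, 1.0, 0.5):
            img = voxelize(midsize_lv, spacing=sp)
            errs.append(abs(img.label_volume(2) - wall_volume(midsize_lv)))
        assert errs[2] < errs[0]

    def test_disjoint_extent_gives_empty_image(self, midsize_lv):
        img = voxelize(midsize_lv, spacing=1.0, extent=(20, 20, 20),
                       origin=(500, 500, 500))
        assert not img.voxels.any()

    def test_clipping_extent_rejected(self, midsize_lv):
        with pytest.raises(ValueError, match="extent"):
            voxelize(midsize_lv, spacing=1.0, extent=(30, 30, 30),
                     origin=(-15, -15, 0))

    def test_whole_voxel_translation_invariance(self, midsize_lv):
        kw = dict(spacing=2.0, extent=(140, 140, 140), origin=(-70, -70, -20))
        a = voxelize(midsize_lv, RigidPose(), **kw)
        b = voxelize(midsize_lv, RigidPose(translation=[2.0, -4.0, 6.0]), **kw)
        for lab in (1, 2):
            assert np.count_nonzero(a.voxels == lab) == np.count_nonzero(
                b.voxels == lab)

    def test_classifier_labels_match_analytic_regions(self, midsize_lv):
        g = midsize_lv
        inside_cav = np.array([[0.0, 0.0, g.Z]])
        inside_wall = np.array([[g.R_b - g.L / 2, 0.0, g.Z]])
        outside = np.array([[g.R_b + 5, 0.0, g.Z]])
        assert classify_points(g, inside_cav) == 1
        assert classify_points(g, inside_wall) == 2
        assert classify_points(g, outside) == 0


class TestRegionMask:
    def test_full_ranges_select_everything(self, midsize_lv):
        grid = make_quadrature(midsize_lv)
        assert region_mask(grid, (0, 1), (0, 1)).all()

    def test_disjoint_range_errors(self, midsize_lv):
        grid = make_quadrature(midsize_lv)
        with pytest.raises(ValueError, match="empty"):
            region_mask(grid, (1.1, 1.2), (0.45, 0.55))

    def test_default_midwall_slab_size(self, midsize_lv):
        grid = make_quadrature(midsize_lv, 16, 8, 16)
        mask = region_mask(grid)
        frac = mask.mean()
        assert 0 < frac < 0.1  # ~20% of thickness x ~10% of height


class TestPose:
    def test_rotation_validation(self):
        with pytest.raises(ValueError):
            RigidPose(rotation=np.diag([1.0, 1.0, -1.0]))  # improper
        with pytest.raises(ValueError):
            RigidPose(rotation=2 * np.eye(3))

    def test_apply_inverse_roundtrip(self):
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        pose = RigidPose(translation=[1, 2, 3], rotation=R)
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert pose.inverse_apply(pose.apply(pts)) == pytest.approx(pts)


class TestSurfaceExport:
    def test_mesh_is_closed_fan_with_finite_vertices(self, midsize_lv):
        from lvmech.geometry import surface_mesh

        verts, faces = surface_mesh(midsize_lv, "epi", n_psi=16, n_theta=12)
        assert np.isfinite(verts).all()
        assert faces.min() == 0 and faces.max() == len(verts) - 1
        # every edge of the open-based fan is shared by <= 2 triangles
        edges = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert counts.max() <= 2

    def test_ply_roundtrip_preserves_vertex_count(self, midsize_lv, tmp_path):
        import trimesh

        from lvmech.geometry import export_surface

        path = str(tmp_path / "epi.ply")
        export_surface(midsize_lv, path, "endo", n_psi=12, n_theta=10)
        mesh = trimesh.load(path, process=False)
        assert len(mesh.vertices) == 11 * 10 + 1
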