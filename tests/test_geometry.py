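"""Geometry: keyframe blending, volumes, branch splitting, slicing,
curvature."""

import numpy as np
import pytest

from pa4dflow import geometry
from pa4dflow.containers import CenterlineSet, TimeResolvedMesh
from pa4dflow.geometry import (
    centerline_curvature, interpolate_keyframes, mesh_volume,
    slice_at_fraction, split_branches,
)
from pa4dflow.synthetic import PhantomSpec, make_tube, make_y_junction


def _scaled(mesh, s):
    nodes = mesh.nodes_per_frame.copy()
    nodes[..., :2] *= s
    return TimeResolvedMesh(connectivity=mesh.connectivity,
                            nodes_per_frame=nodes,
                            frame_times=mesh.frame_times,
                            surface=mesh.surface, cap_faces=mesh.cap_faces)


@pytest.fixture(scope="module")
def cyl():
    spec = PhantomSpec(case="poiseuille", radius=1.0, length=4.0,
                       element_size=0.2, frames=4)
    return make_tube(spec)


class TestKeyframeInterpolation:
    def test_endpoints_reproduce_keyframes(self, cyl):
        mesh, _ = cyl
        big = _scaled(mesh, 1.2)
        out = interpolate_keyframes(mesh, big, [0.0, 0.5, 1.0],
                                    alpha=[0.0, 0.5, 1.0])
        assert np.array_equal(out.nodes_per_frame[0], mesh.nodes_per_frame[0])
        assert np.array_equal(out.nodes_per_frame[2], big.nodes_per_frame[0])

    def test_midpoint_volume_matches_analytic_cylinder(self, cyl):
        mesh, _ = cyl
        big = _scaled(mesh, 1.2)
        out = interpolate_keyframes(mesh, big, [0.0], alpha=[0.5])
        # radial blend 1.0 -> 1.2 at alpha 0.5 gives radius 1.1
        assert mesh_volume(out, 0) == pytest.approx(np.pi * 1.1 ** 2 * 4.0,
                                                    rel=0.02)

    def test_volume_monotone_in_alpha(self, cyl):
        mesh, _ = cyl
        big = _scaled(mesh, 1.3)
        alphas = np.linspace(0, 1, 7)
        out = interpolate_keyframes(mesh, big, np.arange(7.0), alpha=alphas)
        vols = [mesh_volume(out, f) for f in range(7)]
        assert np.all(np.diff(vols) >= 0)

    def test_node_count_mismatch_rejected(self, cyl, unit_cube_mesh):
        mesh, _ = cyl
        with pytest.raises(ValueError, match="node count"):
            interpolate_keyframes(mesh, unit_cube_mesh, [0.0], alpha=[0.5])


class TestVolumes:
    def test_unit_cube_exact(self, unit_cube_mesh):
        assert mesh_volume(unit_cube_mesh, 0) == pytest.approx(1.0, abs=1e-14)

    def test_two_disjoint_tets_exact(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [5, 0, 0], [6, 0, 0], [5, 1, 0], [5, 0, 1]], float)
        mesh = TimeResolvedMesh(
            connectivity=np.array([[0, 1, 2, 3], [4, 5, 6, 7]]),
            nodes_per_frame=nodes[None], frame_times=[0.0])
        assert mesh_volume(mesh, 0) == pytest.approx(1 / 3, abs=1e-14)

    def test_cylinder_volume_within_2pct(self, cyl):
        mesh, _ = cyl
        assert mesh_volume(mesh, 0) == pytest.approx(np.pi * 4.0, rel=0.02)


class TestBranchSplitting:
    def test_single_tube_all_elements_one_branch(self, cyl):
        mesh, cl = cyl
        regions = split_branches(mesh, cl)
        assert len(regions) == 1
        assert len(regions[0].element_ids) == mesh.n_elements

    def test_y_junction_branches_disjoint_and_additive(self):
        spec = PhantomSpec(case="y_junction", radius=1.0, element_size=0.25,
                           parent_length=4.0, daughter_length=3.5, frames=4)
        mesh, cl, _ = make_y_junction(spec)
        regions = split_branches(mesh, cl)
        ids = [set(r.element_ids.tolist()) for r in regions]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                assert not ids[i] & ids[j]
        # exact volume additivity: branches + bifurcation cover the mesh
        total = sum(mesh_volume(mesh, 0, r.element_ids) for r in regions)
        assert total == pytest.approx(mesh_volume(mesh, 0), rel=1e-12)

    def test_cap_adjacent_elements_in_own_branch(self):
        spec = PhantomSpec(case="y_junction", radius=1.0, element_size=0.25,
                           parent_length=4.0, daughter_length=3.5, frames=4)
        mesh, cl, _ = make_y_junction(spec)
        regions = {r.label: set(r.element_ids.tolist())
                   for r in split_branches(mesh, cl)}
        for label in ("MPA", "LPA", "RPA"):
            cap_nodes = set(
                mesh.surface[mesh.cap_faces[label]].ravel().tolist())
            adjacent = [e for e in range(mesh.n_elements)
                        if cap_nodes & set(mesh.connectivity[e].tolist())]
            assert adjacent, label
            assert set(adjacent) <= regions[label], label

    def test_centerline_outside_mesh_rejected(self, cyl):
        mesh, _ = cyl
        far = CenterlineSet(branches={
            "MPA": np.column_stack([np.full(10, 50.0), np.zeros(10),
                                    np.linspace(0, 4, 10)])})
        with pytest.raises(ValueError, match="outside"):
            split_branches(mesh, far)


class TestSlicing:
    def test_mid_slice_area_and_position(self, cyl):
        mesh, cl = cyl
        s = slice_at_fraction(mesh, cl, "MPA", 0.5)
        assert s.area == pytest.approx(np.pi, rel=0.02)
        assert s.origin[2] == pytest.approx(2.0, abs=1e-6)
        assert abs(np.linalg.norm(s.normal) - 1) < 1e-12
        # all polygon vertices on the plane
        assert np.max(np.abs((s.vertices - s.origin) @ s.normal)) < 1e-6

    def test_proximal_slice_position(self, cyl):
        mesh, cl = cyl
        s = slice_at_fraction(mesh, cl, "MPA", 0.1)
        assert s.origin[2] == pytest.approx(0.4, abs=1e-6)

    @pytest.mark.parametrize("bad", [0.0, 1.0, 1.5, -0.2])
    def test_fraction_out_of_range_rejected(self, cyl, bad):
        mesh, cl = cyl
        with pytest.raises(ValueError, match="fraction"):
            slice_at_fraction(mesh, cl, "MPA", bad)

    def test_area_invariant_under_scene_rotation(self, cyl):
        mesh, cl = cyl
        a0 = slice_at_fraction(mesh, cl, "MPA", 0.5).area
        th = 0.7
        R = np.array([[np.cos(th), 0, np.sin(th)],
                      [0, 1, 0],
                      [-np.sin(th), 0, np.cos(th)]])
        rmesh = TimeResolvedMesh(connectivity=mesh.connectivity,
                                 nodes_per_frame=mesh.nodes_per_frame @ R.T,
                                 frame_times=mesh.frame_times)
        rcl = CenterlineSet(branches={"MPA": cl.points("MPA") @ R.T})
        a1 = slice_at_fraction(rmesh, rcl, "MPA", 0.5).area
        assert abs(a1 - a0) / a0 < 0.005


class TestCurvature:
    def test_straight_line_infinite_radius(self):
        cl = CenterlineSet(branches={
            "MPA": np.column_stack([np.zeros((20, 2)), np.linspace(0, 5, 20)])})
        assert centerline_curvature(cl, "MPA", 0.5) == np.inf

    def test_circle_radius_recovered(self):
        th = np.linspace(0, np.pi / 2, 200)
        pts = np.column_stack([5 * np.cos(th), 5 * np.sin(th), np.zeros(200)])
        cl = CenterlineSet(branches={"MPA": pts})
        assert centerline_curvature(cl, "MPA", 0.5) == pytest.approx(5.0, rel=0.01)

    def test_helix_radius_of_curvature(self):
        # r(t) = (a cos t, a sin t, b t): R_c = (a^2 + b^2)/a
        t = np.linspace(0, 3 * np.pi, 400)
        a, b = 2.0, 1.0
        pts = np.column_stack([a * np.cos(t), a * np.sin(t), b * t])
        cl = CenterlineSet(branches={"MPA": pts})
        assert centerline_curvature(cl, "MPA", 0.5) == pytest.approx(
            (a ** 2 + b ** 2) / a, rel=0.02)

    def test_too_few_points_rejected(self):
        cl = CenterlineSet(branches={"MPA": [[0, 0, 0], [0, 0, 1], [0, 1, 2]]})
        with pytest.raises(ValueError, match="5"):
            centerline_curvature(cl, "MPA", 0.5)
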