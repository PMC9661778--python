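"""Phantom generator: determinism, mesh fidelity, analytic fields and
independent ground-truth values."""

import numpy as np
import pytest

from pa4dflow import field_ops, geometry, metrics
from pa4dflow.synthetic import (
    PhantomSpec, field_curl, field_evaluator, ground_truth, make_field,
    make_phantom, make_tube, make_y_junction,
)


class TestDeterminism:
    def test_identical_specs_identical_outputs(self):
        spec = PhantomSpec(case="poiseuille", radius=1.0, length=2.0,
                           element_size=0.3, spacing=0.2, frames=4, seed=7,
                           noise_pct=1.0)
        m1, c1, f1, _ = make_phantom(spec)
        m2, c2, f2, _ = make_phantom(spec)
        assert np.array_equal(m1.nodes_per_frame, m2.nodes_per_frame)
        assert np.array_equal(m1.connectivity, m2.connectivity)
        assert np.array_equal(f1.velocities, f2.velocities)

    def test_noise_is_seeded(self):
        a = make_field(PhantomSpec(case="shear", frames=4, length=2.0,
                                   spacing=0.3, noise_pct=2.0, seed=1))
        b = make_field(PhantomSpec(case="shear", frames=4, length=2.0,
                                   spacing=0.3, noise_pct=2.0, seed=2))
        assert not np.array_equal(a.velocities, b.velocities)


class TestTubeMesh:
    def test_straight_tube_volume_and_centerline(self):
        spec = PhantomSpec(case="poiseuille", radius=1.0, length=10.0,
                           element_size=0.12, frames=4)
        mesh, cl = make_tube(spec)
        assert mesh.tet_volumes(0).sum() == pytest.approx(np.pi * 10, rel=0.02)
        assert cl.total_length("MPA") == pytest.approx(10.0, abs=1e-9)

    def test_curved_tube_curvature(self):
        spec = PhantomSpec(case="poiseuille", radius=1.0, length=7.0,
                           curvature_radius=5.0, element_size=0.25, frames=4)
        mesh, cl = make_tube(spec)
        rc = geometry.centerline_curvature(cl, "MPA", 0.5)
        assert rc == pytest.approx(5.0, rel=0.01)

    def test_self_intersecting_torus_rejected(self):
        with pytest.raises(ValueError, match="curvature"):
            PhantomSpec(case="poiseuille", radius=2.0, curvature_radius=1.5)

    def test_pulsating_tube_area_ratio(self):
        spec = PhantomSpec(case="pulsating_tube", pulsation=0.1, radius=1.0,
                           length=3.0, element_size=0.25, frames=20)
        mesh, cl = make_tube(spec)
        areas = [geometry.slice_at_fraction(mesh, cl, "MPA", 0.5, frame=f).area
                 for f in range(20)]
        rac = (max(areas) - min(areas)) / min(areas)
        assert rac == pytest.approx(4 * 0.1 / 0.9 ** 2, rel=0.01)


class TestFields:
    def test_poiseuille_peak_on_axis_exact(self):
        spec = PhantomSpec(case="poiseuille", u_max=40.0, radius=1.0,
                           length=2.0, spacing=0.1, frames=4)
        f = make_field(spec)
        # the grid contains the axis; the sample there must be exactly u_max
        ix = np.argmin(np.abs(f.origin[0] / 10 + f.spacing[0] / 10
                              * np.arange(f.dims[0])))
        iy = np.argmin(np.abs(f.origin[1] / 10 + f.spacing[1] / 10
                              * np.arange(f.dims[1])))
        assert f.velocities[0, ix, iy, :, 2].max() == pytest.approx(40.0)

    def test_helical_uniform_helicity(self):
        spec = PhantomSpec(case="helical", rotation_rate=1.0,
                           axial_velocity=1.0)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, (100, 3))
        u = field_evaluator(spec)(pts)
        w = field_curl(spec, pts)
        assert np.allclose(np.einsum("ij,ij->i", u, w), 2.0, atol=1e-6)

    def test_dean_pair_mirror_antisymmetric_helicity(self):
        spec = PhantomSpec(case="dean_pair", radius=1.0,
                           axial_velocity=10.0, vortex_strength=10.0)
        rng = np.random.default_rng(1)
        pts = rng.uniform(-1, 1, (200, 3))
        mirrored = pts * np.array([-1, 1, 1])
        u, um = field_evaluator(spec)(pts), field_evaluator(spec)(mirrored)
        w, wm = field_curl(spec, pts), field_curl(spec, mirrored)
        h = np.einsum("ij,ij->i", u, w)
        hm = np.einsum("ij,ij->i", um, wm)
        assert np.allclose(hm, -h, atol=1e-5)

    def test_dean_pair_net_helicity_vanishes(self):
        spec = PhantomSpec(case="dean_pair", axial_velocity=10.0,
                           vortex_strength=10.0)
        gt = ground_truth(spec, n_samples=200_000)
        assert abs(gt["helicity_mean"]) < 0.05 * abs(
            gt["vorticity_magmean"] * spec.axial_velocity)


@pytest.fixture(scope="module")
def junction():
    spec = PhantomSpec(case="y_junction", radius=1.0, element_size=0.2,
                       parent_length=4.0, daughter_length=3.5,
                       spacing=0.12, frames=4, u_max=40.0)
    return spec, *make_y_junction(spec)


class TestYJunction:
    def _branch_flows(self, spec, mesh, cl, fieldv):
        q = {}
        for label in ("MPA", "LPA", "RPA"):
            s = geometry.slice_at_fraction(mesh, cl, label, 0.1)
            field_ops.sample_on_slice(fieldv, s, 0.0)
            metrics.orient_forward([s])
            q[label] = metrics.flow_rate(s)
        return q

    def test_symmetric_split_conserves_mass(self, junction):
        spec, mesh, cl, fieldv = junction
        q = self._branch_flows(spec, mesh, cl, fieldv)
        err, ok = metrics.conservation_error(q["MPA"], q["LPA"], q["RPA"])
        assert err < 0.01 and ok

    def test_asymmetric_split_ratio(self):
        spec = PhantomSpec(case="y_junction", radius=1.0, element_size=0.2,
                           parent_length=4.0, daughter_length=3.5,
                           spacing=0.12, frames=4, u_max=40.0,
                           flow_split=(0.6, 0.4))
        mesh, cl, fieldv = make_y_junction(spec)
        q = self._branch_flows(spec, mesh, cl, fieldv)
        assert q["LPA"] / q["RPA"] == pytest.approx(1.5, rel=0.05)

    def test_zero_inflow_zero_everywhere(self):
        spec = PhantomSpec(case="y_junction", radius=1.0, element_size=0.3,
                           parent_length=4.0, daughter_length=3.5,
                           spacing=0.2, frames=4, u_max=0.0)
        mesh, cl, fieldv = make_y_junction(spec)
        assert np.max(np.abs(fieldv.velocities)) == 0.0

    def test_overlapping_daughters_rejected(self):
        spec = PhantomSpec(case="y_junction", daughter_radius=0.9,
                           daughter_length=1.0, branch_angle_deg=5.0)
        with pytest.raises(ValueError, match="overlap"):
            make_y_junction(spec)


class TestGroundTruth:
    def test_poiseuille_closed_forms(self):
        spec = PhantomSpec(case="poiseuille", u_max=40.0, radius=1.0,
                           length=10.0)
        gt = ground_truth(spec, n_samples=400_000)
        assert gt["flow"] == pytest.approx(62.832, rel=1e-4)
        assert gt["vorticity_magmean"] == pytest.approx(53.333, rel=0.005)
        assert gt["hfi"] == pytest.approx(0.0, abs=1e-6)

    def test_helical_hfi(self):
        spec = PhantomSpec(case="helical", rotation_rate=1.0,
                           axial_velocity=1.0, radius=1.0)
        gt = ground_truth(spec, n_samples=400_000)
        assert gt["hfi_closed_form"] == pytest.approx(2 * (np.sqrt(2) - 1),
                                                      rel=1e-12)
        assert gt["hfi"] == pytest.approx(gt["hfi_closed_form"], rel=0.005)

    def test_solid_body_q(self):
        gt = ground_truth(PhantomSpec(case="solid_body", rotation_rate=2.0),
                          n_samples=1000)
        assert gt["q_criterion"] == 4.0

    def test_y_junction_truth_is_construction(self):
        spec = PhantomSpec(case="y_junction", u_max=40.0, radius=1.0,
                           outflow_scale=0.7)
        gt = ground_truth(spec)
        assert gt["conservation_error"] == pytest.approx(0.3)
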