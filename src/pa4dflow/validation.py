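"""Phantom validation suites: run the full pipeline on analytic phantoms
and report measured metric values next to their independent ground truths.

Each suite returns a flat dict of numbers; :func:`run_all` collects them.
These are the same computations the ``pa4dflow validate`` subcommand and
the repository's acceptance checks execute.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import field_ops, geometry, metrics, stats, synthetic
from .config import RunConfig
from .containers import FluidConstants, Waveform
from .metrics import compute_all
from .synthetic import PhantomSpec, ground_truth, make_phantom


def _mpa(table, metric, statistic="mean", window="cycle"):
    return table.get(branch="MPA", metric=metric, statistic=statistic,
                     window=window)


def affine_suite(seed: int = 0) -> dict:
    """Exactness of gradient/curl/Q on affine fields (solid body, shear).

    Trilinear resampling and linear-tetrahedron gradients reproduce affine
    velocity fields to round-off on any mesh; reports the worst relative
    errors.
    """
    out = {}
    spec = PhantomSpec(case="solid_body", rotation_rate=2.0, radius=1.0,
                       length=4.0, element_size=0.25, frames=4, seed=seed)
    mesh, _, fieldv, _ = make_phantom(spec)
    nf = field_ops.resample_to_mesh(fieldv, mesh, 0)
    gf = field_ops.velocity_gradient(nf)
    omega = gf.vorticity
    q = field_ops.q_criterion(gf)
    w_true = 2 * spec.rotation_rate
    out["solidbody_curl_rel_err"] = float(
        np.max(np.linalg.norm(omega - [0, 0, w_true], axis=1)) / w_true)
    out["solidbody_q_rel_err"] = float(
        np.max(np.abs(q - spec.rotation_rate ** 2)) / spec.rotation_rate ** 2)

    spec_s = replace(spec, case="shear", shear_rate=3.0)
    mesh, _, fieldv, _ = make_phantom(spec_s)
    nf = field_ops.resample_to_mesh(fieldv, mesh, 0)
    gf = field_ops.velocity_gradient(nf)
    out["shear_curl_rel_err"] = float(
        np.max(np.linalg.norm(gf.vorticity - [0, 0, -spec_s.shear_rate], axis=1))
        / spec_s.shear_rate)
    out["shear_q_abs_err"] = float(np.max(np.abs(field_ops.q_criterion(gf))))
    out["n"] = mesh.n_elements
    return out


def poiseuille_suite(seed: int = 0) -> dict:
    """Full pipeline on the steady Poiseuille tube (u_max 40 cm/s, R 1 cm,
    L 10 cm, 1.2 mm elements) against analytic values."""
    spec = PhantomSpec(case="poiseuille", u_max=40.0, radius=1.0, length=10.0,
                       element_size=0.12, spacing=0.1, frames=4, seed=seed)
    mesh, cl, fieldv, subject = make_phantom(spec)
    table, report = compute_all(fieldv, mesh, cl, subject)
    gt = ground_truth(spec, n_samples=1_000_000)
    return {
        "flow_cm3s": _mpa(table, "flow"),
        "flow_true": gt["flow"],
        "vorticity_magmean": _mpa(table, "vorticity_magmean"),
        "vorticity_magmean_true": 4 * spec.u_max / (3 * spec.radius),
        "vorticity_vectormean": _mpa(table, "vorticity_vectormean"),
        "centerline_velocity": _mpa(table, "centerline_velocity"),
        "centerline_velocity_true": spec.u_max,
        "reverse_flow_fraction": _mpa(table, "reverse_flow_fraction",
                                      statistic="max"),
        "hfi": _mpa(table, "hfi"),
        "n": mesh.n_elements,
    }


def helical_suite(seed: int = 0) -> dict:
    """Helical flow (solid-body swirl + uniform axial drift, W = Omega = 1):
    helicity density, positive fraction, and HFI vs the closed form."""
    spec = PhantomSpec(case="helical", rotation_rate=1.0, axial_velocity=1.0,
                       radius=1.0, length=10.0, element_size=0.12,
                       spacing=0.1, frames=4, seed=seed)
    mesh, cl, fieldv, _ = make_phantom(spec)
    nf = field_ops.resample_to_mesh(fieldv, mesh, 0)
    gf = field_ops.velocity_gradient(nf)
    all_ids = np.arange(mesh.n_elements)
    hel = metrics.helicity_metrics(nf, gf, all_ids)
    gt = ground_truth(spec, n_samples=200_000)
    h_true = 2.0 * spec.rotation_rate * spec.axial_velocity
    return {
        "h_d_max_rel_err": float(np.max(np.abs(hel.h_d - h_true)) / h_true),
        "fraction_positive": hel.fraction_positive,
        "hfi": hel.hfi,
        "hfi_true": gt["hfi_closed_form"],
        "n": mesh.n_elements,
    }


def _mirror_helicity(mesh, nf, gf):
    """Recompute helicity on the mirror image (x -> -x) of mesh and field."""
    from .containers import TimeResolvedMesh

    nodes = mesh.nodes_per_frame.copy()
    nodes[..., 0] *= -1
    conn = mesh.connectivity[:, [0, 1, 3, 2]]  # restore positive orientation
    mmesh = TimeResolvedMesh(connectivity=conn, nodes_per_frame=nodes,
                             frame_times=mesh.frame_times)
    vals = nf.values.copy()
    vals[:, 0] *= -1
    mnf = field_ops.NodeField(mesh=mmesh, frame=nf.frame, values=vals)
    mgf = field_ops.velocity_gradient(mnf)
    return metrics.helicity_metrics(mnf, mgf, np.arange(mmesh.n_elements))


def dean_pair_suite(seed: int = 0) -> dict:
    """Mirror-image counter-rotating vortex pair on an axial plug flow:
    positive-helicity fraction ~ 1/2 and HFI invariance under reflection."""
    spec = PhantomSpec(case="dean_pair", radius=1.0, length=5.0,
                       element_size=0.12, spacing=0.1, frames=4,
                       axial_velocity=10.0, vortex_strength=10.0, seed=seed)
    mesh, cl, fieldv, _ = make_phantom(spec)
    nf = field_ops.resample_to_mesh(fieldv, mesh, 0)
    gf = field_ops.velocity_gradient(nf)
    hel = metrics.helicity_metrics(nf, gf, np.arange(mesh.n_elements))
    mirrored = _mirror_helicity(mesh, nf, gf)
    return {
        "fraction_positive": hel.fraction_positive,
        "mirror_fraction_positive": mirrored.fraction_positive,
        "hfi": hel.hfi,
        "hfi_mirror_abs_diff": abs(hel.hfi - mirrored.hfi),
        "n": mesh.n_elements,
    }


def stiffness_suite(seed: int = 0) -> dict:
    """Pulsating tube (delta = 0.1) with SPAP/DPAP 25/15 mmHg: relative
    area change and the pressure-normalised stiffness indices."""
    spec = PhantomSpec(case="pulsating_tube", pulsation=0.1, radius=1.0,
                       length=4.0, element_size=0.12, spacing=0.1,
                       frames=20, period=1.0, t_systole=0.4, seed=seed)
    mesh, cl, fieldv, subject = make_phantom(spec)
    table, report = compute_all(fieldv, mesh, cl, subject)
    rac = _mpa(table, "rac")
    a_max = _mpa(table, "area", statistic="max")
    a_min = _mpa(table, "area", statistic="min")
    d = spec.pulsation
    return {
        "rac": rac,
        "rac_true": 4 * d / (1 - d) ** 2,
        "compliance": _mpa(table, "compliance"),
        "compliance_hand": (a_max - a_min) / (subject.spap - subject.dpap),
        "distensibility": _mpa(table, "distensibility"),
        "distensibility_hand": rac / (subject.spap - subject.dpap) * 100,
        "acceleration_time_ratio": _mpa(table, "acceleration_time_ratio"),
        "n": mesh.n_elements,
    }


def y_junction_suite(seed: int = 0) -> dict:
    """Conservation-of-flow QC on mass-conserving and 30%-deficient
    Y-junction phantoms."""
    spec = PhantomSpec(case="y_junction", u_max=40.0, radius=1.0,
                       element_size=0.12, spacing=0.1, frames=4, seed=seed)
    mesh, cl, fieldv, subject = make_phantom(spec)
    table, report = compute_all(fieldv, mesh, cl, subject)
    out = {
        "conservation_error": report.qc["conservation_error"],
        "conservation_pass": float(report.qc["conservation_pass"]),
        "flow_mpa": _mpa(table, "flow"),
        "flow_true": ground_truth(spec)["flow_mpa"],
        "n": mesh.n_elements,
    }

    # deliberately unbalanced outlets: flows measured directly on slices
    spec_bad = replace(spec, outflow_scale=0.7)
    mesh_b, cl_b, field_b, _ = make_phantom(spec_bad)
    cfg = RunConfig()
    q = {}
    for label in ("MPA", "LPA", "RPA"):
        slices = []
        for f in range(mesh_b.n_frames):
            s = geometry.slice_at_fraction(mesh_b, cl_b, label,
                                           cfg.slice_fractions[0], frame=f)
            field_ops.sample_on_slice(field_b, s, mesh_b.frame_times[f])
            slices.append(s)
        metrics.orient_forward(slices)
        q[label] = float(np.mean([metrics.flow_rate(s) for s in slices]))
    err, ok = metrics.conservation_error(q["MPA"], q["LPA"], q["RPA"])
    out["imbalanced_conservation_error"] = err
    out["imbalanced_pass"] = float(ok)
    return out


def dean_suite(seed: int = 0) -> dict:
    """Dean number: direct formula evaluation (u_bar 50 cm/s, D 2 cm,
    R_c 5 cm, blood at 1.06 g/cm^3 and 0.04 Poise)."""
    de = metrics.dean_number(50.0, 2.0, 5.0, FluidConstants())
    return {
        "dean_number": de,
        "dean_number_true": 1.06 * 50.0 * 2.0 / 0.04 * np.sqrt(2.0 / 10.0),
        "dean_straight": metrics.dean_number(50.0, 2.0, np.inf),
        "n": 1,
    }


def predicted_rv_suite(seed: int = 0) -> dict:
    """Percent-predicted RV normalisation identities and a worked example."""
    from .containers import PREDICTED_RV_CONSTANTS

    c = PREDICTED_RV_CONSTANTS["RVEF"]
    predicted = c["m_male"] * 60.0 ** c["a"] * 170.0 ** c["b"] * 75.0 ** c["c"]
    example = metrics.percent_predicted_rv(55.0, "RVEF", "M", 60.0, 170.0, 75.0)
    # measured == predicted must give exactly 100%
    identity = metrics.percent_predicted_rv(predicted, "RVEF", "M",
                                            60.0, 170.0, 75.0)
    return {
        "pct_predicted_rvef_example": example,
        "pct_predicted_rvef_hand": 100.0 * 55.0 / predicted,
        "identity_pct": identity,
        "n": 1,
    }


def stats_suite(seed: int = 0, n_reps: int = 1000) -> dict:
    """Rank-correlation fixtures and the null calibration of the paired
    comparison (n = 20 pairs)."""
    r, p = stats.spearman_baseline([1, 2, 3, 4, 5], [2, 3, 1, 4, 5])
    ids = [f"s{i}" for i in range(6)]
    # differences without ties pass the normality gate -> paired t
    pre = np.array([10.0, 12.0, 14.0, 16.0, 18.0, 20.0])
    post = pre + np.array([1.0, 2.5, 0.5, 2.0, 3.0, 1.5])
    rep = stats.paired_compare(stats.PairedSample(ids, pre, post))
    d = post - pre
    t_hand = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(len(d)))
    # heavily tied differences fail the gate -> Wilcoxon substituted
    gated = stats.paired_compare(stats.PairedSample(
        ids, np.arange(1.0, 7.0), np.array([2, 4, 3, 6, 5, 8], float)))
    type1 = stats.null_calibration(n_pairs=20, n_reps=n_reps, seed=seed)
    return {
        "spearman_fixture_r": r,
        "paired_t_statistic": rep.statistic,
        "paired_t_hand": float(t_hand),
        "gate_substituted_wilcoxon": float(gated.test == "wilcoxon"),
        "type1_error": type1,
        "n": n_reps,
    }


SUITES = {
    "affine": affine_suite,
    "poiseuille": poiseuille_suite,
    "helical": helical_suite,
    "dean_pair": dean_pair_suite,
    "stiffness": stiffness_suite,
    "y_junction": y_junction_suite,
    "dean_number": dean_suite,
    "predicted_rv": predicted_rv_suite,
    "stats": stats_suite,
}


def run_all(seed: int = 0) -> dict[str, dict]:
    """Run every validation suite; deterministic for a fixed seed."""
    return {name: fn(seed) for name, fn in SUITES.items()}
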