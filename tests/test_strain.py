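"""Strain tensors, principal decomposition, gamma_max, probes, comparisons."""

import numpy as np
import pandas as pd
import pytest

from thermograde import (
    GPA,
    LoadCase,
    ProbeSet,
    StrainState,
    TetMesh,
    assemble_stiffness,
    compare_modes,
    element_strain,
    make_bar,
    max_shear_strain,
    probe_strains,
    solve_displacements,
)
from thermograde.mesh import find_containing_tet


def test_rigid_translation_gives_zero_strain(small_bar):
    u = np.tile(np.array([1.0, -2.0, 0.5]), (small_bar.n_nodes, 1))
    state = element_strain(small_bar, u)
    assert np.abs(state.tensors).max() < 1e-12


def test_uniaxial_affine_field(small_bar):
    a = 1e-3
    u = np.zeros((small_bar.n_nodes, 3))
    u[:, 0] = a * small_bar.node_coords[:, 0]
    state = element_strain(small_bar, u)
    expected = np.zeros((3, 3))
    expected[0, 0] = a
    np.testing.assert_allclose(
        state.tensors, np.broadcast_to(expected, state.tensors.shape), atol=1e-15
    )
    np.testing.assert_allclose(state.max_shear, a, rtol=1e-10)


def test_strain_matches_finite_difference_gradient():
    rng = np.random.default_rng(17)
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    coords += 0.2 * rng.standard_normal((4, 3))
    mesh = TetMesh(coords, np.array([[0, 1, 2, 3]]))
    u = 1e-3 * rng.standard_normal((4, 3))
    state = element_strain(mesh, u)

    def interp(p):
        M = np.column_stack([np.ones(4), mesh.node_coords[mesh.tets[0]]])
        coeff = np.linalg.solve(M, u[mesh.tets[0]])
        return coeff[0] + np.asarray(p) @ coeff[1:]

    h = 1e-6
    centroid = mesh.centroids()[0]
    grad = np.zeros((3, 3))
    for j in range(3):
        dp = np.zeros(3)
        dp[j] = h
        grad[:, j] = (interp(centroid + dp) - interp(centroid - dp)) / (2 * h)
    fd_eps = 0.5 * (grad + grad.T)
    np.testing.assert_allclose(state.tensors[0], fd_eps, atol=1e-8)


@pytest.mark.parametrize(
    "tensor, expected_gamma",
    [
        (np.diag([2e-3, 0.0, 0.0]), 2e-3),            # uniaxial: eps3 = 0
        (np.array([[0, 1e-3, 0], [1e-3, 0, 0], [0, 0, 0.0]]), 2e-3),  # pure shear
        (np.eye(3) * 5e-4, 0.0),                       # hydrostatic
    ],
)
def test_max_shear_closed_forms(tensor, expected_gamma):
    state = StrainState.from_tensors(tensor[None])
    assert max_shear_strain(state, microstrain=False)[0] == pytest.approx(
        expected_gamma, abs=1e-15
    )


def test_pure_shear_principals():
    g = 1e-3
    t = np.array([[0, g, 0], [g, 0, 0], [0, 0, 0.0]])
    state = StrainState.from_tensors(t[None])
    np.testing.assert_allclose(state.principals[0], [g, 0.0, -g], atol=1e-15)


def test_eigendecomposition_reconstructs_tensor():
    rng = np.random.default_rng(23)
    t = rng.standard_normal((10, 3, 3)) * 1e-3
    t = 0.5 * (t + np.swapaxes(t, 1, 2))
    state = StrainState.from_tensors(t)
    recon = np.einsum(
        "ek,eik,ejk->eij", state.principals, state.directions, state.directions
    )
    np.testing.assert_allclose(recon, t, atol=1e-12)
    np.testing.assert_allclose(
        state.principals.sum(axis=1), np.trace(t, axis1=1, axis2=2), atol=1e-12
    )
    assert np.all(np.diff(state.principals, axis=1) <= 1e-18)
    assert np.all(state.max_shear >= 0)


def _uniform_strain_state(mesh, a=1e-3):
    u = np.zeros((mesh.n_nodes, 3))
    u[:, 0] = a * mesh.node_coords[:, 0]
    u[:, 1] = -0.3 * a * mesh.node_coords[:, 1]
    return element_strain(mesh, u)


def test_probe_modes_agree_on_uniform_strain(small_bar):
    state = _uniform_strain_state(small_bar)
    probes = ProbeSet(
        labels=["a", "b"], points=[[0.5, 0.5, 0.5], [0.25, 0.75, 0.5]]
    )
    r1 = probe_strains(small_bar, state, probes, mode="containing_element")
    r2 = probe_strains(small_bar, state, probes, mode="nodal_average")
    assert r1["gamma_max_micro"].nunique() == 1
    np.testing.assert_allclose(
        r1["gamma_max_micro"], r2["gamma_max_micro"], rtol=1e-9
    )


def test_probe_at_centroid_reports_element_value(unit_tet):
    rng = np.random.default_rng(2)
    u = 1e-4 * rng.standard_normal((4, 3))
    state = element_strain(unit_tet, u)
    probes = ProbeSet(labels=["c"], points=[unit_tet.centroids()[0]])
    rep = probe_strains(unit_tet, state, probes, mode="containing_element")
    assert rep.loc["c", "gamma_max_micro"] == pytest.approx(
        state.max_shear[0] * 1e6, rel=1e-12
    )


def test_probe_outside_mesh_raises(small_bar):
    state = _uniform_strain_state(small_bar)
    probes = ProbeSet(labels=["far"], points=[[10.0, 10.0, 10.0]])
    with pytest.raises(ValueError, match="outside"):
        probe_strains(small_bar, state, probes, mode="containing_element")


def test_compare_modes_equivalence_and_mismatch(small_bar):
    state = _uniform_strain_state(small_bar)
    probes = ProbeSet(labels=["a"], points=[[0.5, 0.5, 0.5]])
    rep = probe_strains(small_bar, state, probes)
    out = compare_modes({"ui": rep, "tg": rep.copy()})
    assert out["rel_diff_ui_vs_tg"].iloc[0] == pytest.approx(0.0, abs=1e-15)
    other = rep.copy()
    other.index = pd.Index(["zzz"], name="label")
    with pytest.raises(ValueError, match="labels"):
        compare_modes({"ui": rep, "tg": other})


def test_frame_invariance_of_probe_gamma_max():
    """Rigidly rotating geometry, loads and constraints leaves gamma_max."""
    mesh = make_bar(L=1.0, W=0.5, H=0.5, nx=4, ny=2, nz=2)
    clamp = LoadCase.fix_nodes(mesh.nodes_on_plane(0, 0.0))
    tip = int(mesh.locate_nearest_node([1.0, 0.25, 0.25]))
    force = np.array([3.0, 1.0, -2.0])
    loads = clamp.merged_with(LoadCase(point_forces=[(tip, force)]))
    K = assemble_stiffness(mesh, np.full(mesh.n_tets, GPA), 0.3)
    u = solve_displacements(K, loads, mesh.n_nodes)
    probes_pts = mesh.centroids()[[3, 20, 40]]
    state = element_strain(mesh, u)
    probes = ProbeSet(labels=["p0", "p1", "p2"], points=probes_pts)
    rep = probe_strains(mesh, state, probes)

    # rotation about an arbitrary axis
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    mesh_r = TetMesh(mesh.node_coords @ R.T, mesh.tets, mesh.region_of_tet)
    loads_r = LoadCase.fix_nodes(mesh.nodes_on_plane(0, 0.0)).merged_with(
        LoadCase(point_forces=[(tip, R @ force)])
    )
    K_r = assemble_stiffness(mesh_r, np.full(mesh.n_tets, GPA), 0.3)
    u_r = solve_displacements(K_r, loads_r, mesh_r.n_nodes)
    state_r = element_strain(mesh_r, u_r)
    probes_r = ProbeSet(labels=["p0", "p1", "p2"], points=probes_pts @ R.T)
    rep_r = probe_strains(mesh_r, state_r, probes_r)
    np.testing.assert_allclose(
        rep_r["gamma_max_micro"], rep["gamma_max_micro"], rtol=1e-8
    )
    np.testing.assert_allclose(rep_r["eps1_micro"], rep["eps1_micro"], rtol=1e-7)


def test_nodal_average_at_shared_node_of_equal_strain(small_bar):
    state = _uniform_strain_state(small_bar)
    nid = small_bar.locate_nearest_node([0.5, 0.5, 0.5])
    probes = ProbeSet(labels=["n"], points=[small_bar.node_coords[nid]])
    rep = probe_strains(small_bar, state, probes, mode="nodal_average")
    assert rep.loc["n", "gamma_max_micro"] == pytest.approx(
        state.max_shear[0] * 1e6, rel=1e-9
    )
    assert rep.loc["n", "snap_distance_m"] == 0.0
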