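"""Elasticity assembly and solve: nullspace, closed forms, material modes."""

import numpy as np
import pytest

from thermograde import (
    GPA,
    LoadCase,
    RegionTable,
    SeedSet,
    SolverError,
    TetMesh,
    assemble_stiffness,
    graded_bar_tip_displacement,
    make_bar,
    make_two_region_bar,
    run_material_mode,
    solve_displacements,
)
from conftest import axial_bar_loadcase, tip_displacement


def symbolic_element_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """Independent 12x12 element stiffness via sympy strain energy.

    Interpolates u symbolically, forms the isotropic strain energy density
    (lambda/2 tr(eps)^2 + mu eps:eps), multiplies by the volume (the density
    is constant for linear tets), and takes the Hessian in the nodal dofs —
    no B matrix, no Voigt bookkeeping.
    """
    import sympy as sp

    x, y, z = sp.symbols("x y z")
    dofs = sp.symbols("u0:12")
    M = sp.Matrix([[1, *c] for c in coords])
    shape = M.inv().T * sp.Matrix([1, x, y, z])  # N_i(x, y, z)
    u = sp.Matrix([sum(shape[a] * dofs[3 * a + i] for a in range(4)) for i in range(3)])
    grad = u.jacobian(sp.Matrix([x, y, z]))
    eps = (grad + grad.T) / 2
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    W = sp.Rational(1, 2) * lam * eps.trace() ** 2 + mu * (eps * eps).trace()
    vol = abs(M.det()) / 6
    energy = sp.expand(W * vol)
    K = sp.hessian(energy, dofs)
    return np.array(K, dtype=float)


def test_single_tet_stiffness_matches_symbolic_oracle():
    rng = np.random.default_rng(5)
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    coords += 0.25 * rng.standard_normal((4, 3))
    mesh = TetMesh(coords, np.array([[0, 1, 2, 3]]))
    E, nu = 3.7, 0.31
    K = assemble_stiffness(mesh, np.array([E]), nu).toarray()
    oracle = symbolic_element_stiffness(mesh.node_coords[mesh.tets[0]], E, nu)
    np.testing.assert_allclose(K, oracle, rtol=1e-9, atol=1e-12)


def test_rigid_modes_in_nullspace(unit_tet):
    K = assemble_stiffness(unit_tet, np.array([1.0 * GPA]), 0.3)
    scale = np.abs(K.toarray()).max()
    # translations
    for axis in range(3):
        u = np.zeros((4, 3))
        u[:, axis] = 1.0
        assert np.abs(K @ u.reshape(-1)).max() <= 1e-9 * scale
    # small rigid rotations u = omega x r
    for omega in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0.3, -0.2, 0.9])):
        u = np.cross(omega, unit_tet.node_coords)
        assert np.abs(K @ u.reshape(-1)).max() <= 1e-9 * scale


def test_nu_out_of_range_rejected(unit_tet):
    with pytest.raises(ValueError, match="nu < 0.5"):
        assemble_stiffness(unit_tet, np.array([1.0]), 0.5)


def test_zero_loads_give_zero_displacements(small_bar):
    K = assemble_stiffness(small_bar, np.full(small_bar.n_tets, GPA), 0.28)
    clamp = LoadCase.fix_nodes(small_bar.nodes_on_plane(0, 0.0))
    u = solve_displacements(K, clamp, small_bar.n_nodes)
    assert np.abs(u).max() == 0.0


def test_unconstrained_system_raises(small_bar):
    K = assemble_stiffness(small_bar, np.full(small_bar.n_tets, GPA), 0.28)
    with pytest.raises(SolverError, match="rigid-body"):
        solve_displacements(K, LoadCase(), small_bar.n_nodes)


def test_uniaxial_bar_closed_form():
    L, E, F = 1.0, 2.0 * GPA, 10.0
    mesh = make_bar(L=L, W=0.5, H=0.5, nx=8, ny=2, nz=2)
    A = 0.25
    loads = axial_bar_loadcase(mesh, L, F)
    K = assemble_stiffness(mesh, np.full(mesh.n_tets, E), 0.0)
    u = solve_displacements(K, loads, mesh.n_nodes)
    assert tip_displacement(mesh, u, L) == pytest.approx(F * L / (A * E), rel=1e-6)


def test_linearity_in_load(small_bar):
    K = assemble_stiffness(small_bar, np.full(small_bar.n_tets, GPA), 0.28)
    clamp = LoadCase.fix_nodes(small_bar.nodes_on_plane(0, 0.0))
    tip = int(small_bar.locate_nearest_node([1.0, 1.0, 1.0]))
    one = clamp.merged_with(LoadCase(point_forces=[(tip, np.array([1.0, 2.0, -3.0]))]))
    two = clamp.merged_with(LoadCase(point_forces=[(tip, np.array([2.0, 4.0, -6.0]))]))
    u1 = solve_displacements(K, one, small_bar.n_nodes)
    u2 = solve_displacements(K, two, small_bar.n_nodes)
    np.testing.assert_allclose(u2, 2.0 * u1, rtol=1e-9, atol=1e-20)


def test_stiffness_scaling_inverse_displacement(small_bar):
    c = 3.5
    loads = axial_bar_loadcase(small_bar, 1.0, 5.0)
    K1 = assemble_stiffness(small_bar, np.full(small_bar.n_tets, GPA), 0.28)
    K2 = assemble_stiffness(small_bar, np.full(small_bar.n_tets, c * GPA), 0.28)
    u1 = solve_displacements(K1, loads, small_bar.n_nodes)
    u2 = solve_displacements(K2, loads, small_bar.n_nodes)
    np.testing.assert_allclose(u2, u1 / c, rtol=1e-9, atol=1e-18)


def test_work_balance(small_bar):
    K = assemble_stiffness(small_bar, np.full(small_bar.n_tets, GPA), 0.28)
    loads = axial_bar_loadcase(small_bar, 1.0, 7.0)
    u = solve_displacements(K, loads, small_bar.n_nodes).reshape(-1)
    f = loads.force_vector(small_bar.n_nodes)
    external = 0.5 * f @ u
    internal = 0.5 * u @ (K @ u)
    assert internal == pytest.approx(external, rel=1e-9)


def test_patch_test_affine_field_reproduced():
    mesh = make_bar(L=3.0, W=1.0, H=1.0, nx=6, ny=2, nz=2)
    A = np.array([[1e-3, 2e-4, -1e-4], [3e-4, -5e-4, 2e-4], [1e-4, 4e-4, 8e-4]])
    b = np.array([1e-4, -2e-4, 3e-5])
    exact = mesh.node_coords @ A.T + b
    boundary = mesh.boundary_nodes()
    fixed = [
        (int(n), axis, float(exact[n, axis])) for n in boundary for axis in range(3)
    ]
    K = assemble_stiffness(mesh, np.full(mesh.n_tets, GPA), 0.3)
    u = solve_displacements(K, LoadCase(fixed_dofs=fixed), mesh.n_nodes)
    np.testing.assert_allclose(u, exact, rtol=1e-9, atol=1e-9 * np.abs(exact).max())


def test_conflicting_force_and_constraint_rejected():
    with pytest.raises(ValueError, match="both"):
        LoadCase(
            point_forces=[(0, np.array([1.0, 0.0, 0.0]))],
            fixed_dofs=[(0, 0, 0.0)],
        )


def test_graded_bar_converges_to_log_formula():
    expected = graded_bar_tip_displacement(1.0, 1.0, 1.0, 1.0, 2.0)
    assert expected == pytest.approx(np.log(2.0), rel=1e-12)
    errors = []
    for nx in (16, 32):
        mesh = make_bar(L=1.0, W=1.0, H=1.0, nx=nx, ny=2, nz=2)
        E_nodal = 1.0 + mesh.node_coords[:, 0]
        from thermograde import element_modulus

        K = assemble_stiffness(mesh, element_modulus(mesh, E_nodal), 0.0)
        u = solve_displacements(K, axial_bar_loadcase(mesh, 1.0, 1.0), mesh.n_nodes)
        errors.append(abs(tip_displacement(mesh, u, 1.0) - expected) / expected)
    assert errors[1] < 0.01
    assert errors[1] < errors[0]


# ------------------------------------------------------------ material modes

def test_regional_on_one_region_mesh_equals_uniform(small_bar):
    import pandas as pd

    tbl = RegionTable(
        pd.DataFrame(
            {"E": [17.3 * GPA], "nu": [0.28]}, index=pd.Index(["default"], name="region")
        )
    )
    loads = axial_bar_loadcase(small_bar, 1.0, 100.0)
    ui = run_material_mode(small_bar, "uniform_isotropic", loads)
    ri = run_material_mode(small_bar, "regional_isotropic", loads, table=tbl)
    np.testing.assert_allclose(ri.displacements, ui.displacements, rtol=1e-12)


def test_two_region_bar_series_compliance():
    import pandas as pd

    L, F, A = 1.0, 10.0, 1.0
    E_stiff, E_soft = 4.0 * GPA, 1.0 * GPA
    mesh = make_two_region_bar(L=L, nx=8, split_fraction=0.5, ny=2, nz=2)
    tbl = RegionTable(
        pd.DataFrame(
            {"E": [E_stiff, E_soft], "nu": [0.0, 0.0]},
            index=pd.Index(["stiff", "compliant"], name="region"),
        )
    )
    loads = axial_bar_loadcase(mesh, L, F)
    ri = run_material_mode(mesh, "regional_isotropic", loads, table=tbl)
    expected = F * 0.5 * L / (A * E_stiff) + F * 0.5 * L / (A * E_soft)
    assert tip_displacement(mesh, ri.displacements, L) == pytest.approx(expected, rel=1e-6)


def test_graded_constant_seeds_equals_uniform(small_bar):
    loads = axial_bar_loadcase(small_bar, 1.0, 50.0)
    seeds = SeedSet([0, small_bar.n_nodes - 1], [50.0, 50.0])
    tg = run_material_mode(small_bar, "thermally_graded", loads, seeds=seeds)
    ui = run_material_mode(small_bar, "uniform_isotropic", loads)
    np.testing.assert_allclose(
        tg.displacements, ui.displacements, rtol=1e-8, atol=1e-20
    )
    np.testing.assert_allclose(tg.E_per_element, 17.3 * GPA, rtol=1e-10)


def test_graded_mode_requires_seeds(small_bar):
    loads = axial_bar_loadcase(small_bar, 1.0, 1.0)
    with pytest.raises(ValueError, match="seed"):
        run_material_mode(small_bar, "thermally_graded", loads)


def test_trabecular_region_keeps_discrete_properties():
    mesh = make_two_region_bar(
        L=1.0, nx=4, ny=2, nz=2, labels=("cortical", "trabecular")
    )
    loads = axial_bar_loadcase(mesh, 1.0, 1.0)
    seeds = SeedSet([0], [50.0])
    tg = run_material_mode(mesh, "thermally_graded", loads, seeds=seeds)
    trab = np.array([r == "trabecular" for r in mesh.region_of_tet])
    np.testing.assert_allclose(tg.E_per_element[trab], 0.64 * GPA, rtol=1e-12)
    np.testing.assert_allclose(tg.E_per_element[~trab], 17.3 * GPA, rtol=1e-10)
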