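"""Tests for the plane-stress finite-element layer, including an
independently coded dense-assembly oracle."""

import numpy as np
import pytest

from emphysim import (
    BreathingLoad,
    MaterialField,
    build_mesh,
    max_tensile_strain_limit,
    mixture_modulus,
    rupture,
    solve_elasticity,
)
from emphysim.mechanics import E_DEAD, StrainField


# --- independent oracle: generic isoparametric Q4 dense assembly -----------

def dense_reference_solution(mesh, E, nu, eps):
    """Dense plane-stress solve written independently of the implementation:
    generic isoparametric Jacobian handling, dense numpy assembly and solve."""
    n_nodes = mesh.nodes.shape[0]
    K = np.zeros((2 * n_nodes, 2 * n_nodes))
    D0 = np.array([[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]]) / (1 - nu**2)
    gp = [(-1 / np.sqrt(3), -1 / np.sqrt(3)), (1 / np.sqrt(3), -1 / np.sqrt(3)),
          (1 / np.sqrt(3), 1 / np.sqrt(3)), (-1 / np.sqrt(3), 1 / np.sqrt(3))]
    xi_n = np.array([-1, 1, 1, -1])
    eta_n = np.array([-1, -1, 1, 1])
    for e, conn in enumerate(mesh.elements):
        xy = mesh.nodes[conn]
        ke = np.zeros((8, 8))
        for xi, eta in gp:
            dN = np.vstack([0.25 * xi_n * (1 + eta * eta_n),
                            0.25 * eta_n * (1 + xi * xi_n)])
            J = dN @ xy
            dNdx = np.linalg.solve(J, dN)
            B = np.zeros((3, 8))
            B[0, 0::2] = dNdx[0]
            B[1, 1::2] = dNdx[1]
            B[2, 0::2] = dNdx[1]
            B[2, 1::2] = dNdx[0]
            ke += B.T @ (E[e] * D0) @ B * np.linalg.det(J)
        dofs = np.empty(8, dtype=int)
        dofs[0::2] = 2 * conn
        dofs[1::2] = 2 * conn + 1
        K[np.ix_(dofs, dofs)] += ke
    # boundary conditions: uniform biaxial boundary strain about the center
    center = mesh.nodes.mean(axis=0)
    bnodes = mesh.boundary_nodes()
    u = np.zeros(2 * n_nodes)
    fixed = []
    for b in bnodes:
        u[2 * b] = eps * (mesh.nodes[b, 0] - center[0])
        u[2 * b + 1] = eps * (mesh.nodes[b, 1] - center[1])
        fixed += [2 * b, 2 * b + 1]
    free = np.setdiff1d(np.arange(2 * n_nodes), fixed)
    if free.size:
        u[free] = np.linalg.solve(K[np.ix_(free, free)],
                                  -K[np.ix_(free, fixed)] @ u[fixed])
    # centroid strains
    strains = np.zeros((mesh.elements.shape[0], 3))
    for e, conn in enumerate(mesh.elements):
        xy = mesh.nodes[conn]
        dN = np.vstack([0.25 * xi_n, 0.25 * eta_n])
        J = dN @ xy
        dNdx = np.linalg.solve(J, dN)
        ue = np.empty(8)
        ue[0::2] = u[2 * conn]
        ue[1::2] = u[2 * conn + 1]
        B = np.zeros((3, 8))
        B[0, 0::2] = dNdx[0]
        B[1, 1::2] = dNdx[1]
        B[2, 0::2] = dNdx[1]
        B[2, 1::2] = dNdx[0]
        strains[e] = B @ ue
    return u.reshape(-1, 2), strains, K[np.ix_(free, free)]


class TestMixtureModulus:
    @pytest.mark.parametrize("cel, ccl, alive, expected", [
        (1.0, 1.0, True, 6070.0),
        (0.5, 0.5, True, 3035.0),
        (0.3, 0.9, False, 1.0),
        (0.0, 1.0, True, 6000.0),
    ])
    def test_values(self, cel, ccl, alive, expected):
        assert mixture_modulus(cel, ccl, alive) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mixture_modulus(1.2, 0.5, True)

    def test_vectorized_with_floor(self):
        E = mixture_modulus(np.array([1.0, 0.0]), np.array([1.0, 0.0]),
                            np.array([True, True]))
        assert E.tolist() == [6070.0, E_DEAD]


class TestStrainLimit:
    @pytest.mark.parametrize("cel, ccl, expected", [
        (1.0, 0.0, 1.0),     # pure elastin stretches to 100 %
        (0.0, 1.0, 0.1),     # pure collagen fails near 10 %
        (0.5, 0.5, 0.55),
        (0.8, 0.2, (0.8 + 0.02) / 1.0),
    ])
    def test_weighted_limit(self, cel, ccl, expected):
        assert max_tensile_strain_limit(cel, ccl) == pytest.approx(expected)

    def test_depleted_cell_gets_conservative_limit(self):
        with pytest.warns(UserWarning):
            assert max_tensile_strain_limit(0.0, 0.0) == 0.1


class TestMesh:
    @pytest.mark.parametrize("rows, cols", [(2, 2), (1, 1), (3, 5)])
    def test_counts(self, rows, cols):
        mesh = build_mesh(rows, cols)
        assert mesh.n_nodes == (rows + 1) * (cols + 1)
        assert mesh.n_elements == rows * cols

    def test_element_areas(self):
        mesh = build_mesh(3, 4, cell_size=0.5)
        for conn in mesh.elements:
            xy = mesh.nodes[conn]
            area = 0.5 * abs(np.dot(xy[:, 0], np.roll(xy[:, 1], -1))
                             - np.dot(xy[:, 1], np.roll(xy[:, 0], -1)))
            assert area == pytest.approx(0.25)

    def test_cell_map_is_bijective(self):
        mesh = build_mesh(4, 3)
        seen = {mesh.element_of_cell(r, c) for r in range(4) for c in range(3)}
        assert seen == set(range(mesh.n_elements))


class TestSolver:
    def test_uniform_strain_patch(self):
        mesh = build_mesh(3, 3)
        mat = MaterialField(np.full(9, 6070.0))
        _, strains = solve_elasticity(mesh, mat, BreathingLoad(0.05))
        assert np.allclose(strains.exx, 0.05, atol=1e-10)
        assert np.allclose(strains.eyy, 0.05, atol=1e-10)
        assert np.allclose(strains.exy, 0.0, atol=1e-10)

    def test_affine_patch_test(self):
        # any affine boundary displacement is reproduced exactly inside
        mesh = build_mesh(4, 4)
        mat = MaterialField(np.full(16, 1234.0))
        disp = lambda x, y: (3e-3 * x + 1e-3 * y, -2e-3 * x + 4e-3 * y)
        u, strains = solve_elasticity(mesh, mat, boundary_displacement=disp)
        assert np.allclose(strains.exx, 3e-3, atol=1e-12)
        assert np.allclose(strains.eyy, 4e-3, atol=1e-12)
        assert np.allclose(strains.exy, 0.5 * (1e-3 - 2e-3), atol=1e-12)
        expected = np.array([disp(x, y) for x, y in mesh.nodes])
        assert np.allclose(u, expected, atol=1e-12)

    @pytest.mark.parametrize("rows, cols", [(3, 3), (4, 4), (2, 4)])
    def test_dense_assembly_oracle(self, rows, cols):
        rng = np.random.default_rng(rows * 10 + cols)
        mesh = build_mesh(rows, cols)
        E = rng.uniform(1.0, 6070.0, size=mesh.n_elements)
        mat = MaterialField(E, nu=0.3)
        u, strains = solve_elasticity(mesh, mat, BreathingLoad(0.05))
        u_ref, s_ref, _ = dense_reference_solution(mesh, E, 0.3, 0.05)
        assert np.allclose(u, u_ref, atol=1e-9)
        assert np.allclose(strains.exx, s_ref[:, 0], atol=1e-9)
        assert np.allclose(strains.eyy, s_ref[:, 1], atol=1e-9)
        assert np.allclose(strains.exy, 0.5 * s_ref[:, 2], atol=1e-9)

    def test_reduced_stiffness_is_spd(self):
        mesh = build_mesh(4, 4)
        E = np.random.default_rng(0).uniform(1.0, 6070.0, size=16)
        _, _, K_ff = dense_reference_solution(mesh, E, 0.3, 0.05)
        assert np.allclose(K_ff, K_ff.T, atol=1e-9)
        assert np.min(np.linalg.eigvalsh(K_ff)) > 0

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(4)
        rows = cols = 5
        half = rng.uniform(100.0, 6070.0, size=(rows, (cols + 1) // 2))
        E = np.hstack([half, half[:, ::-1][:, cols % 2:]])
        mesh = build_mesh(rows, cols)
        _, strains = solve_elasticity(mesh, MaterialField(E.ravel()),
                                      BreathingLoad(0.05))
        mp = strains.max_principal.reshape(rows, cols)
        assert np.allclose(mp, mp[:, ::-1], atol=1e-8)

    def test_dead_center_concentrates_strain(self):
        mesh = build_mesh(3, 3)
        E = np.full(9, 6070.0)
        E[4] = E_DEAD
        _, strains = solve_elasticity(mesh, MaterialField(E), BreathingLoad(0.05))
        neighbors = [1, 3, 5, 7]
        assert max(strains.max_principal[i] for i in neighbors) > 0.05

    def test_weakest_link_softening_raises_local_strain(self):
        """Under displacement control, softening an element never lowers
        that element's own peak strain (randomized 5x5 instances)."""
        rng = np.random.default_rng(7)
        for _ in range(3):
            mesh = build_mesh(5, 5)
            E = rng.uniform(500.0, 6070.0, size=25)
            _, s0 = solve_elasticity(mesh, MaterialField(E.copy()),
                                     BreathingLoad(0.05))
            for idx in rng.choice(25, size=3, replace=False):
                E2 = E.copy()
                E2[idx] = max(E2[idx] / 10.0, 1.0)
                _, s1 = solve_elasticity(mesh, MaterialField(E2),
                                         BreathingLoad(0.05))
                assert (s1.max_principal[idx]
                        >= s0.max_principal[idx] - 1e-12)


class TestRupture:
    def _uniform_strain(self, n, value):
        return StrainField(exx=np.full(n, value), eyy=np.full(n, value),
                           exy=np.zeros(n))

    def test_no_rupture_below_limits(self):
        alive = np.ones((2, 2), dtype=bool)
        cells = rupture(self._uniform_strain(4, 0.05), np.ones((2, 2)),
                        np.ones((2, 2)), alive)
        assert cells == []

    def test_all_collagen_cells_fail_at_20_percent(self):
        alive = np.ones((2, 3), dtype=bool)
        cells = rupture(self._uniform_strain(6, 0.2), np.zeros((2, 3)),
                        np.ones((2, 3)), alive)
        assert sorted(cells) == [(r, c) for r in range(2) for c in range(3)]

    def test_mixed_grid_selective_failure(self):
        cel = np.array([[1.0, 0.0]])
        ccl = np.array([[0.0, 1.0]])
        alive = np.ones((1, 2), dtype=bool)
        cells = rupture(self._uniform_strain(2, 0.2), cel, ccl, alive)
        assert cells == [(0, 1)]  # collagen cell dies, elastin survives

    def test_dead_cells_not_reported(self):
        alive = np.array([[True, False]])
        cells = rupture(self._uniform_strain(2, 0.5), np.zeros((1, 2)),
                        np.ones((1, 2)), alive)
        assert cells == [(0, 0)]
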