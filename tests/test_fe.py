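"""Finite element core: element correctness, boundary conditions,
equilibrium, verification problems."""
import numpy as np
import pytest

from femoneck.fe import (Constraints, FEModel, LoadCase, elasticity_matrix,
                         mesh_convergence_study, principal_strains,
                         select_bc_nodes)
from femoneck.materials import MaterialMap
from femoneck.mesh import TetMesh, extract_surface


def uniform_map(mesh, E=1000.0, nu=0.3):
    return MaterialMap(E=np.full(mesh.n_tets, E), nu=nu,
                       rho=np.full(mesh.n_tets, 1000.0))


def single_tet():
    nodes = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 3.0, 0], [0, 0, 4.0]])
    tets = np.array([[0, 1, 2, 3]])
    return TetMesh(nodes, tets, extract_surface(tets))


class TestAssembly:
    def test_single_tet_matches_hand_assembly(self):
        """K = V B^T D B assembled explicitly with scalar loops."""
        mesh = single_tet()
        E, nu = 1000.0, 0.3
        model = FEModel(mesh, uniform_map(mesh, E, nu))
        K = model.K.toarray()
        assert np.allclose(K, K.T, atol=1e-12)

        # independent hand assembly
        x = mesh.nodes
        M = np.column_stack([np.ones(4), x])
        C = np.linalg.inv(M)          # rows: coefficients of N_i = a+bx+cy+dz
        grads = C[1:, :].T            # (4, 3)
        B = np.zeros((6, 12))
        for i in range(4):
            bx, by, bz = grads[i]
            B[0, 3 * i] = bx
            B[1, 3 * i + 1] = by
            B[2, 3 * i + 2] = bz
            B[3, 3 * i], B[3, 3 * i + 1] = by, bx
            B[4, 3 * i + 1], B[4, 3 * i + 2] = bz, by
            B[5, 3 * i], B[5, 3 * i + 2] = bz, bx
        V = mesh.volumes()[0]
        D = E * elasticity_matrix(nu)
        K_hand = V * B.T @ D @ B
        assert np.abs(K - K_hand).max() < 1e-12 * np.abs(K_hand).max()

    def test_rigid_translation_zero_force(self):
        mesh = single_tet()
        model = FEModel(mesh, uniform_map(mesh))
        u = np.tile([1.0, -2.0, 0.5], mesh.n_nodes)
        assert np.abs(model.K @ u).max() < 1e-9

    def test_doubling_modulus_doubles_operator(self):
        mesh = single_tet()
        k1 = FEModel(mesh, uniform_map(mesh, 1000.0)).K.toarray()
        k2 = FEModel(mesh, uniform_map(mesh, 2000.0)).K.toarray()
        assert np.allclose(k2, 2 * k1)

    def test_six_rigid_body_modes(self, block_mesh):
        mesh = block_mesh(2, 2, 2)
        model = FEModel(mesh, uniform_map(mesh))
        w = np.linalg.eigvalsh(model.K.toarray())
        scale = w[-1]
        assert np.sum(w < 1e-10 * scale) == 6

    def test_inverted_element_detected(self):
        mesh = single_tet()
        mesh.tets = mesh.tets[:, [0, 2, 1, 3]]  # flip orientation
        with pytest.raises(ValueError, match="element"):
            FEModel(mesh, uniform_map(mesh))


class TestSolve:
    def test_pure_shear_principal_strains(self, block_mesh):
        mesh = block_mesh(2, 2, 2)
        model = FEModel(mesh, uniform_map(mesh))
        gamma = 1e-3
        A = np.array([[0, gamma / 2, 0], [gamma / 2, 0, 0], [0, 0, 0]])
        surf = mesh.surface_nodes
        dofs = (3 * surf[:, None] + np.arange(3)).ravel()
        model.apply_constraints(Constraints(dofs, (mesh.nodes[surf] @ A.T).ravel()))
        fld = model.solve(np.zeros(model.n_dof))
        assert np.allclose(fld.principal[:, 0], gamma / 2, atol=1e-12)
        assert np.allclose(fld.principal[:, 2], -gamma / 2, atol=1e-12)

    def test_uniaxial_patch_strains(self, block_mesh):
        mesh = block_mesh(3, 2, 2)
        E, nu, sigma = 5000.0, 0.3, 10.0
        model = FEModel(mesh, uniform_map(mesh, E, nu))
        exx = sigma / E
        A = np.diag([exx, -nu * exx, -nu * exx])
        surf = mesh.surface_nodes
        dofs = (3 * surf[:, None] + np.arange(3)).ravel()
        model.apply_constraints(Constraints(dofs, (mesh.nodes[surf] @ A.T).ravel()))
        fld = model.solve(np.zeros(model.n_dof))
        assert np.allclose(fld.principal[:, 0], sigma / E, rtol=1e-10)
        assert np.allclose(fld.principal[:, 2], -nu * sigma / E, rtol=1e-10)

    def test_unconstrained_system_raises(self):
        mesh = single_tet()
        model = FEModel(mesh, uniform_map(mesh))
        with pytest.raises(RuntimeError, match="rigid-body"):
            model.apply_constraints(Constraints(np.array([0]), np.zeros(1)))

    def test_solution_linearity_in_load(self, block_mesh):
        mesh = block_mesh(2, 2, 6)
        model = FEModel(mesh, uniform_map(mesh))
        base = np.nonzero(mesh.nodes[:, 2] < 1e-9)[0]
        dofs = (3 * base[:, None] + np.arange(3)).ravel()
        model.apply_constraints(Constraints(dofs, np.zeros(len(dofs))))
        top = mesh.surface_nodes[mesh.nodes[mesh.surface_nodes, 2] > 6 - 1e-9]
        lc1 = LoadCase(top, np.tile([1.0, 0, 2.0], (len(top), 1)))
        lc2 = LoadCase(top, np.tile([3.0, 0, 6.0], (len(top), 1)))
        f1, f2 = model.solve(lc1), model.solve(lc2)
        assert np.allclose(3 * f1.element_strain, f2.element_strain,
                           rtol=1e-10, atol=1e-18)


class TestReactions:
    def test_reactions_cancel_applied_loads(self, femur, density):
        from femoneck.materials import build_material_map
        model = FEModel(femur, build_material_map(femur, density))
        model.apply_constraints(select_bc_nodes(femur, "relaxed_three_node"))
        gt = femur.node_sets["greater_trochanter"]
        lc = LoadCase(np.array([gt[0]]), np.array([[100.0, 0.0, 0.0]]))
        fld = model.solve(lc)
        resid = fld.reactions.sum(axis=0) + np.array([100.0, 0, 0])
        assert np.linalg.norm(resid) < 1e-8 * 100.0
        assert fld.r_fem == pytest.approx(100.0, rel=1e-8)
        # zero loads: zero reactions
        z = model.solve(LoadCase(np.array([gt[0]]), np.zeros((1, 3))))
        assert z.r_fem == pytest.approx(0.0, abs=1e-9)

    def test_reactions_only_at_constrained_nodes(self, femur, density):
        from femoneck.materials import build_material_map
        model = FEModel(femur, build_material_map(femur, density))
        cons = select_bc_nodes(femur, "relaxed_three_node")
        model.apply_constraints(cons)
        gt = femur.node_sets["greater_trochanter"]
        fld = model.solve(LoadCase(np.array([gt[0]]),
                                   np.array([[0.0, 200.0, 800.0]])))
        nodes_with_r = np.nonzero(np.abs(fld.reactions).max(axis=1) > 1e-9)[0]
        assert set(nodes_with_r) <= set(np.asarray(cons.dofs) // 3)


class TestBoundaryConditions:
    def test_relaxed_mode_has_six_dofs(self, femur):
        cons = select_bc_nodes(femur, "relaxed_three_node")
        assert len(cons.dofs) == 6

    def test_relaxed_mode_statically_determinate(self, femur, density):
        """Six constraints in 3-D: reactions follow from equilibrium alone,
        so they are invariant to a change of material stiffness."""
        from femoneck.materials import PowerLaw, build_material_map
        gt = femur.node_sets["greater_trochanter"]
        lc = LoadCase(np.array([gt[0]]), np.array([[50.0, -300.0, 900.0]]))
        reactions = []
        for law in (PowerLaw(), PowerLaw(a=3000.0, b=1.2)):
            model = FEModel(femur, build_material_map(femur, density, law))
            model.apply_constraints(select_bc_nodes(femur, "relaxed_three_node"))
            reactions.append(model.solve(lc).reactions.sum(axis=0))
        assert np.allclose(reactions[0], reactions[1], atol=1e-6)

    def test_fully_fixed_dof_count(self, femur):
        cons = select_bc_nodes(femur, "fully_fixed_distal")
        sup = femur.frame["superior"]
        s = femur.nodes @ sup
        n_nodes = np.sum(s <= s.min() + 0.02 * (s.max() - s.min()))
        assert len(cons.dofs) == 3 * n_nodes

    def test_missing_node_set_raises(self, femur):
        stripped = TetMesh(femur.nodes, femur.tets, femur.surface,
                           {}, femur.frame, femur.ground_truth)
        with pytest.raises(ValueError, match="node set"):
            select_bc_nodes(stripped, "relaxed_three_node")

    def test_bc_mode_peak_strain_difference_small(self, femur, density):
        """Fully fixed vs relaxed distal constraints change the averaged
        neck peak strain only marginally (distal end is far from the neck)."""
        from femoneck import post
        from femoneck.materials import build_material_map
        gtset = femur.node_sets["greater_trochanter"]
        n_gt = gtset[int(np.argmax(femur.nodes[gtset][:, 2]))]
        lc = LoadCase(np.array([n_gt]), np.array([[0.0, 400.0, 1400.0]]))
        region = post.neck_region(femur)
        peaks = {}
        for mode in ("relaxed_three_node", "fully_fixed_distal"):
            model = FEModel(femur, build_material_map(femur, density))
            model.apply_constraints(select_bc_nodes(femur, mode))
            peaks[mode] = post.averaged_peak(model.solve(lc), femur,
                                             region, 3.0).peak_e1
        rel = abs(peaks["relaxed_three_node"] - peaks["fully_fixed_distal"]) \
            / peaks["relaxed_three_node"]
        assert rel < 0.10


class TestPrincipalStrains:
    def test_ordering_invariant(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 1e-3, size=(200, 6))
        p = principal_strains(v)
        assert np.all(p[:, 0] >= p[:, 1]) and np.all(p[:, 1] >= p[:, 2])

    def test_known_tensor(self):
        # uniaxial: e = diag(1e-3, 0, 0)
        p = principal_strains(np.array([[1e-3, 0, 0, 0, 0, 0]]))
        assert np.allclose(p[0], [1e-3, 0, 0], atol=1e-15)


class TestConvergenceStudy:
    def test_dof_monotone_and_changes_reported(self):
        from femoneck.subject import SubjectSpec
        df = mesh_convergence_study(SubjectSpec(), [8.0, 6.5], order=1)
        assert len(df) == 2
        assert df.dof.iloc[1] > df.dof.iloc[0]
        assert np.isfinite(df.d_e1_pct.iloc[1])

    def test_identical_size_zero_change(self):
        from femoneck.subject import SubjectSpec
        df = mesh_convergence_study(SubjectSpec(), [8.0, 8.0], order=1)
        assert df.d_e1_pct.iloc[1] == pytest.approx(0.0, abs=1e-9)
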