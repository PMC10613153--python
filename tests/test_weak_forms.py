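"""Element kernels: quadrature, residuals, tangents, follower pressure."""
import numpy as np
import pytest

import vasapf.constitutive as con
from vasapf.params import MaterialParams, SolverConfig
from vasapf.solver import Dirichlet, FEProblem, newton_solve
from vasapf.vv_geometry import build_rect_mesh
from vasapf.weak_forms import (ElementKernelInput, element_residual,
                               element_tangent,
                               follower_pressure_residual,
                               follower_pressure_tangent, shape_quadrature)

UNIT_QUAD = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def make_input(coords, dofs, mat, dt=None, mode="none", phi_prev=None,
               d_prev=None):
    nen = len(coords)
    ngp = 4 if coords.shape[1] == 2 else 8
    return ElementKernelInput(
        coords=coords, dofs=dofs,
        phi_prev=np.zeros(nen) if phi_prev is None else phi_prev,
        d_prev=np.zeros(nen) if d_prev is None else d_prev,
        alpha=np.zeros(ngp), psi_max=np.zeros(ngp),
        params=mat, dt=dt, mode=mode)


class TestShapeQuadrature:
    @pytest.mark.parametrize("et,measure", [("quad4", 4.0), ("hex8", 8.0)])
    def test_partition_of_unity_and_measure(self, et, measure):
        _, w, N, dN = shape_quadrature(et)
        assert np.allclose(N.sum(axis=1), 1.0)
        assert w.sum() == pytest.approx(measure)
        assert np.allclose(dN.sum(axis=1), 0.0, atol=1e-14)

    def test_bilinear_integrand_exact(self):
        # integral of x*y over the unit square via the mapped 2x2 rule
        pts, w, N, _ = shape_quadrature("quad4")
        xy = N @ UNIT_QUAD                       # Gauss points in x-space
        detJ = 0.25                              # d(x)/d(xi) for unit square
        val = np.sum(w * xy[:, 0] * xy[:, 1] * detJ)
        assert val == pytest.approx(0.25)

    def test_unknown_element_type(self):
        with pytest.raises(ValueError):
            shape_quadrature("tri3")


class TestElementResidual:
    def test_reference_state_zero_residual(self, mat):
        dofs = np.zeros((4, 5))
        out = element_residual(make_input(UNIT_QUAD, dofs, mat))
        assert np.allclose(out.residual, 0.0, atol=1e-12)

    def test_uniform_unit_concentration_no_sink_in_equilibrium(self):
        mat = MaterialParams(consumption=0.0)
        dofs = np.zeros((4, 5))
        dofs[:, 2] = 1.0
        out = element_residual(make_input(UNIT_QUAD, dofs, mat))
        r_c = out.residual.reshape(4, 5)[:, 2]
        assert np.allclose(r_c, 0.0, atol=1e-12)

    @pytest.mark.parametrize("phi_star", [0.0, 0.5, 1.0])
    def test_double_well_stationary_points(self, mat, phi_star):
        # uniform phi, no source, dt -> infinity: residual ~ M f'(phi)
        dofs = np.zeros((4, 5))
        dofs[:, 3] = phi_star
        inp = make_input(UNIT_QUAD, dofs, mat, dt=None,
                         phi_prev=np.full(4, phi_star))
        out = element_residual(inp)
        r_phi = out.residual.reshape(4, 5)[:, 3]
        assert np.allclose(r_phi, 0.0, atol=1e-12)

    def test_nonstationary_phi_pulled_by_barrier(self, mat):
        dofs = np.zeros((4, 5))
        dofs[:, 3] = 0.25     # f'(0.25) > 0: residual pushes phi down
        inp = make_input(UNIT_QUAD, dofs, mat, phi_prev=np.full(4, 0.25))
        r_phi = element_residual(inp).residual.reshape(4, 5)[:, 3]
        assert (r_phi > 0).all()

    def test_growth_update_recorded_at_gauss_points(self, mat):
        dofs = np.zeros((4, 5))
        dofs[:, 3] = 0.05
        inp = make_input(UNIT_QUAD, dofs, mat)      # phi_prev = 0
        out = element_residual(inp)
        k = mat.growth_coupling * 0.05
        assert np.allclose(out.alpha, k / (1 - k))

    def test_rigid_translation_invariance(self, mat, rng):
        coords = UNIT_QUAD + 0.05 * rng.standard_normal((4, 2))
        dofs = np.zeros((4, 5))
        base = element_residual(make_input(coords, dofs, mat)).residual
        dofs2 = dofs.copy()
        dofs2[:, 0] += 0.3
        dofs2[:, 1] -= 0.2
        shifted = element_residual(make_input(coords, dofs2, mat)).residual
        assert np.allclose(base, shifted, atol=1e-10)


class TestElementTangent:
    def test_matches_independent_central_differences(self, mat, rng):
        coords = UNIT_QUAD + 0.05 * rng.standard_normal((4, 2))
        dofs = 0.05 * rng.standard_normal((4, 5))
        dofs[:, 3:] = np.abs(dofs[:, 3:])
        inp = make_input(coords, dofs, mat, dt=0.01)
        out = element_tangent(inp)
        K = out.tangent
        K_fd = np.empty_like(K)
        h0 = 1e-7
        flat = dofs.reshape(-1)
        for j in range(20):
            h = h0 * (1 + abs(flat[j]))
            for sgn, tgt in ((1, None), (-1, None)):
                pass
            dp = flat.copy()
            dp[j] += h
            rp = element_residual(make_input(coords, dp.reshape(4, 5), mat,
                                             dt=0.01)).residual
            dm = flat.copy()
            dm[j] -= h
            rm = element_residual(make_input(coords, dm.reshape(4, 5), mat,
                                             dt=0.01)).residual
            K_fd[:, j] = (rp - rm) / (2 * h)
        assert np.linalg.norm(K - K_fd) <= 1e-6 * np.linalg.norm(K)

    def test_diffusion_blocks_symmetric(self, mat):
        dofs = np.zeros((4, 5))
        out = element_tangent(make_input(UNIT_QUAD, dofs, mat, dt=0.01))
        K = out.tangent
        for comp in (2, 4):                      # c-c and d-d blocks
            idx = [4 * 0 + comp + 5 * n for n in range(4)]
            blk = K[np.ix_(idx, idx)]
            assert np.allclose(blk, blk.T, atol=1e-10 * abs(blk).max())

    def test_nutrient_block_constant_in_c(self, mat):
        # at fixed phi the steady nutrient operator is linear: its tangent
        # block does not depend on the c iterate (sink saturated at c ~ 1)
        dofs = np.zeros((4, 5))
        dofs[:, 2] = 1.0
        K1 = element_tangent(make_input(UNIT_QUAD, dofs, mat)).tangent
        dofs2 = dofs.copy()
        dofs2[:, 2] = 1.2
        K2 = element_tangent(make_input(UNIT_QUAD, dofs2, mat)).tangent
        idx = [2 + 5 * n for n in range(4)]
        assert np.allclose(K1[np.ix_(idx, idx)], K2[np.ix_(idx, idx)],
                           rtol=1e-3)


class TestFollowerPressure:
    def test_zero_pressure_zero_contribution(self):
        x = np.array([[[0.0, 0.0], [1.0, 0.0]]])
        assert np.allclose(follower_pressure_residual(x, 0.0), 0.0)

    def test_straight_facet_force_magnitude_and_direction(self):
        # CCW lumen facet along +y at x=1: outward solid normal -x,
        # traction +x with magnitude p*L
        L, p = 2.0, 5.0
        x = np.array([[[1.0, 0.0], [1.0, L]]])
        r = follower_pressure_residual(x, p)[0]
        f = -r.sum(axis=0)                       # external force on facet
        assert f == pytest.approx([p * L, 0.0])

    def test_closed_circle_zero_net_force(self):
        n, R, p = 64, 600.0, 16.0
        th = np.linspace(0, 2 * np.pi, n + 1)
        pts = np.column_stack([R * np.cos(th), R * np.sin(th)])
        facets = np.stack([pts[:-1], pts[1:]], axis=1)
        r = follower_pressure_residual(facets, p)
        net = r.sum(axis=(0, 1))
        assert np.linalg.norm(net) < 1e-10 * p * 2 * R

    def test_tangent_matches_finite_differences(self, rng):
        p = 3.0
        x0 = rng.standard_normal((3, 2, 2))
        K = follower_pressure_tangent(x0, p)
        h = 1e-7
        for f in range(3):
            for j in range(4):
                xp = x0[f].reshape(-1).copy()
                xp[j] += h
                xm = x0[f].reshape(-1).copy()
                xm[j] -= h
                col = (follower_pressure_residual(xp.reshape(1, 2, 2), p)
                       - follower_pressure_residual(xm.reshape(1, 2, 2), p)
                       ).reshape(-1) / (2 * h)
                assert np.allclose(K[f, :, j], col, atol=1e-6)


class TestPatchAndManufactured:
    def test_constant_strain_patch_reproduced_exactly(self, mat):
        """Distorted 4x4 patch with a linear displacement field prescribed
        on the boundary: the interior solves to the same linear field and
        a uniform stress state."""
        mesh = build_rect_mesh(4, 4, 2.0, 2.0, distort=0.25, seed=3)
        problem = FEProblem(mesh, mat, "none")
        A = np.array([[0.02, 0.01], [-0.005, 0.015]])
        u_exact = mesh.coords @ A.T
        boundary = np.unique(np.concatenate(
            [mesh.node_sets[k] for k in ("lumen", "outer", "bottom",
                                         "top")]))
        dofs, vals = [], []
        for comp in range(2):
            dofs.append(problem.dofs_of(boundary, comp))
            vals.append(u_exact[boundary, comp])
        other = np.flatnonzero(problem.dof_field > 0)   # pin c, phi, d
        dofs.append(other)
        vals.append(np.zeros(len(other)))
        bc = Dirichlet(np.concatenate(dofs), np.concatenate(vals))
        D = problem.zero_state()
        res = newton_solve(problem, D, np.zeros(mesh.n_nodes),
                           np.zeros(mesh.n_nodes), problem.zero_gauss(),
                           None, 0.0, bc, SolverConfig())
        u = res.state.reshape(mesh.n_nodes, 5)[:, :2]
        assert np.allclose(u, u_exact, atol=1e-8)

    @staticmethod
    def _nutrient_error(nx):
        """Quadrature L2 error of the steady nutrient parabola on a slab.

        c = 1 at both ends, uniform sink: c = 1 - (R_c/2D) x (L-x).  The
        parameters keep c >= 0.87 so the sink saturation is ~1.
        """
        L = 100.0
        mat = MaterialParams(consumption=1.0e-2, diff_max=100.0,
                             diff_min=100.0)
        mesh = build_rect_mesh(nx, 1, L, L / nx)
        problem = FEProblem(mesh, mat, "none")
        ends = np.unique(np.concatenate([mesh.node_sets["lumen"],
                                         mesh.node_sets["outer"]]))
        other = np.flatnonzero(problem.dof_field != 1)
        bc = Dirichlet(np.concatenate([problem.dofs_of(ends, 2), other]),
                       np.concatenate([np.ones(len(ends)),
                                       np.zeros(len(other))]))
        D = problem.zero_state()
        res = newton_solve(problem, D, np.zeros(mesh.n_nodes),
                           np.zeros(mesh.n_nodes), problem.zero_gauss(),
                           None, 0.0, bc, SolverConfig())
        c = res.state.reshape(mesh.n_nodes, 5)[:, 2]
        kern = problem.kern
        c_gp = np.einsum("gn,en->eg", kern.N, c[mesh.elems])
        x_gp = np.einsum("gn,en->eg", kern.N, mesh.coords[mesh.elems, 0])
        exact = 1.0 - mat.consumption / (2 * mat.diff_max) * x_gp * (
            L - x_gp)
        err2 = np.sum(kern.dV * (c_gp - exact) ** 2)
        return np.sqrt(err2 / np.sum(kern.dV))

    def test_nutrient_parabola_second_order_convergence(self):
        errs = [self._nutrient_error(nx) for nx in (8, 16, 32)]
        assert errs[2] < 5e-4           # resolves the closed form
        rate = np.log2(errs[0] / errs[2]) / 2
        assert rate > 1.6               # ~O(h^2)

    @staticmethod
    def _damage_profile_error(nx):
        """Steady 1D damage profile with d pinned to 1 at the midline.

        The bar spans 12 length scales each side, so the finite-domain
        (cosh) correction to the infinite-bar profile exp(-|x|/l) is
        negligible (~e^-24)."""
        L = 96.0
        mat = MaterialParams(damage_length=4.0)
        mesh = build_rect_mesh(nx, 1, L, L / nx)
        problem = FEProblem(mesh, mat, "none")
        x = mesh.coords[:, 0]
        mid = np.flatnonzero(np.abs(x - L / 2) < 1e-9)
        assert len(mid)
        dofs_d = problem.dofs_of(mid, 4)
        other = np.flatnonzero(problem.dof_field != 3)
        bc = Dirichlet(np.concatenate([dofs_d, other]),
                       np.concatenate([np.ones(len(dofs_d)),
                                       np.zeros(len(other))]))
        D = problem.zero_state()
        res = newton_solve(problem, D, np.zeros(mesh.n_nodes),
                           np.zeros(mesh.n_nodes), problem.zero_gauss(),
                           None, 0.0, bc, SolverConfig())
        d = res.state.reshape(mesh.n_nodes, 5)[:, 4]
        d_exact = np.exp(-np.abs(x - L / 2) / mat.damage_length)
        return np.sqrt(np.mean((d - d_exact) ** 2)), d, x, mat

    def test_damage_profile_matches_exponential(self):
        errs = [self._damage_profile_error(nx)[0] for nx in (20, 40, 80)]
        assert errs[-1] < 5e-3
        assert errs[0] > errs[1] > errs[2]      # converging under refinement

    def test_crack_energy_integral_approaches_length_scale(self):
        _, d, x, mat = self._damage_profile_error(160)
        order = np.argsort(x)
        xs, idx = np.unique(np.round(x[order], 9), return_index=True)
        ds = d[order][idx]
        # integrate one side of the kink (one-sided derivative at the
        # pinned midline) and double: the profile is symmetric
        half = xs >= xs[np.argmax(ds)] - 1e-9
        gd = np.gradient(ds[half], xs[half])
        gamma = con.crack_surface_density(ds[half], gd[:, None],
                                          mat.damage_length)
        total = 2.0 * np.trapezoid(gamma, xs[half])
        assert total == pytest.approx(mat.damage_length, rel=0.05)
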