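"""Element-level residuals and tangents for the four coupled fields.

Every node carries (u_x, u_y[, u_z], c, phi, d) — 5 DOF in 2D plane strain,
6 in 3D — in node-major, DOF-minor ordering.  Per Gauss point the kernel

  * updates the growth internal variable alpha implicitly from the local
    increment of phi (closed-form root of the growth residual),
  * evaluates the degraded stress and the crack-driver history Psi_max,
  * accumulates the weak-form blocks: mechanical stress power, steady
    nutrient diffusion-reaction, Allen-Cahn inflammation/hematoma with its
    double-well barrier and source, and the viscous damage phase field.

Integrals are evaluated by exact pull-back to the reference configuration
(dv = J dV, spatial gradients via F^-T); the damage block is kept entirely
in the reference configuration.  Tangents are consistent perturbation-based
central differences of the element residual (the growth sensitivity
d alpha / d phi is thereby included automatically); the follower-pressure
facet tangent is analytic in 2D.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import constitutive as con
from .params import MaterialParams

_SQ3 = 1.0 / np.sqrt(3.0)


def shape_quadrature(element_type: str):
    """Isoparametric basis and Gauss rule.

    Returns (points (ngp, dim), weights (ngp,), N (ngp, nen),
    dN/dxi (ngp, nen, dim)).  quad4 uses 2x2 points, hex8 2x2x2.
    """
    if element_type == "quad4":
        ref = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
        g1 = np.array([-_SQ3, _SQ3])
        pts = np.array([[x, y] for x in g1 for y in g1])
        w = np.ones(4)
    elif element_type == "hex8":
        ref = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
                       dtype=float)
        g1 = np.array([-_SQ3, _SQ3])
        pts = np.array([[x, y, z] for x in g1 for y in g1 for z in g1])
        w = np.ones(8)
    else:
        raise ValueError(f"unknown element type {element_type!r}")
    dim = ref.shape[1]
    ngp, nen = len(pts), len(ref)
    N = np.empty((ngp, nen))
    dN = np.empty((ngp, nen, dim))
    for g, xi in enumerate(pts):
        terms = 1.0 + ref * xi            # (nen, dim)
        N[g] = np.prod(terms, axis=1) / 2 ** dim
        for a in range(dim):
            parts = terms.copy()
            parts[:, a] = ref[:, a]
            dN[g, :, a] = np.prod(parts, axis=1) / 2 ** dim
    return pts, w, N, dN


def field_indices(dim: int):
    """(u slice, c, phi, d) DOF component indices for the node layout."""
    return slice(0, dim), dim, dim + 1, dim + 2


@dataclass
class ElementKernelInput:
    """Single-element state for the spec-level residual/tangent API."""
    coords: np.ndarray        # (nen, dim)
    dofs: np.ndarray          # (nen, ndpn) current Newton iterate
    phi_prev: np.ndarray      # (nen,) previous time step
    d_prev: np.ndarray        # (nen,)
    alpha: np.ndarray         # (ngp,) committed growth scalars
    psi_max: np.ndarray       # (ngp,) committed history
    params: MaterialParams = None
    dt: Optional[float] = None
    mode: str = "none"        # none | dissection | atherosclerosis


@dataclass
class ElementOutput:
    residual: np.ndarray      # (nen*ndpn,) node-major, DOF-minor
    tangent: Optional[np.ndarray]
    alpha: np.ndarray         # updated Gauss growth scalars
    psi_max: np.ndarray


class ElementKernel:
    """Batched evaluator over all elements of a mesh."""

    def __init__(self, elem_coords: np.ndarray, params: MaterialParams,
                 mode: str = "none"):
        self.X = np.asarray(elem_coords, dtype=float)   # (ne, nen, dim)
        self.ne, self.nen, self.dim = self.X.shape
        self.etype = "quad4" if self.dim == 2 else "hex8"
        self.params = params
        self.mode = mode
        self.ndpn = self.dim + 3
        _, w, self.N, dN = shape_quadrature(self.etype)
        self.ngp = len(w)
        J0 = np.einsum("gnj,eni->egij", dN, self.X)
        detJ0 = np.linalg.det(J0)
        if np.any(detJ0 <= 0):
            raise ValueError("non-positive isoparametric Jacobian")
        invJ0 = np.linalg.inv(J0)
        # dN/dX[e,g,n,i] = dN/dxi[g,n,j] * dxi_j/dX_i
        self.dNdX = np.einsum("gnj,egji->egni", dN, invJ0)
        self.dV = w[None, :] * detJ0                    # (ne, ngp)
        self._eye = np.eye(self.dim)

    # -- core ---------------------------------------------------------------

    def residual(self, De, phi_prev, d_prev, alpha_c, psimax_c,
                 dt: Optional[float]):
        """Residual (ne, nen, ndpn) plus trial Gauss states.

        ``De``: nodal unknowns (ne, nen, ndpn) at the current iterate;
        ``phi_prev``/``d_prev``: nodal values at the previous time step;
        ``alpha_c``/``psimax_c``: committed Gauss states (ne, ngp);
        ``dt=None`` drops the rate terms (steady sub-problems).
        """
        return self._residual_core(self.dNdX, self.dV, De, phi_prev,
                                   d_prev, alpha_c, psimax_c, dt)

    def _residual_core(self, dNdX, dV, De, phi_prev, d_prev, alpha_c,
                       psimax_c, dt: Optional[float]):
        p = self.params
        dim, iu, ic, iphi, idd = self.dim, *field_indices(self.dim)
        N = self.N

        vals = np.einsum("gn,enf->egf", N, De)          # (ne, ngp, ndpn)
        grads = np.einsum("egni,enf->egfi", dNdX, De)   # material gradients
        phi_g = vals[..., iphi]
        d_g = vals[..., idd]
        c_g = vals[..., ic]
        phi_prev_g = np.einsum("gn,en->eg", N, phi_prev)
        d_prev_g = np.einsum("gn,en->eg", N, d_prev)

        alpha, _ = con.update_alpha(alpha_c, phi_prev_g, phi_g,
                                    p.growth_coupling)

        H = grads[..., :dim, :dim]                      # du_i/dX_j
        F = H + self._eye
        J = con.det2(F) if dim == 2 else con.det3(F)
        if np.any(J <= 0):
            raise con.DegenerateDeformationError("det F <= 0 at a Gauss point")
        invF = con.inv2(F, J) if dim == 2 else con.inv3(F, J)

        if dim == 2:                                    # plane strain embed
            F3 = np.zeros(F.shape[:-2] + (3, 3))
            F3[..., :2, :2] = F
            F3[..., 2, 2] = 1.0
        else:
            F3 = F
        kin = con.kinematics_from_F(F3, alpha)
        se = con.energy_and_stress(kin, d_g, p)
        psimax = con.update_history(se.psi_drive, psimax_c)

        if self.mode == "dissection":
            S_phi = con.source_hematoma(c_g, d_g, p.hematoma_rate)
        elif self.mode == "atherosclerosis":
            S_phi = con.source_inflammation(c_g, p.nutrient_threshold,
                                            p.hematoma_rate)
        else:
            S_phi = np.zeros_like(c_g)
        S_d = con.source_damage(d_g, psimax, p.fracture_resistance,
                                p.residual_stiffness)
        _, fprime = con.barrier_f(phi_g, p.barrier_height)
        D_eff = con.diffusivity(phi_g, p.diff_max, p.diff_min)
        sink = p.consumption * con.consumption_cutoff(c_g)

        # spatial gradients and shape-function derivatives
        dNdx = np.einsum("egnj,egji->egni", dNdX, invF)
        gx_c = np.einsum("egj,egji->egi", grads[..., ic, :], invF)
        gx_phi = np.einsum("egj,egji->egi", grads[..., iphi, :], invF)
        gX_d = grads[..., idd, :]

        R = np.zeros((De.shape[0], self.nen, self.ndpn))
        dv = dV * J                                      # current volume

        sig = se.sigma[..., :dim, :dim]
        R[..., iu] += np.einsum("eg,egab,egnb->ena", dv, sig, dNdx)

        R[..., ic] += p.scale_c * (
            np.einsum("eg,egi,egni->en", dv * D_eff, gx_c, dNdx)
            + np.einsum("eg,gn->en", dv * sink, N))

        # f'(phi) already carries the barrier height M (single constant:
        # the mobility in front of the barrier term and the barrier
        # amplitude are not distinguished)
        bulk_phi = fprime - S_phi
        if dt is not None:
            bulk_phi = bulk_phi + (phi_g - phi_prev_g) / dt
        eps2 = p.interface_param ** 2
        R[..., iphi] += p.scale_phi * (
            np.einsum("eg,egi,egni->en", dv * eps2, gx_phi, dNdx)
            + np.einsum("eg,gn->en", dv * bulk_phi, N))

        bulk_d = d_g - S_d
        if dt is not None:
            bulk_d = bulk_d + p.damage_viscosity * (d_g - d_prev_g) / dt
        l2 = p.damage_length ** 2
        R[..., idd] += p.scale_d * (                    # reference config
            np.einsum("eg,egi,egni->en", dV * l2, gX_d, dNdX)
            + np.einsum("eg,gn->en", dV * bulk_d, N))

        return R, alpha, psimax

    def gauss_fields(self, De, alpha):
        """Kinematic/stress quantities at Gauss points for an accepted state
        (``alpha`` are the committed growth scalars): dict with sigma
        (ne, ngp, 3, 3), von_mises, J, J_e, psi_drive."""
        dim, iu, ic, iphi, idd = self.dim, *field_indices(self.dim)
        grads = np.einsum("egni,enf->egfi", self.dNdX, De)
        d_g = np.einsum("gn,enf->egf", self.N, De)[..., idd]
        H = grads[..., :dim, :dim]
        F = H + self._eye
        if dim == 2:
            F3 = np.zeros(F.shape[:-2] + (3, 3))
            F3[..., :2, :2] = F
            F3[..., 2, 2] = 1.0
        else:
            F3 = F
        kin = con.kinematics_from_F(F3, alpha)
        se = con.energy_and_stress(kin, d_g, self.params)
        return {"sigma": se.sigma, "von_mises": con.von_mises(se.sigma),
                "J": np.linalg.det(F), "J_e": kin.J_e,
                "psi_drive": se.psi_drive}

    def tangent_fd(self, De, phi_prev, d_prev, alpha_c, psimax_c,
                   dt: Optional[float], eps: float = 1.0e-6):
        """Consistent tangent by batched central differences of the element
        residual; returns (R, K (ne, ned, ned), alpha, psi_max).

        All 2*ned perturbed states are evaluated in chunked stacked calls
        (the residual is element-local, so perturbations of different
        columns can share one big batch).
        """
        R0, alpha, psimax = self.residual(De, phi_prev, d_prev,
                                          alpha_c, psimax_c, dt)
        ne, ned = self.ne, self.nen * self.ndpn
        flat = De.reshape(ne, ned)
        K = np.empty((ne, ned, ned))
        for j in range(ned):
            h = eps * (1.0 + np.abs(flat[:, j]))        # (ne,)
            Dp = flat.copy()
            Dp[:, j] += h
            Rp, _, _ = self.residual(Dp.reshape(De.shape), phi_prev,
                                     d_prev, alpha_c, psimax_c, dt)
            Dm = flat.copy()
            Dm[:, j] -= h
            Rm, _, _ = self.residual(Dm.reshape(De.shape), phi_prev,
                                     d_prev, alpha_c, psimax_c, dt)
            K[:, :, j] = (Rp - Rm).reshape(ne, ned) / (2.0 * h[:, None])
        return R0.reshape(ne, ned), K, alpha, psimax


# -- spec-level single-element wrappers -------------------------------------

def element_residual(inp: ElementKernelInput) -> ElementOutput:
    kern = ElementKernel(inp.coords[None], inp.params, inp.mode)
    R, a, h = kern.residual(inp.dofs[None], inp.phi_prev[None],
                            inp.d_prev[None], inp.alpha[None],
                            inp.psi_max[None], inp.dt)
    return ElementOutput(R.reshape(-1), None, a[0], h[0])


def element_tangent(inp: ElementKernelInput) -> ElementOutput:
    kern = ElementKernel(inp.coords[None], inp.params, inp.mode)
    R, K, a, h = kern.tangent_fd(inp.dofs[None], inp.phi_prev[None],
                                 inp.d_prev[None], inp.alpha[None],
                                 inp.psi_max[None], inp.dt)
    return ElementOutput(R[0], K[0], a[0], h[0])


# ---------------------------------------------------------------------------
# Follower pressure on the lumen boundary
# ---------------------------------------------------------------------------

_PERP = np.array([[0.0, -1.0], [1.0, 0.0]])   # 90 deg CCW rotation


def follower_pressure_residual(x_facets: np.ndarray, p: float) -> np.ndarray:
    """Mechanical residual of the follower load t = -p n on the *current*
    facet geometry.

    2D: ``x_facets`` (nf, 2, 2) current node positions of oriented lumen
    segments (counter-clockwise around the lumen, solid outside); returns
    (nf, 2, 2) nodal residual contributions (to be added to the global
    mechanical residual).  3D: (nf, 4, 3) bilinear facets, 2x2 quadrature.
    """
    x = np.asarray(x_facets, dtype=float)
    if x.shape[-1] == 2:
        e = x[:, 1] - x[:, 0]                  # (nf, 2)
        nL = e @ _PERP.T                       # outward solid normal * length
        f_node = -p * nL / 2.0                 # traction integral per node
        return -np.stack([f_node, f_node], axis=1)
    # 3D bilinear facet
    pts, w, N, dN = shape_quadrature("quad4")
    # surface tangents d x / d xi at Gauss points
    t = np.einsum("gnj,enk->egjk", dN, x)      # (nf, ngp, 2(par), 3)
    cross = np.cross(t[:, :, 0, :], t[:, :, 1, :])   # points into the solid
    # n_out dA = -cross ; traction t = -p n_out -> nodal force += p*cross*w*N
    f = np.einsum("g,gn,egi->eni", w, N, p * cross)
    return -f


def follower_pressure_tangent(x_facets: np.ndarray, p: float) -> np.ndarray:
    """d(residual)/d(u) of the 2D follower load: analytic, (nf, 4, 4) in
    (node-major, component-minor) facet DOF ordering."""
    x = np.asarray(x_facets, dtype=float)
    nf = x.shape[0]
    K = np.zeros((nf, 4, 4))
    blk = p / 2.0 * _PERP
    for n in range(2):                         # residual rows at both nodes
        K[:, 2 * n:2 * n + 2, 2:4] += blk      # d/dx2
        K[:, 2 * n:2 * n + 2, 0:2] -= blk      # d/dx1
    return K
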