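"""Global assembly, monolithic Newton-Raphson and backward-Euler marching.

All four fields (displacement, nutrient, inflammation/hematoma phase phi,
damage d) are solved simultaneously in one sparse system per Newton
iteration (direct factorization).  The nutrient block is steady — it simply
carries no rate term.  Time marching ramps the lumen pressure first (with
the phase fields frozen), then advances the coupled evolution with a fixed
step that is cut on Newton failure.  After each accepted step the damage
field is clamped to be non-decreasing and both phase fields are projected
to [0, 1]; the Gauss history Psi_max and growth alpha are committed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as con
from .params import MaterialParams, SolverConfig
from .vv_geometry import Mesh
from .weak_forms import (ElementKernel, field_indices,
                         follower_pressure_residual,
                         follower_pressure_tangent)

log = logging.getLogger("vasapf")


class NonConvergenceError(RuntimeError):
    """Newton failed; the caller may cut the time step."""


class SolverAbort(RuntimeError):
    """Time marching exhausted its step cuts."""


def dof_map(mesh: Mesh) -> dict:
    """Global DOF layout: node-major with per-node components
    (u_x, u_y[, u_z], c, phi, d)."""
    ndpn = mesh.dim + 3
    names = ["u_x", "u_y", "u_z"][: mesh.dim] + ["c", "phi", "d"]
    return {"n_nodes": mesh.n_nodes, "dofs_per_node": ndpn,
            "component_names": names, "n_dofs": mesh.n_nodes * ndpn}


@dataclass
class GaussState:
    alpha: np.ndarray      # (ne, ngp) growth scalar
    psi_max: np.ndarray    # (ne, ngp) crack-driver history, kPa

    def copy(self) -> "GaussState":
        return GaussState(self.alpha.copy(), self.psi_max.copy())


@dataclass
class Dirichlet:
    dofs: np.ndarray
    values: np.ndarray

    @staticmethod
    def combine(*parts: "Dirichlet") -> "Dirichlet":
        dofs = np.concatenate([p.dofs for p in parts])
        vals = np.concatenate([p.values for p in parts])
        # later entries win on duplicates
        _, idx = np.unique(dofs[::-1], return_index=True)
        keep = len(dofs) - 1 - idx
        return Dirichlet(dofs[keep], vals[keep])


class FEProblem:
    """Mesh + material + mode bound to the batched element kernel."""

    def __init__(self, mesh: Mesh, params: MaterialParams,
                 mode: str = "none"):
        self.mesh = mesh
        self.params = params
        self.mode = mode
        self.ndpn = mesh.dim + 3
        self.ndof = mesh.n_nodes * self.ndpn
        self.kern = ElementKernel(mesh.coords[mesh.elems], params, mode)
        ne, nen = mesh.elems.shape
        comp = np.arange(self.ndpn)
        self.edofs = (mesh.elems[:, :, None] * self.ndpn
                      + comp[None, None, :]).reshape(ne, -1)
        self._rows = np.repeat(self.edofs, self.edofs.shape[1], axis=1).ravel()
        self._cols = np.tile(self.edofs, (1, self.edofs.shape[1])).ravel()
        # field id per global dof (0 mech, 1 c, 2 phi, 3 d) for scaled norms
        iu, ic, iphi, idd = field_indices(mesh.dim)
        per_node = np.empty(self.ndpn, dtype=int)
        per_node[iu] = 0
        per_node[ic], per_node[iphi], per_node[idd] = 1, 2, 3
        self.dof_field = np.tile(per_node, mesh.n_nodes)
        self.elem_volume = self.kern.dV.sum(axis=1)

    # -- state helpers ------------------------------------------------------

    def zero_state(self) -> np.ndarray:
        return np.zeros(self.ndof)

    def zero_gauss(self) -> GaussState:
        ne = self.mesh.n_elems
        return GaussState(np.zeros((ne, self.kern.ngp)),
                          np.zeros((ne, self.kern.ngp)))

    def nodal(self, D: np.ndarray, comp: int) -> np.ndarray:
        return D.reshape(self.mesh.n_nodes, self.ndpn)[:, comp]

    def set_nodal(self, D: np.ndarray, comp: int, values) -> None:
        D.reshape(self.mesh.n_nodes, self.ndpn)[:, comp] = values

    def dofs_of(self, nodes: np.ndarray, comp: int) -> np.ndarray:
        return np.asarray(nodes, dtype=int) * self.ndpn + comp

    # -- assembly -----------------------------------------------------------

    def assemble(self, D: np.ndarray, phi_prev: np.ndarray,
                 d_prev: np.ndarray, gauss: GaussState,
                 dt: Optional[float], pressure: float,
                 bc: Dirichlet, with_tangent: bool = True):
        """Global residual, sparse tangent (Dirichlet rows/cols eliminated
        symmetrically) and trial Gauss states."""
        mesh = self.mesh
        Dn = D.reshape(mesh.n_nodes, self.ndpn)
        De = Dn[mesh.elems]
        pp, dp = phi_prev[mesh.elems], d_prev[mesh.elems]
        if with_tangent:
            Re, Ke, alpha, psimax = self.kern.tangent_fd(
                De, pp, dp, gauss.alpha, gauss.psi_max, dt)
        else:
            Re, alpha, psimax = self.kern.residual(
                De, pp, dp, gauss.alpha, gauss.psi_max, dt)
            Re = Re.reshape(mesh.n_elems, -1)
            Ke = None

        R = np.bincount(self.edofs.ravel(), weights=Re.ravel(),
                        minlength=self.ndof)

        rows_extra, cols_extra, vals_extra = [], [], []
        if pressure != 0.0 and mesh.lumen_facets is not None \
                and len(mesh.lumen_facets):
            fac = mesh.lumen_facets
            iu = slice(0, mesh.dim)
            u = Dn[:, iu]
            x = mesh.coords[fac] + u[fac]               # (nf, fn, dim)
            rf = follower_pressure_residual(x, pressure)
            fdofs = (fac[:, :, None] * self.ndpn
                     + np.arange(mesh.dim)[None, None, :]).reshape(
                         len(fac), -1)
            R += np.bincount(fdofs.ravel(), weights=rf.reshape(len(fac), -1)
                             .ravel(), minlength=self.ndof)
            if with_tangent and mesh.dim == 2:
                kf = follower_pressure_tangent(x, pressure)
                rows_extra.append(np.repeat(fdofs, 4, axis=1).ravel())
                cols_extra.append(np.tile(fdofs, (1, 4)).ravel())
                vals_extra.append(kf.ravel())

        if Ke is None:
            K = None
        else:
            rows = self._rows
            cols = self._cols
            vals = Ke.ravel()
            if rows_extra:
                rows = np.concatenate([rows] + rows_extra)
                cols = np.concatenate([cols] + cols_extra)
                vals = np.concatenate([vals] + vals_extra)
            constrained = np.zeros(self.ndof, dtype=bool)
            constrained[bc.dofs] = True
            keep = ~(constrained[rows] | constrained[cols])
            rows = np.concatenate([rows[keep], bc.dofs])
            cols = np.concatenate([cols[keep], bc.dofs])
            vals = np.concatenate([vals[keep], np.ones(len(bc.dofs))])
            K = sp.coo_matrix((vals, (rows, cols)),
                              shape=(self.ndof, self.ndof)).tocsr()
        R[bc.dofs] = 0.0
        return R, K, GaussState(alpha, psimax)

    # -- norms --------------------------------------------------------------

    def field_rms(self, R: np.ndarray) -> np.ndarray:
        """RMS of the residual per field (mech, c, phi, d)."""
        out = np.zeros(4)
        for f in range(4):
            mask = self.dof_field == f
            out[f] = np.sqrt(np.mean(R[mask] ** 2))
        return out


@dataclass
class NewtonResult:
    state: np.ndarray
    gauss: GaussState
    iterations: int
    norms: list


def newton_solve(problem: FEProblem, D: np.ndarray, phi_prev, d_prev,
                 gauss: GaussState, dt: Optional[float], pressure: float,
                 bc: Dirichlet, cfg: SolverConfig,
                 ref_scales: Optional[np.ndarray] = None) -> NewtonResult:
    """Monolithic Newton iteration to the scaled residual tolerance.

    The composite convergence norm normalizes each field's residual RMS by
    its value at the first iteration (the K_c = K_phi = K_d = 1 scalings
    are applied inside the residual), so ``newton_tol`` is relative.
    ``ref_scales`` (mutable, per field) carries the peak residual seen over
    a whole time march: it floors the normalization so that a nearly
    unloaded step (tiny dt after cuts) is judged against the problem's
    characteristic residual, not against its own vanishing imbalance.  On
    failure the input state is left untouched.
    """
    D = D.copy()
    D[bc.dofs] = bc.values

    def scaled(rms, scales):
        active = rms > 0
        if not np.any(active):
            return 0.0
        return float(np.sqrt(np.mean((rms[active] / scales[active]) ** 2)))

    try:
        R, K, gtrial = problem.assemble(D, phi_prev, d_prev, gauss,
                                        dt, pressure, bc)
    except (con.DegenerateDeformationError, con.StepSizeError) as exc:
        raise NonConvergenceError(f"element failure: {exc}") from exc
    rms = problem.field_rms(R)
    if np.max(rms) <= cfg.newton_abs_tol:
        return NewtonResult(D, gtrial, 0, [0.0])
    scales = np.maximum(rms, 1e-30)
    if ref_scales is not None:
        np.maximum(ref_scales, scales, out=ref_scales)
        scales = ref_scales.copy()
    norm = scaled(rms, scales)
    norms = [norm]

    for it in range(1, cfg.newton_max_iter + 1):
        dD = spla.spsolve(K, R)
        if not np.all(np.isfinite(dD)):
            raise NonConvergenceError(
                "linear solve produced non-finite update")
        # backtracking line search on the scaled residual norm.  Newton on
        # this stiff coupled system routinely overshoots transiently (the
        # mechanical residual can rise an order of magnitude on the first
        # update and still contract quadratically), so growth up to 10x is
        # tolerated; trial iterates that invert an element or grow worse
        # than that halve the step
        s, accepted = 1.0, False
        best = None
        for _ in range(12):
            D_try = D - s * dD
            try:
                R2, gt2 = _residual_only(problem, D_try, phi_prev, d_prev,
                                         gauss, dt, pressure, bc)
            except (con.DegenerateDeformationError, con.StepSizeError):
                s *= 0.5
                continue
            norm2 = scaled(problem.field_rms(R2),
                           np.maximum(scales, problem.field_rms(R2)))
            if best is None or norm2 < best[1]:
                best = (D_try, norm2)
            if norm2 < 10.0 * norm or norm2 <= cfg.newton_tol:
                accepted = True
                break
            s *= 0.5
        if best is None:
            raise NonConvergenceError(
                "element failure persists along the Newton direction")
        D = best[0]
        if not accepted:
            log.debug("newton: no acceptable step (norm %.3e -> %.3e)",
                      norm, best[1])
        try:
            R, K, gtrial = problem.assemble(D, phi_prev, d_prev, gauss,
                                            dt, pressure, bc)
        except (con.DegenerateDeformationError, con.StepSizeError) as exc:
            raise NonConvergenceError(f"element failure: {exc}") from exc
        rms = problem.field_rms(R)
        # normalize by the peak residual seen per field: a field that
        # starts converged must not dominate the relative norm
        scales = np.maximum(scales, rms)
        norm = scaled(rms, scales)
        norms.append(norm)
        if norm <= cfg.newton_tol:
            log.debug("newton converged: %d iterations, norm %.3e", it, norm)
            return NewtonResult(D, gtrial, it, norms)
        # the residual is non-smooth (tension/compression switch, history
        # kink, clamps) and the perturbation tangent has a noise floor in
        # regions of extreme volumetric stiffness: accept a small stalled
        # residual instead of cutting the step forever
        if (norm <= cfg.newton_stall_tol and len(norms) >= 4
                and norms[-4] <= 10.0 * norm):
            log.debug("newton stalled at norm %.3e after %d its: accepted",
                      norm, it)
            return NewtonResult(D, gtrial, it, norms)
    raise NonConvergenceError(
        f"no convergence in {cfg.newton_max_iter} iterations "
        f"(norm {norm:.3e})")


def _residual_only(problem, D, phi_prev, d_prev, gauss, dt, pressure, bc):
    R, _, gt = problem.assemble(D, phi_prev, d_prev, gauss, dt, pressure,
                                bc, with_tangent=False)
    return R, gt


@dataclass
class StepRecord:
    time: float
    dt: float
    iterations: int
    extrema: dict


@dataclass
class MarchResult:
    state: np.ndarray
    gauss: GaussState
    records: list
    time: float


def solve_steady_fields(problem: FEProblem, D: np.ndarray,
                        gauss: GaussState, bc: Dirichlet, cfg: SolverConfig,
                        free_fields=(0, 1, 2, 3),
                        pressure: float = 0.0) -> NewtonResult:
    """Steady solve with only the listed fields free (0=u, 1=c, 2=phi, 3=d);
    every DOF of the other fields is pinned at its current value."""
    pinned = np.flatnonzero(~np.isin(problem.dof_field,
                                     np.asarray(free_fields)))
    bc_all = Dirichlet.combine(Dirichlet(pinned, D[pinned]), bc)
    phi_prev = problem.nodal(D, problem.mesh.dim + 1).copy()
    d_prev = problem.nodal(D, problem.mesh.dim + 2).copy()
    return newton_solve(problem, D, phi_prev, d_prev, gauss, None,
                        pressure, bc_all, cfg)


def time_march(problem: FEProblem, D0: np.ndarray, gauss0: GaussState,
               bc: Dirichlet, cfg: SolverConfig, pressure_max: float,
               on_step: Optional[Callable] = None) -> MarchResult:
    """Pressure ramp followed by coupled backward-Euler evolution.

    Ramp stage: the phase fields are frozen (pinned at their initial
    values) while the follower pressure grows linearly to ``pressure_max``
    over ``load_ramp_steps`` solves.  Evolution stage: fixed ``dt`` cut by
    ``step_cut_factor`` on Newton failure (recovered gradually), damage
    clamped non-decreasing and both phase fields projected to [0, 1] after
    each accepted step.
    """
    dim = problem.mesh.dim
    iphi, idd = dim + 1, dim + 2
    D = D0.copy()
    gauss = gauss0.copy()
    records = []
    ref_scales = np.zeros(4)    # peak per-field residual over the march

    # pressure ramp with frozen phase fields; the increment is halved on
    # Newton failure (large inflation at p of order mu is strongly nonlinear)
    phid_dofs = np.flatnonzero(np.isin(problem.dof_field, (2, 3)))
    if pressure_max != 0.0:
        p = 0.0
        dp = pressure_max / max(cfg.load_ramp_steps, 1)
        cuts = 0
        while p < pressure_max - 1e-12 * abs(pressure_max):
            p_try = min(p + dp, pressure_max)
            bc_ramp = Dirichlet.combine(Dirichlet(phid_dofs, D[phid_dofs]),
                                        bc)
            phi_prev = problem.nodal(D, iphi).copy()
            d_prev = problem.nodal(D, idd).copy()
            try:
                res = newton_solve(problem, D, phi_prev, d_prev, gauss,
                                   None, p_try, bc_ramp, cfg,
                                   ref_scales=ref_scales)
            except NonConvergenceError as exc:
                cuts += 1
                if cuts > cfg.max_step_cuts:
                    raise SolverAbort(
                        f"pressure ramp failed at p={p_try:.3f} kPa "
                        f"({exc})") from exc
                dp *= cfg.step_cut_factor
                log.warning("ramp: newton failed at p=%.3f (%s); "
                            "increment cut to %.3f", p_try, exc, dp)
                continue
            D, gauss = res.state, res.gauss
            p = p_try
            log.info("ramp: p=%.3f/%.3f kPa, %d newton its", p,
                     pressure_max, res.iterations)

    t = 0.0
    dt = cfg.dt
    cuts_total = 0
    step = 0
    cooldown = 0    # clean steps to wait before growing dt again
    while t < cfg.t_end - 1e-12 * cfg.t_end:
        dt_step = min(dt, cfg.t_end - t)
        phi_prev = problem.nodal(D, iphi).copy()
        d_prev = problem.nodal(D, idd).copy()
        cuts = 0
        while True:
            try:
                res = newton_solve(problem, D, phi_prev, d_prev, gauss,
                                   dt_step, pressure_max, bc, cfg,
                                   ref_scales=ref_scales)
                break
            except NonConvergenceError as exc:
                cuts += 1
                cuts_total += 1
                if cuts > cfg.max_step_cuts:
                    raise SolverAbort(
                        f"step {step}: exceeded {cfg.max_step_cuts} step "
                        f"cuts at t={t:.3e} ({exc})") from exc
                dt_step *= cfg.step_cut_factor
                log.warning("step %d: newton failed (%s); dt cut to %.3e",
                            step, exc, dt_step)
        D, gauss = res.state, res.gauss
        # irreversibility clamp and [0,1] projection on accepted fields
        d_new = np.clip(np.maximum(problem.nodal(D, idd), d_prev), 0.0, 1.0)
        problem.set_nodal(D, idd, d_new)
        problem.set_nodal(D, iphi,
                          np.clip(problem.nodal(D, iphi), 0.0, 1.0))
        t += dt_step
        step += 1
        if cuts > 0:
            dt = dt_step
            cooldown = 3
        elif cooldown > 0:
            cooldown -= 1
        else:
            dt = min(dt * 1.25, cfg.dt)
        extrema = {
            "phi_max": float(problem.nodal(D, iphi).max()),
            "d_max": float(d_new.max()),
            "c_min": float(problem.nodal(D, dim).min()),
            "alpha_max": float(gauss.alpha.max()),
        }
        records.append(StepRecord(t, dt_step, res.iterations, extrema))
        log.info("step %d: t=%.4e dt=%.2e its=%d phi_max=%.3f d_max=%.3f "
                 "c_min=%.3f", step, t, dt_step, res.iterations,
                 extrema["phi_max"], extrema["d_max"], extrema["c_min"])
        if on_step is not None:
            on_step(step, t, D, gauss)
    return MarchResult(D, gauss, records, t)


def field_measure(problem: FEProblem, D: np.ndarray, comp: int,
                  threshold: float) -> float:
    """Reference-configuration measure of the region where the nodal field
    exceeds ``threshold`` (Gauss-point quadrature of the indicator)."""
    vals = problem.nodal(D, comp)[problem.mesh.elems]     # (ne, nen)
    at_gp = np.einsum("gn,en->eg", problem.kern.N, vals)
    return float(np.sum(problem.kern.dV * (at_gp > threshold)))


def save_checkpoint(path, problem: FEProblem, D: np.ndarray,
                    gauss: GaussState, time: float) -> None:
    dim = problem.mesh.dim
    Dn = D.reshape(problem.mesh.n_nodes, problem.ndpn)
    np.savez(path, u=Dn[:, :dim], c=Dn[:, dim], phi=Dn[:, dim + 1],
             dmg=Dn[:, dim + 2], alpha=gauss.alpha, psi_max=gauss.psi_max,
             time=np.array(time))


def load_checkpoint(path, problem: FEProblem):
    data = np.load(path)
    D = problem.zero_state()
    Dn = D.reshape(problem.mesh.n_nodes, problem.ndpn)
    dim = problem.mesh.dim
    Dn[:, :dim] = data["u"]
    Dn[:, dim] = data["c"]
    Dn[:, dim + 1] = data["phi"]
    Dn[:, dim + 2] = data["dmg"]
    gauss = GaussState(data["alpha"], data["psi_max"])
    return D, gauss, float(data["time"])
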