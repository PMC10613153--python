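"""The two disease scenarios end-to-end, with post-processing and output.

*Atherosclerosis*: the occluded VV starves the outer wall of nutrient; the
inflammation phase field grows wherever the concentration falls below the
threshold, driving isotropic overgrowth and an inward bulge.  The wall's
fracture resistance is effectively infinite and the damage field is pinned
at zero, so the wall thickens without rupture.

*Dissection*: the fracture resistance keeps its finite reference value and
a micro-injury — a small disc of fully damaged tissue at the VV occlusion
point — seeds the intramural hematoma.  Blood availability times rupture
openness (R_s c d) feeds the hematoma phase, whose confined swelling
pressurizes the aperture and drives the damage front like a hydraulic
fracture.

Both scenarios: maximum nutrient concentration (c = 1) on every surface in
contact with blood (lumen plus the unoccluded VV segments), follower
systolic pressure on the deformed lumen, tangential displacement fixed on
the sector cut faces, natural (zero-flux) conditions for both phase fields.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .constitutive import von_mises
from .params import (ConfigError, GeometryParams, MaterialParams,
                     SolverConfig, VVTreeParams, dataclass_from_dict)
from .solver import (Dirichlet, FEProblem, GaussState, MarchResult,
                     field_measure, solve_steady_fields, time_march)
from .vv_geometry import (Mesh, VVTree, apply_occlusion, build_annulus_mesh,
                          generate_vv_tree, mark_vv_supply_nodes,
                          occlusion_point, GeometryError)
from .vtkio import write_manifest, write_vtk
from .weak_forms import field_indices

log = logging.getLogger("vasapf")

MODES = ("atherosclerosis", "dissection")


@dataclass
class ScenarioConfig:
    mode: str = "atherosclerosis"
    geometry: GeometryParams = dc_field(default_factory=GeometryParams)
    vv_tree: VVTreeParams = dc_field(default_factory=VVTreeParams)
    material: MaterialParams = dc_field(default_factory=MaterialParams)
    solver: SolverConfig = dc_field(default_factory=SolverConfig)
    nucleus_radius: Optional[float] = None   # um; default 2*h_fine
    fracture_override: float = 1.0e9         # kPa, atherosclerosis mode
    tether_outer: bool = True                # clamp the adventitial surface
    output_dir: Optional[str] = None
    output_stride: int = 10
    n_path_samples: int = 200

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}")
        r0 = self.resolved_nucleus_radius()
        if r0 < self.geometry.h_fine:
            raise ConfigError("nucleus_radius must be at least h_fine")

    def resolved_nucleus_radius(self) -> float:
        return (2.0 * self.geometry.h_fine if self.nucleus_radius is None
                else self.nucleus_radius)


def scenario_preset(mode: str, level: str = "small",
                    seed: int = 0) -> ScenarioConfig:
    """Reference desk-scale configuration for a scenario.

    ``level`` selects the mesh resolution (``tiny`` ~2x10^2 elements,
    ``small`` ~10^3).  The damage length scale tracks the mesh (l = 2
    h_fine).  The evolution windows cover the early phase of each
    pathology: the hematoma run to t=1.5e-3 (rupture front visibly
    propagating), the inflammation run to t=4e-4 (lesion established;
    with the growth law 1+alpha=e^{k_g phi} and k_g=10, later times drive
    the confined swelling towards a structural fold).
    """
    from .vv_geometry import FIXTURE_GEOMS
    geom = GeometryParams(**FIXTURE_GEOMS[level])
    mat = MaterialParams(damage_length=2.0 * geom.h_fine)
    if mode == "dissection":
        sol = SolverConfig(dt=5e-5, t_end=1.5e-3, load_ramp_steps=8,
                           newton_max_iter=18, seed=seed)
    else:
        sol = SolverConfig(dt=2e-5, t_end=4e-4, load_ramp_steps=8,
                           newton_max_iter=18, seed=seed)
    vv = VVTreeParams(seed=seed)
    return ScenarioConfig(mode=mode, geometry=geom, vv_tree=vv,
                          material=mat, solver=sol)


_SECTIONS = {"geometry": GeometryParams, "vv_tree": VVTreeParams,
             "material": MaterialParams, "solver": SolverConfig}
_TOP_KEYS = {"mode", "nucleus_radius", "fracture_override", "output_dir",
             "output_stride", "n_path_samples", "seed"}


def config_from_dict(data: dict) -> ScenarioConfig:
    unknown = set(data) - _TOP_KEYS - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = dict(data.get(name, {}))
        if name == "vv_tree" and "seed" in data:
            section.setdefault("seed", data["seed"])
        if name == "solver" and "seed" in data:
            section.setdefault("seed", data["seed"])
        kwargs[name] = dataclass_from_dict(cls, section)
    for key in _TOP_KEYS - {"seed"}:
        if key in data:
            kwargs[key] = data[key]
    return ScenarioConfig(**kwargs)


def load_config(path) -> ScenarioConfig:
    """Read a TOML (or YAML) scenario configuration; unspecified keys take
    the reference defaults.  Pressures accept kPa numbers or "120 mmHg"."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        data = yaml.safe_load(text) or {}
    else:
        import tomllib
        data = tomllib.loads(text)
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# Scenario setup
# ---------------------------------------------------------------------------

def build_scenario_domain(config: ScenarioConfig):
    """Mesh, VV tree (occluded, supply nodes marked) and occlusion point."""
    geom = config.geometry
    mesh = build_annulus_mesh(geom, dim=2)
    root = np.array([geom.outer_radius, 0.0])
    direction = np.array([-1.0, 0.0])
    tree = generate_vv_tree(config.vv_tree, root, direction,
                            outer_radius=geom.outer_radius,
                            clip_radius=geom.outer_radius
                            - 0.5 * geom.wall_thickness)
    tree = apply_occlusion(tree, config.vv_tree.occlusion_arclength)
    mark_vv_supply_nodes(mesh, tree, tol=geom.h_fine)
    site = occlusion_point(config.vv_tree, root, direction)
    return mesh, tree, site


def apply_boundary_conditions(problem: FEProblem, mesh: Mesh,
                              config: ScenarioConfig,
                              nucleus_center=None) -> Dirichlet:
    """Dirichlet set for a scenario (the follower pressure is handled as a
    boundary residual, not here)."""
    dim = mesh.dim
    iu, ic, iphi, idd = field_indices(dim)
    lumen = mesh.node_sets["lumen"]
    if len(lumen) == 0:
        raise GeometryError("empty lumen node set")
    supply = mesh.node_sets.get("vv_supply", np.array([], int))
    c_nodes = np.unique(np.concatenate([lumen, supply]))
    parts = [Dirichlet(problem.dofs_of(c_nodes, ic),
                       np.ones(len(c_nodes)))]

    sym = mesh.node_sets.get("symmetry", np.array([], int))
    if len(sym):
        # half-annulus cut faces lie on the y-axis: tangential = u_x
        parts.append(Dirichlet(problem.dofs_of(sym, 0), np.zeros(len(sym))))
    outer = mesh.node_sets["outer"]
    if config.tether_outer:
        # adventitia tethered by perivascular tissue; a free neo-Hookean
        # tube of this geometry has an inflation limit pressure
        # mu*ln(r_out/r_in) ~ 15.3 kPa, below the systolic 16 kPa
        for comp in range(dim):
            parts.append(Dirichlet(problem.dofs_of(outer, comp),
                                   np.zeros(len(outer))))
    elif len(sym):
        pin = outer[np.argmin(np.abs(np.arctan2(
            mesh.coords[outer, 1], mesh.coords[outer, 0])))]
        parts.append(Dirichlet(problem.dofs_of(np.array([pin]), 1),
                               np.zeros(1)))
    else:
        # free full annulus: remove the three rigid-body modes by point pins
        ang = np.arctan2(mesh.coords[outer, 1], mesh.coords[outer, 0])
        n_back = outer[np.argmax(np.abs(ang))]        # near theta = pi
        n_front = outer[np.argmin(np.abs(ang))]       # near theta = 0
        parts.append(Dirichlet(
            np.array([problem.dofs_of(np.array([n_back]), 0)[0],
                      problem.dofs_of(np.array([n_back]), 1)[0],
                      problem.dofs_of(np.array([n_front]), 1)[0]]),
            np.zeros(3)))

    if config.mode == "atherosclerosis":
        # infinite-strength limit: the damage unknown is removed entirely
        all_nodes = np.arange(mesh.n_nodes)
        parts.append(Dirichlet(problem.dofs_of(all_nodes, idd),
                               np.zeros(mesh.n_nodes)))
    else:
        r0 = config.resolved_nucleus_radius()
        dist = np.linalg.norm(mesh.coords[:, :2]
                              - np.asarray(nucleus_center), axis=1)
        nucleus = np.flatnonzero(dist <= r0)
        parts.append(Dirichlet(problem.dofs_of(nucleus, idd),
                               np.ones(len(nucleus))))
    return Dirichlet.combine(*parts)


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def recover_nodal_stress(problem: FEProblem, D: np.ndarray,
                         gauss: GaussState) -> dict:
    """Volume-weighted patch averaging of Gauss-point stresses to nodes.
    Returns nodal sigma (n, 3, 3) and von Mises, plus per-cell means."""
    mesh = problem.mesh
    De = D.reshape(mesh.n_nodes, problem.ndpn)[mesh.elems]
    gf = problem.kern.gauss_fields(De, gauss.alpha)
    w = problem.kern.dV                                   # (ne, ngp)
    N = problem.kern.N                                    # (ngp, nen)
    wN = np.einsum("eg,gn->egn", w, N)
    num = np.zeros((mesh.n_nodes, 3, 3))
    den = np.zeros(mesh.n_nodes)
    np.add.at(num, mesh.elems,
              np.einsum("egn,egij->enij", wN, gf["sigma"]))
    np.add.at(den, mesh.elems, wN.sum(axis=1))
    sig_nodal = num / den[:, None, None]
    cell_mean = gf["sigma"].mean(axis=1)
    return {"sigma_nodal": sig_nodal,
            "von_mises_nodal": von_mises(sig_nodal),
            "sigma_cell": cell_mean,
            "von_mises_cell": von_mises(gf["sigma"]).max(axis=1),
            "alpha_cell": gauss.alpha.mean(axis=1),
            "J_cell": gf["J"].mean(axis=1)}


@dataclass
class PathProfile:
    """Field samples along a straight segment (point 1 -> point 2)."""
    s: np.ndarray           # arclength, um
    points: np.ndarray      # (n, 2)
    r: np.ndarray           # radius from the annulus center
    sigma_rr: np.ndarray
    sigma_tt: np.ndarray
    von_mises: np.ndarray
    u_r: np.ndarray
    c: np.ndarray
    phi: np.ndarray
    dmg: np.ndarray

    def to_csv(self, path) -> None:
        header = "s,r,sigma_rr,sigma_tt,von_mises,u_r,c,phi,dmg"
        data = np.column_stack([self.s, self.r, self.sigma_rr, self.sigma_tt,
                                self.von_mises, self.u_r, self.c, self.phi,
                                self.dmg])
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.10g")


class _PointLocator:
    """Inverse isoparametric map on a quad4 mesh via candidate search."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.X = mesh.coords[mesh.elems]                  # (ne, 4, 2)
        self.tree = cKDTree(self.X.mean(axis=1))
        self.radius = np.max(np.linalg.norm(
            self.X - self.X.mean(axis=1)[:, None, :], axis=2), axis=1)

    def locate(self, p: np.ndarray):
        k = min(16, self.mesh.n_elems)
        _, cand = self.tree.query(p, k=k)
        for e in np.atleast_1d(cand):
            xi = self._invert(self.X[e], p)
            if xi is not None:
                return int(e), xi
        return None

    @staticmethod
    def _invert(Xe, p, tol=1e-10):
        xi = np.zeros(2)
        ref = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
        for _ in range(30):
            terms = 1.0 + ref * xi
            N = terms[:, 0] * terms[:, 1] / 4.0
            dN = np.column_stack([ref[:, 0] * terms[:, 1],
                                  terms[:, 0] * ref[:, 1]]) / 4.0
            res = N @ Xe - p
            if np.linalg.norm(res) < tol * (1 + np.linalg.norm(p)):
                break
            J = dN.T @ Xe
            try:
                xi -= np.linalg.solve(J.T, res)
            except np.linalg.LinAlgError:
                return None
        if np.max(np.abs(xi)) <= 1.0 + 1e-6:
            return xi
        return None


def extract_path(problem: FEProblem, D: np.ndarray, gauss: GaussState,
                 point1, point2, n_samples: int = 200,
                 center=(0.0, 0.0)) -> PathProfile:
    """Interpolate the solution and the recovered nodal stresses along the
    segment point1 -> point2; cylindrical components about ``center``."""
    mesh = problem.mesh
    rec = recover_nodal_stress(problem, D, gauss)
    loc = _PointLocator(mesh)
    p1, p2 = np.asarray(point1, float), np.asarray(point2, float)
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = p1 + ts[:, None] * (p2 - p1)
    s = ts * np.linalg.norm(p2 - p1)
    Dn = D.reshape(mesh.n_nodes, problem.ndpn)
    dim = mesh.dim
    out = {k: np.empty(n_samples) for k in
           ("sigma_rr", "sigma_tt", "von_mises", "u_r", "c", "phi", "dmg",
            "r")}
    center = np.asarray(center, float)
    for i, p in enumerate(pts):
        hit = loc.locate(p)
        if hit is None:
            raise GeometryError(f"path sample {p} lies outside the mesh")
        e, xi = hit
        terms = 1.0 + np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) * xi
        N = terms[:, 0] * terms[:, 1] / 4.0
        nodes = mesh.elems[e]
        sig = np.einsum("n,nij->ij", N, rec["sigma_nodal"][nodes])
        u = N @ Dn[nodes, :dim]
        rel = p - center
        rr = np.linalg.norm(rel)
        er = rel / rr if rr > 0 else np.array([1.0, 0.0])
        et = np.array([-er[1], er[0]])
        e3r = np.append(er, 0.0)
        e3t = np.append(et, 0.0)
        out["r"][i] = rr
        out["sigma_rr"][i] = e3r @ sig @ e3r
        out["sigma_tt"][i] = e3t @ sig @ e3t
        out["von_mises"][i] = von_mises(sig)
        out["u_r"][i] = u @ er
        out["c"][i] = N @ Dn[nodes, dim]
        out["phi"][i] = N @ Dn[nodes, dim + 1]
        out["dmg"][i] = N @ Dn[nodes, dim + 2]
    return PathProfile(s, pts, out["r"], out["sigma_rr"], out["sigma_tt"],
                       out["von_mises"], out["u_r"], out["c"], out["phi"],
                       out["dmg"])


# ---------------------------------------------------------------------------
# Scenario driver
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    config: ScenarioConfig
    mesh: Mesh
    tree: VVTree
    problem: FEProblem
    state: np.ndarray
    gauss: GaussState
    march: MarchResult
    rupture_area: list          # measure of {d > 0.5} per accepted step
    path: PathProfile
    nucleus_center: np.ndarray
    outputs: list               # written files


def _write_state(problem, D, gauss, mesh, path, comment):
    dim = mesh.dim
    Dn = D.reshape(mesh.n_nodes, problem.ndpn)
    rec = recover_nodal_stress(problem, D, gauss)
    point_data = {"u": Dn[:, :dim], "c": Dn[:, dim], "phi": Dn[:, dim + 1],
                  "dmg": Dn[:, dim + 2]}
    cs = rec["sigma_cell"]
    cell_data = {"sigma_xx": cs[:, 0, 0], "sigma_yy": cs[:, 1, 1],
                 "sigma_xy": cs[:, 0, 1], "sigma_zz": cs[:, 2, 2],
                 "von_mises": von_mises(cs), "alpha": rec["alpha_cell"]}
    write_vtk(mesh, point_data, cell_data, path, comment)


def run_scenario(config: ScenarioConfig,
                 output_dir: Optional[str] = None) -> ScenarioResult:
    """Execute one scenario: initial nutrient solve, pressure ramp, coupled
    evolution, VTK series and radial path profile through the lesion."""
    outdir = output_dir or config.output_dir
    mesh, tree, site = build_scenario_domain(config)
    mat = config.material
    if config.mode == "atherosclerosis":
        mat = replace(mat, fracture_resistance=config.fracture_override)
    problem = FEProblem(mesh, mat, config.mode)
    bc = apply_boundary_conditions(problem, mesh, config,
                                   nucleus_center=site)

    D = problem.zero_state()
    gauss = problem.zero_gauss()
    D[bc.dofs] = bc.values

    # nutrient pre-solve on the undeformed, uninflamed wall
    res = solve_steady_fields(problem, D, gauss, bc, config.solver,
                              free_fields=(1,))
    D = res.state
    log.info("initial nutrient solve: %d iterations, c in [%.3f, %.3f]",
             res.iterations, problem.nodal(D, mesh.dim).min(),
             problem.nodal(D, mesh.dim).max())

    outputs = []
    manifest = []
    rupture_area = []
    idd = mesh.dim + 2

    def on_step(step, t, Dk, gk):
        rupture_area.append(field_measure(problem, Dk, idd, 0.5))
        if outdir and step % config.output_stride == 0:
            p = Path(outdir) / f"{config.mode}_{step:04d}.vtk"
            _write_state(problem, Dk, gk, mesh, p,
                         f"{config.mode} t={t:.6e}")
            outputs.append(str(p))
            manifest.append({"step": step, "time": t, "file": p.name})

    if outdir:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        p0 = Path(outdir) / f"{config.mode}_0000.vtk"
        _write_state(problem, D, gauss, mesh, p0, f"{config.mode} t=0")
        outputs.append(str(p0))
        manifest.append({"step": 0, "time": 0.0, "file": p0.name})

    march = time_march(problem, D, gauss, bc, config.solver,
                       mat.lumen_pressure, on_step=on_step)
    D, gauss = march.state, march.gauss

    geom = config.geometry
    eps_in = 1e-6 * geom.wall_thickness
    p1 = np.array([geom.inner_radius + eps_in, 0.0])
    p2 = np.array([geom.outer_radius - eps_in, 0.0])
    path = extract_path(problem, D, gauss, p1, p2, config.n_path_samples)

    if outdir:
        pf = Path(outdir) / f"{config.mode}_final.vtk"
        _write_state(problem, D, gauss, mesh, pf,
                     f"{config.mode} t={march.time:.6e}")
        outputs.append(str(pf))
        manifest.append({"step": len(march.records), "time": march.time,
                         "file": pf.name})
        write_manifest(Path(outdir) / f"{config.mode}.manifest.json",
                       manifest)
        csv = Path(outdir) / f"{config.mode}_path.csv"
        path.to_csv(csv)
        outputs.append(str(csv))

    return ScenarioResult(config, mesh, tree, problem, D, gauss, march,
                          rupture_area, path, site, outputs)


def lesion_region_stats(result: ScenarioResult) -> dict:
    """Mean cylindrical stresses in the lesion core and its tensile shell.

    The core is the region where phi exceeds half its current maximum (a
    relative threshold: saturated inflammation is mechanically unreachable
    under the exponential growth law, see docs/methods.md); the shell is
    the near-healthy tissue (phi < 0.1 max) within two interface widths of
    the lesion boundary.
    """
    problem, mesh = result.problem, result.mesh
    D = result.state
    dim = mesh.dim
    phi = problem.nodal(D, dim + 1)
    rec = recover_nodal_stress(problem, D, result.gauss)
    sig = rec["sigma_nodal"]
    ang = np.arctan2(mesh.coords[:, 1], mesh.coords[:, 0])
    er = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(len(ang))])
    et = np.column_stack([-np.sin(ang), np.cos(ang), np.zeros(len(ang))])
    srr = np.einsum("ni,nij,nj->n", er, sig, er)
    stt = np.einsum("ni,nij,nj->n", et, sig, et)
    pmax = phi.max()
    core = phi > 0.5 * pmax
    stats = {"phi_max": float(pmax),
             "core_mean_sigma_rr": float(srr[core].mean()),
             "core_mean_sigma_tt": float(stt[core].mean())}
    if core.any():
        tree = cKDTree(mesh.coords[core, :2])
        dist, _ = tree.query(mesh.coords[:, :2])
        shell = (phi < 0.1 * pmax) & \
            (dist < 2.0 * result.config.material.interface_param
             + result.config.geometry.h_fine)
        if shell.any():
            stats["shell_mean_sigma_tt"] = float(stt[shell].mean())
    return stats


def aperture_stats(result: ScenarioResult) -> dict:
    """Stress state inside the rupture aperture {d > 0.9} and at the front:
    mean pressure, von Mises ratio to the global maximum, and the distance
    from the global von Mises maximum to the damage front."""
    problem, mesh = result.problem, result.mesh
    D = result.state
    d = problem.nodal(D, mesh.dim + 2)
    rec = recover_nodal_stress(problem, D, result.gauss)
    sig, vm = rec["sigma_nodal"], rec["von_mises_nodal"]
    pressure = -np.trace(sig, axis1=1, axis2=2) / 3.0
    inside = d > 0.9
    vm_global = float(vm.max())
    n_peak = int(np.argmax(vm))
    front_nodes = np.flatnonzero(inside)
    dist_front = float(np.min(np.linalg.norm(
        mesh.coords[front_nodes, :2] - mesh.coords[n_peak, :2], axis=1))) \
        if len(front_nodes) else math.inf
    return {"aperture_mean_pressure": float(pressure[inside].mean()),
            "aperture_max_vm": float(vm[inside].max()),
            "global_max_vm": vm_global,
            "vm_peak_distance_to_front": dist_front,
            "aperture_nodes": int(inside.sum())}


def jump_indicator(path: PathProfile) -> float:
    """Largest radial-displacement jump between adjacent path samples —
    the discontinuity marker that separates dissection from pure
    thickening."""
    return float(np.max(np.abs(np.diff(path.u_r))))
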