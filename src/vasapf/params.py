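"""Parameter containers for geometry, vasa-vasorum tree, material and solver.

All lengths are micrometres, stresses kPa, and the evolution time is the
dimensionless pseudo-time of the phase-field equations.  Defaults reproduce
the coronary-artery reference configuration: a 1200 um lumen with a 400 um
wall, a four-level binary vasa-vasorum (VV) tree with an occlusion 30 um
down its trunk, a nearly incompressible neo-Hookean wall (mu = 30 kPa,
nu = 0.49) and an inter-layer fracture resistance of 100 kPa.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields


class ConfigError(ValueError):
    """Raised for out-of-range or unknown configuration values."""


MMHG_TO_KPA = 0.133322


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class GeometryParams:
    """Annular artery cross-section and mesh sizing.

    ``h_coarse``/``h_fine`` are target element edge lengths; the mesh is
    refined to ``h_fine`` inside the angular sector of half-angle
    ``refine_center_angle`` (widened by ``refine_arc_margin``) that contains
    the VV tree, centred on the positive x-axis.
    """

    inner_diameter: float = 1200.0   # um
    wall_thickness: float = 400.0    # um
    h_coarse: float = 20.0           # um
    h_fine: float = 2.0              # um
    refine_center_angle: float = 0.35   # rad, half-angle of refined sector
    refine_arc_margin: float = 40.0     # um, extra arc beyond the sector
    axial_length: float = 400.0         # um, 3D extrusion only
    sector_half_angle: float = math.pi / 2   # pi/2 = half annulus, pi = full

    def __post_init__(self) -> None:
        _check(self.inner_diameter > 0, "inner_diameter must be positive")
        _check(self.wall_thickness > 0, "wall_thickness must be positive")
        _check(0 < self.h_fine <= self.h_coarse,
               "need 0 < h_fine <= h_coarse")
        _check(self.sector_half_angle in (math.pi / 2, math.pi),
               "sector_half_angle must be pi/2 (half) or pi (full annulus)")

    @property
    def inner_radius(self) -> float:
        return 0.5 * self.inner_diameter

    @property
    def outer_radius(self) -> float:
        return 0.5 * self.inner_diameter + self.wall_thickness


@dataclass
class VVTreeParams:
    """Tree-fractal VV network: trunk plus three binary branching levels.

    ``branch_angles`` are the angles *between sibling branches*; each child
    leaves the parent axis at half that angle.  Only the angles carry the
    seeded stochastic jitter; lengths are deterministic.
    ``occlusion_arclength`` is measured along the trunk from its root on the
    outer wall.
    """

    trunk_length: float = 80.0                     # um (L0)
    length_ratios: tuple = (1.0, 1.0, 1.0)         # lambda_2..4
    branch_angles: tuple = (2 * math.pi / 3,) * 3  # gamma_2..4, rad
    occlusion_arclength: float = 30.0              # um (S)
    angle_jitter: float = 0.1                      # rad
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.trunk_length > 0, "trunk_length must be positive")
        _check(all(l > 0 for l in self.length_ratios),
               "length_ratios must be positive")
        _check(0.0 <= self.occlusion_arclength <= self.trunk_length,
               "occlusion_arclength must lie within the trunk")
        _check(self.angle_jitter >= 0, "angle_jitter must be non-negative")


@dataclass
class MaterialParams:
    """Pointwise material constants of the coupled wall model."""

    shear_modulus: float = 30.0        # mu, kPa
    poisson: float = 0.49              # nu
    growth_coupling: float = 10.0      # k_g, dimensionless
    consumption: float = 1.0e-2        # R_c, model units / T
    diff_max: float = 1.0e3            # D_max, um^2 / T
    diff_min: float = 1.0              # D_min, um^2 / T
    hematoma_rate: float = 100.0       # R_s
    barrier_height: float = 1.0        # M
    interface_param: float = 25.0      # eps, um (interface width scale)
    damage_length: float = 4.0         # l, um (2 x fine mesh size)
    damage_viscosity: float = 0.01     # eta_d
    residual_stiffness: float = 1.0e-4  # d_min
    fracture_resistance: float = 100.0  # G_f = Psi_cri / l, kPa
    lumen_pressure: float = 120 * MMHG_TO_KPA  # p_max, kPa (120 mmHg)
    nutrient_threshold: float = 0.25   # c_th (atherosclerosis source only)
    scale_c: float = 1.0               # K_c
    scale_phi: float = 1.0             # K_phi
    scale_d: float = 1.0               # K_d

    def __post_init__(self) -> None:
        _check(self.shear_modulus > 0, "shear_modulus must be positive")
        _check(0 < self.poisson < 0.5, "poisson must be in (0, 0.5)")
        _check(self.diff_min <= self.diff_max, "need diff_min <= diff_max")
        _check(0 < self.residual_stiffness < 1,
               "residual_stiffness must be in (0, 1)")
        _check(self.fracture_resistance > 0,
               "fracture_resistance must be positive")
        _check(self.damage_length > 0, "damage_length must be positive")
        _check(0 <= self.nutrient_threshold <= 1,
               "nutrient_threshold must be in [0, 1]")

    @property
    def kappa(self) -> float:
        """Volumetric penalty coefficient nu*mu/(1-2*nu), kPa."""
        return self.poisson * self.shear_modulus / (1 - 2 * self.poisson)

    @property
    def youngs_modulus(self) -> float:
        return 2 * self.shear_modulus * (1 + self.poisson)


@dataclass
class SolverConfig:
    """Monolithic Newton / backward-Euler controls."""

    dt: float = 1.0e-4              # pseudo-time step
    t_end: float = 4.0e-3
    newton_tol: float = 1.0e-8      # relative, on the scaled residual norm
    newton_abs_tol: float = 1.0e-11
    newton_stall_tol: float = 1.0e-5   # accept a stagnated iteration here
    newton_max_iter: int = 25
    step_cut_factor: float = 0.5
    max_step_cuts: int = 8
    load_ramp_steps: int = 4        # pressure ramp before evolution
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.dt > 0, "dt must be positive")
        _check(self.newton_tol > 0, "newton_tol must be positive")
        _check(self.newton_max_iter >= 1, "newton_max_iter must be >= 1")
        _check(0 < self.step_cut_factor < 1,
               "step_cut_factor must be in (0, 1)")


def parse_pressure(value) -> float:
    """Parse a pressure given in kPa (number) or as ``"<x> mmHg"``/``"<x> kPa"``."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    parts = text.split()
    try:
        if len(parts) == 1:
            return float(parts[0])
        num = float(parts[0])
    except ValueError as exc:
        raise ConfigError(f"cannot parse pressure {value!r}") from exc
    unit = parts[1].lower()
    if unit == "mmhg":
        return num * MMHG_TO_KPA
    if unit == "kpa":
        return num
    raise ConfigError(f"unknown pressure unit {parts[1]!r}")


def dataclass_from_dict(cls, data: dict):
    """Build a params dataclass from a plain dict, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) for {cls.__name__}: {sorted(unknown)}")
    clean = dict(data)
    for key in ("length_ratios", "branch_angles"):
        if key in clean and isinstance(clean[key], list):
            clean[key] = tuple(clean[key])
    if cls is MaterialParams and "lumen_pressure" in clean:
        clean["lumen_pressure"] = parse_pressure(clean["lumen_pressure"])
    return cls(**clean)
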