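"""Pointwise material laws of the coupled wall model.

Kinematics with multiplicative volumetric growth, the degraded nearly
incompressible neo-Hookean energy and Cauchy stress, the growth
internal-variable update, the double-well barrier and degradation
functions, diffusivity interpolation, and the three source terms
(hematoma, inflammation, damage).

Growth is isotropic, F = F_e F_g with F_g = (1+alpha) I, and the growth
scalar alpha follows d(alpha)/(1+alpha) = k_g d(phi): integrated exactly,
1 + alpha = exp(k_g * phi) for a point that inflames from phi = 0.

The volumetric energy is Psi_vol = kappa (J_e - 1)^2 + mu (J_e - 1 - log J_e)
with kappa = nu mu / (1 - 2 nu).  The mu-term is the standard compensated
log form: it vanishes to second order at J_e = 1 so the reference state is
stress free, is non-negative for all J_e > 0, and still provides the
log-type compression barrier.  Small-strain bulk modulus is 2 kappa + mu
(within 0.7% of the linear-elastic value at nu = 0.49).

All functions accept scalars or broadcastable numpy arrays; tensor-valued
arguments use trailing (3, 3) axes.  2D plane strain states are embedded in
3x3 tensors with unit total out-of-plane stretch, so the out-of-plane
elastic stretch is 1/(1+alpha).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MaterialParams

I3 = np.eye(3)


def det3(A: np.ndarray) -> np.ndarray:
    """Closed-form determinant of batched 3x3 matrices (faster than the
    LAPACK path for large batches of small matrices)."""
    return (A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2]
                            - A[..., 1, 2] * A[..., 2, 1])
            - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2]
                              - A[..., 1, 2] * A[..., 2, 0])
            + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1]
                              - A[..., 1, 1] * A[..., 2, 0]))


def det2(A: np.ndarray) -> np.ndarray:
    return (A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0])


def inv2(A: np.ndarray, det: np.ndarray) -> np.ndarray:
    out = np.empty_like(A)
    out[..., 0, 0] = A[..., 1, 1]
    out[..., 1, 1] = A[..., 0, 0]
    out[..., 0, 1] = -A[..., 0, 1]
    out[..., 1, 0] = -A[..., 1, 0]
    return out / det[..., None, None]


def inv3(A: np.ndarray, det: np.ndarray) -> np.ndarray:
    out = np.empty_like(A)
    for i in range(3):
        for j in range(3):
            # adjugate: cofactor of (j, i)
            r = [k for k in range(3) if k != j]
            c = [k for k in range(3) if k != i]
            minor = (A[..., r[0], c[0]] * A[..., r[1], c[1]]
                     - A[..., r[0], c[1]] * A[..., r[1], c[0]])
            out[..., i, j] = ((-1) ** (i + j)) * minor
    return out / det[..., None, None]


class DegenerateDeformationError(FloatingPointError):
    """det(I - grad u) <= 0 or J_e <= 0: the step must be cut."""


class StepSizeError(FloatingPointError):
    """k_g * dphi >= 1: the growth update has no admissible root."""


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

@dataclass
class Kinematics:
    F: np.ndarray        # (..., 3, 3) total deformation gradient
    F_g: np.ndarray      # growth part (1+alpha) I
    F_e: np.ndarray      # elastic part
    J_e: np.ndarray      # det F_e
    C_e_iso: np.ndarray  # J_e^(-2/3) F_e^T F_e
    I1_iso: np.ndarray   # tr C_e_iso
    alpha: np.ndarray


def kinematics(grad_u: np.ndarray, alpha) -> Kinematics:
    """Multiplicative-split kinematics from the *spatial* displacement
    gradient: F = (I - grad u)^-1, F_g = (1+alpha) I, F_e = F F_g^-1."""
    grad_u = np.asarray(grad_u, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    A = I3 - grad_u
    detA = np.linalg.det(A)
    if np.any(detA <= 0):
        raise DegenerateDeformationError("det(I - grad u) <= 0")
    F = np.linalg.inv(A)
    return kinematics_from_F(F, alpha)


def kinematics_from_F(F: np.ndarray, alpha) -> Kinematics:
    """Same split, starting from the total deformation gradient."""
    F = np.asarray(F, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    g = 1.0 + alpha
    F_g = g[..., None, None] * I3
    F_e = F / g[..., None, None]
    J_e = det3(F_e)
    if np.any(J_e <= 0):
        raise DegenerateDeformationError("J_e <= 0")
    C_e = np.einsum("...ji,...jk->...ik", F_e, F_e)
    C_e_iso = C_e * (J_e ** (-2.0 / 3.0))[..., None, None]
    I1_iso = np.einsum("...ii->...", C_e_iso)
    return Kinematics(F, F_g, F_e, J_e, C_e_iso, I1_iso, alpha)


def update_alpha(alpha_n, phi_n, phi_np1, k_g, k_max: float = 1.0 - 1e-9):
    """Backward-Euler root of the growth residual
    (alpha_{n+1} - alpha_n)/(1 + alpha_{n+1}) - k_g (phi_{n+1} - phi_n) = 0,

    closed form alpha_{n+1} = (alpha_n + k) / (1 - k), k = k_g * dphi.
    Returns (alpha_{n+1}, d alpha_{n+1} / d phi_{n+1}).  Raises
    StepSizeError when k >= 1 (time step too large for the growth rate).
    alpha is floored at 0 (growth cannot undo the reference volume)."""
    alpha_n = np.asarray(alpha_n, dtype=float)
    k = np.asarray(k_g * (np.asarray(phi_np1, float) - np.asarray(phi_n, float)))
    if np.any(k >= k_max):
        raise StepSizeError("k_g * dphi >= 1; cut the time step")
    alpha = (alpha_n + k) / (1.0 - k)
    dalpha_dphi = k_g * (1.0 + alpha_n) / (1.0 - k) ** 2
    floored = alpha < 0.0
    alpha = np.where(floored, 0.0, alpha)
    dalpha_dphi = np.where(floored, 0.0, dalpha_dphi)
    return alpha, dalpha_dphi


# ---------------------------------------------------------------------------
# Scalar laws
# ---------------------------------------------------------------------------

def degradation_g(d, d_min):
    """Stiffness degradation g(d) = (1-d)^2 + d*d_min (d clamped to [0,1])."""
    dc = np.clip(d, 0.0, 1.0)
    return (1.0 - dc) ** 2 + dc * d_min


def degradation_g_prime(d, d_min):
    dc = np.clip(d, 0.0, 1.0)
    return -2.0 * (1.0 - dc) + d_min


def tension_indicator(J_e):
    """H_J = 1 for J_e <= 1 (compression: volumetric energy undegraded and
    excluded from the crack driver), else 0."""
    return np.where(np.asarray(J_e, float) <= 1.0, 1.0, 0.0)


def barrier_f(phi, M):
    """Double-well barrier f = 16 M phi^2 (1-phi)^2 and its derivative.
    M = f(1/2) is the barrier height."""
    phi = np.asarray(phi, dtype=float)
    f = 16.0 * M * phi ** 2 * (1.0 - phi) ** 2
    df = 32.0 * M * phi * (1.0 - phi) * (1.0 - 2.0 * phi)
    return f, df


def diffusivity(phi, D_max, D_min):
    """Linear healthy/inflamed interpolation D = phi D_min + (1-phi) D_max."""
    p = np.clip(phi, 0.0, 1.0)
    return p * D_min + (1.0 - p) * D_max


def consumption_cutoff(c, c_eps: float = 0.1):
    """Smooth saturation multiplying the constant nutrient sink,
    1 - exp(-c/c_eps): consumption is proportional to availability when
    nutrient is scarce (vanishing as c -> 0, restoring below 0) and
    saturates at the uniform rate where nutrient is plentiful.  Keeps the
    concentration non-negative without the sharp reaction layer a
    one-sided cutoff would create."""
    x = np.clip(np.asarray(c, float) / c_eps, -50.0, None)
    return 1.0 - np.exp(-x)


def source_hematoma(c, d, R_s):
    """Hematoma driver S_phi = R_s c d: blood availability times rupture
    openness.  Inputs clamped to their physical range [0,1]."""
    return R_s * np.clip(c, 0.0, 1.0) * np.clip(d, 0.0, 1.0)


def source_inflammation(c, c_th, R_s):
    """Atherosclerosis driver: inflammation grows only below the nutrient
    threshold, ramping linearly to R_s at full starvation."""
    cc = np.clip(c, 0.0, 1.0)
    return R_s * np.maximum(c_th - cc, 0.0) / c_th


def source_damage(d, psi_max, G_f, d_min):
    """Crack driver S_d = -g'(d) Psi_max / G_f with G_f = Psi_cri / l."""
    return -degradation_g_prime(d, d_min) * np.asarray(psi_max, float) / G_f


def update_history(psi_drive_now, psi_max_prev):
    """Irreversibility history: running maximum of the crack driving
    energy (increasing during loading, frozen during unloading)."""
    return np.maximum(np.asarray(psi_drive_now, float),
                      np.asarray(psi_max_prev, float))


def crack_surface_density(d, grad_d, l):
    """Regularized crack surface density gamma = d^2/2 + (l^2/2)|grad d|^2.
    For the optimal 1D profile d = exp(-|x|/l) its line integral equals l."""
    grad_d = np.asarray(grad_d, dtype=float)
    return 0.5 * np.asarray(d, float) ** 2 \
        + 0.5 * l * l * np.sum(grad_d * grad_d, axis=-1)


# ---------------------------------------------------------------------------
# Energy and stress
# ---------------------------------------------------------------------------

@dataclass
class StressEnergy:
    psi_iso: np.ndarray
    psi_vol: np.ndarray
    psi_deg: np.ndarray     # degraded total energy density, kPa
    psi_drive: np.ndarray   # undegraded tensile part (crack driver), kPa
    sigma: np.ndarray       # Cauchy stress, (..., 3, 3) kPa
    g_d: np.ndarray
    H_J: np.ndarray


def _psi_vol_parts(J_e, mu, kap):
    psi = kap * (J_e - 1.0) ** 2 + mu * (J_e - 1.0 - np.log(J_e))
    dpsi = 2.0 * kap * (J_e - 1.0) + mu * (1.0 - 1.0 / J_e)
    return psi, dpsi


def energy_and_stress(kin: Kinematics, d, params: MaterialParams) -> StressEnergy:
    """Degraded energy density and Cauchy stress.

    Psi_deg = g(d) Psi_iso + [(1-H_J) g(d) + H_J] Psi_vol: the isochoric
    part is always degraded; the volumetric part only in tension (J_e > 1).
    The crack driver is the *undegraded* tensile part
    Psi_drive = Psi_iso + (1-H_J) Psi_vol.  Stress follows from
    sigma = (1/J_e) dPsi_deg/dF_e F_e^T evaluated analytically.
    """
    mu, kap = params.shear_modulus, params.kappa
    J_e = kin.J_e
    psi_iso = 0.5 * mu * (kin.I1_iso - 3.0)
    psi_vol, dpsi_vol = _psi_vol_parts(J_e, mu, kap)
    H = tension_indicator(J_e)
    g = degradation_g(d, params.residual_stiffness)
    g_vol = (1.0 - H) * g + H
    psi_deg = g * psi_iso + g_vol * psi_vol
    psi_drive = psi_iso + (1.0 - H) * psi_vol

    B_e = np.einsum("...ij,...kj->...ik", kin.F_e, kin.F_e)
    B_hat = B_e * (J_e ** (-2.0 / 3.0))[..., None, None]
    trB = np.einsum("...ii->...", B_hat)
    dev = B_hat - (trB / 3.0)[..., None, None] * I3
    sigma = (np.asarray(g)[..., None, None]
             * (mu / J_e)[..., None, None] * dev
             + (g_vol * dpsi_vol)[..., None, None] * I3)
    return StressEnergy(psi_iso, psi_vol, psi_deg, psi_drive, sigma,
                        np.asarray(g), H)


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Equivalent (von Mises) stress sqrt(3/2 dev(sigma):dev(sigma))."""
    sigma = np.asarray(sigma, dtype=float)
    tr = np.trace(sigma, axis1=-2, axis2=-1)
    dev = sigma - (tr / 3.0)[..., None, None] * I3
    return np.sqrt(1.5 * np.sum(dev * dev, axis=(-2, -1)))
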