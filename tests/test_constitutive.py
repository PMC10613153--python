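"""Pointwise laws: kinematics, growth update, energy/stress, sources."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vasapf.constitutive as con
from vasapf.params import MaterialParams


def random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    return Q * np.sign(np.linalg.det(Q))


class TestKinematics:
    def test_reference_state(self):
        kin = con.kinematics(np.zeros((3, 3)), 0.0)
        assert np.allclose(kin.F, np.eye(3))
        assert kin.J_e == pytest.approx(1.0)
        assert kin.I1_iso == pytest.approx(3.0)

    def test_spatial_gradient_inversion(self):
        kin = con.kinematics(np.diag([0.5, 0.0, 0.0]), 0.0)
        assert np.allclose(kin.F, np.diag([2.0, 1.0, 1.0]))

    def test_blocked_growth_compresses_elastically(self):
        kin = con.kinematics(np.zeros((3, 3)), 0.1)
        assert np.allclose(kin.F_e, np.eye(3) / 1.1)
        assert kin.J_e == pytest.approx(1.1 ** -3)

    def test_isochoric_tensor_has_unit_determinant(self, rng):
        for _ in range(10):
            gu = 0.3 * rng.standard_normal((3, 3))
            try:
                kin = con.kinematics(gu, float(rng.uniform(0, 0.5)))
            except con.DegenerateDeformationError:
                continue
            assert np.linalg.det(kin.C_e_iso) == pytest.approx(1.0,
                                                               abs=1e-10)

    def test_degenerate_deformation_raises(self):
        with pytest.raises(con.DegenerateDeformationError):
            con.kinematics(np.diag([2.0, 0.0, 0.0]), 0.0)


class TestGrowthUpdate:
    def test_no_phase_change_keeps_alpha(self):
        a, _ = con.update_alpha(0.3, 0.5, 0.5, 10.0)
        assert a == pytest.approx(0.3)

    def test_closed_form_root(self):
        a, _ = con.update_alpha(0.0, 0.0, 0.01, 10.0)
        assert a == pytest.approx(0.1 / 0.9)
        # the returned alpha satisfies the growth residual exactly
        k = 10.0 * 0.01
        assert (a - 0.0) / (1 + a) == pytest.approx(k)

    @pytest.mark.parametrize("k_g,n,tol", [(1.0, 1000, 0.01),
                                           (10.0, 1000, 0.06),
                                           (10.0, 20000, 0.01)])
    def test_continuous_limit_exponential(self, k_g, n, tol):
        """Sub-stepping phi: 0 -> 1 converges to 1+alpha = e^{k_g} at first
        order: the recursion gives exactly (1 - k_g/n)^{-n}."""
        alpha, phi = 0.0, 0.0
        for _ in range(n):
            alpha, _ = con.update_alpha(alpha, phi, phi + 1.0 / n, k_g)
            phi += 1.0 / n
        assert (1 + alpha) == pytest.approx((1 - k_g / n) ** -n, rel=1e-9)
        assert (1 + alpha) == pytest.approx(np.exp(k_g), rel=tol)

    def test_oversized_step_raises(self):
        with pytest.raises(con.StepSizeError):
            con.update_alpha(0.0, 0.0, 0.2, 10.0)

    def test_derivative_matches_finite_difference(self):
        h = 1e-7
        a0, da = con.update_alpha(0.2, 0.1, 0.15, 8.0)
        ap, _ = con.update_alpha(0.2, 0.1, 0.15 + h, 8.0)
        assert da == pytest.approx((ap - a0) / h, rel=1e-5)


class TestScalarLaws:
    @pytest.mark.parametrize("d,expect", [(0.0, 1.0), (1.0, 1e-4),
                                          (0.5, 0.25005)])
    def test_degradation_endpoints_and_midpoint(self, d, expect):
        assert con.degradation_g(d, 1e-4) == pytest.approx(expect)

    @pytest.mark.parametrize("je,expect", [(0.9, 1.0), (1.0, 1.0),
                                           (1.1, 0.0)])
    def test_tension_indicator(self, je, expect):
        assert con.tension_indicator(je) == expect

    def test_barrier_midpoint_is_local_max(self):
        M = 2.5
        f0, _ = con.barrier_f(0.0, M)
        f1, _ = con.barrier_f(1.0, M)
        fm, dfm = con.barrier_f(0.5, M)
        assert f0 == 0.0 and f1 == pytest.approx(0.0, abs=1e-14)
        assert fm == pytest.approx(M)
        assert dfm == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("phi,expect", [(0.0, 1e3), (1.0, 1.0),
                                            (0.5, (1e3 + 1) / 2)])
    def test_diffusivity_interpolation(self, phi, expect):
        assert con.diffusivity(phi, 1e3, 1.0) == pytest.approx(expect)

    @pytest.mark.parametrize("c,d,expect", [(0.0, 1.0, 0.0),
                                            (1.0, 0.0, 0.0),
                                            (1.0, 1.0, 100.0)])
    def test_hematoma_source_bilinear(self, c, d, expect):
        assert con.source_hematoma(c, d, 100.0) == pytest.approx(expect)

    @pytest.mark.parametrize("c,expect", [(0.6, 0.0), (0.0, 100.0),
                                          (0.25, 50.0)])
    def test_inflammation_ramp(self, c, expect):
        assert con.source_inflammation(c, 0.5, 100.0) == pytest.approx(
            expect)

    def test_damage_source_forced_values(self):
        d_min = 1e-4
        assert con.source_damage(0.3, 0.0, 100.0, d_min) == 0.0
        assert con.source_damage(0.0, 100.0, 100.0, d_min) == pytest.approx(
            2 - d_min)
        s1 = con.source_damage(0.4, 50.0, 100.0, d_min)
        s2 = con.source_damage(0.4, 80.0, 100.0, d_min)
        assert s2 > s1  # strictly increasing in the history variable

    def test_history_running_maximum(self):
        assert con.update_history(1.0, 3.0) == 3.0
        assert con.update_history(3.0, 1.0) == 3.0
        seq = [0.0, 2.0, 1.0, 5.0, 4.0]
        hist, out = 0.0, []
        for v in seq:
            hist = con.update_history(v, hist)
            out.append(hist)
        assert out == [0.0, 2.0, 2.0, 5.0, 5.0]

    def test_crack_surface_density_point_values(self):
        assert con.crack_surface_density(0.0, [0.0], 2.0) == 0.0
        assert con.crack_surface_density(1.0, [0.0], 2.0) == 0.5

    def test_optimal_profile_integrates_to_length_scale(self):
        # d(x) = exp(-|x|/l): integral of gamma over the line equals l
        l = 3.0
        x = np.linspace(-60, 60, 200001)
        d = np.exp(-np.abs(x) / l)
        gd = np.gradient(d, x)
        gamma = con.crack_surface_density(d, gd[:, None], l)
        assert np.trapezoid(gamma, x) == pytest.approx(l, rel=1e-3)


class TestEnergyStress:
    def test_stress_free_reference_any_damage(self, mat):
        kin = con.kinematics(np.zeros((3, 3)), 0.0)
        for d in (0.0, 0.37, 1.0):
            se = con.energy_and_stress(kin, d, mat)
            assert se.psi_iso == pytest.approx(0.0, abs=1e-14)
            assert se.psi_vol == pytest.approx(0.0, abs=1e-14)
            assert np.allclose(se.sigma, 0.0, atol=1e-12)

    def test_stress_matches_energy_finite_difference(self, mat, rng):
        """sigma = (1/J_e) dPsi_deg/dF_e F_e^T on 50 random states."""
        h = 1e-6
        for _ in range(50):
            gu = 0.1 * rng.standard_normal((3, 3))
            alpha = float(rng.uniform(0.0, 0.3))
            d = float(rng.uniform(0.0, 1.0))
            try:
                kin = con.kinematics(gu, alpha)
            except con.DegenerateDeformationError:
                continue

            def psi(Fe):
                Je = np.linalg.det(Fe)
                I1 = Je ** (-2 / 3) * np.trace(Fe.T @ Fe)
                p_iso = 0.5 * mat.shear_modulus * (I1 - 3)
                p_vol = mat.kappa * (Je - 1) ** 2 + mat.shear_modulus * (
                    Je - 1 - np.log(Je))
                H = 1.0 if Je <= 1 else 0.0
                g = con.degradation_g(d, mat.residual_stiffness)
                return g * p_iso + ((1 - H) * g + H) * p_vol

            P = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = kin.F_e.copy(), kin.F_e.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P[i, j] = (psi(Fp) - psi(Fm)) / (2 * h)
            sig_fd = P @ kin.F_e.T / kin.J_e
            se = con.energy_and_stress(kin, d, mat)
            err = np.linalg.norm(sig_fd - se.sigma) / max(
                np.linalg.norm(se.sigma), 1e-10)
            assert err < 1e-6

    def test_confined_growth_fully_damaged_is_hydrostatic(self, mat):
        """Fully ruptured, swollen and confined: deviatoric response scaled
        by the residual stiffness, volumetric response undegraded - the
        pressurized-hematoma aperture state."""
        kin = con.kinematics(np.zeros((3, 3)), 0.3)   # J_e < 1, confined
        se = con.energy_and_stress(kin, 1.0, mat)
        pressure = -np.trace(se.sigma) / 3
        assert pressure > 0
        assert con.von_mises(se.sigma) < 10 * mat.residual_stiffness * abs(
            pressure)

    def test_objectivity_under_rotations(self, mat, rng):
        gu = 0.1 * rng.standard_normal((3, 3))
        kin = con.kinematics(gu, 0.1)
        se = con.energy_and_stress(kin, 0.4, mat)
        for _ in range(20):
            Q = random_rotation(rng)
            kin_r = con.kinematics_from_F(Q @ kin.F, np.asarray(0.1))
            se_r = con.energy_and_stress(kin_r, 0.4, mat)
            assert se_r.psi_deg == pytest.approx(float(se.psi_deg),
                                                 abs=1e-10, rel=1e-10)

    def test_isochoric_energy_volumetric_invariance(self, mat, rng):
        gu = 0.1 * rng.standard_normal((3, 3))
        kin = con.kinematics(gu, 0.0)
        se = con.energy_and_stress(kin, 0.0, mat)
        for lam in (0.8, 1.25):
            kin_s = con.kinematics_from_F(lam * kin.F, np.asarray(0.0))
            se_s = con.energy_and_stress(kin_s, 0.0, mat)
            assert se_s.psi_iso == pytest.approx(float(se.psi_iso),
                                                 rel=1e-10)

    def test_free_growth_is_stress_free(self, mat):
        for alpha in (0.1, 0.5, 2.0):
            F = (1 + alpha) * np.eye(3)      # total deformation = growth
            kin = con.kinematics_from_F(F, np.asarray(alpha))
            se = con.energy_and_stress(kin, 0.0, mat)
            assert np.allclose(se.sigma, 0.0, atol=1e-10)
            assert np.allclose(kin.F_e, np.eye(3))

    def test_small_strain_limit_matches_linear_elasticity(self, mat, rng):
        lam = 2 * mat.shear_modulus * mat.poisson / (1 - 2 * mat.poisson)
        for _ in range(10):
            gu = 1e-4 * rng.standard_normal((3, 3))
            kin = con.kinematics(gu, 0.0)
            se = con.energy_and_stress(kin, 0.0, mat)
            eps = 0.5 * (gu + gu.T)
            sig_lin = lam * np.trace(eps) * np.eye(3) \
                + 2 * mat.shear_modulus * eps
            assert np.linalg.norm(se.sigma - sig_lin) <= \
                0.01 * np.linalg.norm(sig_lin)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(d1=st.floats(0, 1), d2=st.floats(0, 1),
           s=st.floats(0.01, 0.25))
    def test_degraded_energy_monotone_in_damage(self, d1, d2, s):
        mat = MaterialParams()
        kin = con.kinematics(np.diag([s, 0.0, 0.0]), 0.0)  # tensile state
        lo, hi = sorted((d1, d2))
        e_lo = con.energy_and_stress(kin, lo, mat).psi_deg
        e_hi = con.energy_and_stress(kin, hi, mat).psi_deg
        assert e_hi <= e_lo + 1e-12


class TestVonMises:
    def test_hydrostatic_is_zero(self):
        assert con.von_mises(-7.3 * np.eye(3)) == pytest.approx(0.0,
                                                                abs=1e-12)

    def test_uniaxial(self):
        assert con.von_mises(np.diag([5.0, 0, 0])) == pytest.approx(5.0)

    def test_pure_shear(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 2.0
        assert con.von_mises(s) == pytest.approx(np.sqrt(3) * 2.0)
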