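"""Constitutive laws: closed-form checks and tangent consistency."""

import numpy as np
import pytest
from scipy.optimize import brentq

from aaaprobe.constitutive import (HGOWall, HGOWallParams, LinearWall,
                                   LinearWallParams, MembraneState,
                                   TissueParams, hgo_membrane_response,
                                   linear_membrane_response,
                                   neo_hookean_energy, neo_hookean_pk1,
                                   neo_hookean_stress)
from aaaprobe.errors import (ElementInversionError, MaterialDefinitionError,
                             StretchRangeError)


def hgo_energy_oracle(lam, p):
    """Independent evaluation of the membrane strain energy at λ_z = 1,
    incompressible thickness stretch 1/λ (used only to differentiate
    numerically)."""
    lam2 = lam * lam
    I1 = lam2 + 1.0 + 1.0 / lam2
    th = np.deg2rad(p.theta_deg)
    I4 = lam2 * np.cos(th) ** 2 + np.sin(th) ** 2
    E = p.kappa * (I1 - 3.0) + (1.0 - 3.0 * p.kappa) * (I4 - 1.0)
    fib = (p.k1 / p.k2) * (np.exp(p.k2 * E * E) - 1.0) if E > 0 else 0.0
    return p.C10 * (I1 - 3.0) + fib


class TestHGOMembrane:
    def test_reference_is_stress_free(self, hgo_params):
        sig, _ = hgo_membrane_response(1.0, 1.0, hgo_params)
        assert sig == 0.0

    def test_isotropic_dispersion_limit_ignores_fiber_angle(self):
        p0 = HGOWallParams(kappa=1 / 3, theta_deg=0.0)
        p90 = HGOWallParams(kappa=1 / 3, theta_deg=90.0)
        s0, _ = hgo_membrane_response(1.05, 1.0, p0)
        s90, _ = hgo_membrane_response(1.05, 1.0, p90)
        assert s0 == pytest.approx(s90, rel=1e-14)

    @pytest.mark.parametrize("lam", [1.01, 1.05, 1.10])
    def test_stress_matches_energy_derivative(self, lam, hgo_params):
        """σ_circ = λ dΨ/dλ, central difference of the independent energy."""
        h = 1e-6
        sig_fd = lam * (hgo_energy_oracle(lam + h, hgo_params)
                        - hgo_energy_oracle(lam - h, hgo_params)) / (2 * h)
        sig, _ = hgo_membrane_response(lam, 1.0, hgo_params)
        assert sig == pytest.approx(sig_fd, rel=1e-7)

    def test_tension_only_fibers_matrix_response_in_compression(self):
        p = HGOWallParams(kappa=0.0)
        matrix_only = HGOWallParams(kappa=0.0, k1=0.0)
        for lam in (0.9, 0.95, 0.99):
            s_full, _ = hgo_membrane_response(lam, 1.0, p)
            s_mat, _ = hgo_membrane_response(lam, 1.0, matrix_only)
            assert s_full == pytest.approx(s_mat, rel=1e-14)

    def test_convex_stiffening_along_loading_path(self, hgo_params):
        """J-shaped response: the tangent grows monotonically on [1, 1.15]."""
        lam = np.linspace(1.0, 1.15, 80)
        _, dsig = hgo_membrane_response(lam, 1.0, hgo_params)
        assert np.all(np.diff(dsig) > 0)

    def test_extreme_stretch_signals_range_error(self, hgo_params):
        with pytest.raises(StretchRangeError):
            hgo_membrane_response(2.5, 1.0, hgo_params)
        with pytest.raises(StretchRangeError):
            hgo_membrane_response(-0.5, 1.0, hgo_params)

    def test_parameter_invariants_enforced(self):
        with pytest.raises(MaterialDefinitionError):
            HGOWallParams(kappa=0.5)
        with pytest.raises(MaterialDefinitionError):
            HGOWallParams(C10=-1.0)

    def test_k1_unit_conversion(self):
        p = HGOWallParams.from_k1_mpa(100.9, 4.07, 165.55, 0.16, 48.4)
        assert p.k1 == pytest.approx(4070.0)


class TestLinearMembrane:
    def test_zero_strain_zero_stress(self):
        sig, _ = linear_membrane_response(0.0)
        assert sig == 0.0

    def test_linearity(self):
        s1, _ = linear_membrane_response(0.013)
        s2, _ = linear_membrane_response(0.026)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-14)

    def test_effective_hoop_modulus(self):
        """C_eff = E_θ/(1 − ν_θz ν_zθ) with ν_zθ from orthotropic
        symmetry; direct arithmetic oracle."""
        p = LinearWallParams()
        nu_zt = 0.44 * 3580.0 / 1110.0
        c_eff = 1110.0 / (1.0 - 0.44 * nu_zt)
        sig, mod = linear_membrane_response(0.01, p)
        assert mod == pytest.approx(c_eff, rel=1e-12)
        assert sig == pytest.approx(0.01 * c_eff, rel=1e-12)

    def test_non_positive_definite_reduction_rejected(self):
        # nu^2 * E_z/E_theta >= 1 breaks the reduction
        with pytest.raises(MaterialDefinitionError):
            LinearWallParams(E_theta=100.0, E_z=3000.0, nu=0.45)


class TestNeoHookeanTissue:
    def test_identity_and_rotation_are_stress_free(self, soft_tissue):
        assert np.allclose(
            neo_hookean_stress(np.eye(2), soft_tissue, tangent=False), 0.0)
        th = 0.8
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert np.allclose(
            neo_hookean_stress(R, soft_tissue, tangent=False), 0.0,
            atol=1e-12)

    def test_plane_strain_uniaxial_closed_form(self, soft_tissue):
        """Incompressible plane-strain uniaxial tension, lateral traction
        free: σ = μ(λ² − λ⁻²), here within penalty error."""
        lam = 1.2
        f = lambda l2: neo_hookean_stress(
            np.diag([lam, l2]), soft_tissue, tangent=False)[1, 1]
        l2 = brentq(f, 0.5, 1.1, xtol=1e-14)
        sig = neo_hookean_stress(np.diag([lam, l2]), soft_tissue,
                                 tangent=False)
        exact = soft_tissue.mu * (lam ** 2 - lam ** -2)
        assert sig[0, 0] == pytest.approx(exact, rel=1e-2)
        assert abs(lam * l2 - 1.0) < 1e-3    # near-incompressible

    def test_inverted_state_signals(self, soft_tissue):
        with pytest.raises(ElementInversionError):
            neo_hookean_pk1(np.diag([1.0, -0.5]), soft_tissue)

    def test_bulk_penalty_floor_enforced(self):
        with pytest.raises(MaterialDefinitionError):
            TissueParams(mu=5.0, bulk_penalty=10.0)


class TestTangentConsistency:
    """Analytic tangents vs central finite differences of the stress,
    100 random admissible states per material, relative error < 1e-5."""

    N = 100
    H = 1e-6

    def test_hgo_tangent(self, hgo_params):
        rng = np.random.default_rng(7)
        lam = rng.uniform(0.92, 1.12, self.N)
        sig_p, _ = hgo_membrane_response(lam + self.H, 1.0, hgo_params)
        sig_m, _ = hgo_membrane_response(lam - self.H, 1.0, hgo_params)
        _, dsig = hgo_membrane_response(lam, 1.0, hgo_params)
        fd = (sig_p - sig_m) / (2 * self.H)
        scale = np.maximum(np.abs(fd), 1.0)
        assert np.max(np.abs(dsig - fd) / scale) < 1e-5

    def test_linear_tangent(self):
        rng = np.random.default_rng(8)
        eps = rng.uniform(-0.05, 0.05, self.N)
        sig_p, _ = linear_membrane_response(eps + self.H)
        sig_m, _ = linear_membrane_response(eps - self.H)
        _, mod = linear_membrane_response(eps)
        fd = (sig_p - sig_m) / (2 * self.H)
        assert np.max(np.abs(mod - fd) / np.abs(fd)) < 1e-5

    def test_tissue_stress_and_tangent(self, soft_tissue):
        rng = np.random.default_rng(9)
        n_ok = 0
        while n_ok < self.N:
            F = np.eye(2) + 0.25 * rng.standard_normal((2, 2))
            if np.linalg.det(F) < 0.4:
                continue
            n_ok += 1
            P, A = neo_hookean_pk1(F, soft_tissue)
            Pfd = np.zeros((2, 2))
            Afd = np.zeros((2, 2, 2, 2))
            for k in range(2):
                for L in range(2):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[k, L] += self.H
                    Fm[k, L] -= self.H
                    Pfd[k, L] = (neo_hookean_energy(Fp, soft_tissue)
                                 - neo_hookean_energy(Fm, soft_tissue)
                                 ) / (2 * self.H)
                    Afd[:, :, k, L] = (
                        neo_hookean_pk1(Fp, soft_tissue, tangent=False)
                        - neo_hookean_pk1(Fm, soft_tissue, tangent=False)
                    ) / (2 * self.H)
            assert np.max(np.abs(P - Pfd)) / np.max(np.abs(P)) < 1e-5
            assert np.max(np.abs(A - Afd)) / np.max(np.abs(A)) < 1e-5


class TestWallAdapters:
    def test_membrane_state_thickness(self):
        st = MembraneState.from_stretch(1.1, t_ref=2.0)
        assert st.thickness_current == pytest.approx(2.0 / 1.1)

    def test_slack_wall_sheds_compression(self):
        for wall in (HGOWall(), LinearWall()):
            n_taut, _ = wall.tension(1.05)
            n_slack, _ = wall.tension(0.95)
            n_elastic, _ = type(wall)(compression="elastic").tension(0.95)
            assert n_taut > 0
            assert n_elastic < 0
            assert abs(n_slack) <= 0.06 * abs(n_elastic)

    def test_slack_and_elastic_agree_in_tension(self):
        for cls in (HGOWall, LinearWall):
            lam = np.linspace(1.0, 1.1, 10)
            n_s, dn_s = cls().tension(lam)
            n_e, dn_e = cls(compression="elastic").tension(lam)
            assert np.allclose(n_s, n_e)
            assert np.allclose(dn_s, dn_e)

    def test_ring_equilibrium_stress_scale(self):
        """Laplace law scale check: at P=13.3 kPa, r≈25 mm, t=2 mm the
        equilibrium hoop stress is ≈ P·r/t ≈ 166 kPa (small-strain)."""
        wall = HGOWall()
        f = lambda lam: 13.3 * 25.0 * lam - wall.tension(lam)[0]
        lam = brentq(f, 1.0001, 1.4)
        sig = wall.stress(lam)[0]
        assert sig == pytest.approx(13.3 * 25.0 * lam ** 2 / 2.0, rel=1e-10)
        assert 140.0 < sig < 210.0
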