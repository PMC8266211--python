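"""Constitutive laws: kinematics, energies, stresses, and their consistency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from valvemech.casedata import CALIBRATED_PARAMS
from valvemech.constitutive import (
    LAWS,
    DeformationState,
    MaterialParams,
    cauchy_from_piola,
    cauchy_stress,
    deformation_from_stretches,
    fiber_strain,
    fiber_stress,
    piola_from_cauchy,
    planar_biaxial_stress,
    strain_energy,
    stress_coefficients,
)

E1 = np.array([1.0, 0.0, 0.0])


def random_incompressible_state(rng, spread=0.15):
    """Random F with det(F)=1 and a random unit fiber direction."""
    F = np.eye(3) + spread * rng.standard_normal((3, 3))
    d = np.linalg.det(F)
    if d < 0:
        F[:, 0] *= -1
        d = -d
    F /= d ** (1.0 / 3.0)
    f0 = rng.standard_normal(3)
    f0 /= np.linalg.norm(f0)
    return DeformationState(F=F, f0=f0)


class TestKinematics:
    def test_identity_state(self):
        st_ = deformation_from_stretches(1.0, 1.0)
        assert np.allclose(st_.F, np.eye(3))
        assert st_.I1 == pytest.approx(3.0)
        assert st_.I4 == pytest.approx(1.0)
        assert st_.J == pytest.approx(1.0)

    def test_fiber_stretch_forces_i4(self):
        st_ = deformation_from_stretches(1.2, 1.0)
        assert st_.I4 == pytest.approx(1.44)
        assert st_.J == pytest.approx(1.0, abs=1e-14)

    def test_invariants_match_explicit_matrices(self):
        l1, l2 = 1.1, 1.05
        st_ = deformation_from_stretches(l1, l2)
        F = np.diag([l1, l2, 1 / (l1 * l2)])
        C = F.T @ F
        assert st_.I1 == pytest.approx(np.trace(C), rel=1e-14)
        assert st_.I1 == pytest.approx(l1**2 + l2**2 + 1 / (l1 * l2) ** 2)
        assert np.allclose(st_.B, F @ F.T)
        assert np.allclose(st_.E, 0.5 * (C - np.eye(3)))

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (1.0, -0.5)])
    def test_nonpositive_stretch_rejected(self, bad):
        with pytest.raises(ValueError):
            deformation_from_stretches(*bad)


class TestMaterialParams:
    def test_wrong_fields_rejected(self):
        with pytest.raises(ValueError):
            MaterialParams("W1", {"C10": 1.0})
        with pytest.raises(ValueError):
            MaterialParams("W9", {})
        with pytest.raises(ValueError):
            MaterialParams.w3(C1=-1.0, a=1.0, b=1.0)

    def test_json_round_trip(self):
        p = CALIBRATED_PARAMS["W2"]
        q = MaterialParams.from_json(p.to_json())
        assert q == p


class TestStrainEnergy:
    @pytest.mark.parametrize("law", LAWS)
    def test_zero_at_identity(self, law):
        st_ = deformation_from_stretches(1.0, 1.0)
        assert strain_energy(CALIBRATED_PARAMS[law], st_) == pytest.approx(0.0, abs=1e-14)

    def test_w3_term_by_term(self):
        # independent evaluation of each W3 term at an equibiaxial state
        C1, a, b = 19.59, 12.94, 77.79
        p = MaterialParams.w3(C1=C1, a=a, b=b)
        lam = 1.05
        st_ = deformation_from_stretches(lam, lam)
        I1 = 2 * lam**2 + 1 / lam**4
        I4 = lam**2
        expected = C1 * (I1 - 3) + a / (2 * b) * (math.exp(b * (I4 - 1) ** 2) - 1)
        assert strain_energy(p, st_) == pytest.approx(expected, rel=1e-12)

    def test_w2_reduces_to_isotropic_when_fiber_unstretched(self):
        p = CALIBRATED_PARAMS["W2"]
        st_ = deformation_from_stretches(1.0, 1.2)  # I4 = 1, I1 > 3
        I1 = st_.I1
        mu, c0, c1 = p["mu"], p["c0"], p["c1"]
        expected = mu * (I1 - 3) + c0 * (math.exp(c1 * (I1 - 3) ** 2) - 1)
        assert strain_energy(p, st_) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("law", LAWS)
    def test_frame_indifference(self, law):
        from scipy.stats import special_ortho_group

        rng = np.random.default_rng(7)
        p = CALIBRATED_PARAMS[law]
        st_ = random_incompressible_state(rng)
        W0 = strain_energy(p, st_)
        for Q in special_ortho_group.rvs(3, size=50, random_state=11):
            WQ = strain_energy(p, DeformationState(F=Q @ st_.F, f0=st_.f0))
            assert WQ == pytest.approx(W0, rel=1e-10)


class TestCauchyStress:
    @pytest.mark.parametrize("law", LAWS)
    def test_stress_free_reference(self, law):
        p = CALIBRATED_PARAMS[law]
        st_ = deformation_from_stretches(1.0, 1.0)
        alpha, _ = stress_coefficients(p, 3.0, 1.0)
        s = cauchy_stress(p, st_, p=float(alpha))
        assert np.allclose(s.sigma, 0.0, atol=1e-12)

    def test_reference_pressure_closed_forms(self):
        # p balancing the isotropic term at identity: 2*C10*C01, 2*mu, 2*C1
        expect = {
            "W1": 2 * 1.21 * 7.99,
            "W2": 2 * 1.18,
            "W3": 2 * 19.59,
        }
        for law, pref in expect.items():
            alpha, _ = stress_coefficients(CALIBRATED_PARAMS[law], 3.0, 1.0)
            assert float(alpha) == pytest.approx(pref, rel=1e-12)

    @pytest.mark.parametrize("law", LAWS)
    def test_finite_difference_hyperelastic_consistency(self, law):
        """Constitutive Cauchy stress equals J^-1 (dW/dF) F^T by central FD."""
        rng = np.random.default_rng(3)
        p = CALIBRATED_PARAMS[law]
        h = 1e-6
        for _ in range(20):
            st_ = random_incompressible_state(rng, spread=0.08)
            P_fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = st_.F.copy(), st_.F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    Wp = strain_energy(p, DeformationState(F=Fp, f0=st_.f0))
                    Wm = strain_energy(p, DeformationState(F=Fm, f0=st_.f0))
                    P_fd[i, j] = (Wp - Wm) / (2 * h)
            sigma_fd = P_fd @ st_.F.T / st_.J
            sigma = cauchy_stress(p, st_, p=0.0).sigma
            scale = max(np.abs(sigma).max(), 1.0)
            assert np.abs(sigma - sigma_fd).max() / scale < 1e-5


class TestPiolaConversion:
    def test_identity_and_diagonal_examples(self):
        st_ = DeformationState(F=np.eye(3), f0=E1)
        sig = np.diag([3.0, 2.0, 1.0])
        assert np.allclose(piola_from_cauchy(st_, sig), sig)
        st2 = DeformationState(F=np.diag([2.0, 1.0, 0.5]), f0=E1)
        P = piola_from_cauchy(st2, np.eye(3))
        assert np.allclose(P, np.diag([0.5, 1.0, 2.0]))

    def test_round_trip_random(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            st_ = random_incompressible_state(rng)
            A = rng.standard_normal((3, 3))
            sig = A @ A.T  # SPD
            back = cauchy_from_piola(st_, piola_from_cauchy(st_, sig))
            assert np.abs(back - sig).max() < 1e-12 * max(1.0, np.abs(sig).max())

    def test_singular_f_rejected(self):
        st_ = DeformationState(F=np.diag([1.0, 1.0, 0.0]), f0=E1)
        with pytest.raises(ValueError):
            piola_from_cauchy(st_, np.eye(3))


def bisect_plane_stress_pressure(params, l1, l2, lo=-1e6, hi=1e6, tol=1e-12):
    """Independent oracle: find p such that sigma33(p) = 0 by bisection."""
    st_ = deformation_from_stretches(l1, l2)

    def s33(p):
        return cauchy_stress(params, st_, p).sigma[2, 2]

    a, b = lo, hi
    assert s33(a) * s33(b) < 0
    for _ in range(200):
        m = 0.5 * (a + b)
        if s33(a) * s33(m) <= 0:
            b = m
        else:
            a = m
        if b - a < tol:
            break
    return 0.5 * (a + b)


class TestPlanarBiaxial:
    @pytest.mark.parametrize("law", LAWS)
    def test_zero_at_reference(self, law):
        s11, s22 = planar_biaxial_stress(CALIBRATED_PARAMS[law], 1.0, 1.0)
        assert s11 == pytest.approx(0.0, abs=1e-12)
        assert s22 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("law", LAWS)
    @pytest.mark.parametrize("stretches", [(1.1, 1.05), (1.05, 1.15), (1.02, 1.3)])
    def test_matches_bisection_oracle(self, law, stretches):
        p = CALIBRATED_PARAMS[law]
        l1, l2 = stretches
        p_star = bisect_plane_stress_pressure(p, l1, l2)
        st_ = deformation_from_stretches(l1, l2)
        sig = cauchy_stress(p, st_, p_star).sigma
        s11, s22 = planar_biaxial_stress(p, l1, l2)
        assert abs(sig[2, 2]) < 1e-6  # bisection residual
        assert s11 == pytest.approx(sig[0, 0], rel=1e-6, abs=1e-6)
        assert s22 == pytest.approx(sig[1, 1], rel=1e-6, abs=1e-6)

    @pytest.mark.parametrize("law", LAWS)
    def test_plane_stress_residual_analytic(self, law):
        """|sigma33| < 1e-10 kPa when p is eliminated analytically."""
        p = CALIBRATED_PARAMS[law]
        for l1, l2 in [(1.05, 1.05), (1.1, 1.02), (1.01, 1.2)]:
            st_ = deformation_from_stretches(l1, l2)
            alpha, _ = stress_coefficients(p, st_.I1, st_.I4)
            l3 = 1.0 / (l1 * l2)
            sig = cauchy_stress(p, st_, float(alpha) * l3**2).sigma
            assert abs(sig[2, 2]) < 1e-10

    @pytest.mark.parametrize("law", LAWS)
    def test_fiber_direction_is_stiffer_equibiaxially(self, law):
        lam = np.linspace(1.01, 1.12, 10)
        s11, s22 = planar_biaxial_stress(CALIBRATED_PARAMS[law], lam, lam)
        assert np.all(s11 >= s22)

    @pytest.mark.parametrize("law", LAWS)
    def test_equibiaxial_monotonicity(self, law):
        lam = np.linspace(1.0, 1.3, 200)
        s11, _ = planar_biaxial_stress(CALIBRATED_PARAMS[law], lam, lam)
        assert np.all(np.diff(s11) > 0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        law=st.sampled_from(LAWS),
        raw=st.lists(st.floats(0.0, 50.0), min_size=4, max_size=4),
    )
    def test_zero_point_property_random_params(self, law, raw):
        """W and the plane-stress response vanish at (1, 1) for any
        non-negative parameter set."""
        k = {"W1": 4, "W2": 4, "W3": 3}[law]
        params = MaterialParams.from_vector(law, raw[:k])
        st_ = deformation_from_stretches(1.0, 1.0)
        assert strain_energy(params, st_) == pytest.approx(0.0, abs=1e-12)
        s11, s22 = planar_biaxial_stress(params, 1.0, 1.0)
        assert abs(s11) < 1e-12 and abs(s22) < 1e-12


class TestFiberMeasures:
    def test_fiber_strain_closed_form(self):
        assert fiber_strain(deformation_from_stretches(1.0, 1.0)) == 0.0
        assert fiber_strain(deformation_from_stretches(1.2, 1.07)) == pytest.approx(0.22)

    def test_fiber_strain_equals_invariant_expression(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            st_ = random_incompressible_state(rng)
            assert fiber_strain(st_) == pytest.approx((st_.I4 - 1) / 2, abs=1e-12)

    def test_fiber_stress_isotropic_and_orthogonal(self):
        st_ = deformation_from_stretches(1.2, 1.1)
        assert fiber_stress(st_, 7.5 * np.eye(3)) == pytest.approx(7.5)
        uni = np.zeros((3, 3))
        uni[1, 1] = 50.0  # axis orthogonal to the (deformed) fiber, e1
        assert fiber_stress(st_, uni) == pytest.approx(0.0, abs=1e-12)

    def test_fiber_stress_matches_direct_quadratic_form(self):
        p = CALIBRATED_PARAMS["W1"]
        st_ = deformation_from_stretches(1.1, 1.05)
        alpha, _ = stress_coefficients(p, st_.I1, st_.I4)
        l3 = 1.0 / (1.1 * 1.05)
        sig = cauchy_stress(p, st_, float(alpha) * l3**2).sigma
        f = st_.f / np.linalg.norm(st_.f)
        assert fiber_stress(st_, sig) == pytest.approx(float(f @ sig @ f), rel=1e-12)
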