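"""Kinematics, energies, stress laws and admissibility diagnostics."""

import numpy as np
import pytest

from ligfit.constitutive import (
    ConfigurationError,
    InvalidDeformationError,
    MaterialParameters,
    check_C1,
    check_C2,
    fiber_energy,
    invariants_from_F,
    matrix_energy,
    membrane_energy_and_stress,
    plane_stress_cauchy,
    total_energy,
    uniaxial_first_PK,
    uniaxial_invariants,
)


class TestInvariants:
    def test_identity(self):
        assert invariants_from_F(np.eye(2), (1, 0)) == (3.0, 3.0, 1.0, 1.0)

    @pytest.mark.parametrize("lam", [1.2, 1.44, 0.9])
    def test_uniaxial_I4_is_stretch_squared(self, lam):
        F2 = np.diag([lam, 1 / np.sqrt(lam)])
        I1, I2, I4, lam3 = invariants_from_F(F2, (1, 0))
        assert I4 == pytest.approx(lam**2, abs=1e-14)
        assert lam3 == pytest.approx(1 / np.sqrt(lam), rel=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_eigenvalue_oracle(self, seed):
        """I1/I2 agree with a brute-force eigendecomposition of C."""
        rng = np.random.default_rng(seed)
        F2 = np.eye(2) + 0.3 * rng.standard_normal((2, 2))
        if np.linalg.det(F2) <= 0.1:
            F2 = np.eye(2) + 0.05 * rng.standard_normal((2, 2))
        I1, I2, I4, lam3 = invariants_from_F(F2, (1, 0))
        F = np.zeros((3, 3))
        F[:2, :2] = F2
        F[2, 2] = 1 / np.linalg.det(F2)
        w = np.linalg.eigvalsh(F.T @ F)
        assert I1 == pytest.approx(w.sum(), abs=1e-12)
        assert I2 == pytest.approx(w[0] * w[1] + w[1] * w[2] + w[2] * w[0], abs=1e-12)

    def test_inverted_deformation_rejected(self):
        with pytest.raises(InvalidDeformationError):
            invariants_from_F(np.diag([-1.0, 1.0]), (1, 0))

    def test_non_unit_fiber_rejected(self):
        with pytest.raises(ConfigurationError):
            invariants_from_F(np.eye(2), (1, 1))


class TestEnergies:
    def test_zero_at_reference(self, three_laws):
        for p in three_laws:
            assert matrix_energy(p, 3.0, 3.0) == pytest.approx(0.0)
            assert fiber_energy(p, 1.0) == pytest.approx(0.0)

    def test_yeoh_hand_value(self):
        p = MaterialParameters("Yeoh", mu=1.0, C10=0.5, C20=1.0, C30=1.0)
        # 0.5*1 + 1*1 + 1*1 at I1 = 4
        assert matrix_energy(p, 4.0, 3.0) == pytest.approx(2.5)

    def test_fiber_hand_value_and_symmetry(self):
        p = MaterialParameters("NH", mu=1.0, C10=0.5, C4=1.0, C5=0.0)
        assert fiber_energy(p, 2.0) == pytest.approx(1.0)
        x = np.linspace(0.0, 2.0, 9)
        assert fiber_energy(p, x) == pytest.approx(fiber_energy(p, 2.0 - x))

    def test_mr_with_zero_c01_nests_nh(self):
        mr = MaterialParameters("MR", mu=1.0, C10=0.5, C01=0.0, C4=2.0, C5=0.3)
        nh = MaterialParameters("NH", mu=1.0, C10=0.5, C4=2.0, C5=0.3)
        lam = np.linspace(1.0, 1.6, 13)
        I1, I2, I4 = uniaxial_invariants(lam)
        np.testing.assert_allclose(total_energy(mr, I1, I2, I4),
                                   total_energy(nh, I1, I2, I4), rtol=0, atol=0)
        np.testing.assert_allclose(uniaxial_first_PK(mr, lam),
                                   uniaxial_first_PK(nh, lam))

    def test_yeoh_with_zero_high_orders_nests_nh(self):
        yeoh = MaterialParameters("Yeoh", mu=1.0, C10=0.5, C20=0.0, C30=0.0, C4=2.0, C5=0.3)
        nh = MaterialParameters("NH", mu=1.0, C10=0.5, C4=2.0, C5=0.3)
        lam = np.linspace(1.0, 1.6, 13)
        np.testing.assert_allclose(uniaxial_first_PK(yeoh, lam),
                                   uniaxial_first_PK(nh, lam))


class TestParameterValidation:
    def test_mu_policy_enforced_nh(self):
        with pytest.raises(ConfigurationError):
            MaterialParameters("NH", mu=1.0, C10=0.4)

    def test_mu_policy_enforced_mr(self):
        with pytest.raises(ConfigurationError):
            MaterialParameters("MR", mu=1.0, C10=0.1, C01=0.1)

    def test_foreign_coefficient_rejected(self):
        with pytest.raises(ConfigurationError):
            MaterialParameters("NH", mu=1.0, C10=0.5, C01=0.2)
        with pytest.raises(ConfigurationError):
            MaterialParameters("MR", mu=1.0, C10=0.0005, C01=0.4995, C20=0.1)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ConfigurationError):
            MaterialParameters("NH", mu=1.0, C10=0.5, C4=-1.0)

    def test_json_round_trip(self, yeoh_params):
        back = MaterialParameters.from_json(yeoh_params.to_json())
        assert back == yeoh_params


class TestUniaxialStress:
    def test_stress_free_reference(self, three_laws):
        for p in three_laws:
            assert uniaxial_first_PK(p, 1.0) == pytest.approx(0.0, abs=1e-14)

    def test_nh_hand_value(self):
        p = MaterialParameters("NH", mu=1.0, C10=0.5)
        assert uniaxial_first_PK(p, 2.0) == pytest.approx(1.75)

    def test_matches_energy_derivative_oracle(self, three_laws):
        """Closed form equals dW/dlam along the incompressible uniaxial path."""
        lam = np.linspace(1.02, 1.6, 30)
        h = 1e-6
        for p in three_laws:
            W = lambda l: total_energy(p, *uniaxial_invariants(l))
            dW = (W(lam + h) - W(lam - h)) / (2 * h)
            np.testing.assert_allclose(uniaxial_first_PK(p, lam), dW, rtol=1e-6)

    def test_nonpositive_stretch_rejected(self, nh_params):
        with pytest.raises(InvalidDeformationError):
            uniaxial_first_PK(nh_params, -0.5)


class TestPlaneStressCauchy:
    def test_zero_at_identity(self, three_laws):
        for p in three_laws:
            np.testing.assert_allclose(plane_stress_cauchy(p, np.eye(2)), 0.0, atol=1e-14)

    @pytest.mark.parametrize("lam", [1.1, 1.3, 1.5])
    def test_uniaxial_consistency(self, three_laws, lam):
        """sigma22 = 0 and sigma11/lam reproduces the closed-form P."""
        F2 = np.diag([lam, 1 / np.sqrt(lam)])
        for p in three_laws:
            sig = plane_stress_cauchy(p, F2)
            assert sig[1, 1] == pytest.approx(0.0, abs=1e-10)
            assert sig[0, 0] / lam == pytest.approx(uniaxial_first_PK(p, lam), rel=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_membrane_stress_is_energy_gradient(self, yeoh_params, seed):
        """P2 = dW/dF2 of the plane-stress reduced energy (FD oracle)."""
        rng = np.random.default_rng(seed)
        F2 = np.eye(2) + 0.2 * rng.standard_normal((2, 2))
        if np.linalg.det(F2) <= 0.2:
            F2 = np.eye(2)
        a0 = np.array([1.0, 0.0])
        _, P2 = membrane_energy_and_stress(yeoh_params, F2, a0)
        num = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                d = np.zeros((2, 2))
                d[i, j] = 1e-7
                Wp, _ = membrane_energy_and_stress(yeoh_params, F2 + d, a0)
                Wm, _ = membrane_energy_and_stress(yeoh_params, F2 - d, a0)
                num[i, j] = (Wp - Wm) / 2e-7
        np.testing.assert_allclose(P2, num, rtol=1e-5, atol=1e-7)

    def test_cauchy_consistent_with_membrane_gradient(self, yeoh_params):
        """sigma = P2 F2^T reproduces the pressure-projected Cauchy stress."""
        rng = np.random.default_rng(3)
        F2 = np.eye(2) + 0.15 * rng.standard_normal((2, 2))
        _, P2 = membrane_energy_and_stress(yeoh_params, F2, np.array([1.0, 0.0]))
        np.testing.assert_allclose(P2 @ F2.T, plane_stress_cauchy(yeoh_params, F2),
                                   rtol=1e-10, atol=1e-12)


class TestAdmissibility:
    def test_c1_satisfied_for_convex_nh(self):
        """Pure NH matrix is convex over the explored range (analytic Hessian)."""
        p = MaterialParameters("NH", mu=1.0, C10=0.5)
        rep = check_C1(p, 1.35)
        assert rep.satisfied and rep.n_saddle == 0

    def test_c1_satisfied_for_ligament_fit(self, nh_params):
        assert check_C1(nh_params, 1.35).satisfied

    def test_c1_detects_constructed_saddle(self):
        """Negative fiber stiffness (validation bypassed) creates saddles."""
        p = MaterialParameters("NH", mu=1.0, C10=0.5, C4=-2.0, C5=0.0, validate=False)
        assert not check_C1(p, 1.35).satisfied

    def test_c1_degenerate_grid_rejected(self, nh_params):
        with pytest.raises(ConfigurationError):
            check_C1(nh_params, 1.35, n_grid=4)

    def test_c2_fiber_dominant(self):
        p = MaterialParameters("NH", mu=0.002, C10=0.001, C4=3.0, C5=0.5)
        assert check_C2(p, 1.35).satisfied

    def test_c2_matrix_only_violated(self):
        p = MaterialParameters("NH", mu=1.0, C10=0.5, C4=0.001, C5=0.001)
        rep = check_C2(p, 1.2)
        assert not rep.satisfied
        lo, hi = rep.failing_interval
        assert hi - lo > 0.15  # violated over essentially the whole range

    def test_c2_reports_energy_partition(self, nh_params):
        rep = check_C2(nh_params, 1.35)
        part = rep.partition
        np.testing.assert_allclose(part.W, part.Wm + part.Wf)
        assert np.all(part.Wm >= 0) and np.all(part.Wf >= 0)
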