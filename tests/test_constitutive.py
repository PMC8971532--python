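"""Reduced Holzapfel-Ogden model: invariants, energy, stress, biaxial fitting."""

import math

import numpy as np
import pytest

import myostiff as ms
from myostiff.constitutive import (BiaxialData, CauchyStress, MaterialParams,
                                   cauchy_stress, equibiaxial_trace,
                                   fit_biaxial, invariants_from_stretches,
                                   strain_energy)

TABLE_BIAXIAL = MaterialParams(0.22, 1.62, 0.806, 0.470)   # rat equibiaxial estimate
TABLE_INVERSE_FE = (34.261, 11.275)                        # human inverse-FE estimate


class TestInvariants:
    def test_identity_deformation(self):
        assert invariants_from_stretches(1, 1, 1, 0.73) == (3.0, 1.0)

    def test_circumferential_fiber_reads_hoop_stretch(self):
        i1, i4f = invariants_from_stretches(1 / 1.21, 1.1, 1.1, 0.0)
        assert i4f == pytest.approx(1.21, abs=1e-15)

    def test_oblique_fiber_oracle(self):
        # frozen from an independent symbolic evaluation of the definitions
        i1, i4f = invariants_from_stretches(0.826, 1.1, 1.1, math.pi / 4)
        assert i1 == pytest.approx(3.102276, abs=1e-12)
        assert i4f == pytest.approx(1.21, abs=1e-12)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            invariants_from_stretches(0.0, 1.0, 1.0, 0.0)


class TestStrainEnergy:
    def test_reference_state_measured_energy_is_zero(self):
        st = ms.DeformationState(1, 1, 1)
        psi, psi_hat = strain_energy(st, TABLE_BIAXIAL)
        assert psi_hat == 0.0
        assert psi == pytest.approx(0.22 / (2 * 1.62))

    def test_vanishing_fiber_stiffness_removes_fiber_term(self):
        st = ms.DeformationState.incompressible(1.3, 1.1, alpha=0.2)
        lo = MaterialParams(0.22, 1.62, 1e-12, 3.0)
        ref = MaterialParams(0.22, 1.62, 1.0, 3.0)
        psi_lo, _ = strain_energy(st, lo)
        psi_matrix = 0.22 / (2 * 1.62) * math.exp(1.62 * (st.invariants[0] - 3))
        assert psi_lo == pytest.approx(psi_matrix, rel=1e-9)
        assert strain_energy(st, ref)[0] > psi_lo

    def test_closed_form_oracle(self):
        # state engineered to I1 = 3.2, I4f = 1.21; frozen sympy evaluation
        # lam_t = 1.1 with alpha = 0 gives I4f = 1.21; solve lam_z for I1 = 3.2
        from scipy.optimize import brentq

        lt = 1.1
        lz = brentq(lambda z: (lt * z) ** -2 + lt ** 2 + z ** 2 - 3.2, 0.9, 1.4)
        st = ms.DeformationState.incompressible(lt, lz, alpha=0.0)
        assert st.invariants[0] == pytest.approx(3.2, abs=1e-12)
        psi, psi_hat = strain_energy(st, TABLE_BIAXIAL)
        assert psi == pytest.approx(0.11184122149970968, rel=1e-12)
        assert psi_hat == pytest.approx(0.04393998693180845, rel=1e-12)


def _random_states(n, rng):
    states = []
    while len(states) < n:
        lt = rng.uniform(0.85, 1.4)
        lz = rng.uniform(0.85, 1.4)
        alpha = rng.uniform(-math.pi / 2, math.pi / 2)
        states.append(ms.DeformationState.incompressible(lt, lz, alpha=alpha))
    return states


class TestCauchyStress:
    def test_reference_state_is_stress_free_with_p_equal_a(self):
        params = MaterialParams(a_f=2.0, b_f=3.0)
        st = ms.DeformationState(1, 1, 1, alpha=0.4, p=params.a)
        s = cauchy_stress(st, params)
        assert np.allclose(list(s), 0.0, atol=1e-15)

    def test_stress_linear_in_stiffness_scales(self):
        st = ms.DeformationState.incompressible(1.2, 1.05, alpha=0.5, p=0.0)
        base = np.array(list(cauchy_stress(st, MaterialParams(a_f=2.0, b_f=3.0))))
        scaled = np.array(list(cauchy_stress(st, MaterialParams(a_f=2.0, b_f=3.0).scaled(2.5))))
        assert np.allclose(scaled, 2.5 * base, rtol=1e-15)

    def test_equibiaxial_stress_oracle(self):
        # lam = 1.1 equibiaxial, fiber circumferential, plane stress in r;
        # frozen from the symbolic plane-stress solution
        lam = 1.1
        e_mat = 0.22 * math.exp(1.62 * (2 * lam ** 2 + lam ** -4 - 3))
        st = ms.DeformationState(lam ** -2, lam, lam, alpha=0.0, p=e_mat * lam ** -4)
        s = cauchy_stress(st, TABLE_BIAXIAL)
        assert s.rr == pytest.approx(0.0, abs=1e-15)
        assert s.tt == pytest.approx(0.5551806642286483, rel=1e-12)
        assert s.zz == pytest.approx(0.13699289748034005, rel=1e-12)
        assert s.ff == pytest.approx(s.tt, rel=1e-12)  # fiber is the theta axis

    def test_stress_matches_energy_derivative(self):
        """Deviatoric Cauchy stress equals lam_i dPsi/dlam_i by finite differences."""
        rng = np.random.default_rng(42)
        params = MaterialParams(a_f=1.7, b_f=2.3)
        h = 1e-6
        for st in _random_states(100, rng):
            s = cauchy_stress(st, params)
            lams = [st.lam_r, st.lam_t, st.lam_z]
            for i, comp in enumerate([s.rr, s.tt, s.zz]):
                def psi_of(lam_i):
                    trial = [*lams]
                    trial[i] = lam_i
                    i1, _ = invariants_from_stretches(*trial, st.alpha)
                    c, sn = math.cos(st.alpha), math.sin(st.alpha)
                    i4f = trial[1] ** 2 * c * c + trial[2] ** 2 * sn * sn
                    return (params.a / (2 * params.b) * math.exp(params.b * (i1 - 3))
                            + params.a_f / (2 * params.b_f)
                            * math.expm1(params.b_f * (i4f - 1) ** 2))

                deriv = (psi_of(lams[i] + h) - psi_of(lams[i] - h)) / (2 * h)
                assert comp + st.p == pytest.approx(lams[i] * deriv, rel=1e-6, abs=1e-8)


class TestEquibiaxialTrace:
    def test_reference_is_zero(self):
        assert equibiaxial_trace(1.0, TABLE_BIAXIAL) == 0.0

    def test_frozen_oracle_values(self):
        # frozen from an independent symbolic plane-stress derivation
        assert equibiaxial_trace(1.1, TABLE_BIAXIAL) == pytest.approx(
            0.6292486924627168, rel=1e-12)
        assert equibiaxial_trace(1.2, TABLE_BIAXIAL) == pytest.approx(
            1.5637365844456388, rel=1e-12)

    def test_consistent_with_cauchy_stress_transform(self):
        lam = 1.15
        e_mat = 0.22 * math.exp(1.62 * (2 * lam ** 2 + lam ** -4 - 3))
        st = ms.DeformationState(lam ** -2, lam, lam, alpha=0.0, p=e_mat * lam ** -4)
        s = cauchy_stress(st, TABLE_BIAXIAL)
        # P = J sigma F^-T: trace over the two in-plane axes
        assert (s.tt + s.zz) / lam == pytest.approx(
            equibiaxial_trace(lam, TABLE_BIAXIAL), rel=1e-12)

    def test_linearity_in_stiffness_scales(self):
        lam = np.array([1.05, 1.1, 1.3])
        p = MaterialParams(a_f=2.0, b_f=1.5)
        np.testing.assert_allclose(equibiaxial_trace(lam, p.scaled(3.0)),
                                   3.0 * equibiaxial_trace(lam, p), rtol=1e-15)

    def test_compression_rejected(self):
        with pytest.raises(ValueError):
            equibiaxial_trace(0.99, TABLE_BIAXIAL)


class TestFitBiaxial:
    lam_grid = np.linspace(1.005, 1.25, 30)

    @pytest.mark.parametrize("a_f,b_f", [(0.806, 0.470), TABLE_INVERSE_FE])
    def test_recovers_known_parameters(self, a_f, b_f):
        truth = MaterialParams(a_f=a_f, b_f=b_f)
        data = BiaxialData(self.lam_grid, equibiaxial_trace(self.lam_grid, truth))
        fit = fit_biaxial(data)
        assert fit.converged
        assert fit.a_f == pytest.approx(a_f, rel=1e-6)
        assert fit.b_f == pytest.approx(b_f, rel=1e-6)
        assert fit.rms_residual < 1e-8

    def test_recovery_across_sampling_range(self):
        """Max relative error 1e-4 over 20 random draws from the LHS ranges."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            a_f = math.exp(rng.uniform(math.log(0.01), math.log(100.0)))
            b_f = math.exp(rng.uniform(math.log(0.01), math.log(20.0)))
            truth = MaterialParams(a_f=a_f, b_f=b_f)
            data = BiaxialData(self.lam_grid, equibiaxial_trace(self.lam_grid, truth))
            fit = fit_biaxial(data)
            assert fit.a_f == pytest.approx(a_f, rel=1e-4)
            assert fit.b_f == pytest.approx(b_f, rel=1e-4)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            fit_biaxial(BiaxialData(np.array([1.0, 1.0 + 1e-12]), np.zeros(2)))

    def test_roundtrip_io(self, tmp_path):
        data = BiaxialData(self.lam_grid,
                           equibiaxial_trace(self.lam_grid, TABLE_BIAXIAL))
        path = tmp_path / "biaxial.csv"
        ms.constitutive.write_biaxial(data, path)
        back = ms.constitutive.read_biaxial(path)
        np.testing.assert_allclose(back.stretches, data.stretches)
        np.testing.assert_allclose(back.trace_P, data.trace_P)


def test_material_params_must_be_positive():
    with pytest.raises(ValueError):
        MaterialParams(a=-0.1)
    with pytest.raises(ValueError):
        MaterialParams(a_f=0.0)
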