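"""Constitutive laws: energies, stresses, and the finite-difference oracle."""

import numpy as np
import pytest

import mvmech.laws as laws
from mvmech import (
    CHORDAE_EXP_DEFAULT,
    CHORDAE_LINEAR_DEFAULT,
    M1_ANTERIOR,
    M1_POSTERIOR,
    M2_ANTERIOR,
    M3_ANTERIOR,
)
from mvmech.kinematics import (
    DeformationState,
    biaxial_deformation,
    default_chordae_protocol,
    default_leaflet_protocol,
    uniaxial_deformation,
)

from conftest import random_rotation

ALL_LAW_PARAMS = [
    ("M1", M1_ANTERIOR),
    ("M1", M1_POSTERIOR),
    ("M2", M2_ANTERIOR),
    ("M3", M3_ANTERIOR),
    ("chordae_linear", CHORDAE_LINEAR_DEFAULT),
    ("chordae_exp", CHORDAE_EXP_DEFAULT),
]


class TestStrainEnergy:
    @pytest.mark.parametrize("law,params", ALL_LAW_PARAMS)
    def test_zero_at_reference(self, law, params):
        assert laws.strain_energy(law, params, 3.0, 1.0) == pytest.approx(0.0, abs=1e-14)

    def test_tension_only_switch_compressed_fiber(self):
        # compressed fiber (I4 < 1) contributes nothing: at I1 = 3 the
        # matrix term also vanishes, so the whole energy is zero
        assert laws.strain_energy("M1", M1_ANTERIOR, 3.0, 0.9) == pytest.approx(0.0, abs=1e-14)

    def test_m3_direct_formula_oracle(self):
        # independent evaluation of c0*(exp(c1 q1 + c2 q4) - 1)
        c0, c1, c2 = 0.29, 0.47, 55.39
        I1, I4 = 3.1, 1.1
        expected = c0 * (np.exp(c1 * (I1 - 3) ** 2 + c2 * (I4 - 1) ** 2) - 1.0)
        got = laws.strain_energy("M3", M3_ANTERIOR, I1, I4)
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("law,params", ALL_LAW_PARAMS)
    def test_nonnegative_over_protocols(self, law, params):
        prot = default_chordae_protocol() if law.startswith("chordae") \
            else default_leaflet_protocol()
        for st_ in prot.states():
            assert laws.strain_energy(law, params, st_.I1, st_.I4) >= 0.0

    def test_unknown_law_rejected(self):
        with pytest.raises(KeyError):
            laws.strain_energy("M4", M1_ANTERIOR, 3.0, 1.0)

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            laws.LeafletParamsM1(c=-1.0, a=1.0, b=1.0)

    def test_mismatched_params_rejected(self):
        with pytest.raises(TypeError):
            laws.strain_energy("M2", M1_ANTERIOR, 3.0, 1.0)


def _fd_stress(law, params, state, constraint, eps=1e-6):
    """Central-difference Cauchy stress through F, with multiplier elimination.

    For a diagonal stretch state, sigma_ii = lambda_i dPsi/dlambda_i
    (incompressible); the multiplier is then removed using the same
    zero-stress condition as the analytic route.
    """
    lam = np.diag(state.F).copy()

    def psi_at(lams):
        F = np.diag(lams)
        C = F.T @ F
        I1 = np.trace(C)
        I4 = state.a0 @ C @ state.a0
        return float(laws.strain_energy(law, params, I1, I4))

    sig = np.zeros(3)
    for i in range(3):
        lp = lam.copy(); lp[i] += eps
        lm = lam.copy(); lm[i] -= eps
        sig[i] = lam[i] * (psi_at(lp) - psi_at(lm)) / (2 * eps)
    if constraint == "plane_stress":
        sig -= sig[2]
    else:  # uniaxial
        sig -= sig[1]
    return np.diag(sig)


class TestCauchyStress:
    def test_identity_plane_stress_m1(self):
        st_ = biaxial_deformation(1.0, 1.0)
        out = laws.cauchy_stress("M1", M1_ANTERIOR, st_, "plane_stress")
        assert np.allclose(out.sigma, 0.0, atol=1e-12)
        assert out.lam_mult == pytest.approx(2 * 17.43)

    @pytest.mark.parametrize("law,params", ALL_LAW_PARAMS[:4])
    def test_equibiaxial_fd_oracle(self, law, params):
        st_ = biaxial_deformation(1.2, 1.2)
        out = laws.cauchy_stress(law, params, st_, "plane_stress")
        fd = _fd_stress(law, params, st_, "plane_stress")
        assert np.allclose(out.sigma, fd, rtol=1e-6, atol=1e-8)

    def test_chordae_linear_closed_form(self):
        lam = 1.1
        st_ = uniaxial_deformation(lam)
        out = laws.cauchy_stress("chordae_linear", laws.ChordaeParamsLinear(1.0),
                                 st_, "uniaxial")
        assert out.sigma[0, 0] == pytest.approx(2 * (lam**2 - 1 / lam), rel=1e-12)
        # with the default C the stress scales linearly
        out2 = laws.cauchy_stress("chordae_linear", CHORDAE_LINEAR_DEFAULT, st_, "uniaxial")
        assert out2.sigma[0, 0] == pytest.approx(CHORDAE_LINEAR_DEFAULT.C * 2 * (lam**2 - 1 / lam),
                                                 rel=1e-12)

    def test_chordae_exp_zero_at_reference(self):
        st_ = uniaxial_deformation(1.0)
        out = laws.cauchy_stress("chordae_exp", CHORDAE_EXP_DEFAULT, st_, "uniaxial")
        assert np.allclose(out.sigma, 0.0, atol=1e-12)

    @pytest.mark.parametrize("law,params", ALL_LAW_PARAMS)
    def test_constraint_components_vanish(self, law, params):
        if law.startswith("chordae"):
            st_ = uniaxial_deformation(1.08)
            out = laws.cauchy_stress(law, params, st_, "uniaxial")
            assert abs(out.sigma[1, 1]) <= 1e-10
            assert abs(out.sigma[2, 2]) <= 1e-10
        else:
            st_ = biaxial_deformation(1.15, 1.1)
            out = laws.cauchy_stress(law, params, st_, "plane_stress")
            assert abs(out.sigma[2, 2]) <= 1e-10
        assert np.allclose(out.sigma, out.sigma.T, atol=1e-10)

    def test_fiber_contribution_vanishes_in_compression(self):
        # cross-fiber-only stretch compresses the fiber (I4 < 1): M1
        # reduces to its neo-Hookean matrix part
        st_ = DeformationState(F=np.diag([0.95, 1.2, 1 / (0.95 * 1.2)]),
                               a0=np.array([1.0, 0, 0]))
        assert st_.I4 < 1.0
        full = laws.cauchy_stress("M1", M1_ANTERIOR, st_, "plane_stress").sigma
        matrix_only = laws.cauchy_stress(
            "M1", laws.LeafletParamsM1(M1_ANTERIOR.c, 0.0, M1_ANTERIOR.b),
            st_, "plane_stress").sigma
        assert np.allclose(full, matrix_only, atol=1e-12)

    def test_objectivity(self, rng):
        st_ = biaxial_deformation(1.2, 1.1)
        out = laws.cauchy_stress("M1", M1_ANTERIOR, st_, "none", multiplier=5.0)
        for _ in range(10):
            R = random_rotation(rng)
            st_rot = DeformationState(F=R @ st_.F, a0=st_.a0)
            out_rot = laws.cauchy_stress("M1", M1_ANTERIOR, st_rot, "none", multiplier=5.0)
            assert np.allclose(out_rot.sigma, R @ out.sigma @ R.T, atol=1e-10)

    def test_missing_multiplier_rejected(self):
        st_ = biaxial_deformation(1.1, 1.1)
        with pytest.raises(ValueError):
            laws.cauchy_stress("M1", M1_ANTERIOR, st_, "none")


class TestAsPrintedVariants:
    """Historically circulated stress formulas kept for comparison only."""

    def test_m1_printed_fiber_factor_differs(self):
        s_deriv = laws.biaxial_stresses("M1", M1_ANTERIOR, 1.2, 1.2)[0]
        s_printed = laws.biaxial_stresses("M1", M1_ANTERIOR, 1.2, 1.2, as_printed=True)[0]
        assert not np.isclose(s_deriv, s_printed)

    def test_chordae_linear_printed_is_half(self):
        lam = 1.1
        s = laws.uniaxial_stress("chordae_linear", CHORDAE_LINEAR_DEFAULT, lam)
        s_printed = laws.uniaxial_stress("chordae_linear", CHORDAE_LINEAR_DEFAULT, lam,
                                         as_printed=True)
        assert s_printed == pytest.approx(s / 2.0, rel=1e-12)

    def test_chordae_exp_printed_missing_a2(self):
        lam = 1.05
        s = laws.uniaxial_stress("chordae_exp", CHORDAE_EXP_DEFAULT, lam)
        s_printed = laws.uniaxial_stress("chordae_exp", CHORDAE_EXP_DEFAULT, lam,
                                         as_printed=True)
        assert s_printed == pytest.approx(s / CHORDAE_EXP_DEFAULT.a2, rel=1e-12)


class TestStressStretchCurve:
    def test_single_point_reference_is_zero(self):
        from mvmech.kinematics import StretchProtocol

        prot = StretchProtocol("biaxial", [np.array([[1.0, 1.0]])])
        ds = laws.stress_stretch_curve("M1", M1_ANTERIOR, prot)
        assert len(ds) == 1
        assert np.allclose(ds.stresses, 0.0, atol=1e-14)

    def test_matches_pointwise_evaluation(self):
        prot = default_leaflet_protocol(n_points=8)
        ds = laws.stress_stretch_curve("M2", M2_ANTERIOR, prot)
        lam = ds.stretches
        s11, s22 = laws.biaxial_stresses("M2", M2_ANTERIOR, lam[:, 0], lam[:, 1])
        assert np.array_equal(ds.stresses, np.column_stack([s11, s22]))

    @pytest.mark.parametrize("law,params", ALL_LAW_PARAMS)
    def test_monotone_on_equibiaxial_or_uniaxial_path(self, law, params):
        lam = np.linspace(1.0, 1.25, 40)
        if law.startswith("chordae"):
            s = laws.uniaxial_stress(law, params, lam)
        else:
            s, _ = laws.biaxial_stresses(law, params, lam, lam)
        assert np.all(np.diff(s) >= -1e-12)

    def test_chordae_exp_convex(self):
        lam = np.linspace(1.0, 1.2, 50)
        s = laws.uniaxial_stress("chordae_exp", CHORDAE_EXP_DEFAULT, lam)
        assert np.all(np.diff(s, 2) >= -1e-9)

    def test_chordae_law_rejects_biaxial_protocol(self):
        with pytest.raises(ValueError):
            laws.stress_stretch_curve("chordae_exp", CHORDAE_EXP_DEFAULT,
                                      default_leaflet_protocol())


class TestEnergyConsistency:
    """Analytic stress == finite-difference energy derivative (the invariant
    behind every stress evaluation in the package)."""

    @pytest.mark.parametrize("law,params", ALL_LAW_PARAMS)
    def test_random_biaxial_states(self, law, params, rng):
        constraint = "uniaxial" if law.startswith("chordae") else "plane_stress"
        for _ in range(25):
            if constraint == "uniaxial":
                st_ = uniaxial_deformation(rng.uniform(1.0, 1.12))
            else:
                st_ = biaxial_deformation(rng.uniform(1.0, 1.3), rng.uniform(1.0, 1.3))
            out = laws.cauchy_stress(law, params, st_, constraint)
            fd = _fd_stress(law, params, st_, constraint)
            scale = max(np.abs(fd).max(), 1.0)
            assert np.abs(out.sigma - fd).max() / scale <= 1e-6
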