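"""FSI core: kernel identities, coupling adjointness, projection, benchmarks."""

import numpy as np
import pytest

from mvmech.ibfe import (
    CFLError,
    EulerianGrid,
    FluidSolver,
    SimulationError,
    interpolate_velocity,
    spread_force,
)
from mvmech.ibfe.kernel import DeltaKernel, phi4
from mvmech.ibfe.demo import ValveDemoConfig, build_valve_mesh
from mvmech.ibfe.mesh import elastic_energy, internal_force
from mvmech.ibfe.waveform import PressureWaveform, default_mitral_waveform


class TestDeltaKernel:
    def test_partition_of_unity(self, rng):
        r = rng.uniform(-0.5, 0.5, 200)
        total = sum(phi4(r - j) for j in range(-3, 4))
        assert np.abs(total - 1.0).max() <= 1e-12

    def test_even_symmetry_and_center_value(self):
        r = np.linspace(0, 2, 100)
        assert np.allclose(phi4(r), phi4(-r))
        assert phi4(0.0) == pytest.approx(0.5)

    def test_compact_support(self):
        assert np.all(phi4(np.array([2.0, 2.5, -3.0])) == 0.0)

    def test_stencil_weights_sum_to_one(self, rng):
        k = DeltaKernel()
        x = rng.uniform(0.0, 10.0, 50)
        _, w = k.stencil_weights(x)
        assert np.abs(w.sum(axis=1) - 1.0).max() <= 1e-12


class TestCoupling:
    def _grid(self):
        return EulerianGrid(nx=32, ny=16, lx=2.0, ly=1.0)

    def test_single_node_weights_sum(self):
        g = self._grid()
        fu, fv = spread_force(np.array([[1.0, 0.5]]), np.array([[1.0, 0.0]]), g)
        assert fu.sum() * g.h**2 == pytest.approx(1.0, abs=1e-12)
        assert fv.sum() == pytest.approx(0.0, abs=1e-14)

    def test_zero_force_zero_field(self):
        g = self._grid()
        fu, fv = spread_force(np.array([[0.7, 0.3]]), np.zeros((1, 2)), g)
        assert not fu.any() and not fv.any()

    def test_conservation_random_configuration(self, rng):
        g = self._grid()
        pos = np.column_stack([rng.uniform(0.3, 1.7, 30), rng.uniform(0.2, 0.8, 30)])
        F = rng.standard_normal((30, 2))
        fu, fv = spread_force(pos, F, g)
        assert fu.sum() * g.h**2 == pytest.approx(F[:, 0].sum(), rel=1e-12, abs=1e-12)
        assert fv.sum() * g.h**2 == pytest.approx(F[:, 1].sum(), rel=1e-12, abs=1e-12)

    def test_uniform_field_interpolates_exactly(self, rng):
        g = self._grid()
        g.u[:] = 3.25
        g.v[:] = -1.5
        pos = np.column_stack([rng.uniform(0.3, 1.7, 20), rng.uniform(0.2, 0.8, 20)])
        vel = interpolate_velocity(g, pos)
        assert np.allclose(vel[:, 0], 3.25, atol=1e-12)
        assert np.allclose(vel[:, 1], -1.5, atol=1e-12)

    def test_adjointness_identity(self, rng):
        g = self._grid()
        pos = np.column_stack([rng.uniform(0.3, 1.7, 25), rng.uniform(0.2, 0.8, 25)])
        F = rng.standard_normal((25, 2))
        fu, fv = spread_force(pos, F, g)
        g.u = rng.standard_normal(g.u.shape)
        g.v = rng.standard_normal(g.v.shape)
        lhs = ((fu * g.u).sum() + (fv * g.v).sum()) * g.h**2
        rhs = (F * interpolate_velocity(g, pos)).sum()
        assert lhs == pytest.approx(rhs, rel=1e-13)

    def test_linear_field_interpolation_accuracy(self):
        # ux = y is reproduced up to the kernel's second-moment error
        g = EulerianGrid(nx=64, ny=32, lx=2.0, ly=1.0)
        yj = (np.arange(g.ny) + 0.5) * g.h
        g.u[:] = yj[None, :]
        pos = np.array([[1.0, 0.5], [0.8, 0.31], [1.3, 0.77]])
        vel = interpolate_velocity(g, pos)
        assert np.allclose(vel[:, 0], pos[:, 1], atol=5e-3)

    def test_node_outside_domain_raises(self):
        g = self._grid()
        with pytest.raises(SimulationError):
            spread_force(np.array([[2.5, 0.5]]), np.ones((1, 2)), g)
        with pytest.raises(SimulationError):
            interpolate_velocity(g, np.array([[1.0, -0.1]]))


class TestInternalForce:
    def _mesh(self):
        cfg = ValveDemoConfig(nx=32, ny=16)
        return build_valve_mesh(cfg)[0]

    def test_undeformed_mesh_zero_forces(self):
        mesh = self._mesh()
        # reference configuration: elements unstretched, springs at rest,
        # bending of the straight chain zero, tethers slack
        f = internal_force(mesh)
        assert np.abs(f).max() <= 1e-8

    def test_translation_invariance(self):
        mesh = self._mesh()
        mesh.target_stiffness = 0.0  # springs break translation invariance
        mesh.tethers = []
        x = mesh.x + np.array([0.05, -0.03])
        f = internal_force(mesh, x)
        assert np.abs(f).max() <= 1e-8

    def test_net_force_and_torque_free_structure(self, rng):
        mesh = self._mesh()
        mesh.target_stiffness = 0.0
        mesh.tethers = []
        x = mesh.x + 0.002 * rng.standard_normal(mesh.x.shape)
        f = internal_force(mesh, x)
        assert np.abs(f.sum(axis=0)).max() <= 1e-6 * max(np.abs(f).max(), 1.0)
        torque = np.sum(x[:, 0] * f[:, 1] - x[:, 1] * f[:, 0])
        assert abs(torque) <= 1e-6 * max(np.abs(f).max(), 1.0)

    def test_forces_match_energy_gradient(self, rng):
        mesh = self._mesh()
        x = mesh.x + 0.002 * rng.standard_normal(mesh.x.shape)
        f = internal_force(mesh, x)
        eps = 1e-6
        gfd = np.zeros_like(x)
        for i in range(x.shape[0]):
            for d in range(2):
                xp = x.copy(); xp[i, d] += eps
                xm = x.copy(); xm[i, d] -= eps
                gfd[i, d] = -(elastic_energy(mesh, xp) - elastic_energy(mesh, xm)) / (2 * eps)
        assert np.abs(f - gfd).max() / np.abs(gfd).max() <= 1e-6

    def test_collapsed_element_rejected(self):
        mesh = self._mesh()
        x = mesh.x.copy()
        x[1] = x[0]
        with pytest.raises(ValueError):
            internal_force(mesh, x)


class TestFluidSolver:
    def test_zero_state_stays_zero(self):
        g = EulerianGrid(nx=16, ny=8, lx=2.0, ly=1.0)
        s = FluidSolver(g)
        for _ in range(10):
            s.step(1e-4, p_in=0.0, p_out=0.0)
        assert g.max_speed() == 0.0

    def test_divergence_free_after_projection(self, rng):
        g = EulerianGrid(nx=32, ny=16, lx=2.0, ly=1.0)
        s = FluidSolver(g)
        fu = rng.standard_normal(g.u.shape) * 10
        fv = rng.standard_normal(g.v.shape) * 10
        for _ in range(5):
            s.step(1e-4, p_in=100.0, p_out=0.0, fu=fu, fv=fv)
        rel_div = np.abs(g.divergence()).max() * g.h / g.max_speed()
        assert rel_div <= 1e-10

    def test_cfl_violation_aborts_with_suggestion(self):
        g = EulerianGrid(nx=16, ny=8, lx=2.0, ly=1.0)
        g.u[:] = 100.0
        s = FluidSolver(g)
        with pytest.raises(CFLError, match="reduce dt"):
            s.step(1e-2, p_in=0.0)

    def test_poiseuille_profile(self):
        """Steady pressure-driven channel flow matches the closed form
        u(y) = dp*y*(H-y)/(2 mu L) within 2% at ny = 64."""
        ny, nx = 64, 8
        H = 0.2
        L = H * nx / ny
        g = EulerianGrid(nx=nx, ny=ny, lx=L, ly=H, rho=1.0, mu=0.2)
        s = FluidSolver(g)
        dp = 8.0 * g.mu * 1.0 * L / H**2  # peak velocity 1 cm/s
        t, t_end = 0.0, 0.12  # several viscous decay times
        while t < t_end:
            dt = 0.9 * s.stability_dt()
            s.step(dt, p_in=dp, p_out=0.0)
            t += dt
        y = (np.arange(ny) + 0.5) * g.h
        exact = dp * y * (H - y) / (2 * g.mu * L)
        err = np.abs(g.u[nx // 2, :] - exact).max() / exact.max()
        assert err <= 0.02


class TestPressureWaveform:
    def test_passes_through_anchors(self):
        wf = default_mitral_waveform()
        for t, p in wf.anchors:
            assert wf(t) == pytest.approx(p)

    def test_continuous_and_held_outside(self):
        wf = PressureWaveform([(0.0, 0.0), (1.0, 10.0)])
        assert wf(-1.0) == 0.0
        assert wf(2.0) == 10.0
        assert wf(0.5) == pytest.approx(5.0)

    def test_default_anchored_pressures(self):
        wf = default_mitral_waveform()
        ps = [p for _, p in wf.anchors]
        assert 10.0 in ps and -80.0 in ps and -150.0 in ps

    def test_reversal_time_between_hold_and_closure(self):
        wf = default_mitral_waveform()
        tr = wf.reversal_time()
        assert tr is not None
        assert wf(tr - 1e-4) > 0 > wf(tr + 1e-4)

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError):
            PressureWaveform([(0.0, 0.0), (0.0, 1.0)])
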