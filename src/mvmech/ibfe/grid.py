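"""Incompressible Navier–Stokes on a staggered (MAC) grid, 2D channel.

The fluid occupies a rectangular channel ``[0, Lx] x [0, Ly]`` with
no-slip walls at ``y = 0, Ly`` and prescribed-pressure open boundaries at
``x = 0`` (inlet) and ``x = Lx`` (outlet); the transvalvular pressure
difference drives the flow.  Time stepping is an explicit projection
scheme: first-order upwind advection and explicit centred diffusion build
a provisional velocity, then a pressure Poisson solve (direct sparse
factorisation, reused across steps) projects it onto the discretely
divergence-free space.  With the exact solve the post-projection discrete
divergence vanishes to rounding error.

Units are CGS: cm, s, g/cm^3 for density, g/(cm s) (poise) for viscosity,
dyn/cm^2 for pressure.  Defaults are typical blood values
``rho = 1.0 g/cm^3`` and ``mu = 0.04 P``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = ["EulerianGrid", "FluidSolver", "CFLError", "SimulationError"]


class CFLError(RuntimeError):
    """Time step exceeds the advective or viscous stability bound."""


class SimulationError(RuntimeError):
    """Field blow-up or an immersed node left the domain."""


@dataclass
class EulerianGrid:
    """Staggered velocity/pressure fields on a uniform square-cell grid.

    ``u`` lives on vertical faces (``(nx+1, ny)``, x-velocity), ``v`` on
    horizontal faces (``(nx, ny+1)``), ``p`` at cell centres
    (``(nx, ny)``).
    """

    nx: int
    ny: int
    lx: float
    ly: float
    rho: float = 1.0
    mu: float = 0.04
    u: np.ndarray = field(init=False)
    v: np.ndarray = field(init=False)
    p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        hx = self.lx / self.nx
        hy = self.ly / self.ny
        if abs(hx - hy) > 1e-12 * hx:
            raise ValueError(f"cells must be square: lx/nx = {hx}, ly/ny = {hy}")
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")
        self.u = np.zeros((self.nx + 1, self.ny))
        self.v = np.zeros((self.nx, self.ny + 1))
        self.p = np.zeros((self.nx, self.ny))

    @property
    def h(self) -> float:
        return self.lx / self.nx

    def divergence(self) -> np.ndarray:
        """Discrete divergence at cell centres (1/s)."""
        h = self.h
        return (self.u[1:, :] - self.u[:-1, :]) / h + (self.v[:, 1:] - self.v[:, :-1]) / h

    def max_speed(self) -> float:
        return max(float(np.max(np.abs(self.u))), float(np.max(np.abs(self.v))))

    def speed_centres(self) -> np.ndarray:
        """Velocity magnitude interpolated to cell centres."""
        uc = 0.5 * (self.u[1:, :] + self.u[:-1, :])
        vc = 0.5 * (self.v[:, 1:] + self.v[:, :-1])
        return np.hypot(uc, vc)


class FluidSolver(object):
    """Explicit projection solver bound to one :class:`EulerianGrid`.

    The pressure Poisson operator (Dirichlet at inlet/outlet faces,
    Neumann at the walls) is factorised once at construction.
    """

    def __init__(self, grid: EulerianGrid):
        self.grid = grid
        self._lu = splu(self._poisson_matrix().tocsc())

    def _poisson_matrix(self) -> sp.spmatrix:
        nx, ny = self.grid.nx, self.grid.ny
        h2 = self.grid.h ** 2
        n = nx * ny

        def k(i, j):
            return i * ny + j

        rows, cols, vals = [], [], []
        for i in range(nx):
            for j in range(ny):
                diag = 0.0
                # west face: interior coupling or Dirichlet (ghost 2*p_in - p)
                if i > 0:
                    rows.append(k(i, j)); cols.append(k(i - 1, j)); vals.append(1.0)
                    diag -= 1.0
                else:
                    diag -= 2.0
                # east face
                if i < nx - 1:
                    rows.append(k(i, j)); cols.append(k(i + 1, j)); vals.append(1.0)
                    diag -= 1.0
                else:
                    diag -= 2.0
                # wall faces: homogeneous Neumann, no contribution
                if j > 0:
                    rows.append(k(i, j)); cols.append(k(i, j - 1)); vals.append(1.0)
                    diag -= 1.0
                if j < ny - 1:
                    rows.append(k(i, j)); cols.append(k(i, j + 1)); vals.append(1.0)
                    diag -= 1.0
                rows.append(k(i, j)); cols.append(k(i, j)); vals.append(diag)
        A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)) / h2
        return A

    # -- time stepping -------------------------------------------------

    def stability_dt(self, cfl: float = 0.5) -> float:
        """Largest stable dt: min of advective CFL and viscous bounds."""
        g = self.grid
        h = g.h
        umax = g.max_speed()
        dt_visc = cfl * g.rho * h * h / (4.0 * g.mu)
        if umax <= 1e-12:
            return dt_visc
        return min(cfl * h / umax, dt_visc)

    def step(self, dt: float, p_in: float, p_out: float = 0.0,
             fu: np.ndarray | None = None, fv: np.ndarray | None = None,
             cfl: float = 1.0) -> None:
        """Advance one explicit projection step.

        Raises :class:`CFLError` if ``dt`` exceeds the stability bound
        (scaled by ``cfl``) and :class:`SimulationError` on field blow-up.
        """
        g = self.grid
        bound = self.stability_dt(cfl=cfl)
        if dt > bound * (1.0 + 1e-9):
            raise CFLError(
                f"dt = {dt:.3e} s exceeds stability bound {bound:.3e} s; "
                f"reduce dt to at most {bound:.3e}"
            )
        h, rho, nu = g.h, g.rho, g.mu / g.rho
        u, v = g.u, g.v

        # ghost-padded fields: x -> zero-gradient at inlet/outlet,
        # y -> odd reflection (no-slip) at the walls
        up = np.empty((g.nx + 3, g.ny + 2))
        up[1:-1, 1:-1] = u
        up[0, 1:-1] = u[0]
        up[-1, 1:-1] = u[-1]
        up[:, 0] = -up[:, 1]
        up[:, -1] = -up[:, -2]

        vp = np.empty((g.nx + 2, g.ny + 3))
        vp[1:-1, 1:-1] = v
        vp[0, 1:-1] = v[0]
        vp[-1, 1:-1] = v[-1]
        vp[:, 0] = vp[:, 1]     # v just outside the wall rows (unused: v wall rows pinned)
        vp[:, -1] = vp[:, -2]

        # --- u momentum -------------------------------------------------
        uc = up[1:-1, 1:-1]
        dudx_m = (uc - up[:-2, 1:-1]) / h
        dudx_p = (up[2:, 1:-1] - uc) / h
        dudy_m = (uc - up[1:-1, :-2]) / h
        dudy_p = (up[1:-1, 2:] - uc) / h
        # v averaged to u-points; clip column indices at the open ends
        iw = np.clip(np.arange(g.nx + 1) - 1, 0, g.nx - 1)
        ie = np.clip(np.arange(g.nx + 1), 0, g.nx - 1)
        v_at_u = 0.25 * (v[iw, :-1] + v[iw, 1:] + v[ie, :-1] + v[ie, 1:])
        adv_u = (np.where(uc > 0, uc * dudx_m, uc * dudx_p)
                 + np.where(v_at_u > 0, v_at_u * dudy_m, v_at_u * dudy_p))
        lap_u = (up[2:, 1:-1] + up[:-2, 1:-1] + up[1:-1, 2:] + up[1:-1, :-2] - 4.0 * uc) / (h * h)
        ustar = u + dt * (-adv_u + nu * lap_u)
        if fu is not None:
            ustar = ustar + dt * fu / rho

        # --- v momentum -------------------------------------------------
        vc = vp[1:-1, 1:-1]
        dvdx_m = (vc - vp[:-2, 1:-1]) / h
        dvdx_p = (vp[2:, 1:-1] - vc) / h
        dvdy_m = (vc - vp[1:-1, :-2]) / h
        dvdy_p = (vp[1:-1, 2:] - vc) / h
        js = np.clip(np.arange(g.ny + 1) - 1, 0, g.ny - 1)
        jn = np.clip(np.arange(g.ny + 1), 0, g.ny - 1)
        u_at_v = 0.25 * (u[:-1, js] + u[1:, js] + u[:-1, jn] + u[1:, jn])
        adv_v = (np.where(u_at_v > 0, u_at_v * dvdx_m, u_at_v * dvdx_p)
                 + np.where(vc > 0, vc * dvdy_m, vc * dvdy_p))
        lap_v = (vp[2:, 1:-1] + vp[:-2, 1:-1] + vp[1:-1, 2:] + vp[1:-1, :-2] - 4.0 * vc) / (h * h)
        vstar = v + dt * (-adv_v + nu * lap_v)
        if fv is not None:
            vstar = vstar + dt * fv / rho
        vstar[:, 0] = 0.0
        vstar[:, -1] = 0.0

        # --- pressure projection ---------------------------------------
        div = (ustar[1:, :] - ustar[:-1, :]) / h + (vstar[:, 1:] - vstar[:, :-1]) / h
        rhs = (rho / dt) * div
        rhs[0, :] -= 2.0 * p_in / (h * h)
        rhs[-1, :] -= 2.0 * p_out / (h * h)
        p = self._lu.solve(rhs.ravel()).reshape(g.nx, g.ny)

        u_new = ustar.copy()
        u_new[1:-1, :] -= (dt / rho) * (p[1:, :] - p[:-1, :]) / h
        u_new[0, :] -= (dt / rho) * (p[0, :] - p_in) * 2.0 / h
        u_new[-1, :] -= (dt / rho) * (p_out - p[-1, :]) * 2.0 / h
        v_new = vstar
        v_new[:, 1:-1] -= (dt / rho) * (p[:, 1:] - p[:, :-1]) / h
        v_new[:, 0] = 0.0
        v_new[:, -1] = 0.0

        if not (np.all(np.isfinite(u_new)) and np.all(np.isfinite(v_new))):
            raise SimulationError("velocity field blew up (non-finite values)")
        g.u, g.v, g.p = u_new, v_new, p
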