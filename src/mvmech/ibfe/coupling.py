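"""Fluid–structure coupling via the regularized delta function.

``spread_force`` transfers Lagrangian nodal forces (dyn per unit depth)
to the staggered velocity grids as a body-force density (dyn/cm^3 per
unit depth):

    f(x) = sum_k F_k delta_h(x - chi_k),   delta_h = phi(x1/h) phi(x2/h) / h^2,

and ``interpolate_velocity`` evaluates the grid velocity at the nodes:

    U_k = sum_ij u_ij phi(..) phi(..).

With the same kernel the two operators are exact adjoints,
``<S(F), u> h^2 = <F, J(u)>``, and spreading conserves total force
(``sum f h^2 = sum F``) by the partition of unity.
"""

from __future__ import annotations

import numpy as np

from .grid import EulerianGrid, SimulationError
from .kernel import DeltaKernel

__all__ = ["spread_force", "interpolate_velocity"]

_kernel = DeltaKernel()


def _weights(coords: np.ndarray, offset: float, n_axis: int, h: float):
    """Stencil indices/weights along one axis for one component grid.

    ``offset`` is the grid-coordinate of sample 0 (0 for on-axis samples,
    0.5 for cell-centred ones).  Out-of-stencil indices are clipped and
    their weight preserved on the boundary sample (boundary-clipped
    spreading keeps conservation exact).
    """
    idx, w = _kernel.stencil_weights(coords / h - offset)
    idx = np.clip(idx, 0, n_axis - 1)
    return idx, w


def _check_inside(pos: np.ndarray, grid: EulerianGrid) -> None:
    bad = (
        (pos[:, 0] < 0.0) | (pos[:, 0] > grid.lx)
        | (pos[:, 1] < 0.0) | (pos[:, 1] > grid.ly)
    )
    if np.any(bad):
        k = int(np.argmax(bad))
        raise SimulationError(
            f"immersed node {k} left the domain at position "
            f"({pos[k, 0]:.4g}, {pos[k, 1]:.4g}) cm"
        )


def spread_force(positions: np.ndarray, forces: np.ndarray, grid: EulerianGrid):
    """Spread nodal forces to ``(fu, fv)`` body-force fields.

    Returns fields shaped like ``grid.u`` / ``grid.v``; total spread
    force times ``h^2`` equals the total nodal force exactly.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    F = np.atleast_2d(np.asarray(forces, dtype=float))
    if pos.shape != F.shape or pos.shape[1] != 2:
        raise ValueError("positions and forces must both be (n, 2)")
    _check_inside(pos, grid)
    h = grid.h
    fu = np.zeros_like(grid.u)
    fv = np.zeros_like(grid.v)
    # u-grid: samples at (i h, (j+0.5) h)
    ix, wx = _weights(pos[:, 0], 0.0, grid.nx + 1, h)
    jy, wy = _weights(pos[:, 1], 0.5, grid.ny, h)
    w2 = wx[:, :, None] * wy[:, None, :] / (h * h)
    np.add.at(fu, (ix[:, :, None], jy[:, None, :]), F[:, 0, None, None] * w2)
    # v-grid: samples at ((i+0.5) h, j h)
    ix, wx = _weights(pos[:, 0], 0.5, grid.nx, h)
    jy, wy = _weights(pos[:, 1], 0.0, grid.ny + 1, h)
    w2 = wx[:, :, None] * wy[:, None, :] / (h * h)
    np.add.at(fv, (ix[:, :, None], jy[:, None, :]), F[:, 1, None, None] * w2)
    return fu, fv


def interpolate_velocity(grid: EulerianGrid, positions: np.ndarray) -> np.ndarray:
    """Kernel-interpolated fluid velocity at the nodes, shape (n, 2)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[1] != 2:
        raise ValueError("positions must be (n, 2)")
    _check_inside(pos, grid)
    h = grid.h
    ix, wx = _weights(pos[:, 0], 0.0, grid.nx + 1, h)
    jy, wy = _weights(pos[:, 1], 0.5, grid.ny, h)
    U = np.einsum("nab,nab->n", grid.u[ix[:, :, None], jy[:, None, :]],
                  wx[:, :, None] * wy[:, None, :])
    ix, wx = _weights(pos[:, 0], 0.5, grid.nx, h)
    jy, wy = _weights(pos[:, 1], 0.0, grid.ny + 1, h)
    V = np.einsum("nab,nab->n", grid.v[ix[:, :, None], jy[:, None, :]],
                  wx[:, :, None] * wy[:, None, :])
    return np.column_stack([U, V])
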