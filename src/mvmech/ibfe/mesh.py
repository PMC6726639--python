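"""Immersed fiber-curve structures: leaflets, target anchors, chordae.

A leaflet is a 1D chain of line elements in 2D, each carrying a leaflet
constitutive law with the fiber direction along the element.  The element
deformation is completed to a 3D incompressible state by plane-strain
completion (stretches ``(lam, 1/lam, 1)``), so the invariants are

    I1 = lam^2 + lam^-2 + 1,      I4 = lam^2,

and the five tissue laws plug in with their 3D parameterisations.  The
axial force per element follows from the strain energy per reference
volume ``Psi`` (kPa, converted to CGS internally) times the reference
cross-section ``area0`` (cm^2 per cm of depth, i.e. the leaflet
thickness):  nodal forces are exactly the negative gradient of the total
elastic energy with respect to nodal positions, which the test suite
verifies against central differences.

A small quadratic bending energy regularises the chain (membrane strips
have no bending stiffness of their own), and attachment is through stiff
target-point springs, the standard immersed-boundary idiom for anchoring
structure to housing.  Optional chordae tethers connect chosen nodes to
fixed anchor points: single elements with uniaxial incompressible
completion ``(lam, 1/sqrt(lam), 1/sqrt(lam))`` carrying a chordae law,
tension-only (slack cords carry nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import laws
from ..laws import KPA_TO_CGS, LawParams

__all__ = ["Tether", "LagrangianMesh", "internal_force", "elastic_energy"]


@dataclass
class Tether:
    """Tension-only chordae element from mesh node ``node`` to ``anchor``."""

    node: int
    anchor: np.ndarray  # (2,) fixed point, cm
    rest_length: float  # cm
    area0: float  # cm^2 per unit depth
    law: str
    params: LawParams

    def __post_init__(self) -> None:
        if self.law not in laws.CHORDAE_LAWS:
            raise ValueError(f"tether law must be a chordae law, got {self.law!r}")
        self.anchor = np.asarray(self.anchor, dtype=float)


@dataclass
class LagrangianMesh:
    """Fiber-aligned line-element structure immersed in the fluid.

    Parameters
    ----------
    X : (n, 2) reference node positions (cm); ``x`` starts equal to ``X``.
    elements : (m, 2) int
        Node index pairs; reference lengths are taken from ``X``.
    law, params
        Leaflet constitutive law shared by all elements.
    area0 : float
        Reference cross-section per unit depth (leaflet thickness, cm).
    target_nodes : int array
        Nodes anchored by stiff springs to their reference positions.
    target_stiffness : float
        Spring constant per anchored node, dyn/cm per unit depth.
    bending_stiffness : float
        Coefficient of the discrete quadratic bending energy, dyn*cm.
    """

    X: np.ndarray
    elements: np.ndarray
    law: str
    params: LawParams
    area0: float
    target_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    target_stiffness: float = 0.0
    bending_stiffness: float = 0.0
    tethers: list[Tether] = field(default_factory=list)
    chains: list[np.ndarray] = field(default_factory=list)  # node chains for bending
    x: np.ndarray = field(init=False)
    L0: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != 2:
            raise ValueError("X must be (n, 2)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 2:
            raise ValueError("elements must be (m, 2)")
        n = len(self.X)
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= n:
            raise ValueError("element indices out of range")
        d = self.X[self.elements[:, 1]] - self.X[self.elements[:, 0]]
        self.L0 = np.linalg.norm(d, axis=1)
        if np.any(self.L0 <= 0):
            raise ValueError("zero-length element in reference configuration")
        self.x = self.X.copy()
        self.target_nodes = np.asarray(self.target_nodes, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.X)

    def element_stretches(self, x: np.ndarray | None = None) -> np.ndarray:
        x = self.x if x is None else x
        d = x[self.elements[:, 1]] - x[self.elements[:, 0]]
        return np.linalg.norm(d, axis=1) / self.L0


def _leaflet_dpsi_dlam(mesh: LagrangianMesh, lam: np.ndarray, h_fd: float = 0.0):
    """d(Psi)/d(lam) (kPa) under plane-strain completion, vectorised."""
    I1 = lam**2 + lam**-2 + 1.0
    I4 = lam**2
    _, psi1, psi4 = laws.energy_derivatives(mesh.law, mesh.params, I1, I4)
    return psi1 * (2.0 * lam - 2.0 * lam**-3) + psi4 * 2.0 * lam


def _tether_dpsi_dlam(t: Tether, lam: float) -> float:
    """d(Psi)/d(lam) (kPa), uniaxial completion, tension-only."""
    if lam <= 1.0:
        return 0.0
    I1 = lam**2 + 2.0 / lam
    I4 = lam**2
    _, psi1, psi4 = laws.energy_derivatives(t.law, t.params, I1, I4)
    return float(psi1 * (2.0 * lam - 2.0 / lam**2) + psi4 * 2.0 * lam)


def elastic_energy(mesh: LagrangianMesh, x: np.ndarray | None = None) -> float:
    """Total elastic energy (erg per unit depth) at configuration ``x``."""
    x = mesh.x if x is None else np.asarray(x, dtype=float)
    lam = mesh.element_stretches(x)
    I1 = lam**2 + lam**-2 + 1.0
    I4 = lam**2
    psi = laws.strain_energy(mesh.law, mesh.params, I1, I4)
    e = float(np.sum(psi * KPA_TO_CGS * mesh.area0 * mesh.L0))
    # target springs
    if mesh.target_nodes.size and mesh.target_stiffness > 0.0:
        d = x[mesh.target_nodes] - mesh.X[mesh.target_nodes]
        e += 0.5 * mesh.target_stiffness * float(np.sum(d * d))
    # bending
    if mesh.bending_stiffness > 0.0:
        for chain in mesh.chains:
            xc = x[chain]
            if len(xc) >= 3:
                curv = xc[:-2] - 2.0 * xc[1:-1] + xc[2:]
                e += 0.5 * mesh.bending_stiffness * float(np.sum(curv * curv))
    # tethers (tension-only)
    for t in mesh.tethers:
        l = float(np.linalg.norm(x[t.node] - t.anchor)) / t.rest_length
        if l > 1.0:
            I1 = l**2 + 2.0 / l
            psi = laws.strain_energy(t.law, t.params, I1, l**2)
            e += float(psi) * KPA_TO_CGS * t.area0 * t.rest_length
    return e


def internal_force(mesh: LagrangianMesh, x: np.ndarray | None = None) -> np.ndarray:
    """Nodal forces (dyn per unit depth): ``-d(energy)/d(x)``.

    Includes element, target-spring, bending and tether contributions.
    Raises on inverted (zero-length) elements.
    """
    x = mesh.x if x is None else np.asarray(x, dtype=float)
    f = np.zeros_like(x)
    d = x[mesh.elements[:, 1]] - x[mesh.elements[:, 0]]
    l = np.linalg.norm(d, axis=1)
    if np.any(l <= 1e-12):
        raise ValueError("collapsed element (length ~ 0)")
    lam = l / mesh.L0
    t_hat = d / l[:, None]
    # axial nodal force magnitude = area0 * dPsi/dlam (CGS)
    fa = (_leaflet_dpsi_dlam(mesh, lam) * KPA_TO_CGS * mesh.area0)[:, None] * t_hat
    np.add.at(f, mesh.elements[:, 0], fa)
    np.add.at(f, mesh.elements[:, 1], -fa)
    if mesh.target_nodes.size and mesh.target_stiffness > 0.0:
        f[mesh.target_nodes] -= mesh.target_stiffness * (
            x[mesh.target_nodes] - mesh.X[mesh.target_nodes]
        )
    if mesh.bending_stiffness > 0.0:
        kb = mesh.bending_stiffness
        for chain in mesh.chains:
            xc = x[chain]
            if len(xc) < 3:
                continue
            curv = xc[:-2] - 2.0 * xc[1:-1] + xc[2:]
            grad = np.zeros_like(xc)
            grad[:-2] += curv
            grad[1:-1] -= 2.0 * curv
            grad[2:] += curv
            np.add.at(f, chain, -kb * grad)
    for t in mesh.tethers:
        dvec = x[t.node] - t.anchor
        dist = float(np.linalg.norm(dvec))
        if dist <= 1e-12:
            continue
        lam_t = dist / t.rest_length
        dpsi = _tether_dpsi_dlam(t, lam_t)
        f[t.node] -= dpsi * KPA_TO_CGS * t.area0 * (dvec / dist)
    return f


def tangent_stiffness_bound(mesh: LagrangianMesh, x: np.ndarray | None = None) -> float:
    """Upper estimate of the stiffest nodal spring constant (dyn/cm).

    Used for the structural time-step restriction of the explicit
    coupling: per element ``k ~ area0 * E_t / L0`` with the tangent
    modulus ``E_t = d^2 Psi / d lam^2`` estimated by central differences,
    plus target-spring, bending and tether contributions.
    """
    x = mesh.x if x is None else np.asarray(x, dtype=float)
    lam = np.maximum(mesh.element_stretches(x), 1.0)
    eps = 1e-5
    et = (_leaflet_dpsi_dlam(mesh, lam + eps) - _leaflet_dpsi_dlam(mesh, lam - eps)) / (2 * eps)
    et = np.maximum(et, 0.0) * KPA_TO_CGS
    k = float(np.max(et * mesh.area0 / mesh.L0, initial=0.0))
    k = max(k, mesh.target_stiffness)
    if mesh.bending_stiffness > 0.0:
        k = max(k, 16.0 * mesh.bending_stiffness)
    for t in mesh.tethers:
        lam_t = max(float(np.linalg.norm(x[t.node] - t.anchor)) / t.rest_length, 1.0)
        dd = (_tether_dpsi_dlam(t, lam_t + eps) - _tether_dpsi_dlam(t, lam_t - eps)) / (2 * eps)
        k = max(k, max(dd, 0.0) * KPA_TO_CGS * t.area0 / t.rest_length)
    return k
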