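"""Deformation kinematics for stretch-controlled tissue tests.

Planar biaxial tests on valve leaflets and uniaxial tests on chordae are
idealised as homogeneous, incompressible deformations.  The deformation
gradient ``F`` is diagonal in the test frame, with the out-of-plane (and,
for uniaxial tests, lateral) stretches completed by exact incompressibility
``det F = 1``.  Every constitutive evaluation downstream consumes only the
two strain invariants

* ``I1 = tr(C)`` with ``C = F^T F`` — overall (isotropic) deformation,
* ``I4 = a0 . (C a0)`` — squared stretch along the collagen fiber
  direction ``a0`` (a unit vector in the reference configuration).

Coordinate convention: axis 1 = fiber/circumferential, axis 2 =
cross-fiber, axis 3 = sheet normal.  The fiber direction is fixed to test
axis 1 in all protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DeformationState",
    "StretchProtocol",
    "biaxial_deformation",
    "uniaxial_deformation",
    "invariants",
    "default_leaflet_protocol",
    "default_chordae_protocol",
]

_AXIS1 = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class DeformationState:
    """A homogeneous deformation: gradient, fiber direction and invariants.

    Attributes
    ----------
    F : (3, 3) ndarray
        Deformation gradient (dimensionless).
    a0 : (3,) ndarray
        Unit fiber direction in the reference configuration.
    I1, I4, J : float
        First invariant of ``C = F^T F``, squared fiber stretch, and
        ``det F``.
    """

    F: np.ndarray
    a0: np.ndarray
    I1: float = field(init=False)
    I4: float = field(init=False)
    J: float = field(init=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        a0 = np.asarray(self.a0, dtype=float)
        if F.shape != (3, 3):
            raise ValueError(f"F must be 3x3, got shape {F.shape}")
        if a0.shape != (3,):
            raise ValueError(f"a0 must be a 3-vector, got shape {a0.shape}")
        n = float(np.linalg.norm(a0))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"a0 must be a unit vector (|a0| = {n:.3e})")
        J = float(np.linalg.det(F))
        if J <= 0.0:
            raise ValueError(f"det(F) must be positive, got {J:.3e}")
        i1, i4 = invariants(F, a0)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "a0", a0)
        object.__setattr__(self, "I1", i1)
        object.__setattr__(self, "I4", i4)
        object.__setattr__(self, "J", J)

    @property
    def B(self) -> np.ndarray:
        """Left Cauchy-Green tensor ``F F^T``."""
        return self.F @ self.F.T

    @property
    def C(self) -> np.ndarray:
        """Right Cauchy-Green tensor ``F^T F``."""
        return self.F.T @ self.F


def invariants(F: np.ndarray, a0: np.ndarray) -> tuple[float, float]:
    """Strain invariants ``I1 = tr(C)`` and ``I4 = a0 . (C a0)``.

    Parameters
    ----------
    F : (3, 3) array_like
        Deformation gradient with ``det F > 0``.
    a0 : (3,) array_like
        Unit fiber direction.

    Returns
    -------
    (I1, I4) : tuple of float
    """
    F = np.asarray(F, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    if abs(np.linalg.norm(a0) - 1.0) > 1e-9:
        raise ValueError("a0 must be a unit vector")
    if np.linalg.det(F) <= 0.0:
        raise ValueError("F must have positive determinant")
    C = F.T @ F
    return float(np.trace(C)), float(a0 @ (C @ a0))


def biaxial_deformation(lambda1: float, lambda2: float) -> DeformationState:
    """Incompressible planar-biaxial stretch state.

    ``F = diag(lambda1, lambda2, 1/(lambda1*lambda2))`` with the fiber
    along axis 1; the out-of-plane stretch is set by ``det F = 1``.
    """
    if lambda1 <= 0.0 or lambda2 <= 0.0:
        raise ValueError("stretches must be positive")
    F = np.diag([lambda1, lambda2, 1.0 / (lambda1 * lambda2)])
    return DeformationState(F=F, a0=_AXIS1)


def uniaxial_deformation(lam: float) -> DeformationState:
    """Incompressible uniaxial stretch ``F = diag(lam, lam**-0.5, lam**-0.5)``.

    The two lateral stretches contract equally to preserve volume; the
    loading axis (axis 1) is the fiber axis.
    """
    if lam <= 0.0:
        raise ValueError("stretch must be positive")
    s = 1.0 / np.sqrt(lam)
    return DeformationState(F=np.diag([lam, s, s]), a0=_AXIS1)


@dataclass(frozen=True)
class StretchProtocol:
    """A stretch-controlled loading protocol.

    Parameters
    ----------
    mode : {"biaxial", "uniaxial"}
    paths : sequence of arrays
        For biaxial mode each path is an ``(n, 2)`` array of
        ``(lambda1, lambda2)`` pairs; for uniaxial mode each path is an
        ``(n,)`` array of stretches.  All stretches must be >= 1 and each
        path must be monotone, strictly increasing in at least one
        coordinate (loading only — unloading is not modelled).
    """

    mode: Literal["biaxial", "uniaxial"]
    paths: tuple[np.ndarray, ...]

    def __init__(self, mode: str, paths: Sequence[np.ndarray]) -> None:
        if mode not in ("biaxial", "uniaxial"):
            raise ValueError(f"unknown protocol mode {mode!r}")
        clean = []
        for k, p in enumerate(paths):
            arr = np.atleast_1d(np.asarray(p, dtype=float))
            if mode == "biaxial":
                arr = np.atleast_2d(arr)
                if arr.shape[1] != 2:
                    raise ValueError("biaxial paths need (n, 2) stretch pairs")
            elif arr.ndim != 1:
                raise ValueError("uniaxial paths must be 1-D stretch arrays")
            if np.any(arr < 1.0):
                raise ValueError(f"path {k}: stretches must be >= 1 (loading only)")
            d = np.diff(arr, axis=0)
            if arr.shape[0] > 1:
                if np.any(d < -1e-14):
                    raise ValueError(f"path {k}: stretches must be non-decreasing")
                inc = d > 0 if d.ndim == 1 else np.any(d > 0, axis=1)
                if not np.all(inc):
                    raise ValueError(f"path {k}: stretch must strictly increase along the path")
            arr.setflags(write=False)
            clean.append(arr)
        if not clean:
            raise ValueError("protocol needs at least one path")
        object.__setattr__(self, "mode", mode)
        object.__setattr__(self, "paths", tuple(clean))

    @property
    def n_points(self) -> int:
        return sum(p.shape[0] for p in self.paths)

    def states(self) -> list[DeformationState]:
        """Deformation states for every point of every path, in order."""
        out: list[DeformationState] = []
        for p in self.paths:
            if self.mode == "biaxial":
                out.extend(biaxial_deformation(l1, l2) for l1, l2 in p)
            else:
                out.extend(uniaxial_deformation(l) for l in p)
        return out


def default_leaflet_protocol(lam_max: float = 1.40, n_points: int = 30) -> StretchProtocol:
    """Default pseudo-biaxial leaflet protocol: three loading paths.

    Equibiaxial, fiber-only (``lambda2 = 1``) and cross-fiber-only
    (``lambda1 = 1``) paths with ``n_points`` samples each over
    ``[1, lam_max]``.  The range extends into the collagen-dominated
    stiffening regime: exponential fiber laws are only distinguishable
    from quasi-linear responses once the fiber term dominates, so
    cross-law calibration needs the upper part of this range (see the
    methods note for the calibration study behind the default).
    """
    lam = np.linspace(1.0, lam_max, n_points)
    ones = np.ones_like(lam)
    return StretchProtocol(
        "biaxial",
        [np.column_stack([lam, lam]),
         np.column_stack([lam, ones]),
         np.column_stack([ones, lam])],
    )


def default_chordae_protocol(lam_max: float = 1.10, n_points: int = 50) -> StretchProtocol:
    """Default uniaxial chordae protocol over ``[1, lam_max]``.

    Chordae are far stiffer than leaflets; the stretch range is kept small.
    """
    return StretchProtocol("uniaxial", [np.linspace(1.0, lam_max, n_points)])
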