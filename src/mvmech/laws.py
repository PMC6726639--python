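"""Hyperelastic constitutive laws for mitral-valve leaflets and chordae.

Three transversely isotropic, incompressible strain-energy functions are
provided for the leaflets (law ids ``"M1"``, ``"M2"``, ``"M3"``) and two
isotropic laws for the chordae tendineae (``"chordae_linear"``,
``"chordae_exp"``), all written in terms of the invariants ``I1`` and
``I4`` (see :mod:`mvmech.kinematics`):

.. code-block:: text

    M1:  psi = c (I1 - 3) + a/(2 b) (exp[b (I4* - 1)^2] - 1)
    M2:  psi = cb0 (exp[cb1 (I1 - 3)^2 + cb2 (sqrt(I4*) - 1)^4] - 1)
    M3:  psi = c0 (exp[c1 (I1 - 3)^2 + c2 (I4* - 1)^2] - 1)
    chordae_linear:  psi = C (I1 - 3)                 (neo-Hookean)
    chordae_exp:     psi = a1 (exp[a2 (I1 - 3)] - 1)

Collagen fibers bear load only in tension, so the fiber terms are
evaluated at ``I4* = max(I4, 1)``; the fiber stress contribution vanishes
identically for ``I4 <= 1``.

The Cauchy stress follows from the energy,

    sigma = -lam_mult I + 2 psi_1 B + 2 psi_4 (F a0) ox (F a0),

with ``B = F F^T``, ``psi_i = d psi / d I_i``, and the Lagrange multiplier
``lam_mult`` enforcing incompressibility.  The multiplier is eliminated in
closed form from the zero-stress condition of the test: plane stress
(``sigma_33 = 0``) for leaflet sheets, uniaxial (``sigma_22 = sigma_33 =
0``) for chordae.

``as_printed=True`` selects historically circulated variants of three
stress formulas (an ``I4`` in place of ``I4 - 1`` in the M1 fiber factor,
``C B`` in place of ``2 C B`` for the linear chordae law, and a missing
``a2`` factor in the exponential chordae law) that are *not* the
derivatives of the energies above.  They are retained for comparison only;
the default derivative-consistent forms are enforced by a
finite-difference oracle in the test suite.

Stresses are in kPa throughout (1 mmHg = 0.1333 kPa).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Union

import numpy as np

from .kinematics import DeformationState, StretchProtocol

__all__ = [
    "LAW_IDS",
    "LEAFLET_LAWS",
    "CHORDAE_LAWS",
    "LeafletParamsM1",
    "LeafletParamsM2",
    "LeafletParamsM3",
    "ChordaeParamsLinear",
    "ChordaeParamsExp",
    "StressState",
    "strain_energy",
    "energy_derivatives",
    "cauchy_stress",
    "biaxial_stresses",
    "uniaxial_stress",
    "stress_stretch_curve",
    "make_params",
    "params_to_array",
    "default_params",
    "M1_ANTERIOR",
    "M1_POSTERIOR",
    "M2_ANTERIOR",
    "M2_POSTERIOR",
    "M3_ANTERIOR",
    "M3_POSTERIOR",
    "CHORDAE_LINEAR_DEFAULT",
    "CHORDAE_EXP_DEFAULT",
    "MMHG_TO_KPA",
    "KPA_TO_CGS",
]

LAW_IDS = ("M1", "M2", "M3", "chordae_linear", "chordae_exp")
LEAFLET_LAWS = ("M1", "M2", "M3")
CHORDAE_LAWS = ("chordae_linear", "chordae_exp")

#: 1 mmHg in kPa.
MMHG_TO_KPA = 0.133322
#: 1 kPa in dyn/cm^2 (CGS), used by the FSI demonstrator.
KPA_TO_CGS = 1.0e4

# exp() argument clip guarding overflow during optimizer excursions
_EXP_CLIP = 500.0


def _check_nonneg(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not np.isfinite(v) or v < 0.0:
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class LeafletParamsM1:
    """M1: neo-Hookean matrix + exponential-quadratic fiber term."""

    c: float  # kPa
    a: float  # kPa
    b: float  # dimensionless

    def __post_init__(self) -> None:
        _check_nonneg(self)


@dataclass(frozen=True)
class LeafletParamsM2:
    """M2: single exponential with quartic fiber-stretch term."""

    cb0: float  # kPa
    cb1: float  # dimensionless (see notes on printed units)
    cb2: float  # dimensionless

    def __post_init__(self) -> None:
        _check_nonneg(self)


@dataclass(frozen=True)
class LeafletParamsM3:
    """M3: single exponential, quadratic in both invariant measures."""

    c0: float  # kPa
    c1: float  # dimensionless
    c2: float  # dimensionless

    def __post_init__(self) -> None:
        _check_nonneg(self)


@dataclass(frozen=True)
class ChordaeParamsLinear:
    """Incompressible neo-Hookean chordae law."""

    C: float  # kPa

    def __post_init__(self) -> None:
        _check_nonneg(self)


@dataclass(frozen=True)
class ChordaeParamsExp:
    """Exponential chordae law."""

    a1: float  # kPa
    a2: float  # dimensionless

    def __post_init__(self) -> None:
        _check_nonneg(self)


LawParams = Union[
    LeafletParamsM1, LeafletParamsM2, LeafletParamsM3, ChordaeParamsLinear, ChordaeParamsExp
]

_PARAM_TYPES = {
    "M1": LeafletParamsM1,
    "M2": LeafletParamsM2,
    "M3": LeafletParamsM3,
    "chordae_linear": ChordaeParamsLinear,
    "chordae_exp": ChordaeParamsExp,
}

# Human-leaflet M1 parameters from in-vitro biaxial testing, and the
# M2/M3 parameter sets obtained by fitting those laws to M1-generated
# pseudo-biaxial data (fits are protocol-dependent; these are reference
# values, not package-reproduced quantities).
M1_ANTERIOR = LeafletParamsM1(c=17.43, a=1.35, b=5.93)
M1_POSTERIOR = LeafletParamsM1(c=10.25, a=0.06, b=3.48)
M2_ANTERIOR = LeafletParamsM2(cb0=7.69, cb1=69.42, cb2=0.0008)
M2_POSTERIOR = LeafletParamsM2(cb0=13.99, cb1=80.22, cb2=0.1447)
M3_ANTERIOR = LeafletParamsM3(c0=0.29, c1=0.47, c2=55.39)
M3_POSTERIOR = LeafletParamsM3(c0=0.44, c1=2.58, c2=61.46)

# Chordae defaults chosen so peak uniaxial stress over lambda in [1, 1.10]
# is a few MPa (physiological chordae stiffness); no tabulated values exist.
CHORDAE_LINEAR_DEFAULT = ChordaeParamsLinear(C=5000.0)
CHORDAE_EXP_DEFAULT = ChordaeParamsExp(a1=10.0, a2=30.0)

_DEFAULTS = {
    ("M1", "anterior"): M1_ANTERIOR,
    ("M1", "posterior"): M1_POSTERIOR,
    ("M2", "anterior"): M2_ANTERIOR,
    ("M2", "posterior"): M2_POSTERIOR,
    ("M3", "anterior"): M3_ANTERIOR,
    ("M3", "posterior"): M3_POSTERIOR,
    ("chordae_linear", "chordae"): CHORDAE_LINEAR_DEFAULT,
    ("chordae_exp", "chordae"): CHORDAE_EXP_DEFAULT,
}


def default_params(law: str, tissue: str = "anterior") -> LawParams:
    """Reference parameter set for a law (leaflets: anterior/posterior)."""
    if law in CHORDAE_LAWS:
        tissue = "chordae"
    try:
        return _DEFAULTS[(law, tissue)]
    except KeyError:
        raise KeyError(f"no default parameters for law={law!r}, tissue={tissue!r}") from None


def make_params(law: str, values) -> LawParams:
    """Build a parameter record for ``law`` from a flat array."""
    try:
        cls = _PARAM_TYPES[law]
    except KeyError:
        raise KeyError(f"unknown law id {law!r}; known: {LAW_IDS}") from None
    values = np.atleast_1d(np.asarray(values, dtype=float))
    names = [f.name for f in fields(cls)]
    if values.shape != (len(names),):
        raise ValueError(f"{law} takes {len(names)} parameters {names}, got {values.shape}")
    return cls(*values)


def params_to_array(params: LawParams) -> np.ndarray:
    return np.array([getattr(params, f.name) for f in fields(params)], dtype=float)


def n_params(law: str) -> int:
    return len(fields(_PARAM_TYPES[law]))


def _exp(x):
    return np.exp(np.minimum(x, _EXP_CLIP))


def energy_derivatives(law: str, params: LawParams, I1, I4, as_printed: bool = False):
    """Energy and its invariant derivatives: ``(psi, psi1, psi4)``.

    Vectorised over ``I1``/``I4``.  The tension-only switch
    ``I4* = max(I4, 1)`` is applied internally, which zeroes ``psi4``
    whenever ``I4 <= 1``.  With ``as_printed=True`` the returned ``psi``
    is unchanged but ``psi1``/``psi4`` follow the as-printed stress
    variants (see module docstring).
    """
    if law not in _PARAM_TYPES:
        raise KeyError(f"unknown law id {law!r}; known: {LAW_IDS}")
    if not isinstance(params, _PARAM_TYPES[law]):
        raise TypeError(f"parameters {type(params).__name__} do not match law {law!r}")
    I1 = np.asarray(I1, dtype=float)
    I4 = np.asarray(I4, dtype=float)
    if np.any(I4 <= 0.0):
        raise ValueError("I4 must be positive")
    I4s = np.maximum(I4, 1.0)
    one = np.ones(np.broadcast(I1, I4).shape)

    if law == "M1":
        c, a, b = params.c, params.a, params.b
        q = (I4s - 1.0) ** 2
        e = _exp(b * q)
        if b > 0.0:
            fiber_psi = a / (2.0 * b) * (e - 1.0)
        else:  # b -> 0 limit of a/(2b)(exp(b q) - 1)
            fiber_psi = 0.5 * a * q
        psi = c * (I1 - 3.0) + fiber_psi
        psi1 = c * one
        factor = I4s if as_printed else (I4s - 1.0)
        psi4 = a * factor * e
        if as_printed:
            # printed factor does not vanish at I4=1; still honor tension-only
            psi4 = np.where(I4 > 1.0, psi4, 0.0)
    elif law == "M2":
        cb0, cb1, cb2 = params.cb0, params.cb1, params.cb2
        r = np.sqrt(I4s) - 1.0
        eq = _exp(cb1 * (I1 - 3.0) ** 2 + cb2 * r**4)
        psi = cb0 * (eq - 1.0)
        psi1 = 2.0 * cb0 * cb1 * (I1 - 3.0) * eq
        psi4 = 2.0 * cb0 * cb2 * r**3 / np.sqrt(I4s) * eq
    elif law == "M3":
        c0, c1, c2 = params.c0, params.c1, params.c2
        eq = _exp(c1 * (I1 - 3.0) ** 2 + c2 * (I4s - 1.0) ** 2)
        psi = c0 * (eq - 1.0)
        psi1 = 2.0 * c0 * c1 * (I1 - 3.0) * eq
        psi4 = 2.0 * c0 * c2 * (I4s - 1.0) * eq
    elif law == "chordae_linear":
        psi = params.C * (I1 - 3.0)
        psi1 = (0.5 if as_printed else 1.0) * params.C * one
        psi4 = np.zeros_like(one)
    elif law == "chordae_exp":
        a1, a2 = params.a1, params.a2
        e = _exp(a2 * (I1 - 3.0))
        psi = a1 * (e - 1.0)
        psi1 = (a1 if as_printed else a1 * a2) * e
        psi4 = np.zeros_like(one)
    else:
        raise KeyError(f"unknown law id {law!r}; known: {LAW_IDS}")
    return psi, psi1, psi4


def strain_energy(law: str, params: LawParams, I1, I4) -> np.ndarray | float:
    """Strain energy density (kPa) at invariants ``(I1, I4)``.

    Zero at the reference state ``(3, 1)`` for every law; the fiber term
    is evaluated at ``I4* = max(I4, 1)``.
    """
    I1a = np.asarray(I1, dtype=float)
    # tolerance admits slightly compressible probe states (finite-difference
    # checks perturb single stretch components)
    if np.any(I1a < 3.0 - 1e-4):
        raise ValueError("I1 must be >= 3 for an incompressible deformation")
    psi, _, _ = energy_derivatives(law, params, I1, I4)
    return float(psi) if np.ndim(psi) == 0 else psi


@dataclass(frozen=True)
class StressState:
    """Cauchy stress (kPa) and the eliminated incompressibility multiplier."""

    sigma: np.ndarray  # (3, 3), symmetric
    lam_mult: float  # kPa


def cauchy_stress(
    law: str,
    params: LawParams,
    state: DeformationState,
    constraint: str = "plane_stress",
    multiplier: float | None = None,
    as_printed: bool = False,
) -> StressState:
    """Cauchy stress ``sigma = -lam I + 2 psi1 B + 2 psi4 (F a0) ox (F a0)``.

    Parameters
    ----------
    constraint : {"plane_stress", "uniaxial", "none"}
        How the incompressibility multiplier is resolved: ``plane_stress``
        sets ``sigma_33 = 0`` (leaflet sheet tests), ``uniaxial`` sets
        ``sigma_22 = sigma_33 = 0`` (chordae; requires a laterally
        symmetric deformation), ``none`` uses the supplied ``multiplier``.
    """
    if abs(state.J - 1.0) > 1e-8:
        raise ValueError(f"state must be incompressible (J = {state.J:.3e})")
    _, psi1, psi4 = energy_derivatives(law, params, state.I1, state.I4, as_printed=as_printed)
    psi1 = float(psi1)
    psi4 = float(psi4)
    m = state.F @ state.a0
    sig = 2.0 * psi1 * state.B + 2.0 * psi4 * np.outer(m, m)
    if constraint == "plane_stress":
        lam = sig[2, 2]
    elif constraint == "uniaxial":
        if abs(sig[1, 1] - sig[2, 2]) > 1e-8 * max(1.0, abs(sig[1, 1])):
            raise ValueError("uniaxial constraint needs a laterally symmetric deformation")
        lam = sig[1, 1]
    elif constraint == "none":
        if multiplier is None:
            raise ValueError("constraint='none' requires an explicit multiplier")
        lam = float(multiplier)
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    sigma = sig - lam * np.eye(3)
    return StressState(sigma=sigma, lam_mult=float(lam))


def biaxial_stresses(law: str, params: LawParams, lambda1, lambda2, as_printed: bool = False):
    """Plane-stress biaxial stresses ``(sigma11, sigma22)`` in kPa, vectorised.

    Closed form for ``F = diag(l1, l2, 1/(l1 l2))`` with the fiber on
    axis 1 and the multiplier eliminated via ``sigma_33 = 0``; identical
    to :func:`cauchy_stress` point by point.
    """
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("stretches must be positive")
    l3sq = 1.0 / (l1 * l2) ** 2
    I1 = l1**2 + l2**2 + l3sq
    I4 = l1**2
    _, psi1, psi4 = energy_derivatives(law, params, I1, I4, as_printed=as_printed)
    s11 = 2.0 * psi1 * (l1**2 - l3sq) + 2.0 * psi4 * l1**2
    s22 = 2.0 * psi1 * (l2**2 - l3sq)
    return s11, s22


def uniaxial_stress(law: str, params: LawParams, lam, as_printed: bool = False):
    """Uniaxial Cauchy stress ``sigma11`` in kPa, vectorised over ``lam``."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretches must be positive")
    I1 = lam**2 + 2.0 / lam
    I4 = lam**2
    _, psi1, psi4 = energy_derivatives(law, params, I1, I4, as_printed=as_printed)
    return 2.0 * psi1 * (lam**2 - 1.0 / lam) + 2.0 * psi4 * lam**2


def stress_stretch_curve(law: str, params: LawParams, protocol: StretchProtocol):
    """Evaluate a law along a protocol, returning a :class:`StretchStressDataset`.

    Biaxial protocols yield ``(sigma11, sigma22)`` per point; uniaxial
    protocols yield ``sigma11`` only.
    """
    from .datasets import StretchStressDataset  # local import to avoid a cycle

    if protocol.mode == "biaxial":
        if law in CHORDAE_LAWS:
            raise ValueError(f"{law} is a chordae law; use a uniaxial protocol")
        l1 = np.concatenate([p[:, 0] for p in protocol.paths])
        l2 = np.concatenate([p[:, 1] for p in protocol.paths])
        s11, s22 = biaxial_stresses(law, params, l1, l2)
        return StretchStressDataset.biaxial(
            l1, l2, s11, s22, metadata={"law": law, "source": "synthetic"}
        )
    lam = np.concatenate(list(protocol.paths))
    s = uniaxial_stress(law, params, lam)
    return StretchStressDataset.uniaxial(lam, s, metadata={"law": law, "source": "synthetic"})
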