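"""Synthetic stand-ins for biaxial leaflet and uniaxial chordae tests.

No public stretch–stress data exist for the porcine experiments this
package models (planar biaxial leaflet tests to ~1.5 N and uniaxial
chordae tests to ~5 N), so this module emulates them in stress–stretch
space: a stretch-controlled protocol, a ground-truth constitutive law,
and a declared noise model.

Noise is applied to stress only — stretch is the controlled variable in
both rigs — and only the post-preconditioning loading curve is produced
(cyclic preconditioning is not simulated).  Supported noise models:

* ``none`` — the exact constitutive curve;
* ``additive_gaussian`` — i.i.d. N(0, sigma_noise^2) kPa per stress value;
* ``proportional_gaussian`` — each stress multiplied by (1 + cv*N(0,1)).

Every generated dataset records its seed, truth law and noise model in
the metadata sidecar, so any file on disk is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from . import laws
from .datasets import StretchStressDataset
from .kinematics import (
    StretchProtocol,
    default_chordae_protocol,
    default_leaflet_protocol,
)
from .laws import LawParams

__all__ = [
    "NoiseModel",
    "ExperimentConfig",
    "generate_leaflet_experiment",
    "generate_chordae_experiment",
    "generate_experiment",
]

_LEAFLET_TISSUES = ("leaflet_anterior", "leaflet_posterior")


@dataclass(frozen=True)
class NoiseModel:
    """Stress-noise specification: kind + magnitude."""

    kind: str = "none"  # none | additive_gaussian | proportional_gaussian
    sigma_noise: float = 0.0  # kPa, additive_gaussian
    cv: float = 0.0  # coefficient of variation, proportional_gaussian

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive_gaussian", "proportional_gaussian"):
            raise ValueError(f"unknown noise model {self.kind!r}")
        if self.sigma_noise < 0.0 or self.cv < 0.0:
            raise ValueError("noise magnitudes must be >= 0")

    def apply(self, sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return sigma
        if self.kind == "additive_gaussian":
            return sigma + self.sigma_noise * rng.standard_normal(sigma.shape)
        return sigma * (1.0 + self.cv * rng.standard_normal(sigma.shape))


@dataclass(frozen=True)
class ExperimentConfig:
    """One emulated experiment: tissue, truth, protocol, noise, seed."""

    tissue: str  # leaflet_anterior | leaflet_posterior | chordae
    truth_law: str
    truth_params: LawParams
    protocol: StretchProtocol | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.tissue not in _LEAFLET_TISSUES + ("chordae",):
            raise ValueError(f"unknown tissue {self.tissue!r}")
        is_leaflet = self.tissue in _LEAFLET_TISSUES
        if is_leaflet and self.truth_law not in laws.LEAFLET_LAWS:
            raise ValueError(f"tissue {self.tissue!r} needs a leaflet law, got {self.truth_law!r}")
        if not is_leaflet and self.truth_law not in laws.CHORDAE_LAWS:
            raise ValueError(f"tissue 'chordae' needs a chordae law, got {self.truth_law!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def resolved_protocol(self) -> StretchProtocol:
        if self.protocol is not None:
            return self.protocol
        if self.tissue == "chordae":
            return default_chordae_protocol()
        return default_leaflet_protocol()


def _generate(config: ExperimentConfig) -> StretchStressDataset:
    protocol = config.resolved_protocol()
    clean = laws.stress_stretch_curve(config.truth_law, config.truth_params, protocol)
    rng = np.random.default_rng(config.seed)
    frames = []
    reps = []
    for r in range(config.n_replicates):
        sig = config.noise.apply(clean.stresses, rng)
        frames.append(sig)
        reps.append(np.full(len(clean), r, dtype=int))
    sig_all = np.concatenate(frames, axis=0)
    rep = np.concatenate(reps)
    meta = {
        "tissue": config.tissue,
        "truth_law": config.truth_law,
        "truth_params": {k: float(v) for k, v in asdict(config.truth_params).items()},
        "noise": asdict(config.noise),
        "seed": int(config.seed),
        "n_replicates": int(config.n_replicates),
        "protocol_mode": protocol.mode,
        "source": "synthetic",
    }
    if clean.mode == "biaxial":
        lam = np.tile(clean.stretches, (config.n_replicates, 1))
        return StretchStressDataset.biaxial(
            lam[:, 0], lam[:, 1], sig_all[:, 0], sig_all[:, 1], metadata=meta, replicate=rep
        )
    lam = np.tile(clean.stretches, config.n_replicates)
    return StretchStressDataset.uniaxial(lam, sig_all, metadata=meta, replicate=rep)


def generate_leaflet_experiment(config: ExperimentConfig) -> StretchStressDataset:
    """Emulated planar-biaxial leaflet test (noise on stress only)."""
    if config.tissue not in _LEAFLET_TISSUES:
        raise ValueError(f"generate_leaflet_experiment needs a leaflet tissue, got {config.tissue!r}")
    return _generate(config)


def generate_chordae_experiment(config: ExperimentConfig) -> StretchStressDataset:
    """Emulated uniaxial chordae test (noise on stress only)."""
    if config.tissue != "chordae":
        raise ValueError(f"generate_chordae_experiment needs tissue='chordae', got {config.tissue!r}")
    return _generate(config)


def generate_experiment(config: ExperimentConfig) -> StretchStressDataset:
    """Dispatch on tissue type."""
    if config.tissue == "chordae":
        return generate_chordae_experiment(config)
    return generate_leaflet_experiment(config)
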