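"""YAML pipeline configuration.

One structured-text file configures the whole pipeline: which stage to
run, seeds, law identifiers, protocol ranges, optimizer settings and the
simulation setup.  Every command writes its *resolved* configuration
snapshot next to its outputs, so any artifact on disk is reproducible
from the snapshot plus the recorded seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import laws
from .fitting import FitConfig
from .kinematics import (
    StretchProtocol,
    default_chordae_protocol,
    default_leaflet_protocol,
)
from .synthetic import ExperimentConfig, NoiseModel
from .ibfe.demo import ValveDemoConfig
from .ibfe.waveform import PressureWaveform, default_mitral_waveform

__all__ = [
    "load_config",
    "dump_config",
    "protocol_from_config",
    "experiment_from_config",
    "fit_config_from_config",
    "demo_config_from_config",
]


def load_config(path: str | Path) -> dict[str, Any]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return doc


def dump_config(doc: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def protocol_from_config(doc: dict[str, Any] | None, tissue: str) -> StretchProtocol:
    """Build a protocol from a config section (or defaults by tissue)."""
    if not doc:
        return default_chordae_protocol() if tissue == "chordae" else default_leaflet_protocol()
    mode = doc.get("mode", "uniaxial" if tissue == "chordae" else "biaxial")
    lam_max = float(doc.get("lam_max", 1.10 if tissue == "chordae" else 1.40))
    n_points = int(doc.get("n_points", 50 if tissue == "chordae" else 30))
    if "paths" in doc:
        return StretchProtocol(mode, [np.asarray(p, dtype=float) for p in doc["paths"]])
    if mode == "uniaxial":
        return default_chordae_protocol(lam_max, n_points)
    return default_leaflet_protocol(lam_max, n_points)


def _params_from(doc: dict[str, Any], law: str, tissue: str):
    if "params" in doc:
        vals = doc["params"]
        if isinstance(vals, dict):
            return laws.make_params(law, [vals[f] for f in
                                          [fl.name for fl in
                                           laws._PARAM_TYPES[law].__dataclass_fields__.values()]])
        return laws.make_params(law, vals)
    t = "posterior" if "posterior" in tissue else ("chordae" if tissue == "chordae" else "anterior")
    return laws.default_params(law, t)


def experiment_from_config(doc: dict[str, Any]) -> ExperimentConfig:
    """Section ``generate:`` -> :class:`ExperimentConfig`."""
    tissue = doc.get("tissue", "leaflet_anterior")
    law = doc.get("truth_law", "chordae_exp" if tissue == "chordae" else "M1")
    noise_doc = doc.get("noise", {}) or {}
    noise = NoiseModel(
        kind=noise_doc.get("kind", "none"),
        sigma_noise=float(noise_doc.get("sigma_noise", 0.0)),
        cv=float(noise_doc.get("cv", 0.0)),
    )
    return ExperimentConfig(
        tissue=tissue,
        truth_law=law,
        truth_params=_params_from(doc, law, tissue),
        protocol=protocol_from_config(doc.get("protocol"), tissue),
        noise=noise,
        seed=int(doc.get("seed", 0)),
        n_replicates=int(doc.get("n_replicates", 1)),
    )


def fit_config_from_config(doc: dict[str, Any]) -> FitConfig:
    """Section ``fit:`` -> :class:`FitConfig`."""
    return FitConfig(
        lower_bounds=doc.get("lower_bounds", 1e-6),
        n_starts=int(doc.get("n_starts", 20)),
        seed=int(doc.get("seed", 0)),
        start_range=tuple(doc.get("start_range", (1e-3, 1e3))),
        tolerance=float(doc.get("tolerance", 1e-12)),
        max_nfev=int(doc.get("max_nfev", 2000)),
    )


def demo_config_from_config(doc: dict[str, Any]) -> ValveDemoConfig:
    """Section ``simulate:`` -> :class:`ValveDemoConfig`."""
    kwargs: dict[str, Any] = {}
    simple = [
        "nx", "ny", "lx", "ly", "rho", "mu", "stiffness_scale",
        "leaflet_thickness", "n_leaflet_nodes", "attach_x", "tip_dx",
        "tip_gap", "bending_stiffness", "target_stiffness", "use_tethers",
        "chordae_area", "chordae_slack", "t_end", "cfl", "struct_safety",
        "dt_max", "dt_min", "sample_dt", "snapshot_every", "flux_station",
    ]
    for key in simple:
        if key in doc:
            kwargs[key] = doc[key]
    law = doc.get("law", "M1")
    kwargs["law"] = law
    kwargs["params"] = _params_from(doc, law, doc.get("tissue", "anterior"))
    if "chordae_law" in doc or "chordae_params" in doc:
        claw = doc.get("chordae_law", "chordae_exp")
        kwargs["chordae_law"] = claw
        kwargs["chordae_params"] = _params_from(
            {"params": doc["chordae_params"]} if "chordae_params" in doc else {},
            claw, "chordae",
        )
    if "waveform" in doc:
        kwargs["waveform"] = PressureWaveform(doc["waveform"])
    else:
        kwargs["waveform"] = default_mitral_waveform()
    return ValveDemoConfig(**kwargs)
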