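"""Stretch–stress datasets: the currency of the inverse problem.

A :class:`StretchStressDataset` wraps a :class:`pandas.DataFrame` of
observed (stretch, Cauchy stress) rows from a biaxial leaflet test
(columns ``lambda1, lambda2, sigma11_kPa, sigma22_kPa``) or a uniaxial
chordae test (columns ``lambda, sigma_kPa``), plus free-form metadata
(specimen label, protocol, source, generator seed, ...).

On disk a dataset is a plain CSV with those headers and a YAML sidecar
``<name>.meta.yaml`` holding the metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = ["StretchStressDataset", "BIAXIAL_COLUMNS", "UNIAXIAL_COLUMNS"]

BIAXIAL_COLUMNS = ["lambda1", "lambda2", "sigma11_kPa", "sigma22_kPa"]
UNIAXIAL_COLUMNS = ["lambda", "sigma_kPa"]


@dataclass(frozen=True)
class StretchStressDataset:
    """Observed stretch–stress rows plus metadata.

    Use the :meth:`biaxial` / :meth:`uniaxial` constructors rather than
    building the frame by hand.
    """

    frame: pd.DataFrame
    mode: str  # "biaxial" | "uniaxial"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = BIAXIAL_COLUMNS if self.mode == "biaxial" else UNIAXIAL_COLUMNS
        if self.mode not in ("biaxial", "uniaxial"):
            raise ValueError(f"unknown dataset mode {self.mode!r}")
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if len(self.frame) < 1:
            raise ValueError("dataset needs at least one row")
        stretch_cols = cols[:2] if self.mode == "biaxial" else cols[:1]
        for c in stretch_cols:
            if np.any(self.frame[c].to_numpy() < 1.0 - 1e-12):
                raise ValueError(f"column {c}: stretches must be >= 1")
        if not np.all(np.isfinite(self.frame[cols].to_numpy())):
            raise ValueError("dataset contains non-finite values")

    # -- constructors -------------------------------------------------
    @classmethod
    def biaxial(cls, lambda1, lambda2, sigma11, sigma22,
                metadata: Mapping[str, Any] | None = None,
                replicate=None) -> "StretchStressDataset":
        data = {
            "lambda1": np.asarray(lambda1, dtype=float),
            "lambda2": np.asarray(lambda2, dtype=float),
            "sigma11_kPa": np.asarray(sigma11, dtype=float),
            "sigma22_kPa": np.asarray(sigma22, dtype=float),
        }
        if replicate is not None:
            data["replicate"] = np.asarray(replicate, dtype=int)
        return cls(pd.DataFrame(data), "biaxial", dict(metadata or {}))

    @classmethod
    def uniaxial(cls, lam, sigma, metadata: Mapping[str, Any] | None = None,
                 replicate=None) -> "StretchStressDataset":
        data = {
            "lambda": np.asarray(lam, dtype=float),
            "sigma_kPa": np.asarray(sigma, dtype=float),
        }
        if replicate is not None:
            data["replicate"] = np.asarray(replicate, dtype=int)
        return cls(pd.DataFrame(data), "uniaxial", dict(metadata or {}))

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def stretches(self) -> np.ndarray:
        """(n, 2) array (lambda1, lambda2) for biaxial, (n,) for uniaxial."""
        if self.mode == "biaxial":
            return self.frame[["lambda1", "lambda2"]].to_numpy()
        return self.frame["lambda"].to_numpy()

    @property
    def stresses(self) -> np.ndarray:
        """(n, 2) observed stresses for biaxial, (n,) for uniaxial (kPa)."""
        if self.mode == "biaxial":
            return self.frame[["sigma11_kPa", "sigma22_kPa"]].to_numpy()
        return self.frame["sigma_kPa"].to_numpy()

    # -- file I/O -----------------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        """Write the data CSV plus a ``<name>.meta.yaml`` sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index=False)
        meta = dict(self.metadata)
        meta["mode"] = self.mode
        sidecar = path.with_suffix(".meta.yaml")
        sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "StretchStressDataset":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = path.with_suffix(".meta.yaml")
        metadata: dict[str, Any] = {}
        if sidecar.exists():
            metadata = yaml.safe_load(sidecar.read_text()) or {}
        mode = metadata.pop("mode", None)
        if mode is None:
            mode = "biaxial" if "lambda1" in frame.columns else "uniaxial"
        return cls(frame, mode, metadata)
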