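"""Inverse estimation of constitutive parameters from stretch–stress data.

The inverse problem is a bound-constrained least-squares fit: minimise

    sum_rows [ (sigma11_model - sigma11_exp)^2 + (sigma22_model - sigma22_exp)^2 ]

over the non-negative material parameters (the sigma22 term is dropped for
uniaxial data), subject to lower bounds ``params >= g`` (default 1e-6).
Local solves use :func:`scipy.optimize.least_squares` (trust-region
reflective) launched from ``n_starts`` seeded log-uniform initial points;
exponential laws make the objective non-convex, and the multi-start guards
against spurious local minima.  The best start by objective wins, so the
result is deterministic given ``(dataset, config)``.

Goodness of fit is reported per stress component as ``R^2 = 1 - SSE/SST``
with SST about the component mean, plus a mean-absolute-residual
"average error" in kPa (an interpretation — there is no canonical
definition — and never used as a pass/fail quantity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from scipy.optimize import least_squares

from . import laws
from .datasets import StretchStressDataset
from .kinematics import StretchProtocol
from .laws import LawParams, make_params, n_params, params_to_array

__all__ = [
    "FitConfig",
    "FitResult",
    "DegenerateProblemError",
    "ConvergenceError",
    "objective",
    "predict",
    "generate_pseudo_data",
    "fit_law",
    "r_squared",
    "average_error",
]


class DegenerateProblemError(ValueError):
    """Fewer data rows than free parameters."""


class ConvergenceError(RuntimeError):
    """No multi-start local solve converged."""


@dataclass(frozen=True)
class FitConfig:
    """Optimizer configuration.

    Parameters
    ----------
    lower_bounds : float or array
        Lower bound(s) ``g`` on the parameters (non-negativity with a
        small margin by default).
    n_starts : int
        Number of seeded log-uniform multi-start initial points.
    seed : int
        Seed for the start-point generator.
    start_range : (float, float)
        Log-uniform sampling range for initial points.
    tolerance : float
        ``ftol``/``xtol``/``gtol`` passed to the local solver.
    """

    lower_bounds: float | np.ndarray = 1e-6
    n_starts: int = 20
    seed: int = 0
    start_range: tuple[float, float] = (1e-3, 1e3)
    upper_bound: float = 1e9
    tolerance: float = 1e-12
    max_nfev: int = 2000

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        lb = np.asarray(self.lower_bounds, dtype=float)
        if np.any(lb < 0.0):
            raise ValueError("lower bounds must be non-negative")


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_law`."""

    law: str
    params: LawParams
    objective: float  # kPa^2
    r2_fiber: float
    r2_crossfiber: float | None
    average_error: float  # kPa
    n_starts_converged: int
    best_start: int
    config: FitConfig = field(repr=False)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        doc: dict[str, Any] = {
            "law": self.law,
            "params": {k: float(v) for k, v in asdict(self.params).items()},
            "objective_kPa2": float(self.objective),
            "r2_fiber": float(self.r2_fiber),
            "r2_crossfiber": None if self.r2_crossfiber is None else float(self.r2_crossfiber),
            "average_error_kPa": float(self.average_error),
            "n_starts_converged": int(self.n_starts_converged),
            "best_start": int(self.best_start),
            "config": {
                "lower_bounds": np.asarray(self.config.lower_bounds).tolist(),
                "n_starts": self.config.n_starts,
                "seed": self.config.seed,
                "start_range": list(self.config.start_range),
                "tolerance": self.config.tolerance,
                "max_nfev": self.config.max_nfev,
            },
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path


def predict(law: str, params: LawParams, dataset: StretchStressDataset) -> np.ndarray:
    """Model stresses at the dataset's stretches: (n, 2) biaxial, (n,) uniaxial."""
    if dataset.mode == "biaxial":
        lam = dataset.stretches
        s11, s22 = laws.biaxial_stresses(law, params, lam[:, 0], lam[:, 1])
        return np.column_stack([s11, s22])
    return np.asarray(laws.uniaxial_stress(law, params, dataset.stretches))


def objective(params: LawParams | np.ndarray, law: str, dataset: StretchStressDataset) -> float:
    """Sum of squared stress residuals (kPa^2) over all fitted components."""
    if not hasattr(params, "__dataclass_fields__"):
        params = make_params(law, params)
    r = predict(law, params, dataset) - dataset.stresses
    return float(np.sum(r * r))


def generate_pseudo_data(
    m1_params: laws.LeafletParamsM1, protocol: StretchProtocol
) -> StretchStressDataset:
    """Noiseless pseudo-biaxial dataset generated from the M1 law.

    This is the cross-law calibration route: M2/M3 parameters are
    determined by fitting them to M1-generated curves.
    """
    ds = laws.stress_stretch_curve("M1", m1_params, protocol)
    ds.metadata.update(
        {"generator": "generate_pseudo_data", "truth_params": asdict(m1_params)}
    )
    return ds


def _residual_fn(law: str, dataset: StretchStressDataset):
    obs = dataset.stresses.ravel()
    if dataset.mode == "biaxial":
        lam = dataset.stretches
        l1, l2 = lam[:, 0], lam[:, 1]

        def resid(x):
            with np.errstate(over="ignore", invalid="ignore"):
                s11, s22 = laws.biaxial_stresses(law, make_params(law, x), l1, l2)
                r = np.column_stack([s11, s22]).ravel() - obs
            return np.nan_to_num(r, nan=1e8, posinf=1e8, neginf=-1e8)

    else:
        lam = dataset.stretches

        def resid(x):
            with np.errstate(over="ignore", invalid="ignore"):
                r = np.asarray(laws.uniaxial_stress(law, make_params(law, x), lam)) - obs
            return np.nan_to_num(r, nan=1e8, posinf=1e8, neginf=-1e8)

    return resid


def fit_law(law: str, dataset: StretchStressDataset, config: FitConfig | None = None) -> FitResult:
    """Fit a constitutive law to a dataset by seeded multi-start least squares.

    Raises
    ------
    DegenerateProblemError
        If the dataset has fewer rows than the law has parameters.
    ConvergenceError
        If no start converges.
    """
    config = config or FitConfig()
    k = n_params(law)
    if len(dataset) < k:
        raise DegenerateProblemError(
            f"{len(dataset)} rows cannot identify {k} parameters of {law}"
        )
    if (dataset.mode == "uniaxial") != (law in laws.CHORDAE_LAWS):
        # leaflet laws need biaxial data and vice versa
        raise ValueError(f"law {law!r} does not match dataset mode {dataset.mode!r}")

    lb = np.broadcast_to(np.asarray(config.lower_bounds, dtype=float), (k,)).copy()
    resid = _residual_fn(law, dataset)

    # Optimize in log-parameter space: the non-negativity bounds become box
    # bounds on z = log(params), and the exponential laws' wildly different
    # parameter scales are equalized.
    zlb = np.log(np.maximum(lb, 1e-12))
    zub = np.full(k, np.log(config.upper_bound))
    rng = np.random.default_rng(config.seed)
    lo, hi = config.start_range
    zstarts = rng.uniform(np.log(lo), np.log(hi), size=(config.n_starts, k))
    zstarts = np.clip(zstarts, zlb + 1e-9, zub - 1e-9)

    def zresid(z):
        return resid(np.exp(z))

    best = None
    best_idx = -1
    n_conv = 0
    import warnings as _warnings

    for i, z0 in enumerate(zstarts):
        try:
            with _warnings.catch_warnings():
                # trf emits benign overflow warnings while probing the
                # exponential laws' steep regions
                _warnings.simplefilter("ignore", RuntimeWarning)
                sol = least_squares(
                    zresid, z0, bounds=(zlb, zub), method="trf", x_scale="jac",
                    ftol=config.tolerance, xtol=config.tolerance,
                    gtol=config.tolerance, max_nfev=config.max_nfev,
                )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_conv += 1
        if best is None or sol.cost < best.cost:
            best = sol
            best_idx = i
    if best is None:
        raise ConvergenceError(
            f"all {config.n_starts} starts failed for law {law!r} "
            f"(n_rows={len(dataset)}, seed={config.seed})"
        )

    params = make_params(law, np.exp(best.x))
    pred = predict(law, params, dataset)
    obs = dataset.stresses
    if dataset.mode == "biaxial":
        r2f = r_squared(obs[:, 0], pred[:, 0])
        r2c = r_squared(obs[:, 1], pred[:, 1])
    else:
        r2f = r_squared(obs, pred)
        r2c = None
    return FitResult(
        law=law,
        params=params,
        objective=float(2.0 * best.cost),  # least_squares cost = 0.5 * SSE
        r2_fiber=r2f,
        r2_crossfiber=r2c,
        average_error=average_error(obs, pred),
        n_starts_converged=n_conv,
        best_start=best_idx,
        config=config,
    )


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SSE/SST`` for one stress component.

    SST is the total sum of squares about the observation mean; the value
    can be negative for fits worse than the mean.  Raises for constant
    observations (SST = 0).
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have matching lengths")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: observations are constant (SST = 0)")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def average_error(observed, predicted) -> float:
    """Mean absolute stress residual (kPa) across all fitted components."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have matching lengths")
    return float(np.mean(np.abs(obs - pred)))
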