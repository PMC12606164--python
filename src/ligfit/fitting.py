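"""Material-parameter identification under the fixed-mu coefficient policy.

The initial shear modulus mu of the ground matrix is prescribed (hydrated
ground substance is soft; mu is not identifiable from a fiber-dominated
uniaxial test), which fixes C10 (NH, Yeoh) or the pair C10/C01 (MR).  The
remaining coefficients are found by bounded least squares on the uniaxial
first Piola-Kirchhoff stress over a uniform stretch grid up to the II
transition point, with every free coefficient bounded below by 0.001 MPa.

The optimizer is multistart trust-region-reflective nonlinear least
squares (log-spaced, seed-deterministic initial values); the contract is
the minimized objective, the bounds and determinism under a seed, not a
particular solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

from .constitutive import (
    COEFFICIENT_FLOOR,
    MR_C10_PRESCRIBED,
    ConfigurationError,
    MaterialParameters,
    MatrixKind,
    uniaxial_first_PK,
)
from .curves import AveragedCurve, StressStretchCurve

__all__ = ["FitSpec", "FitResult", "fixed_mu_coefficients", "fit_model", "rmse"]

#: free-coefficient names per matrix law (fiber coefficients always free)
_FREE = {
    MatrixKind.NH: ("C4", "C5"),
    MatrixKind.MR: ("C4", "C5"),
    MatrixKind.YEOH: ("C20", "C30", "C4", "C5"),
}


@dataclass(frozen=True)
class FitSpec:
    """Configuration of one identification run."""

    matrix_kind: MatrixKind
    mu: float  # MPa, prescribed initial shear modulus
    lam_fit_max: float  # fit up to this stretch (typically lambda_II)
    n_samples: int = 100
    starts: int = 8
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "matrix_kind", MatrixKind(self.matrix_kind))
        if self.mu <= 0:
            raise ConfigurationError("mu must be positive")
        if self.lam_fit_max <= 1:
            raise ConfigurationError("lam_fit_max must exceed 1")
        if self.n_samples < 20:
            raise ConfigurationError("n_samples must be >= 20")


@dataclass(frozen=True)
class FitResult:
    params: MaterialParameters
    rmse: float  # MPa
    converged: bool
    active_bounds: tuple[str, ...] = ()

    def to_record(self, ligament: str = "") -> dict:
        p = self.params
        return {
            "ligament": ligament,
            "matrix_kind": p.matrix_kind.value,
            "mu": p.mu,
            "coefficients": {
                "C10": p.C10, "C01": p.C01, "C20": p.C20, "C30": p.C30,
                "C4": p.C4, "C5": p.C5,
            },
            "rmse_mpa": self.rmse,
            "converged": self.converged,
        }


def fixed_mu_coefficients(matrix_kind: MatrixKind | str, mu: float) -> dict[str, float]:
    """Prescribed low-order matrix coefficients implied by the shear modulus.

    NH/Yeoh: ``C10 = mu/2``.  MR: ``C10`` is a-priori reduced to 0.0005 MPa
    so the second-invariant term dominates, and ``C01 = mu/2 - C10``.
    """
    matrix_kind = MatrixKind(matrix_kind)
    if mu <= 0:
        raise ConfigurationError("mu must be positive")
    if matrix_kind is MatrixKind.MR:
        c01 = mu / 2 - MR_C10_PRESCRIBED
        if c01 <= 0:
            raise ConfigurationError(
                f"MR requires mu > {2 * MR_C10_PRESCRIBED} MPa (C01 would be <= 0)"
            )
        return {"C10": MR_C10_PRESCRIBED, "C01": c01}
    return {"C10": mu / 2}


def _make_params(spec: FitSpec, free: np.ndarray,
                 validate: bool = True) -> MaterialParameters:
    kw = dict(zip(_FREE[spec.matrix_kind], free))
    kw.update(fixed_mu_coefficients(spec.matrix_kind, spec.mu))
    return MaterialParameters(matrix_kind=spec.matrix_kind, mu=spec.mu,
                              validate=validate, **kw)


def _target_on_grid(target, lam: np.ndarray) -> np.ndarray:
    """Evaluate a fit target (averaged curve, raw curve or callable) on a grid."""
    if isinstance(target, AveragedCurve):
        return np.asarray(target(lam), dtype=float)
    if isinstance(target, StressStretchCurve):
        return np.interp(lam, target.lam, target.P)
    if callable(target):
        return np.asarray(target(lam), dtype=float)
    raise TypeError(f"cannot evaluate fit target of type {type(target)!r}")


def fit_model(target, spec: FitSpec) -> FitResult:
    """Identify the free coefficients by bounded multistart least squares.

    Minimizes the sum of squared residuals between the closed-form uniaxial
    stress of the candidate law and the target on ``n_samples`` uniform
    stretch points in ``[1, lam_fit_max]``; free coefficients are bounded to
    ``[0.001, inf)`` MPa.  Initial values are log-spaced over [0.01, 10] MPa
    with seed-deterministic jitter; the best final objective wins (ties go
    to the earlier start).  Optimizer failure on every start yields a
    flagged non-converged result, not an exception.
    """
    lam = np.linspace(1.0, spec.lam_fit_max, spec.n_samples)
    P_target = _target_on_grid(target, lam)
    names = _FREE[spec.matrix_kind]
    nfree = len(names)

    def residuals(free):
        params = _make_params(spec, free, validate=False)
        return np.asarray(uniaxial_first_PK(params, lam)) - P_target

    rng = np.random.default_rng(spec.seed)
    base = np.geomspace(0.01, 10.0, spec.starts)
    best = None
    for i, b in enumerate(base):
        x0 = np.full(nfree, b)
        if i > 0:  # first start is deterministic mid-scale; others jittered
            x0 = x0 * np.exp(rng.normal(0.0, 0.3, nfree))
        x0 = np.maximum(x0, COEFFICIENT_FLOOR)
        try:
            sol = least_squares(residuals, x0, bounds=(COEFFICIENT_FLOOR, np.inf),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        params = _make_params(spec, np.full(nfree, COEFFICIENT_FLOOR))
        return FitResult(params, float("inf"), converged=False)
    params = _make_params(spec, best.x)
    err = float(np.sqrt(np.mean(best.fun**2)))
    active = tuple(n for n, v in zip(names, best.x)
                   if v <= COEFFICIENT_FLOOR * (1 + 1e-6))
    return FitResult(params, err, converged=bool(best.success), active_bounds=active)


def rmse(params: MaterialParameters, target, lam_range: tuple[float, float],
         n_samples: int = 100) -> float:
    """Root-mean-square stress misfit (MPa) on a uniform stretch grid."""
    if n_samples < 1:
        raise ValueError("empty residual grid")
    lam = np.linspace(lam_range[0], lam_range[1], n_samples)
    P_target = _target_on_grid(target, lam)
    res = np.asarray(uniaxial_first_PK(params, lam)) - P_target
    return float(np.sqrt(np.mean(res**2)))
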