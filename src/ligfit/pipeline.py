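"""High-level workflows: reconstruct, fit, screen and simulate a ligament.

These helpers bind the pipeline stages together for the built-in ligament
registry: rebuild the averaged tensile curve from the cohort's mean
characteristic points, identify material parameters under the fixed-mu
policy, screen the fitted energy (C1 saddle-freedom, C2 fiber dominance)
and verify the law in the membrane tension simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import C1Report, C2Report, MaterialParameters, MatrixKind, check_C1, check_C2
from .curves import AveragedCurve, ToeForm, build_averaged_curve
from .fem import FEResult, build_mesh, postprocess, solve_tension
from .fitting import FitResult, FitSpec, fit_model
from .synthetic import LIGAMENTS, LigamentStats

__all__ = ["reconstruct_averaged_curve", "fit_ligament", "admissibility",
           "ligament_model", "simulate_ligament", "reproduce_ligament"]


def _stats(ligament: str | LigamentStats) -> LigamentStats:
    if isinstance(ligament, LigamentStats):
        return ligament
    try:
        return LIGAMENTS[ligament]
    except KeyError:
        raise KeyError(f"unknown ligament {ligament!r}; available: {sorted(LIGAMENTS)}")


def reconstruct_averaged_curve(ligament: str | LigamentStats,
                               toe_form: ToeForm | str = ToeForm.EXPONENTIAL,
                               ) -> AveragedCurve:
    """Averaged curve through the cohort's mean characteristic points."""
    return build_averaged_curve(_stats(ligament).mean_points(), toe_form)


def fit_ligament(ligament: str | LigamentStats, matrix_kind: MatrixKind | str,
                 mu: float = 1.0, toe_form: ToeForm | str = ToeForm.EXPONENTIAL,
                 seed: int = 0) -> FitResult:
    """Fixed-mu fit of one combined law to the reconstructed averaged curve.

    The residual grid runs up to the II transition point, as in the
    identification procedure (the subfailure phase is excluded).
    """
    stats = _stats(ligament)
    curve = reconstruct_averaged_curve(stats, toe_form)
    spec = FitSpec(matrix_kind=MatrixKind(matrix_kind), mu=mu,
                   lam_fit_max=stats.mean_points().ptII[0], seed=seed)
    return fit_model(curve, spec)


def admissibility(params: MaterialParameters, lam_max: float) -> tuple[C1Report, C2Report]:
    """C1 (saddle-free energy) and C2 (fiber dominance) over [1, lam_max]."""
    return check_C1(params, lam_max), check_C2(params, lam_max)


def ligament_model(ligament: str | LigamentStats, params: MaterialParameters,
                   element_size: float = 0.5, **bc_options):
    """Membrane model of a ligament sheet at its mean geometry.

    The membrane thickness is the effective value A0/b so that the
    cross-section equals the cohort's mean area A0 and the simulated
    reaction normalized by A0 is directly comparable with the closed-form
    engineering stress.
    """
    stats = _stats(ligament)
    g = stats.mean_geometry()
    return build_mesh(g.L0, g.b, element_size, thickness=g.A0 / g.b,
                      params=params, **bc_options)


def simulate_ligament(ligament: str | LigamentStats, params: MaterialParameters,
                      lam_target: float = 1.3, element_size: float = 0.5,
                      dlam: float = 0.01, **bc_options) -> dict:
    """Run the tension simulation and post-process the engineering curve."""
    stats = _stats(ligament)
    g = stats.mean_geometry()
    model = ligament_model(stats, params, element_size, **bc_options)
    result = solve_tension(model, lam_target, dlam=dlam)
    out = postprocess(result, A0=g.A0, L0=g.L0)
    out["result"] = result
    return out


def reproduce_ligament(ligament: str, matrix_kind: MatrixKind | str = MatrixKind.NH,
                       mu: float = 1.0, lam_target: float = 1.3,
                       toe_form: ToeForm | str = ToeForm.EXPONENTIAL,
                       element_size: float = 0.5, seed: int = 0) -> dict:
    """Full workflow: reconstruct -> fit -> admissibility -> FE verification."""
    stats = _stats(ligament)
    fit = fit_ligament(stats, matrix_kind, mu, toe_form, seed=seed)
    lam_II = stats.mean_points().ptII[0]
    c1, c2 = admissibility(fit.params, lam_II)
    sim = simulate_ligament(stats, fit.params, lam_target=lam_target,
                            element_size=element_size)
    from .constitutive import uniaxial_first_PK

    analytical = np.asarray(uniaxial_first_PK(fit.params, sim["lam"]))
    return {
        "ligament": stats.name,
        "fit": fit,
        "C1": c1,
        "C2": c2,
        "simulation": sim,
        "P_analytical": analytical,
    }
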