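"""Synthetic ligament tensile-test generator.

Emulates per-specimen stress-stretch curves of human thoracic spinal
ligaments with the published cohort statistics (mean +/- SD of geometry and
of the characteristic toe/linear/subfailure points) so that every pipeline
stage -- segmentation, averaging, fitting, finite-element verification --
can be exercised without access to the raw cadaveric data.

A specimen is drawn by sampling each characteristic-point coordinate and
each geometric dimension from an independent normal distribution truncated
(by rejection) to positivity, stretch/stress ordering and three-region
shape consistency.  Its curve is then a C1 piecewise reference function:
a saturating-exponential toe blending into the exact line through the two
transition points, followed by a softening quadratic to the failure point,
sampled on a uniform stretch grid with multiplicative Gaussian noise.

The generator reproduces the statistical structure of the published
tables, not raw machine output: no preconditioning cycles, strain-rate
effects or inter-coordinate correlations (none are published).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import MaterialParameters, uniaxial_first_PK
from .curves import CharacteristicPoints, StressStretchCurve

__all__ = [
    "LigamentStats",
    "Geometry",
    "GeneratorConfig",
    "GeneratorError",
    "LIGAMENTS",
    "sample_specimen",
    "specimen_curve",
    "model_curve",
    "generate_cohort",
]


class GeneratorError(RuntimeError):
    """Cohort statistics persistently inconsistent with the ordering rules."""


@dataclass(frozen=True)
class Geometry:
    """Reference geometry of one specimen (mm / mm^2)."""

    L0: float
    b: float
    t: float
    A0: float


@dataclass(frozen=True)
class LigamentStats:
    """Cohort statistics (mean, SD) for one ligament group."""

    name: str
    n: int
    L0: tuple[float, float]
    b: tuple[float, float]
    t: tuple[float, float]
    A0: tuple[float, float]
    ptI: tuple[tuple[float, float], tuple[float, float]]   # (lam (m, sd), P (m, sd))
    ptII: tuple[tuple[float, float], tuple[float, float]]
    fail: tuple[tuple[float, float], tuple[float, float]]

    def mean_points(self) -> CharacteristicPoints:
        return CharacteristicPoints(
            (self.ptI[0][0], self.ptI[1][0]),
            (self.ptII[0][0], self.ptII[1][0]),
            (self.fail[0][0], self.fail[1][0]),
        )

    def mean_geometry(self) -> Geometry:
        return Geometry(self.L0[0], self.b[0], self.t[0], self.A0[0])


#: Reference cohort statistics (mean +/- SD) for the five thoracic
#: spinal ligament groups: anterior/posterior longitudinal (ALL, PLL),
#: capsular (CL), flavum (LF) and interspinous+supraspinous (ISL+SSL).
LIGAMENTS: dict[str, LigamentStats] = {
    s.name: s
    for s in [
        LigamentStats("ALL", 17, (7.38, 2.41), (9.42, 5.9), (0.97, 0.34), (17.21, 2.39),
                      ((1.16, 0.09), (5.9, 3.68)), ((1.35, 0.13), (17.22, 9.01)),
                      ((1.62, 0.32), (28.14, 12.26))),
        LigamentStats("PLL", 19, (8.83, 1.82), (12.0, 2.11), (1.73, 0.27), (20.56, 1.68),
                      ((1.08, 0.03), (3.4, 2.11)), ((1.17, 0.08), (9.39, 5.06)),
                      ((1.34, 0.2), (15.17, 9.55))),
        LigamentStats("CL", 31, (6.67, 0.99), (23.03, 5.67), (2.2, 0.52), (49.02, 7.44),
                      ((1.11, 0.07), (1.17, 0.92)), ((1.19, 0.1), (2.82, 1.64)),
                      ((1.29, 0.15), (4.1, 2.25))),
        LigamentStats("LF", 17, (9.94, 2.49), (12.92, 7.04), (4.48, 2.13), (46.1, 8.86),
                      ((1.19, 0.08), (2.57, 1.71)), ((1.25, 0.09), (5.3, 2.72)),
                      ((1.3, 0.09), (6.6, 3.41))),
        LigamentStats("ISL+SSL", 16, (10.65, 2.4), (10.36, 2.6), (1.49, 0.46), (14.46, 3.26),
                      ((1.25, 0.4), (2.88, 2.11)), ((1.32, 0.2), (10.23, 8.15)),
                      ((1.49, 0.27), (13.35, 9.35))),
    ]
}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_specimens: int | None = None  # default: the cohort's published n
    noise_sd_rel: float = 0.01      # multiplicative stress noise SD
    samples_per_curve: int = 200
    #: fraction of the interval between the origin-secant slope and the
    #: linear slope at which the toe meets the line (shape parameter)
    toe_slope_frac: float = 0.3
    #: softening-onset sharpness: fraction of the feasible slope drop taken
    #: abruptly at the II transition (micro-damage onset); the remainder is
    #: spread over the subfailure region as concave curvature
    sub_onset_frac: float = 0.85
    #: C1 toe-to-line blend window as a fraction of the stretch span
    blend_frac: float = 0.01
    #: equicorrelation of the six characteristic-point coordinates across a
    #: specimen (a stiff specimen is stiff throughout); marginal means/SDs
    #: are unchanged.  0 gives fully independent draws.
    point_correlation: float = 0.7

    def __post_init__(self):
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        if self.samples_per_curve < 50:
            raise ValueError("samples_per_curve must be >= 50")


def _shape_consistent(pts: CharacteristicPoints, margin: float = 0.85) -> bool:
    """Three-region consistency: the linear region is clearly the stiffest.

    The origin-to-I secant (toe) and the II-to-failure secant (subfailure)
    must both stay below ``margin`` of the linear-region slope, so the
    specimen has a discernible toe / linear / subfailure structure rather
    than three nearly collinear phases.
    """
    (lI, pI), (lII, pII), (lf, pf) = pts.ptI, pts.ptII, pts.fail
    m = (pII - pI) / (lII - lI)                # linear-region slope
    return pI / (lI - 1.0) < margin * m and (pf - pII) / (lf - lII) < margin * m


def sample_specimen(stats: LigamentStats, rng: np.random.Generator,
                    max_redraws: int = 100, point_correlation: float = 0.7,
                    ) -> tuple[CharacteristicPoints, Geometry]:
    """Draw one specimen's characteristic points and geometry.

    Each coordinate is a normal draw with the cohort mean/SD; the six
    characteristic-point coordinates share an equicorrelation
    ``point_correlation`` (stiff specimens are stiff throughout -- the
    marginal means and SDs are unaffected).  Draws violating positivity,
    the stretch/stress ordering (1 < lam_I < lam_II < lam_fail,
    0 < P_I < P_II < P_fail) or the three-region shape-consistency rule
    are rejected and redrawn, up to ``max_redraws`` times.
    """
    rho = float(np.clip(point_correlation, 0.0, 0.999))
    means = np.array([stats.ptI[0][0], stats.ptI[1][0], stats.ptII[0][0],
                      stats.ptII[1][0], stats.fail[0][0], stats.fail[1][0]])
    sds = np.array([stats.ptI[0][1], stats.ptI[1][1], stats.ptII[0][1],
                    stats.ptII[1][1], stats.fail[0][1], stats.fail[1][1]])
    for _ in range(max_redraws):
        z = np.sqrt(rho) * rng.standard_normal() + np.sqrt(1 - rho) * rng.standard_normal(6)
        vals = means + sds * z
        lI, pI, lII, pII, lf, pf = vals
        if not (1.0 < lI < lII < lf and 0.0 < pI < pII < pf):
            continue
        pts = CharacteristicPoints((lI, pI), (lII, pII), (lf, pf))
        if not _shape_consistent(pts):
            continue
        geom_vals = rng.normal(
            [stats.L0[0], stats.b[0], stats.t[0], stats.A0[0]],
            [stats.L0[1], stats.b[1], stats.t[1], stats.A0[1]],
        )
        if np.any(geom_vals <= 0):
            continue
        return pts, Geometry(*geom_vals)
    raise GeneratorError(
        f"no admissible draw for {stats.name} after {max_redraws} attempts"
    )


def _reference_function(points: CharacteristicPoints, cfg: GeneratorConfig):
    """Piecewise toe / linear / subfailure reference curve as a callable.

    Toe: exponential through the origin and point I whose end slope is a
    fraction of the way from the origin secant to the linear slope, blended
    C1 into the exact I-II line over a short window before point I.
    Subfailure: a concave quadratic to the failure point with an abrupt
    slope drop at the II transition (softening onset).  The sharp onset
    keeps the extracted linear region from bleeding into the subfailure
    phase; the residual concave curvature marks the region as non-linear.
    """
    from scipy.optimize import brentq

    (lI, pI), (lII, pII), (lf, pf) = points.ptI, points.ptII, points.fail
    m = (pII - pI) / (lII - lI)
    s0 = pI / (lI - 1.0)
    # toe exponential with prescribed end slope between s0 and m
    target = s0 + cfg.toe_slope_frac * (m - s0)

    xI = lI - 1.0

    def slope_of_B(B):
        t = B * xI
        if t > 500.0:  # asymptote: pI * B
            return pI * B
        return pI * B * np.exp(t) / np.expm1(t)

    lo, hi = 1e-8, 1.0
    while slope_of_B(hi) < target:
        hi *= 2.0
    B = brentq(lambda B: slope_of_B(B) - target, lo, hi, xtol=1e-13)

    def toe_eval(lam):
        # pI * expm1(B (lam-1)) / expm1(B xI), stable for large B:
        # = pI * exp(B (lam - lI)) * (1 - e^{-B(lam-1)}) / (1 - e^{-B xI})
        s = np.asarray(lam, dtype=float) - 1.0
        # exponent clamped at 0: values beyond point I are never used
        return pI * np.exp(B * np.minimum(s - xI, 0.0)) * (
            -np.expm1(-B * np.maximum(s, 0.0))) / -np.expm1(-B * xI)

    # subfailure: concave quadratic through the failure point whose entry
    # slope drops abruptly at the II transition (softening onset).  The
    # slope drop is sub_onset_frac of the feasible range: eta interpolates
    # between the linear slope m (no kink) and the II->failure secant slope
    # (all softening at onset, straight afterwards); it is clamped so the
    # stress still peaks at the failure point.
    D = lf - lII
    r = (pf - pII) / (D * m)  # secant ratio, < 1 by shape-consistent sampling
    eta = min(r + (1.0 - cfg.sub_onset_frac) * (1.0 - r), 2.0 * r)
    c = (pf - pII - eta * m * D) / D**2

    w = cfg.blend_frac * (lf - 1.0)

    def f(lam):
        lam = np.asarray(lam, dtype=float)
        toe = toe_eval(lam)
        line = pI + m * (lam - lI)
        d = lam - lII
        sub = pII + eta * m * d + c * d * d
        # smoothstep weight of the line over the blend window [lI - w, lI]
        t = np.clip((lam - (lI - w)) / w, 0.0, 1.0)
        sw = t * t * (3.0 - 2.0 * t)
        toe_blend = (1.0 - sw) * toe + sw * line
        out = np.where(lam < lI, toe_blend, np.where(lam <= lII, line, sub))
        return out

    return f


def specimen_curve(points: CharacteristicPoints, cfg: GeneratorConfig,
                   rng: np.random.Generator | None = None,
                   specimen_id: str = "", ligament: str = "") -> StressStretchCurve:
    """Sample the C1 reference function on a uniform grid and add noise.

    Multiplicative Gaussian noise ``P -> P (1 + N(0, noise_sd_rel))`` is
    applied to the stresses; the first sample is clamped to (1, 0).
    """
    f = _reference_function(points, cfg)
    lam = np.linspace(1.0, points.fail[0], cfg.samples_per_curve)
    P = f(lam)
    if cfg.noise_sd_rel > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        P = P * (1.0 + rng.normal(0.0, cfg.noise_sd_rel, P.shape))
    P[0] = 0.0
    return StressStretchCurve(lam, P, specimen_id=specimen_id, ligament=ligament)


def model_curve(params: MaterialParameters, lam_max: float, n: int = 100,
                noise_sd_rel: float = 0.0,
                rng: np.random.Generator | None = None) -> StressStretchCurve:
    """Forward-model curve from the closed-form uniaxial stress law.

    The ground-truth input for parameter-recovery tests: the uniaxial first
    Piola-Kirchhoff stress sampled on a uniform stretch grid, optionally
    with multiplicative Gaussian noise.
    """
    lam = np.linspace(1.0, lam_max, n)
    P = np.asarray(uniaxial_first_PK(params, lam), dtype=float)
    if noise_sd_rel > 0:
        if rng is None:
            rng = np.random.default_rng()
        P = P * (1.0 + rng.normal(0.0, noise_sd_rel, P.shape))
    P[0] = 0.0
    return StressStretchCurve(lam, P, ligament="model")


def generate_cohort(stats: LigamentStats, cfg: GeneratorConfig
                    ) -> list[tuple[StressStretchCurve, Geometry, CharacteristicPoints]]:
    """Generate a reproducible cohort of specimens from one seed stream.

    Returns one ``(curve, geometry, true_points)`` triple per specimen; the
    true construction points are returned so recovery tests can compare the
    segmentation output against the generator's ground truth.
    """
    n = cfg.n_specimens if cfg.n_specimens is not None else stats.n
    if n < 2:
        raise ValueError("cohort needs at least 2 specimens")
    rng = np.random.default_rng(cfg.seed)
    out = []
    for k in range(n):
        pts, geom = sample_specimen(stats, rng,
                                    point_correlation=cfg.point_correlation)
        curve = specimen_curve(pts, cfg, rng=rng,
                               specimen_id=f"{stats.name}-{k + 1:03d}",
                               ligament=stats.name)
        out.append((curve, geom, pts))
    return out
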