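"""Incompressible transversely isotropic hyperelasticity for ligament tissue.

The strain energy is split additively into a ground-matrix part ``Wm`` (an
isotropic function of the first and second invariants of the right
Cauchy-Green tensor) and a fiber part ``Wf`` depending on the squared fiber
stretch ``I4 = a0 . C a0`` of a single dominant collagen family ``a0``:

    W = Wm(I1, I2) + Wf(I4)

Three matrix laws are supported -- Neo-Hookean (NH), Mooney-Rivlin (MR) and
Yeoh -- each combined with a fourth-order polynomial fiber law (P4):

    Wf = C4 (I4 - 1)^2 + C5 (I4 - 1)^4

Tissue is treated as fully incompressible (J = det F = 1), so the
isochoric ("bar") invariants coincide with the plain ones.  All stresses and
energies are in MPa, stretches are dimensionless.

Admissibility diagnostics:

* C1 -- the combined energy must be free of saddle points in the principal
  stretch plane over the explored deformation range;
* C2 -- the fiber contribution must dominate the matrix contribution along
  the uniaxial path (a matrix-dominated ligament is non-physical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "MatrixKind",
    "MaterialParameters",
    "DeformationState",
    "EnergyPartition",
    "InvalidDeformationError",
    "ConfigurationError",
    "invariants_from_F",
    "matrix_energy",
    "fiber_energy",
    "total_energy",
    "uniaxial_invariants",
    "uniaxial_first_PK",
    "plane_stress_cauchy",
    "membrane_energy_and_stress",
    "check_C1",
    "check_C2",
    "COEFFICIENT_FLOOR",
    "MR_C10_PRESCRIBED",
]

#: lower bound imposed on every fitted coefficient (MPa)
COEFFICIENT_FLOOR = 0.001
#: a-priori reduced C10 used with the Mooney-Rivlin matrix (MPa)
MR_C10_PRESCRIBED = 0.0005


class InvalidDeformationError(ValueError):
    """Deformation gradient with non-positive determinant."""


class ConfigurationError(ValueError):
    """Inconsistent material / algorithm configuration."""


class MatrixKind(str, Enum):
    NH = "NH"
    MR = "MR"
    YEOH = "Yeoh"


@dataclass(frozen=True)
class MaterialParameters:
    """Coefficients of one combined matrix + P4 fiber law.

    The initial shear modulus ``mu`` is prescribed, which ties the
    low-order matrix coefficients: ``C10 = mu/2`` for NH and Yeoh, and
    ``C10 + C01 = mu/2`` for MR (where ``C10`` is a-priori reduced to
    0.0005 MPa so the second-invariant term carries the matrix response).
    """

    matrix_kind: MatrixKind
    mu: float  # MPa, prescribed initial shear modulus
    C10: float  # MPa
    C01: float | None = None  # MPa, MR only
    C20: float | None = None  # MPa, Yeoh only
    C30: float | None = None  # MPa, Yeoh only
    C4: float = 0.0  # MPa, fiber quadratic
    C5: float = 0.0  # MPa, fiber quartic
    validate: bool = True

    def __post_init__(self):
        object.__setattr__(self, "matrix_kind", MatrixKind(self.matrix_kind))
        if not self.validate:
            return
        k = self.matrix_kind
        coeffs = {"C10": self.C10, "C4": self.C4, "C5": self.C5}
        if k is MatrixKind.MR:
            if self.C01 is None:
                raise ConfigurationError("MR matrix requires C01")
            if self.C20 is not None or self.C30 is not None:
                raise ConfigurationError("C20/C30 are Yeoh-only coefficients")
            coeffs["C01"] = self.C01
            if abs(self.C10 + self.C01 - self.mu / 2) > 1e-9:
                raise ConfigurationError(
                    f"MR mu-policy violated: C10 + C01 = {self.C10 + self.C01} != mu/2 = {self.mu / 2}"
                )
        else:
            if self.C01 is not None:
                raise ConfigurationError("C01 is an MR-only coefficient")
            if abs(self.C10 - self.mu / 2) > 1e-9:
                raise ConfigurationError(
                    f"{k.value} mu-policy violated: C10 = {self.C10} != mu/2 = {self.mu / 2}"
                )
            if k is MatrixKind.YEOH:
                if self.C20 is None or self.C30 is None:
                    raise ConfigurationError("Yeoh matrix requires C20 and C30")
                coeffs["C20"] = self.C20
                coeffs["C30"] = self.C30
            elif self.C20 is not None or self.C30 is not None:
                raise ConfigurationError("C20/C30 are Yeoh-only coefficients")
        for name, v in coeffs.items():
            if v is None or not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"coefficient {name} must be finite and >= 0, got {v}")

    # -- derivative helpers (vectorised over invariant arrays) ------------

    def dW_dI1(self, I1):
        if self.matrix_kind is MatrixKind.YEOH:
            x = np.asarray(I1) - 3.0
            return self.C10 + 2.0 * self.C20 * x + 3.0 * self.C30 * x * x
        return np.full_like(np.asarray(I1, dtype=float), self.C10)

    def dW_dI2(self, I2):
        c01 = self.C01 if self.matrix_kind is MatrixKind.MR else 0.0
        return np.full_like(np.asarray(I2, dtype=float), c01)

    def dW_dI4(self, I4):
        x = np.asarray(I4) - 1.0
        return 2.0 * self.C4 * x + 4.0 * self.C5 * x**3

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("validate")
        d["matrix_kind"] = self.matrix_kind.value
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaterialParameters":
        d = json.loads(text)
        return cls(**d)


@dataclass(frozen=True)
class DeformationState:
    """In-plane deformation gradient plus the derived incompressible state."""

    F2: np.ndarray  # 2x2, dimensionless
    a0: np.ndarray  # unit fiber direction in the reference plane
    lambda3: float
    I1bar: float
    I2bar: float
    I4bar: float

    @classmethod
    def from_F(cls, F2, a0) -> "DeformationState":
        I1, I2, I4, lam3 = invariants_from_F(F2, a0)
        return cls(np.asarray(F2, float), np.asarray(a0, float), lam3, I1, I2, I4)


@dataclass(frozen=True)
class EnergyPartition:
    """Matrix / fiber energy split along a stretch path (MPa)."""

    lambda_grid: np.ndarray
    Wm: np.ndarray
    Wf: np.ndarray

    @property
    def W(self) -> np.ndarray:
        return self.Wm + self.Wf


# ---------------------------------------------------------------------------
# kinematics and invariants
# ---------------------------------------------------------------------------

def invariants_from_F(F2, a0):
    """Invariants of the 3D incompressible state built from an in-plane gradient.

    The 3D gradient is ``diag(F2, lambda3)`` with the through-thickness
    stretch fixed by incompressibility, ``lambda3 = 1/det(F2)``.  Returns
    ``(I1bar, I2bar, I4bar, lambda3)``; with J = 1 the bar invariants equal
    the plain ones.
    """
    F2 = np.asarray(F2, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    det2 = F2[0, 0] * F2[1, 1] - F2[0, 1] * F2[1, 0]
    if det2 <= 0:
        raise InvalidDeformationError(f"det(F2) = {det2} must be positive")
    if abs(np.linalg.norm(a0) - 1.0) > 1e-8:
        raise ConfigurationError("fiber direction a0 must be a unit vector")
    lam3 = 1.0 / det2
    C2 = F2.T @ F2
    trC2 = C2[0, 0] + C2[1, 1]
    I1 = trC2 + lam3 * lam3
    # det C = 1, hence I2 = tr(C^{-1}) = tr(C2^{-1}) + 1/lam3^2
    trC2inv = trC2 / (det2 * det2)
    I2 = trC2inv + det2 * det2
    I4 = float(a0 @ C2 @ a0)
    return float(I1), float(I2), I4, float(lam3)


def uniaxial_invariants(lam):
    """I1, I2, I4 on the incompressible uniaxial path (fiber along the load)."""
    lam = np.asarray(lam, dtype=float)
    I1 = lam**2 + 2.0 / lam
    I2 = 2.0 * lam + 1.0 / lam**2
    I4 = lam**2
    return I1, I2, I4


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def matrix_energy(params: MaterialParameters, I1bar, I2bar):
    """Ground-matrix strain energy Wm in MPa (NH, MR or Yeoh)."""
    x = np.asarray(I1bar, dtype=float) - 3.0
    k = params.matrix_kind
    if k is MatrixKind.NH:
        return params.C10 * x
    if k is MatrixKind.MR:
        return params.C10 * x + params.C01 * (np.asarray(I2bar, dtype=float) - 3.0)
    return params.C10 * x + params.C20 * x**2 + params.C30 * x**3


def fiber_energy(params: MaterialParameters, I4bar):
    """P4 fiber strain energy Wf = C4 (I4-1)^2 + C5 (I4-1)^4 in MPa."""
    x = np.asarray(I4bar, dtype=float) - 1.0
    return params.C4 * x**2 + params.C5 * x**4


def total_energy(params: MaterialParameters, I1bar, I2bar, I4bar):
    return matrix_energy(params, I1bar, I2bar) + fiber_energy(params, I4bar)


# ---------------------------------------------------------------------------
# stress laws
# ---------------------------------------------------------------------------

def uniaxial_first_PK(params: MaterialParameters, lam):
    """Axial first Piola-Kirchhoff stress P(lambda) in uniaxial tension (MPa).

    Closed form for an incompressible bar with the fiber along the load,
    lateral stretches 1/sqrt(lambda):

        P = 2 lam (1 - lam^-3) dW/dI1 + 2 (1 - lam^-3) dW/dI2 + 2 lam dW/dI4

    The second term is present only for the MR matrix.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise InvalidDeformationError("stretch must be positive")
    I1, I2, I4 = uniaxial_invariants(lam)
    g = 1.0 - lam**-3
    P = (
        2.0 * lam * g * params.dW_dI1(I1)
        + 2.0 * g * params.dW_dI2(I2)
        + 2.0 * lam * params.dW_dI4(I4)
    )
    return P if P.ndim else float(P)


def plane_stress_cauchy(params: MaterialParameters, F2, a0=(1.0, 0.0)):
    """In-plane Cauchy stress (2x2, MPa) under plane stress, sigma33 = 0.

    Builds the incompressible 3D state ``F = diag(F2, 1/det F2)``, evaluates
    the constitutively determinate part of the Cauchy stress

        sigma* = 2 (W1 + I1 W2) B - 2 W2 B^2 + 2 W4 a x a,   a = F a0,

    and removes the hydrostatic pressure using sigma33 = 0 (subtracting a
    pressure and taking the deviator shift sigma* only by multiples of the
    identity, so the plane-stress condition fixes the shift uniquely).
    """
    F2 = np.asarray(F2, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    I1, I2, I4, lam3 = invariants_from_F(F2, a0)
    F = np.zeros((3, 3))
    F[:2, :2] = F2
    F[2, 2] = lam3
    B = F @ F.T
    a = F @ np.array([a0[0], a0[1], 0.0])
    W1 = float(params.dW_dI1(I1))
    W2 = float(params.dW_dI2(I2))
    W4 = float(params.dW_dI4(I4))
    sig = 2.0 * (W1 + I1 * W2) * B - 2.0 * W2 * (B @ B) + 2.0 * W4 * np.outer(a, a)
    sig -= sig[2, 2] * np.eye(3)
    return sig[:2, :2]


def membrane_energy_and_stress(params: MaterialParameters, F2, a0=(1.0, 0.0)):
    """Plane-stress reduced energy W(F2) and its gradient P2 = dW/dF2, batched.

    ``F2`` may have shape (..., 2, 2).  Substituting the incompressibility
    constraint lambda3 = 1/det(F2) into W eliminates the pressure: the
    gradient of the reduced energy is exactly the in-plane first
    Piola-Kirchhoff stress of the plane-stress problem (sigma33 = 0).
    Used by the membrane finite elements.
    """
    F2 = np.asarray(F2, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    F00, F01 = F2[..., 0, 0], F2[..., 0, 1]
    F10, F11 = F2[..., 1, 0], F2[..., 1, 1]
    det2 = F00 * F11 - F01 * F10
    if np.any(det2 <= 0):
        raise InvalidDeformationError("element inversion: det(F2) <= 0")
    inv_det2 = 1.0 / det2
    lam3sq = inv_det2 * inv_det2

    # C2 = F2^T F2 and its invariants
    C00 = F00 * F00 + F10 * F10
    C01c = F00 * F01 + F10 * F11
    C11 = F01 * F01 + F11 * F11
    trC2 = C00 + C11
    I1 = trC2 + lam3sq
    trC2inv = trC2 * lam3sq  # tr(C2^{-1}) = trC2 / det2^2
    I2 = trC2inv + det2 * det2
    a0x, a0y = a0[..., 0], a0[..., 1]
    I4 = C00 * a0x * a0x + 2.0 * C01c * a0x * a0y + C11 * a0y * a0y

    W = total_energy(params, I1, I2, I4)
    W1 = params.dW_dI1(I1)
    W2 = params.dW_dI2(I2)
    W4 = params.dW_dI4(I4)

    # cofactor matrix: G = F2^{-T} * det2  -> F2^{-T} = G / det2
    G00, G01 = F11, -F10
    G10, G11 = -F01, F00
    # dI1/dF2 = 2 F2 - 2 lam3^2 F2^{-T}
    c1 = 2.0 * lam3sq * inv_det2
    dI1_00 = 2.0 * F00 - c1 * G00
    dI1_01 = 2.0 * F01 - c1 * G01
    dI1_10 = 2.0 * F10 - c1 * G10
    dI1_11 = 2.0 * F11 - c1 * G11
    # dI2/dF2 = -2 F2 C2^{-2} + 2 det2^2 F2^{-T}
    # C2^{-1} = adj(C2)/det(C2), det(C2) = det2^2
    iC00 = C11 * lam3sq
    iC01 = -C01c * lam3sq
    iC11 = C00 * lam3sq
    # C2^{-2}
    s00 = iC00 * iC00 + iC01 * iC01
    s01 = iC01 * (iC00 + iC11)
    s11 = iC01 * iC01 + iC11 * iC11
    c2 = 2.0 * det2 * det2 * inv_det2  # = 2 det2
    dI2_00 = -2.0 * (F00 * s00 + F01 * s01) + c2 * G00
    dI2_01 = -2.0 * (F00 * s01 + F01 * s11) + c2 * G01
    dI2_10 = -2.0 * (F10 * s00 + F11 * s01) + c2 * G10
    dI2_11 = -2.0 * (F10 * s01 + F11 * s11) + c2 * G11
    # dI4/dF2 = 2 (F2 a0) x a0
    Fa0 = F00 * a0x + F01 * a0y
    Fa1 = F10 * a0x + F11 * a0y
    dI4_00 = 2.0 * Fa0 * a0x
    dI4_01 = 2.0 * Fa0 * a0y
    dI4_10 = 2.0 * Fa1 * a0x
    dI4_11 = 2.0 * Fa1 * a0y

    P2 = np.empty(np.broadcast(F00, W1).shape + (2, 2))
    P2[..., 0, 0] = W1 * dI1_00 + W2 * dI2_00 + W4 * dI4_00
    P2[..., 0, 1] = W1 * dI1_01 + W2 * dI2_01 + W4 * dI4_01
    P2[..., 1, 0] = W1 * dI1_10 + W2 * dI2_10 + W4 * dI4_10
    P2[..., 1, 1] = W1 * dI1_11 + W2 * dI2_11 + W4 * dI4_11
    return W, P2


# ---------------------------------------------------------------------------
# admissibility diagnostics
# ---------------------------------------------------------------------------

@dataclass
class C1Report:
    satisfied: bool
    n_saddle: int
    worst_point: tuple[float, float] | None
    lam1_grid: np.ndarray = field(repr=False, default=None)
    lam2_grid: np.ndarray = field(repr=False, default=None)


@dataclass
class C2Report:
    satisfied: bool
    crossover: float | None
    failing_interval: tuple[float, float] | None
    partition: EnergyPartition = field(repr=False, default=None)


def _energy_principal(params: MaterialParameters, lam1, lam2):
    """W(lam1, lam2) with lam3 = 1/(lam1 lam2), fiber along axis 1."""
    lam3 = 1.0 / (lam1 * lam2)
    I1 = lam1**2 + lam2**2 + lam3**2
    I2 = lam1**2 * lam2**2 + lam2**2 * lam3**2 + lam3**2 * lam1**2
    I4 = lam1**2
    return total_energy(params, I1, I2, I4)


def check_C1(params: MaterialParameters, lam_max: float, n_grid: int = 101,
             tol: float = 1e-8) -> C1Report:
    """Screen the principal-stretch energy surface for saddle points.

    ``W(lam1, lam2)`` is evaluated on a rectangular grid
    ``lam1 in [1, lam_max] x lam2 in [1/sqrt(lam_max), 1]`` (the region swept
    by uniaxial-like states) and the 2x2 Hessian is estimated at interior
    points by central differences.  The condition fails if any interior point
    has Hessian eigenvalues of strictly mixed sign beyond ``tol`` (MPa);
    semi-definite points are treated as admissible to avoid false saddles
    from round-off.
    """
    if lam_max <= 1:
        raise ConfigurationError("lam_max must exceed 1")
    if n_grid < 5:
        raise ConfigurationError("C1 grid needs at least 5 points per axis")
    l1 = np.linspace(1.0, lam_max, n_grid)
    l2 = np.linspace(1.0 / np.sqrt(lam_max), 1.0, n_grid)
    L1, L2 = np.meshgrid(l1, l2, indexing="ij")
    W = _energy_principal(params, L1, L2)
    h1 = l1[1] - l1[0]
    h2 = l2[1] - l2[0]
    Wxx = (W[2:, 1:-1] - 2 * W[1:-1, 1:-1] + W[:-2, 1:-1]) / h1**2
    Wyy = (W[1:-1, 2:] - 2 * W[1:-1, 1:-1] + W[1:-1, :-2]) / h2**2
    Wxy = (W[2:, 2:] - W[2:, :-2] - W[:-2, 2:] + W[:-2, :-2]) / (4 * h1 * h2)
    mean = 0.5 * (Wxx + Wyy)
    rad = np.sqrt((0.5 * (Wxx - Wyy)) ** 2 + Wxy**2)
    eig_lo, eig_hi = mean - rad, mean + rad
    saddle = (eig_lo < -tol) & (eig_hi > tol)
    n_saddle = int(saddle.sum())
    worst = None
    if n_saddle:
        # worst = most indefinite point (largest |eig_lo * eig_hi| among saddles)
        score = np.where(saddle, -eig_lo * eig_hi, -np.inf)
        i, j = np.unravel_index(np.argmax(score), score.shape)
        worst = (float(l1[i + 1]), float(l2[j + 1]))
    return C1Report(n_saddle == 0, n_saddle, worst, l1, l2)


def check_C2(params: MaterialParameters, lam_max: float, n_grid: int = 200) -> C2Report:
    """Check fiber dominance Wf > Wm along the uniaxial path (1, lam_max]."""
    if lam_max <= 1:
        raise ConfigurationError("lam_max must exceed 1")
    lam = np.linspace(1.0, lam_max, n_grid + 1)[1:]
    I1, I2, I4 = uniaxial_invariants(lam)
    Wm = np.asarray(matrix_energy(params, I1, I2), dtype=float)
    Wf = np.asarray(fiber_energy(params, I4), dtype=float)
    part = EnergyPartition(lam, Wm, Wf)
    bad = Wf <= Wm
    if not bad.any():
        return C2Report(True, None, None, part)
    # longest contiguous failing run
    idx = np.flatnonzero(bad)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    runs = max(splits, key=len)
    interval = (float(lam[runs[0]]), float(lam[runs[-1]]))
    # crossover: first stretch where fiber overtakes matrix for good, if any
    crossover = None
    if not bad[-1]:
        crossover = float(lam[idx[-1] + 1])
    return C2Report(False, crossover, interval, part)
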