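"""Plane-stress incompressible membrane finite elements for ligament tension.

A rectangular ligament sheet (length L0 along the loading axis, width b) is
meshed with bilinear quadrilaterals and loaded in displacement-controlled
tension: one edge is constrained at the bone interface, the opposite edge
is pulled axially with all of its nodes coupled.  The formulation is total
Lagrangian with 2x2 full Gauss integration.  At every Gauss point the
through-thickness stretch is eliminated by full incompressibility
(lambda3 = 1/det F2), which also removes the hydrostatic pressure: the
in-plane first Piola-Kirchhoff stress is the gradient of the reduced
strain energy of :func:`ligfit.constitutive.membrane_energy_and_stress`.

The model is a membrane: pure in-plane tension carries no bending or
transverse shear, so no rotational degrees of freedom, shear-correction
factors or hourglass control are needed.  Equilibrium is solved with
incremental prescribed-displacement steps and Newton iterations using a
finite-difference consistent tangent assembled element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .constitutive import (
    InvalidDeformationError,
    MaterialParameters,
    membrane_energy_and_stress,
)

__all__ = ["MembraneModel", "FEResult", "build_mesh", "internal_forces",
           "solve_tension", "postprocess", "MeshError"]

_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float) / np.sqrt(3.0)


class MeshError(ValueError):
    """Degenerate mesh request."""


@dataclass
class MembraneModel:
    """Quad membrane mesh with tension boundary conditions.

    ``fixed_edge_mode``: ``"clamped"`` pins both displacement components on
    the bone-interface edge (the physical case); ``"roller"`` pins only the
    axial component (plus one transverse pin against rigid motion), giving
    a homogeneous uniaxial patch state used for verification.
    ``loaded_edge_transverse``: ``"tied"`` couples the transverse
    displacement of all loaded-edge nodes to one common unknown (the edge
    translates rigidly, mirroring an all-DOF edge coupling), ``"fixed"``
    pins it to zero, ``"free"`` leaves it unconstrained.
    """

    nodes: np.ndarray          # (nnode, 2) reference coordinates, mm
    elements: np.ndarray       # (nelem, 4) CCW connectivity
    L0: float                  # mm, loading-direction length
    b: float                   # mm, width
    thickness: float = 1.0     # mm, reference thickness
    params: MaterialParameters | None = None
    a0: np.ndarray | None = None  # (nelem, 2) per-element fiber direction
    fixed_edge_mode: str = "clamped"
    loaded_edge_transverse: str = "tied"

    def __post_init__(self):
        if self.a0 is None:
            self.a0 = np.tile([1.0, 0.0], (len(self.elements), 1))
        self._precompute()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def fixed_edge_nodes(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.nodes[:, 0]) < 1e-12)

    @property
    def loaded_edge_nodes(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.nodes[:, 0] - self.L0) < 1e-12)

    # -- element geometry -------------------------------------------------

    def _precompute(self):
        Xe = self.nodes[self.elements]  # (nelem, 4, 2)
        dNdX = np.empty((self.n_elements, 4, 4, 2))
        wdetJ = np.empty((self.n_elements, 4))
        for g, (xi, eta) in enumerate(_GP):
            dNdxi = 0.25 * np.array([
                [-(1 - eta), -(1 - xi)],
                [(1 - eta), -(1 + xi)],
                [(1 + eta), (1 + xi)],
                [-(1 + eta), (1 - xi)],
            ])  # (4, 2)
            J = np.einsum("eai,aj->eij", Xe, dNdxi)  # (nelem, 2, 2)
            detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            if np.any(detJ <= 0):
                raise MeshError("element with non-positive area (connectivity not CCW?)")
            Jinv = np.empty_like(J)
            Jinv[:, 0, 0] = J[:, 1, 1] / detJ
            Jinv[:, 0, 1] = -J[:, 0, 1] / detJ
            Jinv[:, 1, 0] = -J[:, 1, 0] / detJ
            Jinv[:, 1, 1] = J[:, 0, 0] / detJ
            dNdX[:, g] = np.einsum("aj,eji->eai", dNdxi, Jinv)
            wdetJ[:, g] = detJ  # unit Gauss weights
        self._dNdX = dNdX
        self._wdetJ = wdetJ
        self._edof = (2 * self.elements[:, :, None] +
                      np.arange(2)[None, None, :]).reshape(self.n_elements, 8)

    # -- kinematics and element forces ------------------------------------

    def _deformation(self, u_e):
        """F2 at every Gauss point from element displacements (nelem, 4, 2)."""
        F2 = np.einsum("eai,egaJ->egiJ", u_e, self._dNdX)
        F2[..., 0, 0] += 1.0
        F2[..., 1, 1] += 1.0
        return F2

    def element_forces(self, u_e):
        """Internal nodal forces (nelem, 4, 2) and total strain energy (N mm)."""
        F2 = self._deformation(u_e)
        W, P2 = membrane_energy_and_stress(self.params, F2, self.a0[:, None, :])
        f = np.einsum("egiJ,egaJ,eg->eai", P2, self._dNdX, self._wdetJ) * self.thickness
        energy = float(np.sum(W * self._wdetJ) * self.thickness)
        return f, energy

    def element_stiffness(self, u_e, h: float = 1e-7):
        """Forward-difference element tangents (nelem, 8, 8)."""
        f0, _ = self.element_forces(u_e)
        f0 = f0.reshape(-1, 8)
        K = np.empty((self.n_elements, 8, 8))
        for d in range(8):
            up = u_e.copy().reshape(-1, 8)
            up[:, d] += h
            fd, _ = self.element_forces(up.reshape(-1, 4, 2))
            K[:, :, d] = (fd.reshape(-1, 8) - f0) / h
        return K

    def centroid_stress(self, u):
        """Cauchy stresses (sigma11, sigma22) at element centroids (MPa)."""
        u_e = u[self.elements]
        # centroid: average of the 2x2 Gauss-point deformation gradients
        F2 = self._deformation(u_e).mean(axis=1)
        _, P2 = membrane_energy_and_stress(self.params, F2, self.a0)
        sig = np.einsum("eiJ,ekJ->eik", P2, F2)  # sigma = P F^T (J = 1)
        return np.stack([sig[:, 0, 0], sig[:, 1, 1]], axis=1)


def build_mesh(L0: float, b: float, element_size: float = 0.5,
               thickness: float = 1.0,
               params: MaterialParameters | None = None,
               **bc_options) -> MembraneModel:
    """Structured quad mesh of an L0 x b sheet, axis 1 = loading direction.

    Uses ``ceil(L0/size) x ceil(b/size)`` elements so the element size never
    exceeds the request.
    """
    if L0 <= 0 or b <= 0 or element_size <= 0:
        raise MeshError("L0, b and element_size must be positive")
    if element_size >= min(L0, b):
        raise MeshError(f"element size {element_size} too coarse for {L0} x {b} sheet")
    nx = int(np.ceil(L0 / element_size))
    ny = int(np.ceil(b / element_size))
    x = np.linspace(0.0, L0, nx + 1)
    y = np.linspace(0.0, b, ny + 1)
    nodes = np.array([[xi, yj] for xi in x for yj in y])  # id = i*(ny+1) + j
    elems = []
    for i in range(nx):
        for j in range(ny):
            n0 = i * (ny + 1) + j
            elems.append([n0, n0 + (ny + 1), n0 + (ny + 1) + 1, n0 + 1])
    return MembraneModel(nodes=nodes, elements=np.array(elems, dtype=int),
                         L0=L0, b=b, thickness=thickness, params=params,
                         **bc_options)


@dataclass
class FEResult:
    """Converged states of an incremental tension solve."""

    lam: np.ndarray                # (nstep,) global stretch per converged step
    reaction: np.ndarray           # (nstep,) axial reaction force, N
    u_steps: list[np.ndarray]      # (nnode, 2) displacements per step, mm
    stress_steps: list[np.ndarray]  # (nelem, 2) centroid (s11, s22) per step, MPa
    converged: bool
    model: MembraneModel = field(repr=False, default=None)

    @property
    def u(self) -> np.ndarray:
        return self.u_steps[-1]

    @property
    def stresses(self) -> np.ndarray:
        return self.stress_steps[-1]


# ---------------------------------------------------------------------------
# constraint handling
# ---------------------------------------------------------------------------

def _dof_maps(model: MembraneModel):
    """Reduced-DOF map: dofmap[n, c] >= 0 is a free index, -1 is prescribed.

    Loaded-edge tied transverse displacements share one reduced index.
    """
    nn = model.n_nodes
    dofmap = np.full((nn, 2), -2, dtype=int)
    fixed = model.fixed_edge_nodes
    loaded = model.loaded_edge_nodes
    dofmap[fixed, 0] = -1
    if model.fixed_edge_mode == "clamped":
        dofmap[fixed, 1] = -1
    elif model.fixed_edge_mode == "roller":
        mid = fixed[np.argmin(np.abs(model.nodes[fixed, 1] - model.b / 2))]
        dofmap[mid, 1] = -1
    else:
        raise ValueError(f"unknown fixed_edge_mode {model.fixed_edge_mode!r}")
    dofmap[loaded, 0] = -1
    if model.loaded_edge_transverse == "fixed":
        dofmap[loaded, 1] = -1
    elif model.loaded_edge_transverse == "tied":
        dofmap[loaded, 1] = -3  # placeholder: tied group numbered below
    elif model.loaded_edge_transverse != "free":
        raise ValueError(
            f"unknown loaded_edge_transverse {model.loaded_edge_transverse!r}")
    free = dofmap == -2
    n_free = int(free.sum())
    dofmap[free] = np.arange(n_free)
    if model.loaded_edge_transverse == "tied":
        dofmap[dofmap == -3] = n_free
        n_free += 1
    return dofmap, n_free


def _full_u(model, dofmap, q, u1_presc):
    u = np.zeros((model.n_nodes, 2))
    m = dofmap >= 0
    u[m] = q[dofmap[m]]
    u[model.loaded_edge_nodes, 0] = u1_presc
    return u


def internal_forces(model: MembraneModel, u: np.ndarray, tangent: bool = False):
    """Global internal-force vector (and optionally the sparse tangent).

    ``u`` is the full nodal displacement array (nnode, 2); the residual of
    the unconstrained equilibrium problem is returned flattened to
    (2 nnode,).  The tangent is assembled from forward-difference element
    stiffnesses.
    """
    u_e = u[model.elements]
    f, _ = model.element_forces(u_e)
    R = np.zeros(2 * model.n_nodes)
    np.add.at(R, model._edof.ravel(), f.reshape(-1))
    if not tangent:
        return R
    Ke = model.element_stiffness(u_e)
    rows = np.repeat(model._edof, 8, axis=1).ravel()
    cols = np.tile(model._edof, (1, 8)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(2 * model.n_nodes, 2 * model.n_nodes)).tocsr()
    return R, K


def _reduce(model, dofmap, n_free, R, K=None):
    Rr = np.zeros(n_free)
    m = (dofmap >= 0).ravel()
    np.add.at(Rr, dofmap.ravel()[m], R[m])
    if K is None:
        return Rr
    # transformation u_full = T q + prescribed: K_red = T^T K T
    idx = np.flatnonzero(m)
    T = sp.coo_matrix((np.ones(idx.size), (idx, dofmap.ravel()[m])),
                      shape=(2 * model.n_nodes, n_free)).tocsr()
    return Rr, (T.T @ K @ T).tocsr()


def solve_tension(model: MembraneModel, lam_target: float, dlam: float = 0.01,
                  tol: float = 1e-6, max_iter: int = 25, max_cutbacks: int = 4,
                  force_floor: float = 1e-3) -> FEResult:
    """Displacement-controlled tension solve up to a global stretch.

    The loaded-edge axial displacement is ramped in increments of
    ``dlam * L0`` with Newton iterations to a force-relative residual
    ``||R|| / max(|reaction|, force_floor) <= tol``.  On non-convergence the
    increment is halved (up to ``max_cutbacks`` times); if the step still
    fails, the partial result up to the last converged step is returned
    flagged as non-converged.
    """
    if model.params is None:
        raise ValueError("model has no material parameters attached")
    if lam_target < 1:
        raise ValueError("lam_target must be >= 1")
    dofmap, n_free = _dof_maps(model)
    loaded_u1 = 2 * model.loaded_edge_nodes  # flat dof ids of loaded-edge u1
    q = np.zeros(n_free)
    lam_now = 1.0
    lams, reactions, u_steps, stress_steps = [], [], [], []
    converged_all = True

    def newton(q, lam):
        u1 = (lam - 1.0) * model.L0
        for _ in range(max_iter):
            u = _full_u(model, dofmap, q, u1)
            try:
                R, K = internal_forces(model, u, tangent=True)
            except InvalidDeformationError:
                return None
            reaction = float(R[loaded_u1].sum())
            Rr, Kr = _reduce(model, dofmap, n_free, R, K)
            if np.linalg.norm(Rr) <= tol * max(abs(reaction), force_floor):
                return q, u, reaction
            try:
                dq = spsolve(Kr, -Rr)
            except Exception:
                return None
            if not np.all(np.isfinite(dq)):
                return None
            q = q + dq
        return None

    while lam_now < lam_target - 1e-12:
        step = min(dlam, lam_target - lam_now)
        cut = 0
        while True:
            out = newton(q.copy(), lam_now + step)
            if out is not None:
                break
            cut += 1
            if cut > max_cutbacks:
                converged_all = False
                break
            step /= 2.0
        if out is None:
            break
        q, u, reaction = out
        lam_now += step
        lams.append(lam_now)
        reactions.append(reaction)
        u_steps.append(u)
        stress_steps.append(model.centroid_stress(u))

    if not lams:  # record the trivial reference state
        lams, reactions = [1.0], [0.0]
        u_steps = [np.zeros((model.n_nodes, 2))]
        stress_steps = [np.zeros((model.n_elements, 2))]
    return FEResult(np.array(lams), np.array(reactions), u_steps, stress_steps,
                    converged=converged_all, model=model)


def postprocess(result: FEResult, A0: float, L0: float,
                central_frac: float = 0.1) -> dict:
    """Engineering curve and transverse-response measures of a tension solve.

    Returns the global stress-stretch curve (P = reaction / A0 against
    lambda = (L0 + u1) / L0), the contraction ratio (max nodal |u2| over
    prescribed u1 at the final step) and the ratio of average transverse to
    longitudinal Cauchy stress over the central ``central_frac`` of
    elements, both as percentages.
    """
    if result.model is None:
        raise ValueError("result carries no model")
    model = result.model
    u1 = (result.lam - 1.0) * model.L0  # prescribed edge displacement, mm
    P = result.reaction / A0
    lam = (L0 + u1) / L0
    u_final = result.u
    u1_final = (result.lam[-1] - 1.0) * model.L0
    contraction = float(np.max(np.abs(u_final[:, 1])) / u1_final) if u1_final > 0 else 0.0
    # central patch: the fraction of elements nearest the sheet center
    centroids = model.nodes[model.elements].mean(axis=1)
    center = np.array([model.L0 / 2, model.b / 2])
    order = np.argsort(np.linalg.norm(centroids - center, axis=1))
    n_take = max(1, int(np.ceil(central_frac * model.n_elements)))
    patch = order[:n_take]
    s = result.stresses[patch]
    stress_ratio = float(s[:, 1].mean() / s[:, 0].mean()) if s[:, 0].mean() != 0 else 0.0
    return {
        "lam": lam,
        "P": P,
        "reaction": result.reaction,
        "contraction_ratio_pct": 100.0 * contraction,
        "stress_ratio_pct": 100.0 * stress_ratio,
        "converged": result.converged,
    }
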