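"""Total-Lagrangian finite-strain solution of the pressurised sphincter.

Displacement-based FEM on 6-node (quadratic, default) or 3-node triangles,
plane stress enforced pointwise at the quadrature points through the
condensed Mooney–Rivlin kernels, intraluminal pressure applied as a follower
load on the deformed lumen boundary (with its load-stiffness contribution,
so Newton keeps the quadratic rate), and incremental loading with adaptive
step halving.  The domain is fixed in space only through two pinned points
on the outer boundary, which leaves the opening deformation unconstrained.

If a converged increment leaves elements with a displaced corner angle above
the distortion limit (default 160 deg), the step is rejected and the
increment halved; if distortion persists at the minimum increment, the mesh
is regenerated at 0.75x element size and the load program restarts from
zero.  Everything is deterministic.

Unit out-of-plane thickness is assumed; areas and the opening metrics are
thickness-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import constitutive as ct
from . import geometry as geo
from . import meshing as msh

__all__ = [
    "BoundaryConditions",
    "LoadProgram",
    "SolverSettings",
    "SolutionField",
    "SolverError",
    "DEFAULT_MATERIAL_MAP",
    "material_map",
    "follower_pressure_forces",
    "assemble",
    "solve_case",
    "sweep_pressure",
]

#: tissue assignment by region tag
DEFAULT_MATERIAL_MAP = {
    "epithelium": "dense_connective",
    "spongy_sane": "spongy",
    "spongy_fibrotic": "fibrotic",
}


def material_map(overrides: dict | None = None) -> dict[str, ct.MooneyRivlin5]:
    """Region-tag -> material mapping, presets by default."""
    names = dict(DEFAULT_MATERIAL_MAP)
    out: dict[str, ct.MooneyRivlin5] = {}
    for tag, name in names.items():
        mat = (overrides or {}).get(tag, name)
        out[tag] = ct.MATERIALS[mat] if isinstance(mat, str) else mat
    return out


class SolverError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


class _Distorted(Exception):
    """Internal signal: inverted element during assembly."""


@dataclass(frozen=True)
class BoundaryConditions:
    """Two pinned points on the outer boundary at the top and bottom of the
    vertical symmetry axis.

    ``mode`` "both" (default) pins both displacement components at both
    points; besides fixing the rigid-body modes this suppresses the rigid
    vertical drift of the sane half, which is part of how the fibrotic
    restraint manifests in the opening metrics.  ``mode`` "minimal" is the
    3-DOF rigid-body constraint (both components at the bottom point plus
    ux at the top), useful for sensitivity checks: at large opening ratios
    the "both" mode locks the vertical diameter and eventually pinches the
    material near the pins."""

    pinned_nodes: tuple[int, int]
    mode: str = "both"

    def fixed_dofs(self) -> np.ndarray:
        a, b = self.pinned_nodes  # (top, bottom)
        if self.mode == "both":
            return np.array([2 * a, 2 * a + 1, 2 * b, 2 * b + 1])
        if self.mode == "minimal":
            return np.array([2 * b, 2 * b + 1, 2 * a])
        raise ValueError(f"unknown BC mode {self.mode!r}")


@dataclass(frozen=True)
class LoadProgram:
    """Target intraluminal pressure [Pa] and incremental stepping."""

    target_pressure: float = 1960.0
    n_increments: int = 16
    sweep: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.target_pressure < 0:
            raise ValueError("pressure must be non-negative")
        if self.n_increments < 1:
            raise ValueError("need at least one increment")
        if self.sweep is not None and np.any(np.diff(self.sweep) <= 0):
            raise ValueError("sweep pressures must be strictly increasing")


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-8
    max_newton_iter: int = 30
    line_search: bool = True
    angle_limit: float = 160.0
    min_step_fraction: float = 1.0  # no halving: stabilization is the fallback
    max_mesh_refinements: int = 2
    bc_mode: str = "both"
    stabilization: bool = True
    stall_limit: int = 30  # consecutive tiny energy-descent steps before giving up

    def __post_init__(self):
        if self.rtol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class SolutionField:
    """Converged solution: displacements per recorded load level plus the
    metadata needed to post-process stresses and strains."""

    case_id: str
    domain: geo.PlanarDomain
    mesh: msh.Mesh
    materials: dict[str, ct.MooneyRivlin5]
    pressures: list[float]
    displacements: list[np.ndarray]
    log: list[dict]
    external_work: float = 0.0

    @property
    def u(self) -> np.ndarray:
        return self.displacements[-1]

    @property
    def pressure(self) -> float:
        return self.pressures[-1]

    def qp_state(self, level: int = -1):
        """Recompute (F, lam3, S2d, sigma, wdet, element_index) at a level."""
        pre = _precompute(self.mesh)
        u = self.displacements[level]
        F = _deformation_gradients(pre, u)
        lam3 = np.ones(F.shape[:2])
        S2d = np.zeros_like(F)
        sigma = np.zeros_like(F)
        for tag, mat in self.materials.items():
            sel = self.mesh.region_tag == tag
            if not sel.any():
                continue
            lam = ct.plane_stress_stretch(mat, _c_of(F[sel]))
            _, S, _ = ct.stress_and_condensed_tangent(mat, _c_of(F[sel]), lam)
            lam3[sel] = lam
            S2d[sel] = S
            st = ct.DeformationState(F=F[sel], lam3=lam)
            sigma[sel] = ct.cauchy_stress(st, S)
        return F, lam3, S2d, sigma, pre.wdet

    def strain_energy_total(self, level: int = -1) -> float:
        """Stored strain energy [J per unit thickness] at a load level."""
        pre = _precompute(self.mesh)
        u = self.displacements[level]
        F = _deformation_gradients(pre, u)
        total = 0.0
        for tag, mat in self.materials.items():
            sel = self.mesh.region_tag == tag
            if not sel.any():
                continue
            lam = ct.plane_stress_stretch(mat, _c_of(F[sel]))
            W, _, _ = ct.stress_and_condensed_tangent(mat, _c_of(F[sel]), lam)
            total += float((W * pre.wdet[sel]).sum())
        return total


# ---------------------------------------------------------------------------
# Reference elements and precomputation
# ---------------------------------------------------------------------------

# 3-point quadrature on the reference triangle (degree 2)
_QP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_QW = np.array([1 / 6, 1 / 6, 1 / 6])


def _shape_tri6(xi, eta):
    l1 = 1 - xi - eta
    N = np.array(
        [l1 * (2 * l1 - 1), xi * (2 * xi - 1), eta * (2 * eta - 1),
         4 * l1 * xi, 4 * xi * eta, 4 * eta * l1]
    )
    dN = np.array(
        [
            [1 - 4 * l1, 1 - 4 * l1],
            [4 * xi - 1, 0.0],
            [0.0, 4 * eta - 1],
            [4 * (l1 - xi), -4 * xi],
            [4 * eta, 4 * xi],
            [-4 * eta, 4 * (l1 - eta)],
        ]
    )
    return N, dN


def _shape_tri3(xi, eta):
    N = np.array([1 - xi - eta, xi, eta])
    dN = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    return N, dN


@dataclass
class _ElementData:
    gradN: np.ndarray  # (E, Q, n, 2) reference gradients
    wdet: np.ndarray  # (E, Q) quadrature weight x |J0|
    dofmap: np.ndarray  # (E, 2n)
    nodes_per_el: int


_PRECOMP_CACHE: dict[int, _ElementData] = {}


def _precompute(mesh: msh.Mesh) -> _ElementData:
    cached = _PRECOMP_CACHE.get(id(mesh))
    if cached is not None:
        return cached
    conn = mesh.elements
    nn = conn.shape[1]
    shape = _shape_tri6 if nn == 6 else _shape_tri3
    X = mesh.nodes[conn]  # (E, n, 2)
    gradN = np.empty((len(conn), len(_QP), nn, 2))
    wdet = np.empty((len(conn), len(_QP)))
    for q, (xi, eta) in enumerate(_QP):
        _, dN = shape(xi, eta)  # (n, 2)
        J = np.einsum("enk,nj->ekj", X, dN)  # dX/dxi
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            raise msh.MeshingError("non-positive reference Jacobian")
        Jinv = np.empty_like(J)
        Jinv[:, 0, 0] = J[:, 1, 1]
        Jinv[:, 1, 1] = J[:, 0, 0]
        Jinv[:, 0, 1] = -J[:, 0, 1]
        Jinv[:, 1, 0] = -J[:, 1, 0]
        Jinv /= detJ[:, None, None]
        gradN[:, q] = np.einsum("nj,ejJ->enJ", dN, Jinv)
        wdet[:, q] = _QW[q] * detJ
    dofmap = np.empty((len(conn), 2 * nn), dtype=int)
    dofmap[:, 0::2] = 2 * conn
    dofmap[:, 1::2] = 2 * conn + 1
    out = _ElementData(gradN=gradN, wdet=wdet, dofmap=dofmap, nodes_per_el=nn)
    _PRECOMP_CACHE.clear()  # keep at most one mesh cached
    _PRECOMP_CACHE[id(mesh)] = out
    return out


def _deformation_gradients(pre: _ElementData, u: np.ndarray) -> np.ndarray:
    ue = u.reshape(-1)[pre.dofmap].reshape(len(pre.dofmap), pre.nodes_per_el, 2)
    F = np.einsum("eni,eqnJ->eqiJ", ue, pre.gradN)
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    return F


def _c_of(F: np.ndarray) -> np.ndarray:
    return np.einsum("...ki,...kj->...ij", F, F)


# ---------------------------------------------------------------------------
# Follower pressure on the lumen boundary
# ---------------------------------------------------------------------------

# edge quadrature (3-point Gauss on [0, 1]; exact through degree 5)
_EQ = (np.array([-np.sqrt(3 / 5), 0.0, np.sqrt(3 / 5)]) + 1) / 2
_EW = np.array([5 / 18, 8 / 18, 5 / 18])


def _edge_shape(nn: int):
    xi = _EQ
    if nn == 3:
        M = np.stack([(1 - xi) * (1 - 2 * xi), xi * (2 * xi - 1), 4 * xi * (1 - xi)], axis=1)
        dM = np.stack([4 * xi - 3, 4 * xi - 1, 4 - 8 * xi], axis=1)
    else:
        M = np.stack([1 - xi, xi], axis=1)
        dM = np.stack([-np.ones_like(xi), np.ones_like(xi)], axis=1)
    return M, dM  # (Q, nn)


def follower_pressure_forces(
    mesh: msh.Mesh,
    displacement: np.ndarray,
    p: float,
    edge_group: str = "lumen",
    *,
    with_stiffness: bool = True,
):
    """Nodal forces of a uniform pressure acting on the deformed edge group.

    The pressure acts along the into-the-solid normal of the *deformed*
    boundary (follower load).  Returns ``(f, K_load)`` with ``f`` a flat
    (2N,) force vector and ``K_load`` the load-stiffness matrix
    (``d f / d u``, COO) or ``None``.  On a closed loop the total force is
    identically zero (self-equilibration).
    """
    edges = mesh.edge_groups[edge_group]
    if isinstance(edges, list):
        raise ValueError("pass a named group, e.g. 'lumen'")
    msh._check_closed_loop(edges, edge_group, single=False)
    return _pressure_on_edges(mesh, edges, displacement, p, with_stiffness)


def _pressure_on_edges(mesh, edges, displacement, p, with_stiffness):
    ndof = 2 * len(mesh.nodes)
    f = np.zeros(ndof)
    nn = edges.shape[1]
    M, dM = _edge_shape(nn)
    x = mesh.nodes[edges] + np.asarray(displacement).reshape(-1, 2)[edges]  # (K, nn, 2)
    t = np.einsum("qn,kni->kqi", dM, x)  # tangent dx/dxi at edge qps
    # solid-on-left orientation: inward (into-solid) normal ~ (-t_y, t_x)
    nvec = np.stack([-t[..., 1], t[..., 0]], axis=-1)
    fe = p * np.einsum("q,qn,kqi->kni", _EW, M, nvec)  # (K, nn, 2)
    np.add.at(f, 2 * edges, fe[..., 0])
    np.add.at(f, 2 * edges + 1, fe[..., 1])
    if not with_stiffness:
        return f, None
    # d f_a / d u_b: f_ax depends on y_b, f_ay on x_b
    G = np.einsum("q,qa,qb->ab", _EW, M, dM)  # (nn, nn)
    K = len(edges)
    rows = np.concatenate(
        [(2 * edges[:, :, None] + 0).repeat(nn, axis=2).ravel(),
         (2 * edges[:, :, None] + 1).repeat(nn, axis=2).ravel()]
    )
    cols = np.concatenate(
        [np.repeat(2 * edges[:, None, :] + 1, nn, axis=1).ravel(),
         np.repeat(2 * edges[:, None, :] + 0, nn, axis=1).ravel()]
    )
    vals = np.concatenate(
        [np.broadcast_to(-p * G, (K, nn, nn)).ravel(),
         np.broadcast_to(+p * G, (K, nn, nn)).ravel()]
    )
    Kload = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof))
    return f, Kload


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _psd_project_tangent(CC: np.ndarray, floor: float) -> np.ndarray:
    """Clamp the eigenvalues of the condensed material tangent at each
    quadrature point to ``floor`` (in the energy inner product), yielding a
    positive-definite modified-Newton iteration matrix for locally
    non-elliptic (wrinkling) states.  Only the iteration matrix changes;
    residuals stay exact."""
    # condensed Voigt 3x3 over [11, 22, 12], single off-diagonal count
    pairs = [(0, 0), (1, 1), (0, 1)]
    Mc = np.empty(CC.shape[:-4] + (3, 3))
    for r, (A, B) in enumerate(pairs):
        for c, (C_, D) in enumerate(pairs):
            Mc[..., r, c] = CC[..., A, B, C_, D] / (2.0 if C_ == D else 1.0)
    g = np.array([1.0, 1.0, 2.0])
    H = Mc * g[:, None]  # G @ Mc
    H = 0.5 * (H + np.swapaxes(H, -1, -2))
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, floor)
    Hc = np.einsum("...ij,...j,...kj->...ik", V, w, V)
    Mc = Hc / g[:, None]
    out = np.empty_like(CC)
    vmap = {(0, 0): 0, (1, 1): 1, (0, 1): 2, (1, 0): 2}
    for (A, B), r in vmap.items():
        for (C_, D), c in vmap.items():
            out[..., A, B, C_, D] = Mc[..., r, c] * (2.0 if C_ == D else 1.0)
    return out


def assemble(
    mesh: msh.Mesh,
    materials: dict[str, ct.MooneyRivlin5],
    displacement: np.ndarray,
    p: float,
    *,
    pre: _ElementData | None = None,
    lam3_ws: np.ndarray | None = None,
    with_tangent: bool = True,
    psd_fix: bool = False,
    return_energy: bool = False,
):
    """Residual R = f_int - f_ext and exact tangent K = dR/du.

    Region interfaces are bonded by shared nodes ("perfect interface").
    Raises an internal distortion signal when an element inverts during
    evaluation, which the stepping loop converts into step halving.  Returns
    ``(R, K, lam3)``; ``K`` is None when ``with_tangent`` is false.
    """
    pre = pre if pre is not None else _precompute(mesh)
    u = np.asarray(displacement, dtype=float).reshape(-1, 2)
    ndof = 2 * len(mesh.nodes)
    F = _deformation_gradients(pre, u)
    detF = np.linalg.det(F)
    if np.any(detF <= 0):
        raise _Distorted("inverted element during assembly")

    E, Q, nn = F.shape[0], F.shape[1], pre.nodes_per_el
    lam3 = np.ones((E, Q)) if lam3_ws is None else lam3_ws.copy()
    S = np.zeros((E, Q, 2, 2))
    CC = np.zeros((E, Q, 2, 2, 2, 2)) if with_tangent else None
    Wtot = 0.0
    for tag, mat in materials.items():
        sel = mesh.region_tag == tag
        if not sel.any():
            continue
        C2d = _c_of(F[sel])
        lam = ct.plane_stress_stretch(mat, C2d, lam3_init=lam3[sel])
        lam3[sel] = lam
        Wm, Sm, CCm = ct.stress_and_condensed_tangent(mat, C2d, lam)
        S[sel] = Sm
        if return_energy:
            Wtot += float((Wm * pre.wdet[sel]).sum())
        if with_tangent:
            if psd_fix:
                CCm = _psd_project_tangent(CCm, 1e-3 * mat.mu0)
            CC[sel] = CCm

    P = np.einsum("eqiK,eqKJ->eqiJ", F, S)  # first Piola-Kirchhoff
    fint_e = np.einsum("eq,eqnJ,eqiJ->eni", pre.wdet, pre.gradN, P)
    R = np.zeros(ndof)
    np.add.at(R, 2 * mesh.elements, fint_e[..., 0])
    np.add.at(R, 2 * mesh.elements + 1, fint_e[..., 1])

    fext, Kload = (
        _pressure_on_edges(mesh, mesh.edge_groups["lumen"], u, p, with_tangent)
        if p != 0.0
        else (np.zeros(ndof), None)
    )
    R -= fext

    if not with_tangent:
        if return_energy:
            return R, None, lam3, Wtot
        return R, None, lam3

    # A_{iJ pQ} = delta_ip S_JQ + F_iK CC_{KJLQ} F_pL
    A = np.einsum("eqiK,eqKJLQ,eqpL->eqiJpQ", F, CC, F, optimize=True)
    A[:, :, 0, :, 0, :] += S
    A[:, :, 1, :, 1, :] += S
    Kel = np.einsum(
        "eq,eqnJ,eqiJpQ,eqmQ->enimp", pre.wdet, pre.gradN, A, pre.gradN, optimize=True
    )
    Kel = Kel.reshape(E, 2 * nn, 2 * nn)
    rows = np.repeat(pre.dofmap, 2 * nn, axis=1).ravel()
    cols = np.tile(pre.dofmap, (1, 2 * nn)).ravel()
    K = sp.coo_matrix((Kel.ravel(), (rows, cols)), shape=(ndof, ndof))
    if Kload is not None:
        K = K - Kload
    if return_energy:
        return R, K.tocsc(), lam3, Wtot
    return R, K.tocsc(), lam3


# ---------------------------------------------------------------------------
# Newton iteration and incremental loading
# ---------------------------------------------------------------------------


def _newton(mesh, materials, u, p, fixed, settings, pre, lam3_ws, log, *,
            beta=0.0, anchor=None):
    """Energy-descent Newton iteration at fixed pressure.

    The uniform lumen pressure is conservative, so equilibrium states are
    stationary points of the total potential Pi(u) = int W dV - p A(u); the
    assembled residual is its exact gradient.  Each iteration solves with
    the (PSD-projected) tangent — identical to the exact tangent wherever
    the response is elliptic — and backtracks with an Armijo condition on
    Pi, which guarantees monotone progress even across wrinkling
    bifurcations where a residual-norm line search has no descent
    direction.  Convergence is still declared on the exact residual norm.

    With ``beta > 0`` the potential gains an artificial-spring term
    ``beta*s/2 |u - anchor|^2`` (stabilised continuation); the spring force
    ratio is recorded in the convergence log.
    """
    free = np.ones(2 * len(mesh.nodes), dtype=bool)
    free[fixed] = False
    fext_ref, _ = _pressure_on_edges(mesh, mesh.edge_groups["lumen"], u, p, False)
    load_norm = np.linalg.norm(fext_ref[free])
    tol = settings.rtol * max(load_norm, 1e-30)

    spring = 0.0

    def merit(uu, lam3_in):
        """(Pi_augmented, R_augmented, lam3) in one tangent-free pass."""
        R, _, lam3, W = assemble(
            mesh, materials, uu, p, pre=pre, lam3_ws=lam3_in,
            with_tangent=False, return_energy=True,
        )
        Pi = W - p * _lumen_enclosed_area(mesh, uu)
        if spring != 0.0:
            d = (uu - anchor).reshape(-1)
            Pi = Pi + 0.5 * spring * float(d[free] @ d[free])
            R = R + spring * d
        return Pi, R, lam3

    res_hist = []
    alpha = 0.0  # Levenberg damping on top of the PSD projection
    slow = 0
    Pi = None
    for it in range(settings.max_newton_iter):
        R, K, lam3_ws = assemble(
            mesh, materials, u, p, pre=pre, lam3_ws=lam3_ws, psd_fix=True
        )
        if it == 0 and beta > 0.0:
            spring = beta * float(np.abs(K.diagonal()).mean())
        if spring != 0.0:
            d = (u - anchor).reshape(-1)
            R = R + spring * d
            K = (K + spring * sp.eye(K.shape[0], format="csc")).tocsc()
        if Pi is None:
            Pi, _, _ = merit(u, lam3_ws)
        rnorm = np.linalg.norm(R[free])
        res_hist.append(rnorm)
        # fail fast when the iteration makes no real progress: healthy runs
        # (including slow wrinkle traversals) contract the residual by well
        # over 2x across any eight-iteration window
        if it >= 8 and rnorm > 0.5 * res_hist[-8]:
            raise _Distorted("stalled iteration")
        if rnorm <= tol:
            rec = {"p": p, "iterations": it, "residual": rnorm, "history": res_hist}
            if spring != 0.0:
                fs = spring * np.linalg.norm((u - anchor).reshape(-1)[free])
                rec["stabilization_ratio"] = fs / max(load_norm, 1e-30)
                rec["beta"] = beta
            log.append(rec)
            return u, lam3_ws

        Kff = K[free][:, free].tocsc()
        dscale = float(np.abs(Kff.diagonal()).mean())
        accepted = False
        while not accepted:
            Km = Kff if alpha == 0.0 else (
                Kff + (alpha * dscale) * sp.eye(Kff.shape[0], format="csc")
            )
            du = np.zeros_like(R)
            du[free] = splu(Km, permc_spec="MMD_AT_PLUS_A").solve(-R[free])
            gd = float(R[free] @ du[free])  # directional derivative of Pi
            if gd >= 0.0:
                alpha = 1e-4 if alpha == 0.0 else alpha * 10.0
                if alpha > 1e4:
                    raise _Distorted("no descent direction for the potential")
                continue
            # ladder search: prefer the step that both lowers the potential
            # (Armijo) and contracts the residual most — an energy-only
            # acceptance can ride the potential downhill into wild states,
            # while a residual-only one has no valid direction at wrinkling
            # bifurcations.  The full Newton step is taken outright whenever
            # it contracts the residual (the ordinary quadratic phase).
            best = None  # (step, Pit, rt, lam3)
            for step in (1.0, 0.4, 0.15, 0.05, 0.015, 0.004):
                ut = (u.reshape(-1) + step * du).reshape(-1, 2)
                try:
                    Pit, Rt, lam3_t = merit(ut, lam3_ws)
                except (_Distorted, ct.PlaneStressError, ct.InvertedStateError):
                    continue
                rt = np.linalg.norm(Rt[free])
                if step == 1.0 and rt <= 0.8 * rnorm:
                    best = (step, Pit, rt, lam3_t)
                    break
                armijo = Pit <= Pi + 1e-4 * step * gd
                contract = rt <= 0.7 * rnorm
                if armijo or contract:
                    if best is None or rt < best[2]:
                        best = (step, Pit, rt, lam3_t)
                    if rt > 2.0 * best[2]:
                        break  # past the U-shaped minimum of rt(step)
            if best is not None:
                step, Pit, rt, lam3_t = best
                u = (u.reshape(-1) + step * du).reshape(-1, 2)
                Pi, lam3_ws = Pit, lam3_t
                slow = slow + 1 if rt > 0.9 * rnorm else 0
                alpha = alpha * 0.25 if rt < 0.5 * rnorm else alpha
                alpha = 0.0 if alpha < 1e-5 else alpha
                if rt > 0.95 * rnorm:
                    alpha = 1e-4 if alpha == 0.0 else min(alpha * 4.0, 1e2)
                accepted = True
            else:
                alpha = 1e-4 if alpha == 0.0 else alpha * 10.0
                if alpha > 1e4:
                    raise _Distorted("energy line search failed")
        if slow >= settings.stall_limit:
            raise _Distorted("stalled energy descent")
    raise _Distorted(f"no convergence in {settings.max_newton_iter} iterations")


def _advance(mesh, materials, u, p_from, p_to, n_sub, fixed, settings, pre, lam3_ws, log,
             rescued=False):
    """March the pressure from p_from to p_to with adaptive halving.

    When a clean increment fails even at the minimum step — which happens
    when the iterate crosses a wrinkling (locally non-elliptic) regime of
    the tissue response — the increment is traversed with stabilised
    continuation: artificial springs to the last converged state, with the
    smallest spring factor that converges, followed by an attempt to relax
    back to the unstabilised equilibrium.  The stabilisation force ratio of
    every rescue is recorded in the convergence log.
    """
    p = p_from
    dp0 = (p_to - p_from) / n_sub
    dp = dp0
    dp_min = dp0 * settings.min_step_fraction
    beta_hint = 1e-2  # working spring factor carried across increments
    # once wrinkling starts, rescue directly instead of halving
    while p < p_to - 1e-12 * max(p_to, 1.0):
        p_try = min(p + dp, p_to)
        try:
            if rescued:
                # wrinkled regime: go straight to stabilised continuation;
                # clean equilibria are recovered at recorded levels only
                u_new, lam3_new, beta_hint = _rescue(
                    mesh, materials, u, p_try, fixed, settings, pre, lam3_ws, log,
                    beta_hint,
                )
            else:
                u_new, lam3_new = _newton(
                    mesh, materials, u.copy(), p_try, fixed, settings, pre, lam3_ws, log
                )
            if len(msh.detect_distortion(mesh, u_new, settings.angle_limit)):
                raise _Distorted("element distortion above angle limit")
        except (_Distorted, ct.PlaneStressError, ct.InvertedStateError) as exc:
            if rescued:
                # a distorted stabilised state: hand over to the remeshing
                # remediation policy
                raise SolverError(
                    f"distorted state at p = {p_try:.6g} Pa in the wrinkled "
                    f"regime: {exc}",
                    history=log,
                ) from exc
            if dp / 2 >= dp_min:
                dp /= 2
                continue
            if not settings.stabilization:
                raise SolverError(
                    f"no convergence at p = {p_try:.6g} Pa at minimum increment: {exc}",
                    history=log,
                ) from exc
            u_new, lam3_new, beta_hint = _rescue(
                mesh, materials, u, p_try, fixed, settings, pre, lam3_ws, log,
                beta_hint,
            )
            rescued = True
        u, lam3_ws, p = u_new, lam3_new, p_try
        if dp < dp0:
            dp = min(2 * dp, dp0)
    return u, lam3_ws, rescued


def _rescue(mesh, materials, u, p_try, fixed, settings, pre, lam3_ws, log, beta_hint=1e-3):
    """Traversal of one load increment across a wrinkling bifurcation with
    spring-anchored stabilisation, starting from the spring factor that
    worked last (pseudo-transient continuation as the deepest fallback).
    Returns ``(u, lam3, beta_used)``."""
    last_exc = None
    short = replace(settings, max_newton_iter=20)
    betas = [beta_hint] + [b for b in (1e-2, 1e-1, 1.0) if b > beta_hint]
    for beta in betas:
        try:
            u_s, l3_s = _newton(
                mesh, materials, u.copy(), p_try, fixed, short, pre, lam3_ws, log,
                beta=beta, anchor=u.copy(),
            )
            return u_s, l3_s, beta
        except (_Distorted, ct.PlaneStressError, ct.InvertedStateError) as exc:
            last_exc = exc
    u_s, l3_s = _pseudo_transient(
        mesh, materials, u, p_try, fixed, settings, pre, lam3_ws, log, last_exc
    )
    return u_s, l3_s, betas[-1]


def _lumen_enclosed_area(mesh, u):
    """Enclosed lumen area via the same quadrature as the follower load.

    A uniform pressure on a closed boundary loop is conservative; the
    follower nodal forces are exactly the gradient of p times this area, so
    the assembled residual is the exact gradient of the total potential
    Pi(u) = int W dV - p * A_lumen(u)."""
    edges = mesh.edge_groups["lumen"]
    nn = edges.shape[1]
    M, dM = _edge_shape(nn)
    x = mesh.nodes[edges] + u.reshape(-1, 2)[edges]
    xq = np.einsum("qn,kni->kqi", M, x)
    tq = np.einsum("qn,kni->kqi", dM, x)
    cross = xq[..., 0] * tq[..., 1] - xq[..., 1] * tq[..., 0]
    return -0.5 * float(np.einsum("q,kq->", _EW, cross))  # solid-on-left loop


def _relax_recorded(mesh, materials, u, p_t, fixed, settings, pre, lam3_ws, log,
                    passes: int = 3):
    """Shrink the artificial-spring content of a recorded stabilised state.

    Re-anchoring the working spring at the current state and re-solving is
    an implicit gradient-flow step whose fixed point is an exact
    equilibrium: each pass converges quickly while the recorded spring
    force shrinks with the drift; a final clean attempt removes it entirely
    whenever the clean equilibrium is attainable."""
    short = replace(settings, max_newton_iter=10)
    beta = next(
        (rec["beta"] for rec in reversed(log) if "beta" in rec), 1e-2
    )
    best = (np.inf, u, lam3_ws)
    for _ in range(passes):
        try:
            u, lam3_ws = _newton(
                mesh, materials, u.copy(), p_t, fixed, short, pre, lam3_ws, log,
                beta=beta, anchor=u.copy(),
            )
        except (_Distorted, ct.PlaneStressError, ct.InvertedStateError):
            break
        ratio = log[-1].get("stabilization_ratio", 0.0)
        if ratio < best[0]:
            best = (ratio, u, lam3_ws)
        else:
            break  # drifting away: no nearby attractor, keep the best state
        if ratio < 1e-3:
            break
    ratio, u, lam3_ws = best
    if ratio > 1e-2:
        return u, lam3_ws  # clean equilibrium out of reach, don't burn budget
    try:
        return _newton(
            mesh, materials, u.copy(), p_t, fixed, short, pre, lam3_ws, log
        )
    except (_Distorted, ct.PlaneStressError, ct.InvertedStateError):
        return u, lam3_ws


def _pseudo_transient(mesh, materials, u, p_try, fixed, settings, pre, lam3_ws, log,
                      last_exc, max_steps: int = 60):
    """Pseudo-transient continuation at fixed pressure: repeated spring-
    anchored solves with the anchor advanced each step (implicit-Euler
    gradient flow toward the discrete equilibrium), with the spring factor
    adapted on the fly.  Returns once a weakly stabilised or clean solve
    converges at this pressure; the accepted state's stabilisation ratio is
    in the log."""
    short = replace(settings, max_newton_iter=12)
    beta = 1.0
    uu, l3 = u.copy(), lam3_ws
    for step in range(max_steps):
        try:
            uu_new, l3_new = _newton(
                mesh, materials, uu.copy(), p_try, fixed, short, pre, l3, log,
                beta=beta, anchor=uu.copy(),
            )
        except (_Distorted, ct.PlaneStressError, ct.InvertedStateError) as exc:
            beta *= 10.0
            if beta > 1e4:
                raise SolverError(
                    f"no convergence at p = {p_try:.6g} Pa even with "
                    f"pseudo-transient stabilization: {exc}",
                    history=log,
                ) from exc
            continue
        drift = float(np.linalg.norm(uu_new - uu)) / max(float(np.linalg.norm(uu_new)), 1e-30)
        uu, l3 = uu_new, l3_new
        # try to land: a weak-spring anchored solve counts as arrival
        if drift < 1e-3 or step % 4 == 3:
            try:
                return _newton(
                    mesh, materials, uu.copy(), p_try, fixed, short, pre, l3, log,
                    beta=1e-4, anchor=uu.copy(),
                )
            except (_Distorted, ct.PlaneStressError, ct.InvertedStateError):
                pass
        beta = max(beta / 3.0, 1e-2)
    raise SolverError(
        f"pseudo-transient continuation did not settle at p = {p_try:.6g} Pa "
        f"within {max_steps} steps: {last_exc}",
        history=log,
    )


def _nearest_corner(mesh: msh.Mesh, point) -> int:
    corners = np.unique(mesh.tri)
    d = np.linalg.norm(mesh.nodes[corners] - point, axis=1)
    return int(corners[np.argmin(d)])


def _pinned_nodes(domain: geo.PlanarDomain, mesh: msh.Mesh) -> tuple[int, int]:
    """Mesh nodes closest to the domain's pin points (corner nodes only)."""
    return tuple(_nearest_corner(mesh, pp) for pp in domain.pin_points)


def _fixed_dofs(domain: geo.PlanarDomain, mesh: msh.Mesh, mode: str) -> np.ndarray:
    """Constrained dofs for the given BC mode.

    "both"/"minimal" pin the two outer pin points (see
    :class:`BoundaryConditions`); "symmetry" instead imposes the
    symmetry-consistent minimal set ux = 0 on the vertical axis and uy = 0 on
    the horizontal axis (used for radially symmetric verification problems,
    where pinning full points would perturb the radial field)."""
    if mode in ("both", "minimal"):
        return BoundaryConditions(_pinned_nodes(domain, mesh), mode).fixed_dofs()
    if mode == "symmetry":
        prm = domain.params
        cx, cy = prm.lumen_center
        r = prm.outer_radius
        top = _nearest_corner(mesh, (cx, cy + r))
        bot = _nearest_corner(mesh, (cx, cy - r))
        left = _nearest_corner(mesh, (cx - r, cy))
        right = _nearest_corner(mesh, (cx + r, cy))
        return np.unique([2 * top, 2 * bot, 2 * left + 1, 2 * right + 1])
    raise ValueError(f"unknown BC mode {mode!r}")


def solve_case(
    case_id: str | None = None,
    *,
    domain: geo.PlanarDomain | None = None,
    mesh: msh.Mesh | None = None,
    geometry: geo.GeometryParams | None = None,
    materials: dict[str, ct.MooneyRivlin5] | None = None,
    load: LoadProgram | None = None,
    settings: SolverSettings | None = None,
    h_coarse: float = 5.0e-4,
    h_fine: float = 2.5e-4,
    quadratic: bool = True,
    record_sweep: bool = False,
) -> SolutionField:
    """Solve one study configuration up to the target pressure.

    Either a ``case_id`` from the registry or an explicit ``domain`` must be
    given.  With ``record_sweep`` (used by :func:`sweep_pressure` through
    ``load.sweep``) every sweep pressure level is recorded; otherwise only
    the final state is stored.
    """
    load = load or LoadProgram()
    settings = settings or SolverSettings()
    materials = materials or material_map()
    if domain is None:
        if case_id is None:
            raise ValueError("need case_id or domain")
        domain = geo.build_case(case_id, geometry)
    case_id = case_id or "custom"

    targets = list(load.sweep) if load.sweep else [load.target_pressure]
    n_first = load.n_increments

    h_c, h_f = h_coarse, h_fine
    for refinement in range(settings.max_mesh_refinements + 1):
        m = mesh if mesh is not None and refinement == 0 else msh.generate_mesh(
            domain, h_c, h_f, quadratic
        )
        pre = _precompute(m)
        fixed = _fixed_dofs(domain, m, settings.bc_mode)
        u = np.zeros_like(m.nodes)
        lam3_ws = np.ones(pre.wdet.shape)
        log: list[dict] = []
        pressures: list[float] = []
        snaps: list[np.ndarray] = []
        work = 0.0
        f_prev = np.zeros(2 * len(m.nodes))
        try:
            p_prev = 0.0
            rescued = False
            for k, p_t in enumerate(targets):
                n_sub = n_first if k == 0 else max(1, n_first // len(targets))
                if load.sweep:
                    n_sub = max(2, n_first // len(targets)) if k == 0 else 1
                u_new, lam3_ws, rescued = _advance(
                    m, materials, u, p_prev, p_t, n_sub, fixed, settings, pre,
                    lam3_ws, log, rescued=rescued,
                )
                recording = record_sweep or k == len(targets) - 1
                if rescued and recording:
                    passes = 3 if k == len(targets) - 1 else 1
                    u_new, lam3_ws = _relax_recorded(
                        m, materials, u_new, p_t, fixed, settings, pre, lam3_ws,
                        log, passes=passes,
                    )
                f_new, _ = _pressure_on_edges(m, m.edge_groups["lumen"], u_new, p_t, False)
                work += 0.5 * float((f_prev + f_new) @ (u_new - u).reshape(-1))
                u, p_prev, f_prev = u_new, p_t, f_new
                if recording:
                    pressures.append(p_t)
                    snaps.append(u.copy())
            return SolutionField(
                case_id=case_id, domain=domain, mesh=m, materials=materials,
                pressures=pressures, displacements=snaps, log=log,
                external_work=work,
            )
        except SolverError:
            if refinement == settings.max_mesh_refinements:
                raise
            h_c, h_f = 0.75 * h_c, 0.75 * h_f
            mesh = None
    raise AssertionError("unreachable")


def sweep_pressure(
    case_id: str | None = None,
    pressures: tuple[float, ...] | None = None,
    **kwargs,
) -> SolutionField:
    """Warm-started continuation over a strictly increasing pressure list.

    Defaults to the 13-level program 196, 392, ..., 2584 Pa.  The returned
    solution records the displacement at every sweep level.
    """
    if pressures is None:
        pressures = tuple(196.0 * k for k in range(1, 14))
    load = kwargs.pop("load", None) or LoadProgram(
        target_pressure=pressures[-1], n_increments=20, sweep=tuple(pressures)
    )
    return solve_case(case_id, load=load, record_sweep=True, **kwargs)
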