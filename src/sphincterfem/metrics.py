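"""Post-processing: lumen area, opening loss/recovery, principal fields.

The primary clinical outcome of the simulation is the deformed open
cross-sectional area A of the lumen.  Two derived percentages compare the
drilled configurations Hi against the sane (P0) and fibrotic no-hole (H0)
baselines:

    opening loss      delta_l = 100 * (A(Hi) - A(P0)) / A(H0)   [%]
    opening recovery  delta_r = 100 * (A(Hi) - A(H0)) / A(H0)   [%]

(the loss is normalised by A(H0), exactly as defined in the study design).

Principal-field reporting uses the Cauchy stress and, by default, the
logarithmic (Hencky) strain ln(lambda_i) of the principal stretches
including the out-of-plane stretch; Green–Lagrange strain is available via
``measure="green"``.  The per-point "maximum principal" value includes the
zero out-of-plane principal stress of plane stress, so it is never negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import meshing as msh
from .solver import SolutionField, _precompute, _deformation_gradients

__all__ = [
    "MetricsReport",
    "BoundaryProfile",
    "GeometricValidityError",
    "lumen_area",
    "opening_loss",
    "opening_recovery",
    "principal_fields",
    "boundary_profile",
    "case_metrics",
    "battery_table",
]


class GeometricValidityError(RuntimeError):
    """Deformed boundary is self-intersecting."""


@dataclass
class MetricsReport:
    """Per-case scalar outputs (the machine-readable results-table row)."""

    case_id: str
    area_mm2: float
    delta_l_pct: float | None = None
    delta_r_pct: float | None = None
    smax_Pa: float | None = None
    smin_Pa: float | None = None
    emax: float | None = None
    emin: float | None = None
    strain_measure: str = "hencky"


@dataclass
class BoundaryProfile:
    """Fields along the deformed intraluminal edge of one arc.

    ``s`` is the curvilinear abscissa [m], clockwise along the deformed
    lumen boundary, restarting at zero at the start of each arc
    ("physiological": upper half; "fibrotic": lower half, split at the
    sane/fibrotic interface points of the undeformed tags)."""

    arc: str
    s: np.ndarray
    e_max: np.ndarray
    s_max_Pa: np.ndarray
    length: float = 0.0  # total deformed arc length [m]


# ---------------------------------------------------------------------------
# Lumen area
# ---------------------------------------------------------------------------


def _ordered_loop(edges: np.ndarray) -> np.ndarray:
    """Order an oriented closed edge set into traversal order."""
    nxt = {int(e[0]): i for i, e in enumerate(edges)}
    out = []
    i = 0
    start = int(edges[0, 0])
    node = start
    for _ in range(len(edges)):
        i = nxt[node]
        out.append(i)
        node = int(edges[i, 1])
        if node == start and len(out) < len(edges):
            raise msh.MeshingError("edge group contains more than one loop")
    return edges[out]


# Gauss rule on [0, 1] shared with the solver's edge integration
_EQ = (np.array([-np.sqrt(3 / 5), 0.0, np.sqrt(3 / 5)]) + 1) / 2
_EW = np.array([5 / 18, 8 / 18, 5 / 18])


def _loop_signed_area_and_lengths(xy_loop: np.ndarray, quadratic: bool):
    """Signed shoelace area and per-edge arc lengths of a closed loop given
    per-edge node coordinates (K, nn, 2) in traversal order."""
    if quadratic:
        xi = _EQ
        M = np.stack([(1 - xi) * (1 - 2 * xi), xi * (2 * xi - 1), 4 * xi * (1 - xi)], axis=1)
        dM = np.stack([4 * xi - 3, 4 * xi - 1, 4 - 8 * xi], axis=1)
    else:
        xi = _EQ
        M = np.stack([1 - xi, xi], axis=1)
        dM = np.stack([-np.ones_like(xi), np.ones_like(xi)], axis=1)
    x = np.einsum("qn,kni->kqi", M, xy_loop)
    t = np.einsum("qn,kni->kqi", dM, xy_loop)
    cross = x[..., 0] * t[..., 1] - x[..., 1] * t[..., 0]
    area = 0.5 * float(np.einsum("q,kq->", _EW, cross))
    lengths = np.einsum("q,kq->k", _EW, np.linalg.norm(t, axis=-1))
    return area, lengths


def lumen_area(solution: SolutionField, level: int = -1) -> float:
    """Deformed open cross-sectional area of the lumen [mm^2].

    Signed shoelace integral over the deformed intraluminal boundary with
    curved-edge (quadratic) correction; raises
    :class:`GeometricValidityError` if the deformed corner polyline
    self-intersects."""
    mesh = solution.mesh
    u = solution.displacements[level]
    edges = _ordered_loop(mesh.edge_groups["lumen"])
    xy = mesh.nodes[edges] + u[edges]

    import shapely.geometry as sg

    poly = sg.LineString(np.vstack([xy[:, 0], xy[:1, 0]]))
    if not poly.is_simple:
        raise GeometricValidityError("deformed lumen boundary self-intersects")

    area, _ = _loop_signed_area_and_lengths(xy, mesh.quadratic)
    # lumen edges are stored solid-on-left, i.e. clockwise around the lumen,
    # so the enclosed (lumen) area is minus the shoelace value
    return -area * 1e6


def opening_loss(A_i: float, A_P0: float, A_H0: float) -> float:
    """Opening-capacity loss delta_l [%] of configuration i."""
    if A_H0 == 0:
        raise ZeroDivisionError("A(H0) must be non-zero")
    return 100.0 * (A_i - A_P0) / A_H0


def opening_recovery(A_i: float, A_H0: float) -> float:
    """Opening-deformation recovery delta_r [%] of configuration i."""
    if A_H0 == 0:
        raise ZeroDivisionError("A(H0) must be non-zero")
    return 100.0 * (A_i - A_H0) / A_H0


# ---------------------------------------------------------------------------
# Principal fields
# ---------------------------------------------------------------------------


def _principal_from_sym2(T: np.ndarray):
    """Eigenvalues of symmetric 2x2 tensors (..., 2, 2), ascending."""
    a, b, c = T[..., 0, 0], T[..., 1, 1], T[..., 0, 1]
    m = 0.5 * (a + b)
    r = np.sqrt(0.25 * (a - b) ** 2 + c**2)
    return np.stack([m - r, m + r], axis=-1)


def principal_fields(solution: SolutionField, level: int = -1, measure: str = "hencky"):
    """Per-quadrature-point maximum principal Cauchy stress and strain.

    Returns a dict with arrays ``smax`` [Pa] and ``emax`` (dimensionless,
    per-point maxima over the three principal directions including the
    out-of-plane one) plus their global extrema (the results-table ranges).
    """
    F, lam3, S2d, sigma, wdet = solution.qp_state(level)
    sp = _principal_from_sym2(sigma)
    # plane stress: the third principal stress is exactly zero
    smax = np.maximum(sp[..., 1], 0.0)

    C = np.einsum("...ki,...kj->...ij", F, F)
    cp = _principal_from_sym2(C)
    lam = np.sqrt(np.concatenate([cp, (lam3**2)[..., None]], axis=-1))
    if measure == "hencky":
        e = np.log(lam)
    elif measure == "green":
        e = 0.5 * (lam**2 - 1.0)
    else:
        raise ValueError(f"unknown strain measure {measure!r}")
    emax = e.max(axis=-1)
    return {
        "smax": smax,
        "emax": emax,
        "smax_range": (float(smax.min()), float(smax.max())),
        "emax_range": (float(emax.min()), float(emax.max())),
        "measure": measure,
    }


# ---------------------------------------------------------------------------
# Boundary profiles
# ---------------------------------------------------------------------------


def boundary_profile(
    solution: SolutionField, arc: str, level: int = -1, measure: str = "hencky"
) -> BoundaryProfile:
    """Principal fields along the deformed intraluminal edge of one arc.

    ``arc`` is "physiological" (upper half) or "fibrotic" (lower half); the
    split points are the sane/fibrotic interface points of the undeformed
    region tags, mapped to the deformed boundary.  The abscissa runs
    clockwise.  Fields are sampled from the quadrature point of the owning
    element nearest to each edge midpoint.
    """
    if arc not in ("physiological", "fibrotic"):
        raise ValueError("arc must be 'physiological' or 'fibrotic'")
    mesh = solution.mesh
    u = solution.displacements[level]
    loop = _ordered_loop(mesh.edge_groups["lumen"])
    # stored orientation is clockwise around the lumen already (solid on left)
    xy = mesh.nodes[loop] + u[loop]
    _, lengths = _loop_signed_area_and_lengths(xy, mesh.quadratic)

    # undeformed midpoint angle decides the arc of each edge
    mid_ref = mesh.nodes[loop[:, :2]].mean(axis=1) - solution.domain.center
    ang = np.arctan2(mid_ref[:, 1], mid_ref[:, 0])
    is_phys = ang > 0

    # rotate the loop so traversal starts at the requested arc's first edge
    target = is_phys if arc == "physiological" else ~is_phys
    if target.all() or not target.any():
        sel_order = np.arange(len(loop))  # single-material boundary
        target = np.ones(len(loop), dtype=bool)
    else:
        starts = np.flatnonzero(target & ~np.roll(target, 1))
        k0 = starts[0]
        sel_order = (np.arange(len(loop)) + k0) % len(loop)
    order = [i for i in sel_order if target[i]]
    s_edges = lengths[order]
    s = np.concatenate([[0.0], np.cumsum(s_edges)])[:-1] + s_edges / 2.0

    # owning element of each boundary edge and its nearest quadrature point
    F, lam3, S2d, sigma, _ = solution.qp_state(level)
    pairs = {}
    for e_idx, tri in enumerate(mesh.tri):
        for k in range(3):
            pairs[(tri[k], tri[(k + 1) % 3])] = e_idx
    qp_ref = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
    emax = np.empty(len(order))
    smax = np.empty(len(order))
    for j, i_edge in enumerate(order):
        a, b = int(loop[i_edge, 0]), int(loop[i_edge, 1])
        e_idx = pairs[(a, b)]
        tri = mesh.tri[e_idx]
        # reference coords of the edge midpoint within the element
        verts = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        ia, ib = list(tri).index(a), list(tri).index(b)
        mid = 0.5 * (verts[ia] + verts[ib])
        q = int(np.argmin(np.linalg.norm(qp_ref - mid, axis=1)))
        sp = _principal_from_sym2(sigma[e_idx, q])
        smax[j] = max(float(sp[-1]), 0.0)
        C = F[e_idx, q].T @ F[e_idx, q]
        lam = np.sqrt(np.concatenate([_principal_from_sym2(C), [lam3[e_idx, q] ** 2]]))
        if measure == "hencky":
            emax[j] = float(np.log(lam).max())
        else:
            emax[j] = float((0.5 * (lam**2 - 1)).max())
    return BoundaryProfile(arc=arc, s=s, e_max=emax, s_max_Pa=smax,
                           length=float(s_edges.sum()))


# ---------------------------------------------------------------------------
# Case and battery reports
# ---------------------------------------------------------------------------


def case_metrics(
    solution: SolutionField,
    A_P0: float | None = None,
    A_H0: float | None = None,
    measure: str = "hencky",
) -> MetricsReport:
    """Scalar report row for one solved case."""
    A = lumen_area(solution)
    pf = principal_fields(solution, measure=measure)
    dl = dr = None
    if A_P0 is not None and A_H0 is not None and solution.case_id != "P0":
        dl = opening_loss(A, A_P0, A_H0)
        if solution.case_id != "H0" and len(solution.domain.holes) > 0:
            dr = opening_recovery(A, A_H0)
    return MetricsReport(
        case_id=solution.case_id,
        area_mm2=A,
        delta_l_pct=dl,
        delta_r_pct=dr,
        smin_Pa=pf["smax_range"][0],
        smax_Pa=pf["smax_range"][1],
        emin=pf["emax_range"][0],
        emax=pf["emax_range"][1],
        strain_measure=measure,
    )


def battery_table(solutions: dict[str, SolutionField], measure: str = "hencky") -> pd.DataFrame:
    """Results table over a set of solved cases (one row per case).

    delta columns are computed against the P0 and H0 rows of the same
    bundle; areas in mm^2, deltas in percent, rounded to 2 decimals in the
    exported CSV (full precision kept in the returned frame).
    """
    A_P0 = lumen_area(solutions["P0"]) if "P0" in solutions else None
    A_H0 = lumen_area(solutions["H0"]) if "H0" in solutions else None
    rows = []
    for cid, sol in solutions.items():
        r = case_metrics(sol, A_P0, A_H0, measure=measure)
        rows.append(
            {
                "case_id": cid,
                "A_mm2": r.area_mm2,
                "delta_l_pct": r.delta_l_pct,
                "delta_r_pct": r.delta_r_pct,
                "smax_Pa": r.smax_Pa,
                "emax": r.emax,
            }
        )
    return pd.DataFrame(rows)
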