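"""Triangular meshing of the sphincter cross-section.

A force-equilibrium (Persson–Strang) mesh generator on signed-distance
functions: points relax under repulsive bar forces over successive Delaunay
triangulations until the edge lengths match a prescribed size field.  The
size field implements the model's two-level refinement — a fine band covering
the dense-connective ring and its surroundings plus a band around every
surgical hole, coarse elsewhere — and the generator is deterministic (fixed
internal seed for the density-controlled initial point rejection; everything
else is arithmetic).

Boundary points on the lumen, hole, and outer curves are seeded as fixed
points at the local target spacing, so boundary loops lie exactly on the
analytic curves; with quadratic (6-node) elements the midside nodes of
boundary edges are snapped back onto the curves.

Orientation conventions: triangles are counterclockwise; boundary-edge groups
are stored in triangle order, i.e. traversed with the solid on the left, so
the into-the-solid normal of an edge with tangent t is (-t_y, t_x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .geometry import PlanarDomain

__all__ = [
    "Mesh",
    "MeshQuality",
    "MeshingError",
    "generate_mesh",
    "mesh_quality",
    "detect_distortion",
    "triangulate",
    "mesh_unit_square",
]

_SEED = 20210622  # fixed internal seed: meshing is reproducible bit-for-bit
# internal size-field scale: equilibrium edge lengths fluctuate around the
# target, so aim below the requested maxima to keep them hard bounds
_SIZE_SCALE = 0.66


class MeshingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Core distmesh iteration
# ---------------------------------------------------------------------------


def triangulate(
    fd,
    fh,
    bbox: tuple[float, float, float, float],
    pfix: np.ndarray,
    h0: float,
    *,
    max_iter: int = 140,
    dptol: float = 1e-3,
    seed: int = _SEED,
) -> tuple[np.ndarray, np.ndarray]:
    """Persson–Strang triangulation of the region {fd <= 0}.

    ``fd``: signed distance to the region boundary (negative inside);
    ``fh``: relative element-size field; ``pfix``: points that never move;
    ``h0``: smallest target edge length.  Returns (points, triangles) with
    counterclockwise triangles.
    """
    xmin, ymin, xmax, ymax = bbox
    geps = 1e-3 * h0
    deps = np.sqrt(np.finfo(float).eps) * h0
    deltat, fscale, ttol = 0.2, 1.2, 0.1

    # initial equilateral grid, density-thinned by the size field
    xs = np.arange(xmin, xmax + h0, h0)
    ys = np.arange(ymin, ymax + h0 * np.sqrt(3) / 2, h0 * np.sqrt(3) / 2)
    X, Y = np.meshgrid(xs, ys)
    X[1::2] += h0 / 2
    p = np.c_[X.ravel(), Y.ravel()]
    p = p[fd(p) < geps]
    r0 = 1.0 / fh(p) ** 2
    rng = np.random.default_rng(seed)
    p = p[rng.random(len(p)) < r0 / r0.max()]

    pfix = np.asarray(pfix, dtype=float).reshape(-1, 2)
    if len(pfix):
        # drop initial points that crowd the fixed ones
        tree = cKDTree(pfix)
        d, _ = tree.query(p)
        p = p[d > 0.7 * fh(p)]
        p = np.vstack([pfix, p])
    nfix = len(pfix)

    pold = np.full_like(p, np.inf)
    tri = None
    for _ in range(max_iter):
        if np.max(np.linalg.norm(p - pold, axis=1)) > ttol * h0:
            pold = p.copy()
            tri = _good_triangles(p, fd, geps)
            bars = np.unique(
                np.sort(
                    np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1
                ),
                axis=0,
            )
        barvec = p[bars[:, 0]] - p[bars[:, 1]]
        L = np.linalg.norm(barvec, axis=1)
        hbars = fh((p[bars[:, 0]] + p[bars[:, 1]]) / 2)
        L0 = hbars * fscale * np.sqrt((L**2).sum() / (hbars**2).sum())
        F = np.maximum(L0 - L, 0.0)
        Fvec = (F / np.where(L == 0, 1.0, L))[:, None] * barvec
        Ftot = np.zeros_like(p)
        np.add.at(Ftot, bars[:, 0], Fvec)
        np.add.at(Ftot, bars[:, 1], -Fvec)
        Ftot[:nfix] = 0.0
        p = p + deltat * Ftot

        # project escaped points back onto the boundary
        d = fd(p)
        out = d > 0
        if out.any():
            dgx = (fd(p[out] + [deps, 0]) - d[out]) / deps
            dgy = (fd(p[out] + [0, deps]) - d[out]) / deps
            g2 = dgx**2 + dgy**2
            g2 = np.where(g2 == 0, 1.0, g2)
            p[out] -= (d[out] / g2)[:, None] * np.c_[dgx, dgy]

        inner = d < -geps
        inner[:nfix] = False
        if inner.any():
            move = np.max(np.linalg.norm(deltat * Ftot[inner], axis=1))
            if move < dptol * h0:
                break

    tri = _good_triangles(p, fd, geps)
    # drop unused points and remap
    used = np.unique(tri)
    remap = -np.ones(len(p), dtype=int)
    remap[used] = np.arange(len(used))
    return p[used], remap[tri]


def _good_triangles(p: np.ndarray, fd, geps: float) -> np.ndarray:
    tri = Delaunay(p).simplices
    cent = p[tri].mean(axis=1)
    tri = tri[fd(cent) < -geps]
    # enforce counterclockwise orientation
    a = _signed_areas(p, tri)
    flip = a < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return tri


def _signed_areas(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    d1 = p[tri[:, 1]] - p[tri[:, 0]]
    d2 = p[tri[:, 2]] - p[tri[:, 0]]
    return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])


# ---------------------------------------------------------------------------
# Signed distance and size fields for the sphincter domain
# ---------------------------------------------------------------------------


def _domain_fd(domain: PlanarDomain):
    prm = domain.params
    cx, cy = prm.lumen_center
    holes = [(np.asarray(c, float), r) for c, r in domain.holes]

    if domain.annulus_only:
        r_in, r_out = prm.lumen_radius, prm.outer_radius

        def fd(p):
            rr = np.hypot(p[:, 0] - cx, p[:, 1] - cy)
            return np.maximum(rr - r_out, r_in - rr)

        return fd

    r_lum = prm.lumen_radius
    r0slot = prm.epi_radius + prm.bound_length
    alpha = prm.slot_half_angle

    def fd(p):
        x = p[:, 0] - cx
        y = p[:, 1] - cy
        rr = np.hypot(x, y)
        th = np.arctan2(y, x)
        d = np.maximum(rr - prm.outer_radius_at(th), r_lum - rr)
        # two lateral V-notches: radial wedge SDF (negative inside), subtracted
        for sgn in (1.0, -1.0):
            tht = np.arctan2(y, sgn * x)  # angle from the wedge axis
            d_lines = rr * np.maximum(np.sin(tht - alpha), np.sin(-tht - alpha))
            d_wedge = np.maximum(d_lines, r0slot - rr)
            d = np.maximum(d, -d_wedge)
        for c, r in holes:
            d = np.maximum(d, r - np.hypot(p[:, 0] - c[0], p[:, 1] - c[1]))
        return d

    return fd


def _domain_fh(domain: PlanarDomain, h_coarse: float, h_fine: float, band: float):
    prm = domain.params
    cx, cy = prm.lumen_center
    holes = [(np.asarray(c, float), r) for c, r in domain.holes]
    grading = 0.35
    r_fine = prm.epi_radius + band

    def fh(p):
        rr = np.hypot(p[:, 0] - cx, p[:, 1] - cy)
        d = np.maximum(rr - r_fine, 0.0)
        h = h_fine + grading * d
        for c, r in holes:
            # cap the local size so every hole boundary stays well resolved
            # even when the requested sizes are very coarse
            h_hole = min(h_fine, r / 2.5)
            dh = np.maximum(np.hypot(p[:, 0] - c[0], p[:, 1] - c[1]) - (r + band), 0.0)
            h = np.minimum(h, h_hole + grading * dh)
        return np.minimum(h, h_coarse)

    return fh


def _circle_points(center, radius, spacing) -> np.ndarray:
    n = max(8, int(np.ceil(2 * np.pi * radius / spacing)))
    th = 2 * np.pi * np.arange(n) / n
    return np.c_[center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]


def _fixed_points(domain: PlanarDomain, h_coarse, h_fine, fd, fh) -> np.ndarray:
    prm = domain.params
    cx, cy = prm.lumen_center

    def local_h(center, radius):
        # sample the size field on the circle so boundary spacing matches it
        return float(fh(np.array([[center[0] + radius, center[1]]]))[0])

    pts = [_circle_points((cx, cy), prm.lumen_radius, local_h((cx, cy), prm.lumen_radius))]
    if domain.annulus_only:
        pts.append(_circle_points((cx, cy), prm.outer_radius, h_coarse))
        return np.vstack(pts)

    pts.append(_circle_points((cx, cy), prm.epi_radius, h_fine))
    for c, r in domain.holes:
        pts.append(_circle_points(c, r, local_h(c, r)))
    # outer curve, sampled by arc length at the coarse spacing
    th = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    r = prm.outer_radius_at(th)
    xy = np.c_[cx + r * np.cos(th), cy + r * np.sin(th)]
    seg = np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # walk the outer curve placing points at the local target spacing
    hloc = fh(xy)
    pos, target = [], 0.0
    for k in range(len(xy)):
        if s[k] >= target:
            pos.append(k)
            target = s[k] + hloc[k]
    outer_pts = xy[pos]
    if len(outer_pts) > 1 and s[-1] - s[pos[-1]] < 0.5 * hloc[pos[-1]]:
        outer_pts = outer_pts[:-1]

    # V-notch outlines: two straight walls (rays at +-alpha from the lateral
    # axis, from the inner arc to the exact outer-curve corner) plus the
    # inner arc at the bound radius
    r0slot = prm.epi_radius + prm.bound_length
    alpha = prm.slot_half_angle
    corners = []
    for base in (0.0, np.pi):
        for sa in (alpha, -alpha):
            th_wall = base + sa
            r_end = prm.outer_radius_at(th_wall)
            p0 = np.array([cx + r0slot * np.cos(th_wall), cy + r0slot * np.sin(th_wall)])
            p1 = np.array([cx + r_end * np.cos(th_wall), cy + r_end * np.sin(th_wall)])
            length = np.linalg.norm(p1 - p0)
            n = max(2, int(np.ceil(length / h_coarse)))
            ts = np.linspace(0.0, 1.0, n + 1)
            pts.append(p0 + ts[:, None] * (p1 - p0))
            corners.append(tuple(p1))
        arc_len = 2 * alpha * r0slot
        m = max(2, int(np.ceil(arc_len / h_coarse)))
        th_arc = base + np.linspace(-alpha, alpha, m + 1)[1:-1]
        pts.append(np.c_[cx + r0slot * np.cos(th_arc), cy + r0slot * np.sin(th_arc)])
        # sane/fibrotic interface along the bound segment (conforming tags)
        nb = max(2, int(np.ceil(prm.bound_length / h_coarse)))
        xs = np.linspace(prm.epi_radius, r0slot, nb + 1)[1:-1]
        pts.append(np.c_[cx + np.cos(base) * xs, np.full(len(xs), cy)])

    # keep outer points clear of the slots and of the mouth corners
    keep = np.abs(fd(outer_pts)) < 0.25 * h_coarse
    for qx, qy in corners:
        keep &= np.hypot(outer_pts[:, 0] - qx, outer_pts[:, 1] - qy) > 0.55 * h_coarse
    pts.append(outer_pts[keep])
    allp = np.vstack(pts)
    # dedupe
    _, idx = np.unique(np.round(allp / (1e-4 * h_fine)).astype(np.int64), axis=0, return_index=True)
    return allp[np.sort(idx)]


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """Triangulated domain with region tags and named boundary edge groups.

    ``nodes``: (N, 2) coordinates [m].  ``tri``: (E, 3) corner connectivity
    (counterclockwise).  ``elements``: (E, 6) with midside nodes
    [v0, v1, v2, m01, m12, m20] when quadratic, else identical to ``tri``.
    ``edge_groups``: "lumen" and "outer" map to (K, 2) or (K, 3) edge arrays
    (corner, corner[, midside]) in solid-on-left orientation; "holes" is a
    list of such arrays, one per hole.
    """

    nodes: np.ndarray
    tri: np.ndarray
    elements: np.ndarray
    region_tag: np.ndarray
    edge_groups: dict
    h_coarse: float
    h_fine: float
    quadratic: bool = True

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tri)

    def signed_areas(self) -> np.ndarray:
        return _signed_areas(self.nodes, self.tri)

    def edge_lengths(self) -> np.ndarray:
        """Corner-edge lengths of every element, shape (E, 3)."""
        p = self.nodes[self.tri]
        return np.stack(
            [
                np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
                np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
                np.linalg.norm(p[:, 0] - p[:, 2], axis=1),
            ],
            axis=1,
        )


def _corner_angles(nodes: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Interior angles per element in degrees, shape (E, 3)."""
    p = nodes[tri]
    ang = np.empty((len(tri), 3))
    for k in range(3):
        a = p[:, (k + 1) % 3] - p[:, k]
        b = p[:, (k + 2) % 3] - p[:, k]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosv = np.einsum("ij,ij->i", a, b) / np.where(na * nb == 0, 1.0, na * nb)
        ang[:, k] = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
    return ang


@dataclass
class MeshQuality:
    min_angle_deg: float
    max_angle_deg: float
    max_aspect: float
    n_elements: int
    n_nodes: int
    region_counts: dict


def mesh_quality(mesh: Mesh) -> MeshQuality:
    """Aggregate per-element angle and aspect-ratio statistics."""
    ang = _corner_angles(mesh.nodes, mesh.tri)
    L = mesh.edge_lengths()
    aspect = L.max(axis=1) / L.min(axis=1)
    labels, counts = np.unique(mesh.region_tag, return_counts=True)
    return MeshQuality(
        min_angle_deg=float(ang.min()),
        max_angle_deg=float(ang.max()),
        max_aspect=float(aspect.max()),
        n_elements=mesh.n_elements,
        n_nodes=mesh.n_nodes,
        region_counts=dict(zip(labels.tolist(), counts.tolist())),
    )


def detect_distortion(mesh: Mesh, displacement: np.ndarray, angle_limit: float = 160.0) -> np.ndarray:
    """Indices of elements whose displaced maximum corner angle exceeds
    ``angle_limit`` degrees (strict inequality) or whose displaced signed
    area is non-positive (inverted elements are always flagged)."""
    displacement = np.asarray(displacement, dtype=float)
    if displacement.shape != mesh.nodes.shape:
        raise ValueError("displacement must be defined on all nodes (corner + midside)")
    moved = mesh.nodes + displacement
    ang = _corner_angles(moved, mesh.tri)
    areas = _signed_areas(moved, mesh.tri)
    flagged = (ang.max(axis=1) > angle_limit) | (areas <= 0.0)
    return np.flatnonzero(flagged)


# ---------------------------------------------------------------------------
# generate_mesh
# ---------------------------------------------------------------------------


def generate_mesh(
    domain: PlanarDomain,
    h_coarse: float = 2.0e-4,
    h_fine: float = 1.0e-4,
    quadratic: bool = True,
    *,
    refine_band: float | None = None,
    max_iter: int = 140,
) -> Mesh:
    """Mesh the domain with two-level refinement.

    ``h_coarse`` caps every element edge; ``h_fine`` caps edges of elements
    in the dense-connective band and around holes.  Deterministic for
    identical inputs.
    """
    if not 0 < h_fine <= h_coarse:
        raise MeshingError("need 0 < h_fine <= h_coarse")
    if refine_band is None:
        # wide enough that every element touching the dense-connective ring
        # (including tag-fuzz straddlers) lies inside the fine zone
        refine_band = max(2.5e-4, 1.2 * h_fine)
    prm = domain.params
    fd = _domain_fd(domain)
    fh_spec = _domain_fh(domain, h_coarse, h_fine, refine_band)
    cx, cy = prm.lumen_center
    R = prm.outer_radius * (1.0 + abs(prm.outer_ovality)) + prm.outer_center_offset
    bbox = (cx - R, cy - R, cx + R, cy + R)

    # the requested sizes are hard caps: re-triangulate with a shrunken size
    # field if a few equilibrium edges overshoot (deterministic)
    scale = _SIZE_SCALE
    for attempt in range(4):
        def fh(p, _s=scale):
            return _s * fh_spec(p)

        pfix = _fixed_points(domain, scale * h_coarse, scale * h_fine, fd, fh)
        try:
            nodes, tri = triangulate(fd, fh, bbox, pfix, scale * h_fine, max_iter=max_iter)
        except Exception as exc:  # pragma: no cover - defensive
            raise MeshingError(f"triangulation failed: {exc}") from exc
        if len(tri) == 0:
            raise MeshingError("triangulation produced no elements")
        ratio = _cap_violation(domain, nodes, tri, h_coarse, h_fine, refine_band)
        if ratio <= 1.0:
            break
        scale /= 1.05 * ratio
    cent = nodes[tri].mean(axis=1)
    region_tag = domain.classify(cent)

    mesh = _assemble_mesh(domain, nodes, tri, region_tag, h_coarse, h_fine, quadratic)
    return mesh


def _cap_violation(domain, nodes, tri, h_coarse, h_fine, band) -> float:
    """Worst ratio of corner-edge length to its local cap (fine inside the
    dense-connective band and around holes, coarse elsewhere)."""
    prm = domain.params
    cx, cy = prm.lumen_center
    r_fine = prm.epi_radius + band

    def cap(q):
        rr = np.hypot(q[:, 0] - cx, q[:, 1] - cy)
        fine = rr <= r_fine
        for c, r in domain.holes:
            fine |= np.hypot(q[:, 0] - c[0], q[:, 1] - c[1]) <= r + band
        return np.where(fine, h_fine, h_coarse)

    p = nodes[tri]
    ratio = 0.0
    for k in range(3):
        a, b = p[:, k], p[:, (k + 1) % 3]
        L = np.linalg.norm(b - a, axis=1)
        ratio = max(ratio, float((L / cap((a + b) / 2.0)).max()))
    return ratio


def _assemble_mesh(domain, nodes, tri, region_tag, h_coarse, h_fine, quadratic):
    prm = domain.params
    cx, cy = prm.lumen_center

    # --- boundary edges: appear in exactly one triangle, kept in triangle
    # orientation (solid on the left); group them into closed loops and
    # assign each loop topologically (the distance-to-curve heuristic is
    # fragile on coarse meshes)
    edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    bnd = edges[counts[inv] == 1]

    import shapely.geometry as sg

    loops = _split_loops(bnd)
    polys = [sg.Polygon(nodes[lp[:, 0]]) for lp in loops]
    i_outer = int(np.argmax([p.area for p in polys]))
    lumen_edges = None
    hole_edges: list = [None] * len(domain.holes)
    for i, (lp, poly) in enumerate(zip(loops, polys)):
        if i == i_outer:
            continue
        if poly.contains(sg.Point(cx, cy)):
            lumen_edges = lp
            continue
        for j, (c, r) in enumerate(domain.holes):
            if poly.contains(sg.Point(c[0], c[1])):
                hole_edges[j] = lp
                break
    if lumen_edges is None or any(h is None for h in hole_edges):
        raise MeshingError("could not associate boundary loops with lumen/holes")
    edge_groups = {
        "lumen": lumen_edges,
        "outer": loops[i_outer],
        "holes": hole_edges,
    }
    _check_closed_loop(edge_groups["lumen"], "lumen")
    for i, he in enumerate(edge_groups["holes"]):
        _check_closed_loop(he, f"hole {i}")

    elements = tri
    if quadratic:
        nodes, elements, edge_groups = _add_midside_nodes(
            domain, nodes, tri, edge_groups
        )

    return Mesh(
        nodes=nodes,
        tri=tri,
        elements=elements,
        region_tag=np.asarray(region_tag, dtype=str),
        edge_groups=edge_groups,
        h_coarse=h_coarse,
        h_fine=h_fine,
        quadratic=quadratic,
    )


def _check_closed_loop(edges: np.ndarray, name: str, single: bool = True) -> None:
    if len(edges) == 0:
        raise MeshingError(f"boundary group {name!r} is empty")
    starts, cs = np.unique(edges[:, 0], return_counts=True)
    ends, ce = np.unique(edges[:, 1], return_counts=True)
    if not (np.array_equal(starts, ends) and (cs == 1).all() and (ce == 1).all()):
        raise MeshingError(f"boundary group {name!r} does not form closed loops")
    if single and count_loops(edges) != 1:
        raise MeshingError(f"boundary group {name!r} is not a single closed loop")


def _split_loops(edges: np.ndarray) -> list[np.ndarray]:
    """Split an oriented boundary edge set into its closed loops, each in
    traversal order."""
    nxt = {int(a): (int(a), int(b)) for a, b in edges[:, :2]}
    seen: set[int] = set()
    loops = []
    for start in list(nxt):
        if start in seen:
            continue
        loop = []
        n = start
        while n not in seen:
            seen.add(n)
            loop.append(nxt[n])
            n = nxt[n][1]
        loops.append(np.array(loop, dtype=edges.dtype))
    return loops


def count_loops(edges: np.ndarray) -> int:
    """Number of closed loops in an oriented edge set."""
    nxt = {int(a): int(b) for a, b in edges[:, :2]}
    seen: set[int] = set()
    loops = 0
    for start in list(nxt):
        if start in seen:
            continue
        loops += 1
        n = start
        while n not in seen:
            seen.add(n)
            n = nxt[n]
    return loops


def _add_midside_nodes(domain, nodes, tri, edge_groups):
    prm = domain.params
    cx, cy = prm.lumen_center
    pairs = np.sort(
        np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1
    )
    upairs, inv = np.unique(pairs, axis=0, return_inverse=True)
    mid_xy = (nodes[upairs[:, 0]] + nodes[upairs[:, 1]]) / 2.0

    # snap midside nodes of curved boundary edges onto the analytic curves
    tol = 1e-6 * prm.lumen_radius

    def _on_circle(idx_pts, center, radius):
        d = np.abs(np.hypot(idx_pts[:, 0] - center[0], idx_pts[:, 1] - center[1]) - radius)
        return d < max(tol, 1e-9)

    p0, p1 = nodes[upairs[:, 0]], nodes[upairs[:, 1]]
    circles = [((cx, cy), prm.lumen_radius)]
    circles += [((c[0], c[1]), r) for c, r in domain.holes]
    if not domain.annulus_only:
        circles.append(((cx, cy), prm.epi_radius))
    for center, radius in circles:
        on = _on_circle(p0, center, radius) & _on_circle(p1, center, radius)
        if on.any():
            v = mid_xy[on] - center
            nv = np.linalg.norm(v, axis=1)
            short = nv > 0.5 * radius  # exclude near-diametral artefacts
            sel = np.flatnonzero(on)[short]
            v = mid_xy[sel] - center
            mid_xy[sel] = center + radius * v / np.linalg.norm(v, axis=1)[:, None]
    # outer curve (radius varies with angle)
    if domain.annulus_only:
        on = _on_circle(p0, (cx, cy), prm.outer_radius) & _on_circle(p1, (cx, cy), prm.outer_radius)
        sel = np.flatnonzero(on)
        v = mid_xy[sel] - (cx, cy)
        mid_xy[sel] = (cx, cy) + prm.outer_radius * v / np.linalg.norm(v, axis=1)[:, None]
    else:
        def on_outer(q):
            th = np.arctan2(q[:, 1] - cy, q[:, 0] - cx)
            return np.abs(np.hypot(q[:, 0] - cx, q[:, 1] - cy) - prm.outer_radius_at(th)) < max(tol, 1e-9)

        on = on_outer(p0) & on_outer(p1)
        sel = np.flatnonzero(on)
        v = mid_xy[sel] - (cx, cy)
        th = np.arctan2(v[:, 1], v[:, 0])
        r = prm.outer_radius_at(th)
        mid_xy[sel] = (cx, cy) + r[:, None] * v / np.linalg.norm(v, axis=1)[:, None]

    nmid = len(nodes) + np.arange(len(upairs))
    all_nodes = np.vstack([nodes, mid_xy])
    e_mid = nmid[inv].reshape(3, -1).T  # columns: mid01, mid12, mid20
    elements = np.hstack([tri, e_mid])

    # attach midside indices to boundary edges
    lookup = {tuple(pr): int(m) for pr, m in zip(map(tuple, upairs), nmid)}

    def with_mids(earr):
        if len(earr) == 0:
            return earr.reshape(0, 3)
        m = np.array([lookup[tuple(sorted(e))] for e in earr])
        return np.c_[earr, m]

    groups = {
        "lumen": with_mids(edge_groups["lumen"]),
        "outer": with_mids(edge_groups["outer"]),
        "holes": [with_mids(h) for h in edge_groups["holes"]],
    }
    return all_nodes, elements, groups


# ---------------------------------------------------------------------------
# Small verification helper
# ---------------------------------------------------------------------------


def mesh_unit_square(h: float = 0.5, quadratic: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the unit square (verification helper).

    Returns (points, triangles); the triangulation covers area 1 exactly.
    """

    def fd(p):
        return np.maximum.reduce([-p[:, 0], p[:, 0] - 1, -p[:, 1], p[:, 1] - 1])

    def fh(p):
        return np.full(len(p), h)

    corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    n = max(1, int(round(1.0 / h)))
    edge = np.linspace(0, 1, n + 1)[1:-1]
    pfix = np.vstack(
        [corners]
        + [np.c_[edge, np.zeros_like(edge)], np.c_[edge, np.ones_like(edge)]]
        + [np.c_[np.zeros_like(edge), edge], np.c_[np.ones_like(edge), edge]]
    )
    return triangulate(fd, fh, (0, 0, 1, 1), pfix, h)
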