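"""Parametric 2D geometry of the internal urethral sphincter cross-section.

The modelled domain is an idealised histology-like section: a circular lumen
surrounded by a stiff ring of dense connective tissue (transitional
epithelium) and a compliant spongy stratum (lamina propria) divided into four
parts.  The upper and lower halves of the spongy stratum are separated by two
open slots along the lateral (±x) axis, except for a bonded "bound" segment
1 mm long adjacent to the epithelium on each side; the left and right parts
within each half share a fully bonded interface.  The two lower parts can be
fibrotic.  Surgical decompression is modelled as 0–7 circular holes of radius
0.5 mm placed on an arc inside the fibrotic region, aligned on one arc or
staggered over two radially offset arcs.

Coordinates are Cartesian metres with the lumen centre at the origin and the
y-axis up (sane half up, fibrotic half down); angles are measured
counterclockwise from +x.  All construction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import shapely
import shapely.geometry as sg
import yaml

__all__ = [
    "GeometryParams",
    "HoleSpec",
    "PlanarDomain",
    "GeometryError",
    "HolePlacementError",
    "build_sphincter_domain",
    "build_annulus_domain",
    "place_holes",
    "case_registry",
    "CASE_IDS",
    "save_domain",
]

#: resolution used when discretising circles into polygons
_CIRCLE_PTS = 256

REGION_LABELS = ("epithelium", "spongy_sane", "spongy_fibrotic")

CASE_IDS = ("P0", "H0", "H3", "H4", "H5", "H6", "H7", "H6b")


class GeometryError(ValueError):
    """Invalid geometric parameters."""


class HolePlacementError(ValueError):
    """Hole configuration violates disjointness or containment."""

    def __init__(self, msg: str, indices: list[int] | None = None):
        super().__init__(msg)
        self.indices = indices or []


@dataclass(frozen=True)
class GeometryParams:
    """Free parameters of the idealised cross-section (metres).

    The defaults were calibrated once so that the simulated sane
    configuration at p = 1960 Pa opens to a lumen area in the
    physiologically reported range; they are free parameters of the model,
    not measured anatomy.

    ``outer_ovality`` adds a mild angular variation of the outer radius,
    and ``outer_center_offset`` shifts the outer boundary circle upward
    relative to the lumen centre — together they mimic the non-circular,
    non-concentric outline of a histological section, in particular the
    markedly reduced radial wall thickness below the lumen where the
    fibrotic tissue sits.  Both zero gives a concentric circle.
    """

    lumen_radius: float = 1.75e-3
    epithelium_thickness: float = 0.4e-3
    outer_radius: float = 4.2e-3
    outer_ovality: float = 0.05
    outer_center_offset: float = 0.0
    bound_length: float = 1.0e-3
    slot_half_angle: float = 0.14
    fibrotic_half: bool = True
    lumen_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        r_epi = self.lumen_radius + self.epithelium_thickness
        if not 0.0 <= self.outer_center_offset < self.outer_radius * (1.0 - abs(self.outer_ovality)):
            raise GeometryError("outer_center_offset must be in [0, min outer radius)")
        r_min = self.min_outer_radius
        if not 0.0 < self.lumen_radius:
            raise GeometryError(f"lumen_radius must be positive, got {self.lumen_radius}")
        if not self.lumen_radius < r_epi:
            raise GeometryError("epithelium_thickness must be positive")
        if not r_epi < r_min:
            raise GeometryError(
                f"radii ordering violated: lumen_radius + epithelium_thickness = "
                f"{r_epi:g} must be < min outer radius {r_min:g}"
            )
        if self.bound_length <= 0:
            raise GeometryError("bound_length must be positive")
        r_lateral = float(min(self.outer_radius_at(0.0), self.outer_radius_at(np.pi)))
        if r_epi + self.bound_length >= r_lateral:
            raise GeometryError(
                "bound_length does not fit between epithelium and outer boundary"
            )
        if not 0 < self.slot_half_angle < np.pi / 4:
            raise GeometryError("slot_half_angle must be in (0, pi/4)")

    @property
    def epi_radius(self) -> float:
        """Outer radius of the dense-connective (epithelium) ring."""
        return self.lumen_radius + self.epithelium_thickness

    def outer_radius_at(self, theta) -> np.ndarray:
        """Distance from the lumen centre to the outer boundary at angle theta.

        The outer boundary is a (mildly oval) circle of radius
        ``outer_radius * (1 + ovality cos 2 theta)`` centred
        ``outer_center_offset`` above the lumen centre."""
        theta = np.asarray(theta, dtype=float)
        R = self.outer_radius * (1.0 + self.outer_ovality * np.cos(2.0 * theta))
        d = self.outer_center_offset
        if d == 0.0:
            return R
        return d * np.sin(theta) + np.sqrt(R**2 - (d * np.cos(theta)) ** 2)

    @property
    def min_outer_radius(self) -> float:
        th = np.linspace(0.0, 2.0 * np.pi, 721)
        return float(self.outer_radius_at(th).min())


@dataclass(frozen=True)
class HoleSpec:
    """Placement of the surgical holes inside the fibrotic region.

    ``arc_radius`` is the centre-line radius of the hole arc (``None``: the
    mid-thickness circle of the fibrotic stratum); ``arc_span`` the angular
    extent of the arc (``None``: the fibrotic sector minus one hole-diameter
    margin at each end).  ``staggered`` placement alternates hole centres
    between two arcs radially offset by ``stagger_offset``.
    """

    count: int = 0
    radius: float = 0.5e-3
    arrangement: str = "aligned"  # "aligned" | "staggered"
    arc_radius: float | None = None
    arc_span: float | None = None
    stagger_offset: float = 0.6e-3
    clearance: float = 0.05e-3

    def __post_init__(self) -> None:
        if not 0 <= self.count <= 7:
            raise GeometryError(f"hole count must be in 0..7, got {self.count}")
        if self.radius <= 0:
            raise GeometryError("hole radius must be positive")
        if self.arrangement not in ("aligned", "staggered"):
            raise GeometryError(f"unknown arrangement {self.arrangement!r}")


@dataclass
class PlanarDomain:
    """Tagged planar cross-section: regions, holes, lumen boundary, pins.

    ``regions`` maps a tissue label to a list of shapely polygons (the
    epithelium ring plus the four spongy parts); ``holes`` are
    ``(center, radius)`` pairs; ``lumen_boundary`` is a closed polyline on
    the exact lumen circle; ``pin_points`` are the two fixed points on the
    outer boundary at the top and bottom of the vertical symmetry axis.
    """

    params: GeometryParams
    regions: list[tuple[str, sg.Polygon]]
    holes: list[tuple[np.ndarray, float]]
    lumen_boundary: np.ndarray
    pin_points: np.ndarray
    annulus_only: bool = False  # verification geometry (no slots/quadrants)

    # -- derived geometry -------------------------------------------------
    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.params.lumen_center, dtype=float)

    @property
    def body(self) -> sg.Polygon:
        """Union of the region polygons (holes not subtracted)."""
        return shapely.union_all([p for _, p in self.regions])

    def region_areas(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for label, poly in self.regions:
            out[label] = out.get(label, 0.0) + poly.area
        return out

    def hole_area(self) -> float:
        return sum(np.pi * r**2 for _, r in self.holes)

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Label each point by its containing region (nearest region as a
        fallback for points on shared interfaces)."""
        pts = shapely.points(np.asarray(points, dtype=float))
        labels = np.empty(len(pts), dtype=object)
        labels[:] = None
        for name, poly in self.regions:
            free = labels == None  # noqa: E711
            if not free.any():
                break
            hit = shapely.contains(poly, pts[free])
            idx = np.flatnonzero(free)[hit]
            labels[idx] = name
        miss = np.flatnonzero(labels == None)  # noqa: E711
        for i in miss:
            dists = [poly.distance(pts[i]) for _, poly in self.regions]
            labels[i] = self.regions[int(np.argmin(dists))][0]
        return labels.astype(str)

    def has_fibrotic(self) -> bool:
        return any(label == "spongy_fibrotic" for label, _ in self.regions)


def _circle(center, radius, n=_CIRCLE_PTS) -> sg.Polygon:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.c_[center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    return sg.Polygon(pts)


def _outer_polygon(params: GeometryParams, n=_CIRCLE_PTS) -> sg.Polygon:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = params.outer_radius_at(th)
    cx, cy = params.lumen_center
    return sg.Polygon(np.c_[cx + r * np.cos(th), cy + r * np.sin(th)])


def _slot_wedges(params: GeometryParams) -> list[sg.Polygon]:
    """The two open V-notches separating the upper and lower spongy halves.

    Each notch is a radial wedge of half-angle ``slot_half_angle`` centred on
    the lateral (±x) axis, starting ``bound_length`` beyond the epithelium
    ring (the material inside that radius stays bonded: the 1-mm bound) and
    widening out through the outer boundary.
    """
    cx, cy = params.lumen_center
    r0 = params.epi_radius + params.bound_length
    r1 = 2.0 * params.outer_radius  # extends safely past the outer boundary
    a = params.slot_half_angle
    wedges = []
    for base in (0.0, np.pi):
        th_in = base + np.linspace(-a, a, 17)
        inner = np.c_[cx + r0 * np.cos(th_in), cy + r0 * np.sin(th_in)]
        outer_pts = np.array(
            [
                [cx + r1 * np.cos(base + a), cy + r1 * np.sin(base + a)],
                [cx + r1 * np.cos(base - a), cy + r1 * np.sin(base - a)],
            ]
        )
        wedges.append(sg.Polygon(np.vstack([inner, outer_pts])))
    return wedges


def build_sphincter_domain(params: GeometryParams) -> PlanarDomain:
    """Construct the tagged sphincter cross-section (no holes yet).

    Returns five tagged regions: the epithelium ring and four spongy
    quadrant parts; the lower two are tagged ``spongy_fibrotic`` iff
    ``params.fibrotic_half`` is set.  Pin points sit on the outer boundary on
    the vertical symmetry axis.
    """
    cx, cy = params.lumen_center
    lumen = _circle(params.lumen_center, params.lumen_radius)
    epi_disk = _circle(params.lumen_center, params.epi_radius)
    outer = _outer_polygon(params)

    epithelium = epi_disk.difference(lumen)
    spongy = outer.difference(epi_disk)
    for slot in _slot_wedges(params):
        spongy = spongy.difference(slot)

    big = 2.0 * params.outer_radius
    quads = {
        "UR": sg.box(cx, cy, cx + big, cy + big),
        "UL": sg.box(cx - big, cy, cx, cy + big),
        "LL": sg.box(cx - big, cy - big, cx, cy),
        "LR": sg.box(cx, cy - big, cx + big, cy),
    }
    lower_label = "spongy_fibrotic" if params.fibrotic_half else "spongy_sane"
    regions: list[tuple[str, sg.Polygon]] = [("epithelium", epithelium)]
    for q, box in quads.items():
        part = spongy.intersection(box)
        label = lower_label if q in ("LL", "LR") else "spongy_sane"
        regions.append((label, part))

    th = np.linspace(0.0, 2.0 * np.pi, _CIRCLE_PTS, endpoint=False)
    lumen_boundary = np.c_[
        cx + params.lumen_radius * np.cos(th), cy + params.lumen_radius * np.sin(th)
    ]
    pins = np.array(
        [
            [cx, cy + params.outer_radius_at(np.pi / 2)],
            [cx, cy - params.outer_radius_at(-np.pi / 2)],
        ]
    )
    return PlanarDomain(
        params=params, regions=regions, holes=[], lumen_boundary=lumen_boundary,
        pin_points=pins,
    )


def build_annulus_domain(
    inner_radius: float, outer_radius: float, label: str = "spongy_sane"
) -> PlanarDomain:
    """Plain circular annulus with a single tissue region.

    Verification geometry for the thick-walled-cylinder (Lamé) oracle; no
    slots, no quadrant split.
    """
    if not 0 < inner_radius < outer_radius:
        raise GeometryError("need 0 < inner_radius < outer_radius")
    params = GeometryParams(
        lumen_radius=inner_radius,
        epithelium_thickness=1e-9 * inner_radius,  # unused for annulus
        outer_radius=outer_radius,
        outer_ovality=0.0,
        bound_length=(outer_radius - inner_radius) / 2,
        fibrotic_half=False,
    )
    ring = _circle((0, 0), outer_radius).difference(_circle((0, 0), inner_radius))
    th = np.linspace(0.0, 2.0 * np.pi, _CIRCLE_PTS, endpoint=False)
    lumen_boundary = np.c_[inner_radius * np.cos(th), inner_radius * np.sin(th)]
    pins = np.array([[0.0, outer_radius], [0.0, -outer_radius]])
    return PlanarDomain(
        params=params, regions=[(label, ring)], holes=[],
        lumen_boundary=lumen_boundary, pin_points=pins, annulus_only=True,
    )


# ---------------------------------------------------------------------------
# Hole placement
# ---------------------------------------------------------------------------


def _fibrotic_union(domain: PlanarDomain) -> sg.Polygon:
    polys = [p for label, p in domain.regions if label == "spongy_fibrotic"]
    if not polys:
        raise HolePlacementError("domain has no fibrotic region to drill")
    return shapely.union_all(polys)


def hole_centers(domain: PlanarDomain, spec: HoleSpec) -> np.ndarray:
    """Deterministic hole-centre coordinates for a placement spec."""
    params = domain.params
    cx, cy = params.lumen_center
    r_out_bottom = params.outer_radius_at(-np.pi / 2)
    r_arc = spec.arc_radius
    if r_arc is None:
        r_arc = 0.5 * (params.epi_radius + r_out_bottom)
    span = spec.arc_span
    if span is None:
        margin = 2.0 * spec.radius / r_arc  # one hole diameter, as an angle
        span = np.pi - 2.0 * margin
    if span <= 0:
        raise HolePlacementError("arc_span must be positive")
    mid = -np.pi / 2.0  # bottom of the fibrotic sector
    if spec.count == 1:
        thetas = np.array([mid])
    else:
        thetas = mid + np.linspace(-span / 2.0, span / 2.0, spec.count)
    radii = np.full(spec.count, float(r_arc))
    if spec.arrangement == "staggered":
        radii[0::2] -= spec.stagger_offset / 2.0
        radii[1::2] += spec.stagger_offset / 2.0
    return np.c_[cx + radii * np.cos(thetas), cy + radii * np.sin(thetas)]


def place_holes(domain: PlanarDomain, spec: HoleSpec) -> PlanarDomain:
    """Return a new domain with ``spec.count`` holes drilled in the fibrotic
    part, after verifying pairwise disjointness and strict containment."""
    if spec.count == 0:
        return replace(domain, holes=list(domain.holes))
    fib = _fibrotic_union(domain)
    centers = hole_centers(domain, spec)

    bad: list[int] = []
    for i in range(spec.count):
        for j in range(i + 1, spec.count):
            gap = np.linalg.norm(centers[i] - centers[j]) - 2.0 * spec.radius
            if gap < spec.clearance:
                bad.extend([i, j])
    if bad:
        raise HolePlacementError(
            f"holes overlap or violate clearance: indices {sorted(set(bad))}",
            sorted(set(bad)),
        )

    shrunk = fib.buffer(-spec.clearance)
    for i, c in enumerate(centers):
        disk = _circle(c, spec.radius, n=96)
        if not disk.within(shrunk):
            bad.append(i)
    if bad:
        raise HolePlacementError(
            f"holes not strictly inside the fibrotic region: indices {sorted(set(bad))}",
            sorted(set(bad)),
        )
    holes = list(domain.holes) + [(c, spec.radius) for c in centers]
    return replace(domain, holes=holes)


# ---------------------------------------------------------------------------
# Case registry
# ---------------------------------------------------------------------------


def case_registry(case_id: str, base: GeometryParams | None = None) -> tuple[GeometryParams, HoleSpec]:
    """Geometry and hole spec for a named study configuration.

    ``P0``: sane tissue, no holes; ``H0``: fibrotic lower half, no holes;
    ``Hn`` (n = 3..7): fibrotic with n aligned holes; ``H6b``: fibrotic with
    6 staggered holes.
    """
    base = base if base is not None else GeometryParams()
    if case_id == "P0":
        return replace(base, fibrotic_half=False), HoleSpec(count=0)
    if case_id == "H0":
        return replace(base, fibrotic_half=True), HoleSpec(count=0)
    if case_id == "H6b":
        return replace(base, fibrotic_half=True), HoleSpec(count=6, arrangement="staggered")
    if case_id.startswith("H") and case_id[1:].isdigit():
        n = int(case_id[1:])
        if 3 <= n <= 7:
            return replace(base, fibrotic_half=True), HoleSpec(count=n, arrangement="aligned")
    raise KeyError(f"unknown case id {case_id!r}; known: {CASE_IDS}")


def build_case(case_id: str, base: GeometryParams | None = None) -> PlanarDomain:
    """Convenience: registry lookup + domain build + hole placement."""
    params, spec = case_registry(case_id, base)
    return place_holes(build_sphincter_domain(params), spec)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def domain_to_dict(domain: PlanarDomain) -> dict:
    return {
        "params": asdict(domain.params),
        "regions": [
            {"label": label, "exterior": np.asarray(p.exterior.coords).tolist(),
             "interiors": [np.asarray(r.coords).tolist() for r in p.interiors]}
            for label, p in domain.regions
        ],
        "holes": [
            {"center": np.asarray(c).tolist(), "radius": float(r)}
            for c, r in domain.holes
        ],
        "lumen_boundary": domain.lumen_boundary.tolist(),
        "pin_points": domain.pin_points.tolist(),
    }


def save_domain(domain: PlanarDomain, path) -> None:
    """Serialise the domain (regions, holes, pins) as structured YAML text."""
    with open(path, "w") as fh:
        yaml.safe_dump(domain_to_dict(domain), fh, sort_keys=False)
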