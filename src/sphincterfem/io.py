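"""Mesh and field export: Gmsh ``.msh`` (v4.1 ASCII) and legacy VTK ASCII.

Small text emitters/parsers sufficient for visualisation and round-tripping
the package's own meshes: region tags become 2D physical groups, boundary
edge groups 1D physical groups.  No binary formats.
"""

from __future__ import annotations

import numpy as np

from .meshing import Mesh

__all__ = ["write_msh", "read_msh", "write_vtk"]

_REGION_BASE = 100  # physical tags for surfaces start here
_EDGE_BASE = 1  # physical tags for boundary curves


def _edge_group_items(mesh: Mesh):
    items = [("lumen", mesh.edge_groups["lumen"]), ("outer", mesh.edge_groups["outer"])]
    for i, h in enumerate(mesh.edge_groups["holes"]):
        items.append((f"hole{i}", h))
    return items


def write_msh(path, mesh: Mesh) -> None:
    """Write the mesh as Gmsh 4.1 ASCII with physical groups."""
    regions = sorted(set(mesh.region_tag.tolist()))
    groups = _edge_group_items(mesh)
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]

    lines.append("$PhysicalNames")
    lines.append(str(len(groups) + len(regions)))
    for i, (name, _) in enumerate(groups):
        lines.append(f'1 {_EDGE_BASE + i} "{name}"')
    for j, name in enumerate(regions):
        lines.append(f'2 {_REGION_BASE + j} "{name}"')
    lines.append("$EndPhysicalNames")

    # entities: one curve per edge group, one surface per region
    lines.append("$Entities")
    lines.append(f"0 {len(groups)} {len(regions)} 0")
    for i, _ in enumerate(groups):
        lines.append(f"{i + 1} 0 0 0 0 0 0 1 {_EDGE_BASE + i} 0")
    for j, _ in enumerate(regions):
        lines.append(f"{j + 1} 0 0 0 0 0 0 1 {_REGION_BASE + j} 0")
    lines.append("$EndEntities")

    n = len(mesh.nodes)
    lines.append("$Nodes")
    lines.append(f"1 {n} 1 {n}")
    lines.append(f"2 1 0 {n}")  # all nodes attached to the first surface
    lines.extend(str(i + 1) for i in range(n))
    lines.extend(f"{x:.16e} {y:.16e} 0" for x, y in mesh.nodes)
    lines.append("$EndNodes")

    lines.append("$Elements")
    blocks = []
    eid = 1
    for i, (_, earr) in enumerate(groups):
        etype = 8 if earr.shape[1] == 3 else 1  # 3-node or 2-node line
        rows = []
        for e in earr:
            rows.append(f"{eid} " + " ".join(str(v + 1) for v in e))
            eid += 1
        blocks.append((f"1 {i + 1} {etype} {len(earr)}", rows))
    for j, name in enumerate(regions):
        sel = np.flatnonzero(mesh.region_tag == name)
        etype = 9 if mesh.elements.shape[1] == 6 else 2
        rows = []
        for k in sel:
            rows.append(f"{eid} " + " ".join(str(v + 1) for v in mesh.elements[k]))
            eid += 1
        blocks.append((f"2 {j + 1} {etype} {len(sel)}", rows))
    lines.append(f"{len(blocks)} {eid - 1} 1 {eid - 1}")
    for header, rows in blocks:
        lines.append(header)
        lines.extend(rows)
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path) -> Mesh:
    """Read a mesh written by :func:`write_msh` (same conventions)."""
    with open(path) as fh:
        tok = fh.read().split("\n")
    it = iter(tok)

    def until(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"section {tag} not found")

    until("$PhysicalNames")
    n_names = int(next(it))
    names = {}
    for _ in range(n_names):
        dim, tag, name = next(it).split(maxsplit=2)
        names[(int(dim), int(tag))] = name.strip('"')
    until("$Nodes")
    nb, nn, *_ = map(int, next(it).split())
    next(it)  # single block header
    idx = [int(next(it)) for _ in range(nn)]
    xyz = np.array([[float(v) for v in next(it).split()] for _ in range(nn)])
    nodes = np.empty((nn, 2))
    nodes[np.array(idx) - 1] = xyz[:, :2]

    until("$Elements")
    n_blocks, *_ = map(int, next(it).split())
    edge_named: dict[str, np.ndarray] = {}
    tris, tags = [], []
    for _ in range(n_blocks):
        dim, ent, etype, count = map(int, next(it).split())
        rows = [np.array(next(it).split(), dtype=int)[1:] - 1 for _ in range(count)]
        if dim == 1:
            edge_named[names[(1, _EDGE_BASE + ent - 1)]] = np.array(rows)
        else:
            name = names[(2, _REGION_BASE + ent - 1)]
            tris.extend(rows)
            tags.extend([name] * count)
    elements = np.array(tris)
    holes = [edge_named[k] for k in sorted(edge_named) if k.startswith("hole")]
    edge_groups = {
        "lumen": edge_named["lumen"],
        "outer": edge_named["outer"],
        "holes": holes,
    }
    quadratic = elements.shape[1] == 6
    return Mesh(
        nodes=nodes,
        tri=elements[:, :3],
        elements=elements,
        region_tag=np.array(tags, dtype=str),
        edge_groups=edge_groups,
        h_coarse=float("nan"),
        h_fine=float("nan"),
        quadratic=quadratic,
    )


def write_vtk(path, mesh: Mesh, point_data: dict | None = None, cell_data: dict | None = None) -> None:
    """Legacy VTK ASCII unstructured grid with optional nodal/cell fields.

    Vector fields are (N, 2) arrays (padded to 3D); scalars are flat arrays.
    """
    nn = len(mesh.nodes)
    quad = mesh.elements.shape[1] == 6
    lines = [
        "# vtk DataFile Version 3.0",
        "sphincterfem output",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {nn} double",
    ]
    lines.extend(f"{x:.16e} {y:.16e} 0.0" for x, y in mesh.nodes)
    ne = len(mesh.elements)
    npe = 6 if quad else 3
    lines.append(f"CELLS {ne} {ne * (npe + 1)}")
    for e in mesh.elements:
        lines.append(f"{npe} " + " ".join(map(str, e)))
    lines.append(f"CELL_TYPES {ne}")
    lines.extend(["22" if quad else "5"] * ne)

    def emit_fields(data, n):
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.9e} {v[1]:.9e} 0.0" for v in arr)
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9e}" for v in arr)

    if point_data:
        lines.append(f"POINT_DATA {nn}")
        emit_fields(point_data, nn)
    if cell_data:
        lines.append(f"CELL_DATA {ne}")
        emit_fields(cell_data, ne)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
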