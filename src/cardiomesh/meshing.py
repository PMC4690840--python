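"""Tag-carrying tetrahedral meshing of label images.

An open stand-in for boundary-fitted commercial meshers: because the input
image has already been smoothed and upsampled to modeling resolution, each
foreground voxel is split into the six Kuhn tetrahedra, giving a conforming
mesh whose element tags are inherited from the voxel labels and whose
per-tag volume equals the voxel count times the voxel volume exactly.  The
split is translation invariant, so shared cube facets carry the same
diagonal in both neighbouring voxels and global conformity holds without
any parity bookkeeping.

An optional boundary-snapping pass pulls mesh surface nodes towards a
tagged surface under the same half-voxel displacement cap used by the
smoothing stage, reverting any move that would invert an element.  Writers
cover CARP text formats (.pts in micrometres, .elem, .lon), VTU and legacy
VTK; a reader for CARP round-trips the mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._lattice import KUHN_TETS
from .label_io import LabelImage

__all__ = [
    "TetMesh",
    "mesh_from_label_image",
    "mesh_quality",
    "snap_boundary_nodes",
    "write_carp",
    "read_carp",
    "write_vtu",
    "write_vtk_legacy",
]


@dataclass
class TetMesh:
    """Tetrahedral mesh with per-element region tags.

    ``tets`` rows are node indices ordered for positive signed volume;
    ``fibers`` (optional) is a :class:`~cardiomesh.fibers.FiberField`.
    """

    nodes: np.ndarray
    tets: np.ndarray
    element_tags: np.ndarray
    tag_table: dict[int, str] = field(default_factory=dict)
    fibers: object | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, np.int64).reshape(-1, 4)
        self.element_tags = np.asarray(self.element_tags, np.int64).reshape(-1)
        if len(self.element_tags) != len(self.tets):
            raise ValueError("element_tags must match tets")
        if len(self.tets) and self.tets.max() >= len(self.nodes):
            raise ValueError("tet index out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        v = self.nodes[self.tets]
        return np.einsum(
            "ij,ij->i", v[:, 1] - v[:, 0], np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0])
        ) / 6.0

    def label_for(self, name: str) -> int:
        for k, v in self.tag_table.items():
            if v == name:
                return k
        raise KeyError(f"no label named {name!r} in tag table")


def mesh_from_label_image(
    image: LabelImage,
    tags=None,
    snap_surface=None,
    snap_cap_voxels: float = 0.5,
) -> TetMesh:
    """Split each selected foreground voxel into six Kuhn tetrahedra.

    ``tags`` selects which labels are meshed (default: all nonzero).  If
    ``snap_surface`` (a TaggedSurface) is given, boundary nodes are moved
    towards it afterwards via :func:`snap_boundary_nodes`.
    """
    if tags is None:
        tags = sorted(set(image.tag_table) & set(np.unique(image.voxels).tolist()))
    else:
        tags = sorted(int(t) for t in tags)
        unknown = set(tags) - set(image.tag_table)
        if unknown:
            raise KeyError(f"unknown tags {sorted(unknown)}")
    sel = np.isin(image.voxels, tags)
    if not sel.any():
        raise ValueError("empty selection: no foreground voxels to mesh")
    vox_idx = np.argwhere(sel).astype(np.int64)  # (nv, 3)
    labels = image.voxels[sel].astype(np.int64)

    shape = image.dims
    cshape = (shape[0] + 1, shape[1] + 1, shape[2] + 1)
    cstride = np.array([cshape[1] * cshape[2], cshape[2], 1], dtype=np.int64)

    tet_nodes = []
    for tet in KUHN_TETS:  # (4, 3) corner offsets
        corner_ids = (vox_idx[:, None, :] + tet[None, :, :]) @ cstride  # (nv, 4)
        tet_nodes.append(corner_ids)
    # interleave so the 6 tets of a voxel are consecutive
    all_tets = np.stack(tet_nodes, axis=1).reshape(-1, 4)
    element_tags = np.repeat(labels, 6)

    used, inv = np.unique(all_tets.ravel(), return_inverse=True)
    tets = inv.reshape(-1, 4).astype(np.int64)
    ci = used // cstride[0]
    rem = used % cstride[0]
    corners = np.stack([ci, rem // cstride[1], rem % cstride[1]], axis=1)
    nodes = image.origin + corners.astype(float) * image.spacing

    table = {t: image.tag_table[t] for t in tags}
    mesh = TetMesh(nodes, tets, element_tags, table)
    if snap_surface is not None:
        snap_boundary_nodes(mesh, snap_surface, snap_cap_voxels * image.spacing)
    return mesh


def snap_boundary_nodes(mesh: TetMesh, surface, cap) -> int:
    """Move mesh boundary nodes towards the nearest point of ``surface``.

    Displacements are clamped per axis to ``cap`` (mm, scalar or 3-vector);
    any move that would invert an adjacent tetrahedron is reverted.  Returns
    the number of nodes moved.  In-place.
    """
    from .surface_tagging import tag_boundary  # local import, avoids cycle

    cap = np.broadcast_to(np.atleast_1d(np.asarray(cap, float)), (3,))
    boundary = tag_boundary(mesh, sorted(set(mesh.element_tags.tolist())))
    bnodes = np.unique(boundary.faces)
    pts = mesh.nodes[bnodes]
    targets = _closest_points(pts, surface.vertices, surface.triangles)
    delta = np.clip(targets - pts, -cap, cap)

    # node -> adjacent elements
    order = np.argsort(mesh.tets.ravel(), kind="stable")
    flat_elems = np.repeat(np.arange(mesh.n_elements), 4)[order]
    sorted_nodes = mesh.tets.ravel()[order]
    starts = np.searchsorted(sorted_nodes, bnodes, "left")
    ends = np.searchsorted(sorted_nodes, bnodes, "right")

    moved = 0
    for i, node in enumerate(bnodes):
        if not np.any(delta[i]):
            continue
        old = mesh.nodes[node].copy()
        mesh.nodes[node] = old + delta[i]
        adj = flat_elems[starts[i]:ends[i]]
        v = mesh.nodes[mesh.tets[adj]]
        vol = np.einsum(
            "ij,ij->i", v[:, 1] - v[:, 0], np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0])
        )
        if np.any(vol <= 0):
            mesh.nodes[node] = old  # revert inverting move
        else:
            moved += 1
    return moved


def _closest_points(points, vertices, triangles, chunk: int = 128) -> np.ndarray:
    """Closest point on a triangle soup for each query point (brute force)."""
    tv = vertices[triangles]
    out = np.empty_like(points)
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk][:, None, :]
        a, b, c = tv[None, :, 0], tv[None, :, 1], tv[None, :, 2]
        ab, ac = b - a, c - a
        n = np.cross(ab, ac)
        nn = np.maximum(np.einsum("...i,...i->...", n, n), 1e-300)
        ap = p - a
        # project onto plane, clamp barycentrics (adequate for snapping)
        d = np.einsum("...i,...i->...", ap, n) / nn
        proj = p - d[..., None] * n
        v0, v1, v2 = ac, ab, proj - a
        dot00 = np.einsum("...i,...i->...", v0, v0)
        dot01 = np.einsum("...i,...i->...", v0, v1)
        dot02 = np.einsum("...i,...i->...", v0, v2)
        dot11 = np.einsum("...i,...i->...", v1, v1)
        dot12 = np.einsum("...i,...i->...", v1, v2)
        den = np.maximum(dot00 * dot11 - dot01 * dot01, 1e-300)
        u = np.clip((dot11 * dot02 - dot01 * dot12) / den, 0, 1)
        v = np.clip((dot00 * dot12 - dot01 * dot02) / den, 0, 1)
        w = np.clip(1 - u - v, 0, 1)
        ssum = np.maximum(u + v + w, 1e-300)
        u, v = u / ssum, v / ssum
        cand = a + u[..., None] * ac + v[..., None] * ab
        dist = np.linalg.norm(cand - p, axis=-1)
        best = np.argmin(dist, axis=1)
        out[s : s + chunk] = cand[np.arange(len(best)), best]
    return out


def mesh_quality(mesh: TetMesh) -> dict[str, float]:
    """Deterministic quality summary: radius ratios, dihedrals, edge stats."""
    v = mesh.nodes[mesh.tets]
    e = [v[:, j] - v[:, i] for i, j in
         ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))]
    vol = np.einsum("ij,ij->i", e[0], np.cross(e[1], e[2])) / 6.0

    # faces opposite each vertex; areas for inradius
    faces = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))
    areas = np.stack([
        0.5 * np.linalg.norm(
            np.cross(v[:, f[1]] - v[:, f[0]], v[:, f[2]] - v[:, f[0]]), axis=1)
        for f in faces
    ])
    r_in = 3.0 * vol / areas.sum(axis=0)

    # circumradius from |a x b * c| formulation
    a, b, c = e[0], e[1], e[2]
    la, lb, lc = (np.einsum("ij,ij->i", x, x) for x in (a, b, c))
    num = np.linalg.norm(
        la[:, None] * np.cross(b, c)
        + lb[:, None] * np.cross(c, a)
        + lc[:, None] * np.cross(a, b),
        axis=1,
    )
    r_circ = num / (12.0 * vol)
    ratio = 3.0 * r_in / r_circ  # 1 for the regular tet

    # dihedral angles along the 6 edges: angle between adjacent face planes
    normals = [np.cross(v[:, f[1]] - v[:, f[0]], v[:, f[2]] - v[:, f[0]]) for f in faces]
    normals = [n / np.linalg.norm(n, axis=1, keepdims=True) for n in normals]
    edge_faces = ((2, 3), (1, 3), (1, 2), (0, 3), (0, 2), (0, 1))
    dihedrals = []
    for fa, fb in edge_faces:
        cosang = np.clip(-np.einsum("ij,ij->i", normals[fa], normals[fb]), -1, 1)
        dihedrals.append(np.degrees(np.arccos(cosang)))
    dihedrals = np.stack(dihedrals)

    edges = np.vstack([mesh.tets[:, [i, j]] for i, j in
                       ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    elen = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]], axis=1)

    return {
        "n_nodes": float(mesh.n_nodes),
        "n_elements": float(mesh.n_elements),
        "min_volume": float(vol.min()),
        "min_radius_ratio": float(ratio.min()),
        "mean_radius_ratio": float(ratio.mean()),
        "min_dihedral_deg": float(dihedrals.min()),
        "min_edge_mm": float(elen.min()),
        "mean_edge_mm": float(elen.mean()),
        "max_edge_mm": float(elen.max()),
    }


# -- IO -------------------------------------------------------------------


def write_carp(mesh: TetMesh, basename) -> None:
    """CARP text formats: .pts (micrometres), .elem, and .lon if fibers set.

    Layout: ``.pts`` holds the node count then one ``x y z`` line per node
    (um, 4 decimals); ``.elem`` the element count then ``Tt n0 n1 n2 n3
    tag`` lines; ``.lon`` a header line with the number of fiber directions
    (1 or 2) then 3 or 6 numbers per element.
    """
    base = Path(basename)
    pts = mesh.nodes * 1000.0  # mm -> um
    with open(base.with_suffix(".pts"), "w") as fh:
        fh.write(f"{mesh.n_nodes}\n")
        for x, y, z in pts:
            fh.write(f"{x:.4f} {y:.4f} {z:.4f}\n")
    with open(base.with_suffix(".elem"), "w") as fh:
        fh.write(f"{mesh.n_elements}\n")
        for (n0, n1, n2, n3), t in zip(mesh.tets, mesh.element_tags):
            fh.write(f"Tt {n0} {n1} {n2} {n3} {t}\n")
    if mesh.fibers is not None:
        f = np.asarray(mesh.fibers.f, float)
        s = getattr(mesh.fibers, "s", None)
        two = s is not None and np.asarray(s).size
        with open(base.with_suffix(".lon"), "w") as fh:
            fh.write("2\n" if two else "1\n")
            for i in range(len(f)):
                row = f[i].tolist() + (np.asarray(s)[i].tolist() if two else [])
                fh.write(" ".join(f"{x:.8f}" for x in row) + "\n")


def read_carp(basename, tag_table=None) -> TetMesh:
    base = Path(basename)
    with open(base.with_suffix(".pts")) as fh:
        n = int(fh.readline())
        nodes = np.loadtxt(fh, max_rows=n).reshape(n, 3) / 1000.0
    tets, tags = [], []
    with open(base.with_suffix(".elem")) as fh:
        m = int(fh.readline())
        for _ in range(m):
            parts = fh.readline().split()
            if parts[0] != "Tt":
                raise ValueError("only tetrahedral ('Tt') elements supported")
            tets.append([int(x) for x in parts[1:5]])
            tags.append(int(parts[5]))
    table = tag_table or {t: f"tag_{t}" for t in sorted(set(tags))}
    return TetMesh(nodes, np.array(tets), np.array(tags), table)


def _vtk_cells(mesh: TetMesh) -> tuple[str, str]:
    conn = "\n".join(" ".join(map(str, t)) for t in mesh.tets)
    offsets = " ".join(str(4 * (i + 1)) for i in range(mesh.n_elements))
    return conn, offsets


def write_vtu(mesh: TetMesh, path) -> None:
    """XML VTK unstructured grid (ascii) with element tags and fibers."""
    pts = "\n".join(f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.nodes)
    conn, offsets = _vtk_cells(mesh)
    types = " ".join("10" for _ in range(mesh.n_elements))
    cell_arrays = [
        '<DataArray type="Int32" Name="tag" format="ascii">\n'
        + " ".join(map(str, mesh.element_tags))
        + "\n</DataArray>"
    ]
    if mesh.fibers is not None:
        for name in ("f", "s", "n"):
            arr = getattr(mesh.fibers, name, None)
            if arr is None:
                continue
            rows = "\n".join(" ".join(f"{x:.8f}" for x in r) for r in np.asarray(arr))
            cell_arrays.append(
                f'<DataArray type="Float64" Name="fiber_{name}" '
                f'NumberOfComponents="3" format="ascii">\n{rows}\n</DataArray>'
            )
    Path(path).write_text(f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elements}">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">
{pts}
</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{conn}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{offsets}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{types}
</DataArray>
</Cells>
<CellData>
{chr(10).join(cell_arrays)}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
""")


def write_vtk_legacy(mesh: TetMesh, path) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "cardiomesh tetrahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}")
    lines += ["4 " + " ".join(map(str, t)) for t in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["10"] * mesh.n_elements
    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append("SCALARS tag int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(t) for t in mesh.element_tags]
    Path(path).write_text("\n".join(lines) + "\n")
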