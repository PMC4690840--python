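"""Boundary face sets of tagged element regions and their set algebra.

The fiber rule and simulation boundary conditions need named anatomical
surfaces (LV endocardium, RV endocardium, biventricular epicardium, base,
apex).  With a tagged mesh these are automatable: extract the boundary
surface of individual tag sets and combine them with logical set
operations.  The per-ventricle epicardium is the intersection of that
ventricle's surface with the background surface, and the total epicardium
is the union of the two; endocardia are the intersections of the
myocardial surface with each blood-pool surface.  The base is the
myocardial boundary on the flat base cut and the apex the extremal
epicardial node along the long axis (-z).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .meshing import TetMesh

__all__ = [
    "FaceSet",
    "BCSurfaces",
    "tag_boundary",
    "face_set_op",
    "derive_bc_surfaces",
    "write_surf",
    "write_faceset_vtk",
]

_TET_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))


@dataclass
class FaceSet:
    """Canonicalized set of mesh boundary/interface triangles.

    Faces are node-index triples sorted ascending within each row, with no
    duplicates; set operations require both operands to reference the same
    mesh object.
    """

    faces: np.ndarray
    mesh: TetMesh
    name: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.faces, np.int64).reshape(-1, 3)
        f = np.unique(np.sort(f, axis=1), axis=0)
        if len(f) and f.max() >= self.mesh.n_nodes:
            raise ValueError("face references a node outside the mesh")
        self.faces = f

    def __len__(self) -> int:
        return len(self.faces)

    def nodes(self) -> np.ndarray:
        return np.unique(self.faces)

    def _keys(self) -> np.ndarray:
        n = np.int64(self.mesh.n_nodes)
        return (self.faces[:, 0] * n + self.faces[:, 1]) * n + self.faces[:, 2]


def tag_boundary(mesh: TetMesh, tags, name: str = "") -> FaceSet:
    """Topological boundary of the element set with tags in ``tags``.

    A face belongs to the boundary iff exactly one element of the selection
    contains it.  The background region's surface is the complement case:
    pass all foreground tags to obtain the global mesh boundary.
    """
    tags = [int(t) for t in (tags if np.iterable(tags) else [tags])]
    if not tags:
        raise ValueError("tags must be nonempty")
    unknown = set(tags) - set(mesh.tag_table)
    if unknown:
        raise KeyError(f"unknown tags {sorted(unknown)}")
    sel = np.isin(mesh.element_tags, tags)
    tets = mesh.tets[sel]
    faces = np.vstack([tets[:, f] for f in _TET_FACES])
    faces = np.sort(faces, axis=1)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    return FaceSet(uniq[counts == 1], mesh, name)


def face_set_op(a: FaceSet, b: FaceSet, op: str) -> FaceSet:
    """Set algebra on canonical face triples: union | intersection | difference."""
    if a.mesh is not b.mesh:
        raise ValueError("face sets reference different meshes")
    ka, kb = a._keys(), b._keys()
    if op == "union":
        keys = np.union1d(ka, kb)
    elif op == "intersection":
        keys = np.intersect1d(ka, kb)
    elif op == "difference":
        keys = np.setdiff1d(ka, kb)
    else:
        raise ValueError(f"unknown op {op!r}")
    n = np.int64(a.mesh.n_nodes)
    faces = np.stack([keys // (n * n), (keys // n) % n, keys % n], axis=1)
    return FaceSet(faces, a.mesh, f"({a.name} {op} {b.name})")


@dataclass
class BCSurfaces:
    """Named fiber/boundary-condition surfaces plus the apex.

    The apex is a single epicardial node for closed ventricles;
    ``apex_faces`` may carry a face set instead (e.g. the open bottom of an
    idealized annulus), taking precedence when present.
    """

    lv_endo: FaceSet
    rv_endo: FaceSet
    epi: FaceSet
    base: FaceSet
    apex_node: int
    apex_faces: FaceSet | None = None

    def as_dict(self) -> dict[str, FaceSet]:
        return {"lv_endo": self.lv_endo, "rv_endo": self.rv_endo,
                "epi": self.epi, "base": self.base}


def derive_bc_surfaces(
    mesh: TetMesh,
    roles: dict[str, int] | None = None,
    base_band: float | None = None,
) -> BCSurfaces:
    """Derive lv_endo, rv_endo, epi, base and the apex node from tags.

    ``roles`` maps role names ("LV_myo", "RV_myo", "LV_pool", "RV_pool",
    optionally "base") to labels; by default they are looked up by name in
    the mesh tag table.  rv_endo includes the septal faces where the RV
    pool abuts LV myocardium, so the four sets partition the complete
    myocardial boundary.

    ``base_band`` (mm) is the depth below the topmost myocardial boundary
    node within which myocardium-background faces count as base.  The
    default (essentially zero) matches an exactly flat cut; after the
    smoothing + re-rasterization stages the cut is staircased within the
    half-voxel displacement cap, and the pipeline widens the band
    accordingly.
    """
    if roles is None:
        roles = {}
        for role in ("LV_myo", "RV_myo", "LV_pool", "RV_pool"):
            roles[role] = mesh.label_for(role)
        try:
            roles["base"] = mesh.label_for("base")
        except KeyError:
            pass
    for role in ("LV_myo", "RV_myo", "LV_pool", "RV_pool"):
        if role not in roles:
            raise ValueError(f"tag-role map must identify {role}")

    myo = [roles["LV_myo"], roles["RV_myo"]]
    g_myo = tag_boundary(mesh, myo, "myo")
    g_lv = tag_boundary(mesh, [roles["LV_myo"]], "LV")
    g_rv = tag_boundary(mesh, [roles["RV_myo"]], "RV")
    g_lvp = tag_boundary(mesh, [roles["LV_pool"]], "LV_pool")
    g_rvp = tag_boundary(mesh, [roles["RV_pool"]], "RV_pool")
    foreground = sorted(set(mesh.element_tags.tolist()))
    g_bg = tag_boundary(mesh, foreground, "B")  # background surface

    lv_endo = face_set_op(g_myo, g_lvp, "intersection")
    rv_endo = face_set_op(g_myo, g_rvp, "intersection")
    lv_epi = face_set_op(g_lv, g_bg, "intersection")
    rv_epi = face_set_op(g_rv, g_bg, "intersection")
    epi_all = face_set_op(lv_epi, rv_epi, "union")

    if "base" in roles and np.any(mesh.element_tags == roles["base"]):
        g_base = tag_boundary(mesh, [roles["base"]], "base_region")
        base = face_set_op(g_myo, g_base, "intersection")
        epi = face_set_op(epi_all, base, "difference")
    else:
        # flat cut: myocardium-background faces near the top z plane
        if not len(epi_all):
            raise ValueError("empty epicardial surface: mis-tagged segmentation")
        znode = mesh.nodes[:, 2]
        ztop = znode[epi_all.nodes()].max()
        band = base_band if base_band is not None else 1e-6 * max(1.0, abs(ztop))
        flat = np.all(znode[epi_all.faces] > ztop - band - 1e-9, axis=1)
        base = FaceSet(epi_all.faces[flat], mesh, "base")
        epi = FaceSet(epi_all.faces[~flat], mesh, "epi")

    named = {"lv_endo": lv_endo, "rv_endo": rv_endo, "epi": epi, "base": base}
    for nm, fs in named.items():
        fs.name = nm
        if not len(fs):
            raise ValueError(f"empty required surface {nm!r}: mis-tagged segmentation")
    for i, (na, fa) in enumerate(named.items()):
        for nb, fb in list(named.items())[i + 1:]:
            if len(face_set_op(fa, fb, "intersection")):
                raise ValueError(f"derived surfaces {na!r} and {nb!r} overlap")

    epi_nodes = epi.nodes()
    z = mesh.nodes[epi_nodes, 2]
    apex_node = int(epi_nodes[np.lexsort((epi_nodes, z))[0]])
    return BCSurfaces(lv_endo, rv_endo, epi, base, apex_node)


# -- export ---------------------------------------------------------------


def write_surf(faceset: FaceSet, path) -> None:
    """CARP .surf: face count, then 'Tr n0 n1 n2' per line."""
    with open(path, "w") as fh:
        fh.write(f"{len(faceset)}\n")
        for a, b, c in faceset.faces:
            fh.write(f"Tr {a} {b} {c}\n")


def write_faceset_vtk(faceset: FaceSet, path) -> None:
    """Legacy ASCII VTK polydata of the face set (compacted nodes)."""
    nodes = faceset.nodes()
    remap = {int(n): i for i, n in enumerate(nodes)}
    pts = faceset.mesh.nodes[nodes]
    lines = [
        "# vtk DataFile Version 3.0",
        f"cardiomesh face set {faceset.name}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(pts)} double",
    ]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in pts]
    lines.append(f"POLYGONS {len(faceset)} {4 * len(faceset)}")
    lines += [
        f"3 {remap[int(a)]} {remap[int(b)]} {remap[int(c)]}"
        for a, b, c in faceset.faces
    ]
    Path(path).write_text("\n".join(lines) + "\n")
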