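"""Shared fixtures: reduced phantoms, analytic meshes, pipeline bundles.

All inputs are generated programmatically; session scope keeps the more
expensive artifacts (meshes, pipeline runs) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiomesh.label_io import LabelImage
from cardiomesh.meshing import mesh_from_label_image
from cardiomesh.phantom import PhantomSpec, make_biventricular_phantom
from cardiomesh.surface_extraction import extract_tag_surface, merge_tag_surfaces
from cardiomesh.surface_tagging import BCSurfaces, FaceSet, tag_boundary


def small_phantom_spec(**overrides) -> PhantomSpec:
    """Reduced biventricular phantom used throughout the test suite."""
    kw = dict(
        lv_outer_radii=(16.0, 16.0, 24.0),
        lv_wall_thickness=5.0,
        rv_outer_radii=(17.0, 15.0, 21.0),
        rv_wall_thickness=3.0,
        rv_center_offset=(12.0, 0.0, 2.0),
        spacing=1.0,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_phantom():
    """(image, analytic surfaces) of the reduced phantom at 1 mm."""
    return make_biventricular_phantom(small_phantom_spec())


@pytest.fixture(scope="session")
def small_phantom_surface(small_phantom):
    """Merged multi-tag marching surface of the reduced phantom."""
    image, _ = small_phantom
    tags = sorted(set(np.unique(image.voxels).tolist()) - {0})
    return merge_tag_surfaces(
        [extract_tag_surface(image, t) for t in tags], image
    )


@pytest.fixture(scope="session")
def small_phantom_mesh(small_phantom):
    """Kuhn-split mesh of the reduced phantom at source (1 mm) resolution."""
    image, _ = small_phantom
    return mesh_from_label_image(image)


def sphere_image(radius: float = 10.0, spacing: float = 1.0, pad: float = 2.0):
    """Binary sphere label image centred in its grid."""
    half = radius + pad
    n = int(np.ceil(2 * half / spacing))
    origin = np.full(3, -half)
    c = [origin[a] + (np.arange(n) + 0.5) * spacing for a in range(3)]
    r2 = (
        c[0][:, None, None] ** 2 + c[1][None, :, None] ** 2 + c[2][None, None, :] ** 2
    )
    vox = (r2 <= radius**2).astype(np.uint16)
    return LabelImage(vox, np.full(3, spacing), origin, {1: "sphere"})


ANNULUS_R_IN, ANNULUS_R_OUT, ANNULUS_HEIGHT = 10.0, 15.0, 20.0


def annulus_mesh(spacing: float = 1.0):
    """Idealized thick-walled LV annulus (cylindrical shell) mesh + BCs.

    The shell occupies r in [R_IN, R_OUT], z in [0, HEIGHT]; lv_endo is the
    inner wall, epi the outer, base the top disc ring and apex_faces the
    bottom ring, so the apicobasal potential is exactly linear in z.
    """
    half = ANNULUS_R_OUT + 2 * spacing
    n = int(np.ceil(2 * half / spacing))
    nz = int(np.ceil((ANNULUS_HEIGHT + 4 * spacing) / spacing))
    origin = np.array([-half, -half, -2 * spacing])
    cx = origin[0] + (np.arange(n) + 0.5) * spacing
    cy = origin[1] + (np.arange(n) + 0.5) * spacing
    cz = origin[2] + (np.arange(nz) + 0.5) * spacing
    r = np.hypot(cx[:, None, None], cy[None, :, None])
    inz = (cz >= 0) & (cz <= ANNULUS_HEIGHT)
    vox = (
        (r >= ANNULUS_R_IN) & (r <= ANNULUS_R_OUT) & inz[None, None, :]
    ).astype(np.uint16)
    image = LabelImage(vox, np.full(3, spacing), origin, {1: "LV_myo"})
    mesh = mesh_from_label_image(image)

    boundary = tag_boundary(mesh, [1], "all")
    cent = mesh.nodes[boundary.faces].mean(axis=1)
    rc = np.hypot(cent[:, 0], cent[:, 1])
    ztop = mesh.nodes[:, 2].max()
    zbot = mesh.nodes[np.unique(mesh.tets)][:, 2].min()
    top = np.abs(cent[:, 2] - ztop) < 0.25 * spacing
    bot = np.abs(cent[:, 2] - zbot) < 0.25 * spacing
    side = ~top & ~bot
    mid = 0.5 * (ANNULUS_R_IN + ANNULUS_R_OUT)
    inner = side & (rc < mid)
    outer = side & (rc >= mid)
    bc = BCSurfaces(
        lv_endo=FaceSet(boundary.faces[inner], mesh, "lv_endo"),
        rv_endo=FaceSet(np.zeros((0, 3), np.int64), mesh, "rv_endo"),
        epi=FaceSet(boundary.faces[outer], mesh, "epi"),
        base=FaceSet(boundary.faces[top], mesh, "base"),
        apex_node=int(np.unique(mesh.tets)[np.argmin(mesh.nodes[np.unique(mesh.tets)][:, 2])]),
        apex_faces=FaceSet(boundary.faces[bot], mesh, "apex"),
    )
    return mesh, bc


@pytest.fixture(scope="session")
def lv_annulus():
    return annulus_mesh(spacing=1.0)


def two_voxel_image(tag_a: int = 1, tag_b: int = 2) -> LabelImage:
    """2x1x1 image with two abutting voxels of different tags."""
    vox = np.zeros((2, 1, 1), np.uint16)
    vox[0, 0, 0] = tag_a
    vox[1, 0, 0] = tag_b
    return LabelImage(vox, np.ones(3), np.zeros(3), {tag_a: "A", tag_b: "B"})
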