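"""Boundary face sets, set algebra and anatomical surface derivation."""

import numpy as np
import pytest

from cardiomesh.label_io import LabelImage
from cardiomesh.meshing import mesh_from_label_image
from cardiomesh.surface_tagging import (
    FaceSet,
    derive_bc_surfaces,
    face_set_op,
    tag_boundary,
)

_TET_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))


def _brute_force_boundary(mesh, tags):
    """Independent O(n^2-ish) boundary oracle via a face dictionary."""
    count = {}
    for tet, tag in zip(mesh.tets, mesh.element_tags):
        if tag not in tags:
            continue
        for f in _TET_FACES:
            key = tuple(sorted(int(tet[i]) for i in f))
            count[key] = count.get(key, 0) + 1
    return {k for k, v in count.items() if v == 1}


def test_single_voxel_region_has_12_boundary_triangles():
    vox = np.zeros((3, 3, 3), np.uint16)
    vox[1, 1, 1] = 2
    vox[vox == 0] = 1
    image = LabelImage(vox, (1, 1, 1), (0, 0, 0), {1: "bulk", 2: "dot"})
    mesh = mesh_from_label_image(image)
    fs = tag_boundary(mesh, [2])
    assert len(fs) == 12  # 6 cube facets x 2 triangles


def test_all_foreground_boundary_is_global_boundary(small_phantom_mesh):
    """The background surface equals the boundary of all foreground tags."""
    mesh = small_phantom_mesh
    fs = tag_boundary(mesh, [1, 2, 3, 4])
    brute = _brute_force_boundary(mesh, {1, 2, 3, 4})
    assert {tuple(f) for f in fs.faces.tolist()} == brute


def test_lv_rv_interface_matches_element_pair_scan(small_phantom_mesh):
    """Gamma_LV intersect Gamma_RV equals the faces found by scanning
    element pairs of differing myocardial tags."""
    mesh = small_phantom_mesh
    inter = face_set_op(tag_boundary(mesh, [1]), tag_boundary(mesh, [2]),
                        "intersection")
    # brute force: faces shared by one LV_myo and one RV_myo element
    owners = {}
    for ei, (tet, tag) in enumerate(zip(mesh.tets, mesh.element_tags)):
        if tag not in (1, 2):
            continue
        for f in _TET_FACES:
            key = tuple(sorted(int(tet[i]) for i in f))
            owners.setdefault(key, []).append(int(tag))
    brute = {k for k, tags in owners.items() if sorted(tags) == [1, 2]}
    assert len(inter) > 0
    assert {tuple(f) for f in inter.faces.tolist()} == brute


class TestSetAlgebra:
    def test_identities(self, small_phantom_mesh):
        a = tag_boundary(small_phantom_mesh, [1])
        assert len(face_set_op(a, a, "intersection")) == len(a)
        assert len(face_set_op(a, a, "difference")) == 0
        assert len(face_set_op(a, a, "union")) == len(a)

    def test_disjoint_intersection_empty(self, small_phantom_mesh):
        mesh = small_phantom_mesh
        a = tag_boundary(mesh, [3])  # LV pool surface
        b = tag_boundary(mesh, [4])  # RV pool surface
        assert len(face_set_op(a, b, "intersection")) == 0

    def test_inclusion_exclusion(self, small_phantom_mesh):
        mesh = small_phantom_mesh
        a = tag_boundary(mesh, [1])
        b = tag_boundary(mesh, [2])
        u = face_set_op(a, b, "union")
        i = face_set_op(a, b, "intersection")
        assert len(u) == len(a) + len(b) - len(i)

    def test_mismatched_meshes_rejected(self, small_phantom):
        image, _ = small_phantom
        m1 = mesh_from_label_image(image, tags=[1])
        m2 = mesh_from_label_image(image, tags=[1])
        a = tag_boundary(m1, [1])
        b = tag_boundary(m2, [1])
        with pytest.raises(ValueError, match="different meshes"):
            face_set_op(a, b, "union")

    def test_unknown_tag_and_empty_tags(self, small_phantom_mesh):
        with pytest.raises(KeyError):
            tag_boundary(small_phantom_mesh, [42])
        with pytest.raises(ValueError):
            tag_boundary(small_phantom_mesh, [])


def test_boundary_union_subset_property():
    """boundary(A u B) is contained in boundary(A) xor boundary(B) plus the
    A/B interface, brute-forced on a random two-tag image."""
    rng = np.random.default_rng(4)
    vox = rng.choice([0, 1, 2], size=(4, 4, 4), p=[0.3, 0.4, 0.3]).astype(np.uint16)
    vox[0, 0, 0] = 1
    vox[1, 0, 0] = 2
    image = LabelImage(vox, (1, 1, 1), (0, 0, 0), {1: "a", 2: "b"})
    mesh = mesh_from_label_image(image)
    b_ab = {tuple(f) for f in tag_boundary(mesh, [1, 2]).faces.tolist()}
    b_a = {tuple(f) for f in tag_boundary(mesh, [1]).faces.tolist()}
    b_b = {tuple(f) for f in tag_boundary(mesh, [2]).faces.tolist()}
    interface = b_a & b_b
    assert b_ab <= (b_a ^ b_b) | interface


class TestDeriveBCSurfaces:
    def test_nonempty_and_pairwise_disjoint(self, small_phantom_mesh):
        bc = derive_bc_surfaces(small_phantom_mesh)
        named = bc.as_dict()
        for nm, fs in named.items():
            assert len(fs) > 0, nm
        names = list(named)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = face_set_op(named[a], named[b], "intersection")
                assert len(inter) == 0, (a, b)

    def test_epi_faces_have_one_myocardial_element(self, small_phantom_mesh):
        """Every epicardial face belongs to exactly one tet, and that tet is
        myocardial (adjacency scan)."""
        mesh = small_phantom_mesh
        bc = derive_bc_surfaces(mesh)
        owners = {}
        for ei, tet in enumerate(mesh.tets):
            for f in _TET_FACES:
                key = tuple(sorted(int(tet[i]) for i in f))
                owners.setdefault(key, []).append(ei)
        for face in bc.epi.faces[::7]:
            adj = owners[tuple(face.tolist())]
            assert len(adj) == 1
            assert mesh.element_tags[adj[0]] in (1, 2)

    def test_coverage_of_myocardial_boundary(self, small_phantom_mesh):
        """lv_endo + rv_endo + epi + base partition the myocardial boundary."""
        mesh = small_phantom_mesh
        bc = derive_bc_surfaces(mesh)
        union = bc.lv_endo
        for other in (bc.rv_endo, bc.epi, bc.base):
            union = face_set_op(union, other, "union")
        myo = tag_boundary(mesh, [1, 2])
        assert len(union) == len(myo)
        assert len(face_set_op(union, myo, "difference")) == 0

    def test_apex_is_lowest_epicardial_node(self, small_phantom_mesh):
        mesh = small_phantom_mesh
        bc = derive_bc_surfaces(mesh)
        epi_nodes = bc.epi.nodes()
        assert bc.apex_node in epi_nodes
        assert np.isclose(
            mesh.nodes[bc.apex_node, 2], mesh.nodes[epi_nodes, 2].min()
        )

    def test_missing_role_raises(self, small_phantom):
        image, _ = small_phantom
        table = dict(image.tag_table)
        table[4] = "not_a_pool"
        relabeled = LabelImage(image.voxels, image.spacing, image.origin, table)
        mesh = mesh_from_label_image(relabeled)
        with pytest.raises((KeyError, ValueError)):
            derive_bc_surfaces(mesh)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    pick_a=st.lists(st.booleans(), min_size=12, max_size=12),
    pick_b=st.lists(st.booleans(), min_size=12, max_size=12),
    op_chain=st.sampled_from(["union", "intersection", "difference"]),
)
def test_face_set_algebra_properties(pick_a, pick_b, op_chain):
    """Set-algebra laws on arbitrary sub-selections of a small boundary:
    De Morgan-style size bookkeeping and idempotence."""
    vox = np.zeros((3, 3, 3), np.uint16)
    vox[1, 1, 1] = 1
    image = LabelImage(vox, (1, 1, 1), (0, 0, 0), {1: "a"})
    mesh = mesh_from_label_image(image)
    boundary = tag_boundary(mesh, [1])  # 12 faces
    a = FaceSet(boundary.faces[np.array(pick_a, bool)], mesh, "a")
    b = FaceSet(boundary.faces[np.array(pick_b, bool)], mesh, "b")
    u = face_set_op(a, b, "union")
    i = face_set_op(a, b, "intersection")
    d = face_set_op(a, b, "difference")
    assert len(u) == len(a) + len(b) - len(i)
    assert len(d) == len(a) - len(i)
    res = face_set_op(a, a, op_chain)
    assert len(res) == (len(a) if op_chain in ("union", "intersection") else 0)


def test_faceset_canonicalization(small_phantom_mesh):
    mesh = small_phantom_mesh
    faces = np.array([[3, 1, 2], [1, 2, 3], [9, 7, 8]])
    fs = FaceSet(faces, mesh, "x")
    assert len(fs) == 2  # duplicates collapse after sorting rows
    assert np.all(fs.faces[:, 0] <= fs.faces[:, 1])
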