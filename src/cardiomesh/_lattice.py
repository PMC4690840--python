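"""Shared lattice geometry: the Kuhn (Freudenthal) 6-tetrahedron cube split.

The same split is used for marching-tetrahedra surface extraction (cells
between voxel-center samples) and for voxel meshing (cells = voxels).  The
split is translation invariant, so faces on shared cube facets receive the
same diagonal in neighbouring cubes and the global tessellation conforms.
"""

from __future__ import annotations

import itertools

import numpy as np

# Corner offsets of a unit cube, index = 4*dx + 2*dy + dz.
CUBE_CORNERS = np.array(
    [[dx, dy, dz] for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)],
    dtype=np.int64,
)


def _build_kuhn_tets() -> np.ndarray:
    """Six tets around the main diagonal (0,0,0)-(1,1,1), positively oriented.

    For each permutation (p0,p1,p2) of the axes the tet walks the cube edges
    in that order.  Odd permutations produce negative volume; two vertices
    are swapped to restore positive orientation (the case tables in the
    marching-tetrahedra code assume it).
    """
    tets = []
    eye = np.eye(3, dtype=np.int64)
    for perm in itertools.permutations(range(3)):
        c0 = np.zeros(3, dtype=np.int64)
        c1 = c0 + eye[perm[0]]
        c2 = c1 + eye[perm[1]]
        c3 = np.ones(3, dtype=np.int64)
        verts = np.array([c0, c1, c2, c3])
        vol = np.linalg.det((verts[1:] - verts[0]).astype(float))
        if vol < 0:
            verts = verts[[0, 2, 1, 3]]
        tets.append(verts)
    out = np.array(tets)  # (6, 4, 3)
    for t in out:
        assert np.linalg.det((t[1:] - t[0]).astype(float)) > 0
    return out


KUHN_TETS = _build_kuhn_tets()

# Corner index (0..7) of each tet vertex, for gathering cube-corner values.
KUHN_TET_CORNERS = np.array(
    [[4 * v[0] + 2 * v[1] + v[2] for v in tet] for tet in KUHN_TETS],
    dtype=np.int64,
)


def perm_parity(seq) -> int:
    """Parity (0 even, 1 odd) of a permutation given as a sequence."""
    seq = list(seq)
    inv = sum(
        1
        for i in range(len(seq))
        for j in range(i + 1, len(seq))
        if seq[i] > seq[j]
    )
    return inv % 2
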