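"""Laplace-Dirichlet rule-based myocardial fiber architecture.

Muscle-fiber orientation dominates cardiac electrical and mechanical
anisotropy but is not resolvable in clinical images, so orthotropic
eigenaxes (fiber f, sheet s, sheet-normal n) are assigned by rule.  Harmonic
potentials solved on the myocardium with Dirichlet data on the derived
anatomical surfaces give smooth transmural and apicobasal coordinates;
their gradients are orthonormalized into local (circumferential,
apicobasal, transmural) frames, which are rotated about the transmural axis
by a helix angle varying linearly across the wall,

    alpha(d) = alpha_endo * (1 - d) + alpha_epi * d,   d in [0, 1],

(endocardium d=0, epicardium d=1; +60/-60 degrees by default) and about the
fiber axis by an analogous sheet angle beta(d) (0 by default).  Frames are
computed per ventricle from that ventricle's transmural potential and then
blended by bidirectional spherical-linear quaternion interpolation
(bislerp) with the inter-ventricular weight, which resolves the sign/axis
flips of the septum's dual identity.

The Laplace problems use linear tetrahedral finite elements; on the
lattice meshes produced by the voxel mesher the stiffness matrix is an
M-matrix, so the discrete maximum principle holds and every potential stays
inside its Dirichlet range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import TetMesh
from .surface_tagging import BCSurfaces, FaceSet

__all__ = [
    "LaplaceField",
    "FiberConfig",
    "FiberField",
    "solve_laplace",
    "assign_fibers",
    "helix_angle_profile",
]


@dataclass
class LaplaceField:
    """Nodal solution of a Dirichlet Laplace problem on (part of) a mesh.

    ``values`` has one entry per mesh node; nodes outside the solved region
    are NaN.  ``element_mask`` marks the elements the problem was solved on.
    """

    values: np.ndarray
    dirichlet: list
    element_mask: np.ndarray

    def element_means(self, mesh: TetMesh) -> np.ndarray:
        return self.values[mesh.tets].mean(axis=1)


def _dirichlet_entry(entry, value) -> tuple[np.ndarray, np.ndarray]:
    """Normalize one (node spec, value) pair to aligned node/value arrays.

    ``value`` may be a scalar or an array aligned with the node spec
    (enabling analytic boundary data in verification problems)."""
    if isinstance(entry, FaceSet):
        nodes = entry.nodes()
    else:
        nodes = np.atleast_1d(np.asarray(entry, np.int64))
        if nodes.ndim != 1:
            raise ValueError("Dirichlet node spec must be 1-D")
    vals = np.asarray(value, float)
    if vals.ndim == 0:
        vals = np.full(len(nodes), float(vals))
    elif len(vals) != len(nodes):
        raise ValueError("Dirichlet value array must match the node set")
    return nodes, vals


def _p1_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Per-element P1 basis gradients (m,4,3) and volumes (m,)."""
    v = nodes[tets]
    M = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=1)
    vol = np.linalg.det(M) / 6.0
    Minv = np.linalg.inv(M)  # rows of Minv.T are grad lambda_1..3
    g = np.transpose(Minv, (0, 2, 1))  # (m, 3(basis 1..3), 3)
    g0 = -g.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g], axis=1), vol


def solve_laplace(
    mesh: TetMesh,
    dirichlet: list,
    elements: np.ndarray | None = None,
    rtol: float = 1e-10,
) -> LaplaceField:
    """Linear-FE solution of laplace(u)=0 with Dirichlet boundary values.

    ``dirichlet`` is a list of (FaceSet | node-id array | node id, value)
    pairs; overlapping node sets are allowed only when they agree on the
    value.  ``elements`` restricts the problem to an element subset (e.g.
    the myocardium).  Solved iteratively (Jacobi-preconditioned CG) to a
    relative residual <= ``rtol``, with a sparse direct fallback.
    """
    if elements is None:
        elements = np.ones(mesh.n_elements, bool)
    elements = np.asarray(elements, bool)
    tets = mesh.tets[elements]
    if not len(tets):
        raise ValueError("empty element selection")
    used = np.unique(tets)
    n = mesh.n_nodes

    bc_vals = np.full(n, np.nan)
    for entry, value in dirichlet:
        nodes, vals_e = _dirichlet_entry(entry, value)
        inside = np.isin(nodes, used)
        nodes, vals_e = nodes[inside], vals_e[inside]
        conflict = ~np.isnan(bc_vals[nodes]) & (bc_vals[nodes] != vals_e)
        if conflict.any():
            raise ValueError("non-disjoint Dirichlet sets with conflicting values")
        bc_vals[nodes] = vals_e
    fixed = ~np.isnan(bc_vals)
    if not fixed.any():
        raise ValueError("singular system: no Dirichlet nodes in the solved region")
    vals = bc_vals[fixed]

    grads, vol = _p1_gradients(mesh.nodes, tets)
    # local stiffness K_ij = vol * grad_i . grad_j
    K_loc = np.einsum("mik,mjk,m->mij", grads, grads, vol)
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    K = sp.coo_matrix((K_loc.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    u = np.full(n, np.nan)
    u[fixed] = bc_vals[fixed]
    free = np.zeros(n, bool)
    free[used] = True
    free &= ~fixed
    if free.any():
        Kff = K[free][:, free]
        rhs = -K[free][:, fixed] @ bc_vals[fixed]
        if np.unique(vals).size == 1:
            u[free] = vals[0]
        else:
            diag = Kff.diagonal()
            M = sp.diags(1.0 / np.where(diag > 0, diag, 1.0))
            x, info = spla.cg(Kff, rhs, rtol=rtol, atol=0.0, M=M,
                              maxiter=20 * Kff.shape[0])
            if info != 0:
                x = spla.spsolve(Kff.tocsc(), rhs)
            u[free] = x

    lo, hi = vals.min(), vals.max()
    span = max(hi - lo, 1e-30)
    viol = max(lo - np.nanmin(u), np.nanmax(u) - hi)
    if viol > 1e-8 * span:
        warnings.warn(
            f"discrete maximum principle violated by {viol:.3g}; "
            "mesh may contain obtuse elements", stacklevel=2)
    sel = ~np.isnan(u)
    u[sel] = np.clip(u[sel], lo, hi)
    return LaplaceField(u, list(dirichlet), elements)


# -- fiber rule -----------------------------------------------------------


@dataclass
class FiberConfig:
    """Helix/sheet angle rule parameters (degrees)."""

    alpha_endo: float = 60.0
    alpha_epi: float = -60.0
    beta_endo: float = 0.0
    beta_epi: float = 0.0
    interpolation: str = "bislerp"  # or "linear-frame"
    myocardium_names: tuple[str, ...] = ("LV_myo", "RV_myo")
    # face-neighbour averaging passes on the element gradient fields before
    # frame construction; damps gradient-direction noise in the first
    # element layer at staircased Dirichlet boundaries
    gradient_smoothing_passes: int = 1

    def __post_init__(self) -> None:
        for a in (self.alpha_endo, self.alpha_epi, self.beta_endo, self.beta_epi):
            if not (-90.0 < a <= 90.0):
                raise ValueError("angles must lie in (-90, 90] degrees")
        if self.interpolation not in ("bislerp", "linear-frame"):
            raise ValueError("interpolation must be bislerp or linear-frame")


@dataclass
class FiberField:
    """Per-element orthonormal triads (fiber, sheet, sheet-normal).

    Non-myocardial elements carry a zero (flagged) triad and are excluded
    from ``myocardial``.  ``d`` is the element transmural coordinate and
    (``frame_c``, ``frame_l``, ``frame_t``) the unrotated local
    circumferential/apicobasal/transmural frame used to measure helix
    angles.
    """

    f: np.ndarray
    s: np.ndarray
    n: np.ndarray
    myocardial: np.ndarray
    d: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_c: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_l: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_t: np.ndarray = field(default=None)  # type: ignore[assignment]

    def validate(self, atol: float = 1e-9) -> None:
        m = self.myocardial
        for arr in (self.f[m], self.s[m], self.n[m]):
            if np.abs(np.linalg.norm(arr, axis=1) - 1).max() > atol:
                raise ValueError("triad vectors are not unit norm")
        if np.abs(np.einsum("ij,ij->i", self.f[m], self.s[m])).max() > atol:
            raise ValueError("f and s are not orthogonal")
        det = np.einsum("ij,ij->i", np.cross(self.f[m], self.s[m]), self.n[m])
        if np.abs(det - 1).max() > atol:
            raise ValueError("triads are not right-handed orthonormal")

    def helix_angles_deg(self) -> np.ndarray:
        """Helix angle of f against the local circumferential direction.

        The fiber is a direction (f and -f equivalent), so the angle is
        folded into (-90, 90] as conventional for helix angles.
        """
        out = np.full(len(self.f), np.nan)
        m = self.myocardial
        ang = np.degrees(
            np.arctan2(
                np.einsum("ij,ij->i", self.f[m], self.frame_l[m]),
                np.einsum("ij,ij->i", self.f[m], self.frame_c[m]),
            )
        )
        ang = np.where(ang > 90.0, ang - 180.0, ang)
        ang = np.where(ang <= -90.0, ang + 180.0, ang)
        out[m] = ang
        return out


def _element_face_adjacency(tets: np.ndarray) -> np.ndarray:
    """(k, 2) pairs of element indices sharing a face."""
    faces = np.vstack([tets[:, f] for f in ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))])
    faces = np.sort(faces, axis=1)
    owner = np.tile(np.arange(len(tets)), 4)
    order = np.lexsort((faces[:, 2], faces[:, 1], faces[:, 0]))
    sf, so = faces[order], owner[order]
    same = np.all(sf[:-1] == sf[1:], axis=1)
    return np.stack([so[:-1][same], so[1:][same]], axis=1)


def _fill_degenerate_gradients(
    g: np.ndarray, adjacency: np.ndarray, what: str
) -> np.ndarray:
    """Replace (near-)zero element gradients by neighbour averages.

    Elements whose nodes are all Dirichlet (e.g. the top layer under the
    base surface) have an exactly zero field gradient; their direction is
    taken from face-adjacent elements.  If a whole connected component is
    degenerate the boundary sets cannot drive the field there, which is a
    genuine input error.
    """
    norm = np.linalg.norm(g, axis=1)
    ref = np.median(norm[norm > 0]) if np.any(norm > 0) else 0.0
    bad = norm < 1e-12 + 1e-8 * ref
    if not bad.any():
        return g
    g = g.copy()
    for _ in range(1000):
        pick = bad[adjacency[:, 0]] != bad[adjacency[:, 1]]
        if not pick.any():
            break
        pairs = adjacency[pick]
        tgt = np.where(bad[pairs[:, 0]], pairs[:, 0], pairs[:, 1])
        src = np.where(bad[pairs[:, 0]], pairs[:, 1], pairs[:, 0])
        acc = np.zeros_like(g)
        cnt = np.zeros(len(g))
        np.add.at(acc, tgt, g[src])
        np.add.at(cnt, tgt, 1.0)
        newly = cnt > 0
        g[newly] = acc[newly] / cnt[newly][:, None]
        bad[newly] = False
        if not bad.any():
            break
    if bad.any():
        raise ValueError(f"zero {what} gradient: disconnected boundary sets")
    return g


def _normalize(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.maximum(norm, 1e-300)


def _average_gradients(g: np.ndarray, adjacency: np.ndarray, passes: int) -> np.ndarray:
    """Uniform face-neighbour averaging of an element vector field."""
    for _ in range(passes):
        acc = g.copy()
        cnt = np.ones(len(g))
        np.add.at(acc, adjacency[:, 0], g[adjacency[:, 1]])
        np.add.at(cnt, adjacency[:, 0], 1.0)
        np.add.at(acc, adjacency[:, 1], g[adjacency[:, 0]])
        np.add.at(cnt, adjacency[:, 1], 1.0)
        g = acc / cnt[:, None]
    return g


def _build_frames(g_trans: np.ndarray, g_long: np.ndarray) -> tuple[np.ndarray, ...]:
    """(circumferential, apicobasal, transmural) frame per element.

    t = transmural gradient direction; l = apicobasal gradient with the
    transmural component removed; c = l x t (right-handed (c, l, t)).  Where
    the apicobasal gradient is collinear with t (apex pole) a deterministic
    reference axis replaces it.
    """
    t = _normalize(g_trans)
    lraw = g_long - np.einsum("ij,ij->i", g_long, t)[:, None] * t
    bad = np.linalg.norm(lraw, axis=1) < 1e-8 * np.maximum(
        np.linalg.norm(g_long, axis=1), 1e-30
    )
    if bad.any():
        ref = np.zeros((bad.sum(), 3))
        tx = np.abs(t[bad, 0]) < 0.9
        ref[tx, 0] = 1.0
        ref[~tx, 1] = 1.0
        lraw[bad] = ref - np.einsum("ij,ij->i", ref, t[bad])[:, None] * t[bad]
    l = _normalize(lraw)
    c = np.cross(l, t)
    return c, l, t


def _rotate_frames(c, l, t, alpha_deg, beta_deg):
    """Apply helix rotation about t, then sheet rotation about f."""
    a = np.radians(alpha_deg)[:, None]
    b = np.radians(beta_deg)[:, None]
    f = np.cos(a) * c + np.sin(a) * l
    lp = -np.sin(a) * c + np.cos(a) * l
    s = np.cos(b) * t - np.sin(b) * lp
    n = np.cross(f, s)
    return f, s, n


def _quat_from_frames(f, s, n) -> np.ndarray:
    """Unit quaternions (w, x, y, z) of rotation matrices with columns f,s,n."""
    R = np.stack([f, s, n], axis=2)  # (m, 3, 3)
    m = len(R)
    q = np.empty((m, 4))
    tr = R[:, 0, 0] + R[:, 1, 1] + R[:, 2, 2]
    # Shepperd's method, branch per element (vectorized by case)
    case0 = tr > 0
    w = np.sqrt(np.maximum(1 + tr, 0)) / 2
    q[case0, 0] = w[case0]
    denom = np.where(w > 1e-12, 4 * w, 1.0)
    q[case0, 1] = (R[case0, 2, 1] - R[case0, 1, 2]) / denom[case0]
    q[case0, 2] = (R[case0, 0, 2] - R[case0, 2, 0]) / denom[case0]
    q[case0, 3] = (R[case0, 1, 0] - R[case0, 0, 1]) / denom[case0]
    for i in np.flatnonzero(~case0):
        Ri = R[i]
        k = int(np.argmax(np.diag(Ri)))
        j, l2 = (k + 1) % 3, (k + 2) % 3
        sqk = np.sqrt(max(Ri[k, k] - Ri[j, j] - Ri[l2, l2] + 1.0, 0.0)) * 0.5
        qi = np.empty(4)
        qi[1 + k] = sqk
        qi[0] = (Ri[l2, j] - Ri[j, l2]) / (4 * sqk)
        qi[1 + j] = (Ri[j, k] + Ri[k, j]) / (4 * sqk)
        qi[1 + l2] = (Ri[l2, k] + Ri[k, l2]) / (4 * sqk)
        q[i] = qi
    return _normalize(q)


def _quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a[:, 0], a[:, 1], a[:, 2], a[:, 3]
    w2, x2, y2, z2 = b[:, 0], b[:, 1], b[:, 2], b[:, 3]
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=1,
    )


def _quat_to_frames(q: np.ndarray):
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    f = np.stack([1 - 2 * (y * y + z * z), 2 * (x * y + w * z), 2 * (x * z - w * y)], 1)
    s = np.stack([2 * (x * y - w * z), 1 - 2 * (x * x + z * z), 2 * (y * z + w * x)], 1)
    n = np.stack([2 * (x * z + w * y), 2 * (y * z - w * x), 1 - 2 * (x * x + y * y)], 1)
    return f, s, n


_BASIS_QUATS = np.array(
    [[1.0, 0, 0, 0], [0, 1.0, 0, 0], [0, 0, 1.0, 0], [0, 0, 0, 1.0]]
)


def _bislerp(qa: np.ndarray, qb: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Bidirectional slerp: qa is replaced by its closest flip/axis-swap.

    Candidates are qa multiplied by the unit quaternions {1, i, j, k} (the
    180-degree axis flips), with the quaternion double-cover sign folded in
    via |dot|; the candidate with maximal |dot(., qb)| is slerped to qb.
    """
    m = len(qa)
    best = np.full(m, -1.0)
    qstar = np.empty_like(qa)
    for e in _BASIS_QUATS:
        cand = _quat_mul(qa, np.broadcast_to(e, (m, 4)))
        dot = np.einsum("ij,ij->i", cand, qb)
        cand = np.where(dot[:, None] < 0, -cand, cand)
        adot = np.abs(dot)
        upd = adot > best
        best[upd] = adot[upd]
        qstar[upd] = cand[upd]
    dot = np.clip(np.einsum("ij,ij->i", qstar, qb), -1.0, 1.0)
    theta = np.arccos(dot)
    sin_t = np.sin(theta)
    small = sin_t < 1e-9
    wa = np.where(small, 1.0 - w, np.sin((1.0 - w) * theta) / np.where(small, 1, sin_t))
    wb = np.where(small, w, np.sin(w * theta) / np.where(small, 1, sin_t))
    return _normalize(wa[:, None] * qstar + wb[:, None] * qb)


def _blend_frames(Fa, Fb, w, method: str):
    """Blend two frame triples with weight w (0 -> a, 1 -> b)."""
    if method == "bislerp":
        qa = _quat_from_frames(*Fa)
        qb = _quat_from_frames(*Fb)
        return _quat_to_frames(_bislerp(qa, qb, w))
    # linear per-axis blend + Gram-Schmidt (fallback); align signs first
    out = []
    fa, sa, na = Fa
    fb, sb, nb = Fb
    sign = np.sign(np.einsum("ij,ij->i", fa, fb))
    sign[sign == 0] = 1.0
    fb, sb, nb = fb * sign[:, None], sb * sign[:, None], nb * sign[:, None]
    f = _normalize((1 - w)[:, None] * fa + w[:, None] * fb)
    s = (1 - w)[:, None] * sa + w[:, None] * sb
    s = _normalize(s - np.einsum("ij,ij->i", s, f)[:, None] * f)
    n = np.cross(f, s)
    return f, s, n


def assign_fibers(
    mesh: TetMesh,
    surfaces: BCSurfaces,
    config: FiberConfig | None = None,
) -> FiberField:
    """Assign orthotropic triads to all myocardial elements.

    Solves four harmonic potentials on the myocardium (phi_lv, phi_rv,
    phi_epi: one surface at 1, the other two at 0; psi: base 1, apex 0),
    builds per-ventricle frames from the per-element gradients with the
    linear helix/sheet angle rule, and blends them by bislerp with the
    inter-ventricular weight phi_rv / (phi_lv + phi_rv).
    """
    config = config or FiberConfig()
    myo_labels = [mesh.label_for(nm) for nm in config.myocardium_names
                  if any(v == nm for v in mesh.tag_table.values())]
    if not myo_labels:
        raise ValueError("no myocardial tags found")
    myo = np.isin(mesh.element_tags, myo_labels)

    # Node sets are made disjoint with endocardium-over-epicardium
    # precedence: where a blood pool reaches the background within one
    # voxel (crescent seam, base rim) a node can sit on several derived
    # surfaces, and the endocardial identity governs the transmural fields.
    lv = surfaces.lv_endo.nodes()
    rv = np.setdiff1d(surfaces.rv_endo.nodes(), lv)
    epi = np.setdiff1d(surfaces.epi.nodes(), np.union1d(lv, rv))
    base = surfaces.base.nodes()
    has_rv = len(rv) > 0
    bc_rv0 = [(rv, 0.0)] if has_rv else []
    phi_lv = solve_laplace(mesh, [(lv, 1.0)] + bc_rv0 + [(epi, 0.0)], myo)
    phi_epi = solve_laplace(mesh, [(epi, 1.0), (lv, 0.0)] + bc_rv0, myo)
    if has_rv:
        phi_rv = solve_laplace(mesh, [(rv, 1.0), (lv, 0.0), (epi, 0.0)], myo)
    else:
        phi_rv = LaplaceField(np.zeros(mesh.n_nodes), [], myo)
    if surfaces.apex_faces is not None and len(surfaces.apex_faces):
        apex = surfaces.apex_faces.nodes()
    else:
        apex = np.array([surfaces.apex_node])
    psi = solve_laplace(mesh, [(np.setdiff1d(base, apex), 1.0), (apex, 0.0)], myo)

    tets = mesh.tets[myo]
    grads, _vol = _p1_gradients(mesh.nodes, tets)  # (m,4,3)

    def elem_grad(fld: LaplaceField) -> np.ndarray:
        vals = np.nan_to_num(fld.values)[tets]  # (m,4)
        return np.einsum("mi,mik->mk", vals, grads)

    def elem_mean(fld: LaplaceField) -> np.ndarray:
        return np.nan_to_num(fld.values)[tets].mean(axis=1)

    eps = 1e-12
    m_lv, m_rv, m_epi = elem_mean(phi_lv), elem_mean(phi_rv), elem_mean(phi_epi)
    adjacency = _element_face_adjacency(tets)
    g_psi = _average_gradients(
        _fill_degenerate_gradients(elem_grad(psi), adjacency, "apicobasal"),
        adjacency, config.gradient_smoothing_passes,
    )

    # per-ventricle transmural depth and frames
    nodal = {}
    for name, phi in (("lv", phi_lv), ("rv", phi_rv)):
        denom = np.maximum(phi_epi.values + phi.values, eps)
        nodal[name] = phi_epi.values / denom
    d_lv_el = np.nan_to_num(nodal["lv"])[tets].mean(axis=1)
    g_dlv = _average_gradients(
        _fill_degenerate_gradients(
            np.einsum("mi,mik->mk", np.nan_to_num(nodal["lv"])[tets], grads),
            adjacency, "transmural",
        ),
        adjacency, config.gradient_smoothing_passes,
    )
    alpha_lv = config.alpha_endo * (1 - d_lv_el) + config.alpha_epi * d_lv_el
    beta_lv = config.beta_endo * (1 - d_lv_el) + config.beta_epi * d_lv_el
    F_lv = _rotate_frames(*_build_frames(g_dlv, g_psi), alpha_lv, beta_lv)

    if has_rv:
        d_rv_el = np.nan_to_num(nodal["rv"])[tets].mean(axis=1)
        g_drv = _average_gradients(
            _fill_degenerate_gradients(
                np.einsum("mi,mik->mk", np.nan_to_num(nodal["rv"])[tets], grads),
                adjacency, "transmural",
            ),
            adjacency, config.gradient_smoothing_passes,
        )
        alpha_rv = config.alpha_endo * (1 - d_rv_el) + config.alpha_epi * d_rv_el
        beta_rv = config.beta_endo * (1 - d_rv_el) + config.beta_epi * d_rv_el
        F_rv = _rotate_frames(*_build_frames(g_drv, g_psi), alpha_rv, beta_rv)
        w = m_rv / np.maximum(m_lv + m_rv, eps)
        f, s, n = _blend_frames(F_lv, F_rv, w, config.interpolation)
        F0 = _blend_frames(
            _rotate_frames(*_build_frames(g_dlv, g_psi), 0 * alpha_lv, 0 * beta_lv),
            _rotate_frames(*_build_frames(g_drv, g_psi), 0 * alpha_rv, 0 * beta_rv),
            w, config.interpolation,
        )
    else:
        f, s, n = F_lv
        F0 = _rotate_frames(*_build_frames(g_dlv, g_psi), 0 * alpha_lv, 0 * beta_lv)

    # re-orthonormalize against accumulated floating point error
    f = _normalize(f)
    s = _normalize(s - np.einsum("ij,ij->i", s, f)[:, None] * f)
    n = np.cross(f, s)
    c0, t0 = F0[0], F0[1]  # frame with alpha=0: f=c, s=t
    l0 = -F0[2]  # n0 = c x t = -l

    nm = mesh.n_elements
    out = FiberField(
        f=np.zeros((nm, 3)), s=np.zeros((nm, 3)), n=np.zeros((nm, 3)),
        myocardial=myo,
        d=np.full(nm, np.nan),
        frame_c=np.zeros((nm, 3)), frame_l=np.zeros((nm, 3)),
        frame_t=np.zeros((nm, 3)),
    )
    out.f[myo], out.s[myo], out.n[myo] = f, s, n
    denom = np.maximum(m_lv + m_rv + m_epi, eps)
    out.d[myo] = np.clip(m_epi / denom, 0.0, 1.0)
    out.frame_c[myo], out.frame_l[myo], out.frame_t[myo] = c0, l0, t0
    out.validate(atol=1e-7)
    mesh.fibers = out
    return out


def helix_angle_profile(
    mesh: TetMesh,
    fibers: FiberField,
    field: LaplaceField | None = None,
    n_bins: int = 10,
) -> dict[str, np.ndarray]:
    """Binned transmural helix-angle summary.

    ``field`` supplies the transmural coordinate (element mean of a nodal
    Laplace solution); defaults to the coordinate stored on the fiber
    field.  Empty bins are reported as NaN, never interpolated.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    d = fibers.d if field is None else field.element_means(mesh)
    angles = fibers.helix_angles_deg()
    m = fibers.myocardial & np.isfinite(d) & np.isfinite(angles)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(d[m], edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        sel = idx == b
        count[b] = sel.sum()
        if count[b]:
            mean[b] = float(angles[m][sel].mean())
    return {
        "bin_centers": 0.5 * (edges[:-1] + edges[1:]),
        "mean_angle_deg": mean,
        "count": count,
    }
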