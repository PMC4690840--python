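"""Constrained variational smoothing of the tagged boundary surface.

Low-resolution (staircase) artifacts of the extracted surface are corrected
by minimizing the quadratic norm of the discrete Laplacian of the surface
node positions,

    minimize  || L X ||^2   subject to   | X_ia - X0_ia | <= 0.5 * h_a,

where X0 are the initial (marching-cubes) positions and h_a the source
segmentation's voxel size along axis a.  The box constraint caps the
displacement of every node at half a voxel, so the smoothed surface stays
within the margin of error of the segmentation.  The problem is a convex
box-constrained quadratic program, solved either by monotone accelerated
projected gradient (default) or by ADMM; the projection is exact and is the
last step of every iteration, so feasibility always holds exactly.

The default Laplacian is the uniform "umbrella" graph operator
(x_i - mean of neighbours); cotangent weights are available behind the same
configuration.  A Euclidean-ball trust region is provided as an alternative
to the axis-aligned box for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .surface_extraction import TaggedSurface

__all__ = ["SmoothingConfig", "SmoothingReport", "build_surface_laplacian", "smooth_surface"]


@dataclass
class SmoothingConfig:
    box_halfwidth_voxels: float = 0.5
    laplacian_kind: str = "uniform-graph"  # or "cotangent"
    max_iterations: int = 2000
    tolerance: float = 1e-8
    solver: str = "projected-gradient"  # or "admm"
    constraint: str = "box"  # or "ball" (isotropic voxels only)

    def __post_init__(self) -> None:
        if self.box_halfwidth_voxels < 0:
            raise ValueError("box_halfwidth_voxels must be >= 0")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("tolerance > 0 and max_iterations >= 1 required")
        if self.laplacian_kind not in ("uniform-graph", "cotangent"):
            raise ValueError("laplacian_kind must be uniform-graph or cotangent")
        if self.solver not in ("projected-gradient", "admm"):
            raise ValueError("solver must be projected-gradient or admm")
        if self.constraint not in ("box", "ball"):
            raise ValueError("constraint must be box or ball")


@dataclass
class SmoothingReport:
    initial_objective: float
    final_objective: float
    iterations_used: int
    max_displacement_voxels: float
    converged: bool = True


def build_surface_laplacian(
    surface: TaggedSurface, kind: str = "uniform-graph"
) -> sp.csr_matrix:
    """Discrete Laplacian on surface vertices (row sums zero).

    uniform-graph: row i is x_i - mean(neighbours); cotangent: weights
    (cot a + cot b)/2 per edge, normalized by the row's total weight.
    """
    tris = surface.triangles
    n = surface.n_vertices
    edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    if kind == "uniform-graph":
        e = np.unique(np.sort(edges, axis=1), axis=0)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        w = np.ones(len(rows))
    elif kind == "cotangent":
        v = surface.vertices
        ws, rows_l, cols_l = [], [], []
        for k in range(3):
            i, j, o = tris[:, k], tris[:, (k + 1) % 3], tris[:, (k + 2) % 3]
            a, b = v[i] - v[o], v[j] - v[o]
            cross = np.linalg.norm(np.cross(a, b), axis=1)
            cot = np.einsum("ij,ij->i", a, b) / np.maximum(cross, 1e-30)
            rows_l += [i, j]
            cols_l += [j, i]
            ws += [0.5 * cot, 0.5 * cot]
        rows = np.concatenate(rows_l)
        cols = np.concatenate(cols_l)
        w = np.concatenate(ws)
    else:
        raise ValueError(f"unknown laplacian kind {kind!r}")
    A = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError("isolated vertex (no neighbours)")
    Dinv = sp.diags(1.0 / deg)
    return (sp.eye(n) - Dinv @ A).tocsr()


def _project(X, X0, half, constraint):
    if constraint == "box":
        return np.clip(X, X0 - half, X0 + half)
    d = X - X0
    r = np.linalg.norm(d, axis=1)
    radius = float(np.min(half))
    scale = np.where(r > radius, radius / np.maximum(r, 1e-300), 1.0)
    return X0 + d * scale[:, None]


def _objective(L, X) -> float:
    return float(np.sum((L @ X) ** 2))


def _solve_pg(L, X0, half, constraint, tol, max_iter):
    """Monotone accelerated projected gradient (FISTA + adaptive restart)."""
    LtL = (L.T @ L).tocsr()
    lam = spla.norm(LtL, ord=np.inf)  # upper bound; refine by power iteration
    v = np.random.default_rng(0).standard_normal(X0.shape[0])
    for _ in range(60):
        v = LtL @ v
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v /= nv
    lam = max(float(v @ (LtL @ v)), 1e-30)
    step = 1.0 / (2.0 * 1.01 * lam)

    X = X0.copy()
    Y = X0.copy()
    t = 1.0
    best = X.copy()
    f_best = _objective(L, X)
    f_prev = f_best
    iters = 0
    converged = False
    for iters in range(1, max_iter + 1):
        Xn = _project(Y - step * 2.0 * (LtL @ Y), X0, half, constraint)
        f = _objective(L, Xn)
        if f > f_prev:  # restart momentum
            t = 1.0
            Y = best.copy()
            Xn = _project(Y - step * 2.0 * (LtL @ Y), X0, half, constraint)
            f = _objective(L, Xn)
        tn = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Y = Xn + ((t - 1.0) / tn) * (Xn - X)
        X, t = Xn, tn
        if f < f_best:
            if f_best - f <= tol * max(f_best, 1e-300):
                best, f_best = X.copy(), f
                converged = True
                break
            best, f_best = X.copy(), f
        f_prev = f
    return best, f_best, iters, converged


def _solve_admm(L, X0, half, constraint, tol, max_iter):
    LtL = (2.0 * (L.T @ L)).tocsc()
    n = X0.shape[0]
    rho = max(LtL.diagonal().mean(), 1e-8)
    lu = spla.splu((LtL + rho * sp.eye(n, format="csc")).tocsc())
    Z = X0.copy()
    U = np.zeros_like(X0)
    iters = 0
    converged = False
    for iters in range(1, max_iter + 1):
        X = lu.solve(rho * (Z - U))
        Z_new = _project(X + U, X0, half, constraint)
        dual = rho * np.abs(Z_new - Z).max()
        Z = Z_new
        U += X - Z
        primal = np.abs(X - Z).max()
        if primal < np.sqrt(tol) * 1e-2 and dual < np.sqrt(tol) * 1e-2:
            converged = True
            break
    Z = _project(Z, X0, half, constraint)
    return Z, _objective(L, Z), iters, converged


def smooth_surface(
    surface: TaggedSurface,
    voxel_size,
    config: SmoothingConfig | None = None,
) -> tuple[TaggedSurface, SmoothingReport]:
    """Minimize ||L X||^2 subject to per-node half-voxel displacement caps.

    ``voxel_size`` is the SOURCE segmentation's voxel size in mm (scalar or
    per-axis).  Connectivity and face labels are unchanged; only vertex
    positions move, each by at most ``box_halfwidth_voxels`` voxels per axis
    (exactly enforced by projection).
    """
    config = config or SmoothingConfig()
    vs = np.broadcast_to(np.atleast_1d(np.asarray(voxel_size, float)), (3,)).copy()
    if np.any(vs <= 0):
        raise ValueError("voxel_size must be positive")
    if config.constraint == "ball" and not np.allclose(vs, vs[0]):
        raise ValueError("ball constraint requires isotropic voxels")
    X0 = surface.vertices.copy()
    half = config.box_halfwidth_voxels * vs

    L = build_surface_laplacian(surface, config.laplacian_kind)
    f0 = _objective(L, X0)
    if config.box_halfwidth_voxels == 0.0:
        report = SmoothingReport(f0, f0, 0, 0.0, True)
        return (
            TaggedSurface(X0, surface.triangles.copy(), surface.face_labels.copy(),
                          dict(surface.tag_table)),
            report,
        )

    solver = _solve_pg if config.solver == "projected-gradient" else _solve_admm
    X, f, iters, converged = solver(
        L, X0, half, config.constraint, config.tolerance, config.max_iterations
    )
    if f > f0:  # never accept an iterate worse than the start
        X, f = X0.copy(), f0

    d = X - X0
    if config.constraint == "box":
        max_disp = float(np.max(np.abs(d) / vs)) if len(d) else 0.0
    else:
        max_disp = float(np.max(np.linalg.norm(d, axis=1) / vs[0])) if len(d) else 0.0
    report = SmoothingReport(f0, f, iters, max_disp, converged)
    smoothed = TaggedSurface(
        X, surface.triangles.copy(), surface.face_labels.copy(), dict(surface.tag_table)
    )
    return smoothed, report
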