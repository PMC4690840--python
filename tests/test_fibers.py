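"""Laplace solver verification and rule-based fiber architecture."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation, Slerp

from cardiomesh.fibers import (
    FiberConfig,
    _bislerp,
    _quat_from_frames,
    _quat_to_frames,
    assign_fibers,
    helix_angle_profile,
    solve_laplace,
)
from cardiomesh.label_io import LabelImage
from cardiomesh.meshing import mesh_from_label_image
from cardiomesh.surface_tagging import tag_boundary

from conftest import ANNULUS_R_IN, ANNULUS_R_OUT, annulus_mesh


def _slab_mesh(n=10):
    vox = np.ones((n, 4, 4), np.uint16)
    image = LabelImage(vox, (1, 1, 1), (0, 0, 0), {1: "slab"})
    return mesh_from_label_image(image)


def _shell_mesh(h):
    r1, r2 = 10.0, 15.0
    half = r2 + 2 * h
    n = int(np.ceil(2 * half / h))
    origin = np.full(3, -half)
    c = [origin[a] + (np.arange(n) + 0.5) * h for a in range(3)]
    r = np.sqrt(
        c[0][:, None, None] ** 2 + c[1][None, :, None] ** 2 + c[2][None, None, :] ** 2
    )
    vox = ((r >= r1) & (r <= r2)).astype(np.uint16)
    return mesh_from_label_image(
        LabelImage(vox, np.full(3, h), origin, {1: "shell"})
    )


class TestLaplaceSolver:
    def test_slab_linear_solution_exact(self):
        """u linear across a slab is reproduced to 1e-8 (exact for P1)."""
        mesh = _slab_mesh()
        x = mesh.nodes[:, 0]
        left = np.flatnonzero(np.isclose(x, x.min()))
        right = np.flatnonzero(np.isclose(x, x.max()))
        fld = solve_laplace(mesh, [(left, 0.0), (right, 1.0)])
        expected = (x - x.min()) / (x.max() - x.min())
        assert np.nanmax(np.abs(fld.values - expected)) < 1e-8

    def test_constant_dirichlet_gives_constant(self):
        mesh = _slab_mesh(4)
        x = mesh.nodes[:, 0]
        left = np.flatnonzero(np.isclose(x, x.min()))
        right = np.flatnonzero(np.isclose(x, x.max()))
        fld = solve_laplace(mesh, [(left, 0.7), (right, 0.7)])
        assert np.allclose(fld.values[~np.isnan(fld.values)], 0.7)

    def test_spherical_annulus_closed_form_second_order(self):
        """Nodal RMS error against (1/r1 - 1/r)/(1/r1 - 1/r2) drops ~4x
        under one uniform refinement (observed ratio ~6, superconvergent)."""

        def cf(r, r1=10.0, r2=15.0):
            return (1 / r1 - 1 / r) / (1 / r1 - 1 / r2)

        errs = {}
        for h in (2.0, 1.0):
            mesh = _shell_mesh(h)
            bnodes = np.unique(tag_boundary(mesh, [1]).faces)
            rb = np.linalg.norm(mesh.nodes[bnodes], axis=1)
            fld = solve_laplace(mesh, [(bnodes, cf(rb))])
            free = np.setdiff1d(np.unique(mesh.tets), bnodes)
            rf = np.linalg.norm(mesh.nodes[free], axis=1)
            errs[h] = np.sqrt(np.mean((fld.values[free] - cf(rf)) ** 2))
        assert errs[1.0] < 5e-4
        assert errs[2.0] / errs[1.0] > 3.0

    def test_maximum_principle(self, lv_annulus):
        mesh, bc = lv_annulus
        fld = solve_laplace(mesh, [(bc.lv_endo, 0.0), (bc.epi, 1.0)])
        vals = fld.values[~np.isnan(fld.values)]
        assert vals.min() >= -1e-12 and vals.max() <= 1 + 1e-12

    def test_apicobasal_field_linear_on_annulus(self, lv_annulus):
        """Flat top/bottom Dirichlet with natural side walls: the linear
        profile in z is in the P1 space, hence reproduced exactly."""
        mesh, bc = lv_annulus
        fld = solve_laplace(mesh, [(bc.base, 1.0), (bc.apex_faces, 0.0)])
        z = mesh.nodes[:, 2]
        expected = (z - z.min()) / (z.max() - z.min())
        sel = ~np.isnan(fld.values)
        assert np.abs(fld.values[sel] - expected[sel]).max() < 1e-8

    def test_no_dirichlet_raises(self):
        mesh = _slab_mesh(3)
        with pytest.raises(ValueError, match="singular"):
            solve_laplace(mesh, [])

    def test_conflicting_values_raise(self):
        mesh = _slab_mesh(3)
        nodes = np.arange(4)
        with pytest.raises(ValueError, match="conflicting"):
            solve_laplace(mesh, [(nodes, 0.0), (nodes[:2], 1.0)])

    def test_agreeing_overlap_allowed(self):
        mesh = _slab_mesh(3)
        x = mesh.nodes[:, 0]
        left = np.flatnonzero(np.isclose(x, x.min()))
        right = np.flatnonzero(np.isclose(x, x.max()))
        fld = solve_laplace(mesh, [(left, 0.0), (left[:3], 0.0), (right, 1.0)])
        assert np.nanmax(fld.values) <= 1 + 1e-12


class TestBislerp:
    @staticmethod
    def _frames_from_rot(R):
        return R[:, :, 0], R[:, :, 1], R[:, :, 2]

    def test_matches_scipy_slerp_without_flips(self):
        """For nearby frames the bidirectional slerp reduces to plain slerp
        (scipy Rotation as the independent oracle)."""
        rng = np.random.default_rng(0)
        ra = Rotation.random(8, random_state=3)
        # small perturbations: no candidate flip should trigger
        rb = ra * Rotation.from_rotvec(0.3 * rng.standard_normal((8, 3)))
        w = rng.random(8)
        qa = _quat_from_frames(*self._frames_from_rot(ra.as_matrix()))
        qb = _quat_from_frames(*self._frames_from_rot(rb.as_matrix()))
        out = _quat_to_frames(_bislerp(qa, qb, w))
        for i in range(8):
            sl = Slerp([0, 1], Rotation.concatenate([ra[i], rb[i]]))
            expected = sl(w[i]).as_matrix()
            got = np.stack([out[0][i], out[1][i], out[2][i]], axis=1)
            assert np.allclose(got, expected, atol=1e-9)

    def test_endpoints_equivalent_up_to_axis_flip(self):
        rng = np.random.default_rng(1)
        ra = Rotation.random(6, random_state=5)
        rb = Rotation.random(6, random_state=6)
        qa = _quat_from_frames(*self._frames_from_rot(ra.as_matrix()))
        qb = _quat_from_frames(*self._frames_from_rot(rb.as_matrix()))
        f0, s0, n0 = _quat_to_frames(_bislerp(qa, qb, np.zeros(6)))
        fa = ra.as_matrix()[:, :, 0]
        # at w=0 the result is qa times one of {1,i,j,k}: the fiber axis is
        # preserved as a line (possibly sign-flipped or swapped is NOT
        # allowed for f: i flips s,n; j and k move f)
        f1, _, _ = _quat_to_frames(_bislerp(qa, qb, np.ones(6)))
        fb = rb.as_matrix()[:, :, 0]
        assert np.allclose(np.abs(np.einsum("ij,ij->i", f1, fb)), 1, atol=1e-9)


class TestFiberRule:
    def test_triads_orthonormal_right_handed(self, lv_annulus):
        mesh, bc = lv_annulus
        ff = assign_fibers(mesh, bc)
        ff.validate(atol=1e-7)
        assert np.all(np.isfinite(ff.d[ff.myocardial]))
        assert ff.d[ff.myocardial].min() >= 0.0
        assert ff.d[ff.myocardial].max() <= 1.0

    def test_midwall_angle_symmetric_defaults(self, lv_annulus):
        """With alpha_endo = -alpha_epi, elements at transmural coordinate
        0.5 carry helix angle 0 within 2 degrees."""
        mesh, bc = lv_annulus
        ff = assign_fibers(mesh, bc)
        ang = ff.helix_angles_deg()
        mid = ff.myocardial & (np.abs(ff.d - 0.5) < 0.05)
        assert mid.sum() > 100
        assert abs(np.nanmean(ang[mid])) < 2.0

    @pytest.mark.parametrize("alpha_endo,alpha_epi", [(60.0, -60.0), (40.0, -50.0)])
    def test_helix_slope_recovers_configured_angles(self, lv_annulus, alpha_endo, alpha_epi):
        """Helix angle regressed against the analytic transmural coordinate
        recovers slope (alpha_epi - alpha_endo) within 10%, R^2 > 0.95."""
        mesh, bc = lv_annulus
        cfg = FiberConfig(alpha_endo=alpha_endo, alpha_epi=alpha_epi)
        ff = assign_fibers(mesh, bc, cfg)
        myo = ff.myocardial
        cent = mesh.nodes[mesh.tets[myo]].mean(axis=1)
        r = np.hypot(cent[:, 0], cent[:, 1])
        d_analytic = (r - ANNULUS_R_IN) / (ANNULUS_R_OUT - ANNULUS_R_IN)
        ang = ff.helix_angles_deg()[myo]
        keep = (
            (d_analytic > 0.02) & (d_analytic < 0.98)
            & (cent[:, 2] > 3) & (cent[:, 2] < 17)
        )
        A = np.vstack([d_analytic[keep], np.ones(keep.sum())]).T
        coef, res, *_ = np.linalg.lstsq(A, ang[keep], rcond=None)
        slope_expected = alpha_epi - alpha_endo
        assert abs(coef[0] - slope_expected) <= 0.10 * abs(slope_expected)
        r2 = 1 - res[0] / ((ang[keep] - ang[keep].mean()) ** 2).sum()
        assert r2 > 0.95

    def test_fiber_continuity(self, lv_annulus):
        """Fiber directions of face-adjacent elements stay well aligned
        away from the rule's apex/base singularities."""
        from cardiomesh.fibers import _element_face_adjacency

        mesh, bc = lv_annulus
        ff = assign_fibers(mesh, bc)
        tets = mesh.tets[ff.myocardial]
        adj = _element_face_adjacency(tets)
        f = ff.f[ff.myocardial]
        dots = np.abs(np.einsum("ij,ij->i", f[adj[:, 0]], f[adj[:, 1]]))
        ang = np.degrees(np.arccos(np.clip(dots, -1, 1)))
        assert np.quantile(ang, 0.99) < 45.0
        assert (ang > 45).mean() < 0.01

    def test_non_myocardial_elements_flagged(self, small_phantom_mesh):
        from cardiomesh.surface_tagging import derive_bc_surfaces

        mesh = small_phantom_mesh
        bc = derive_bc_surfaces(mesh)
        ff = assign_fibers(mesh, bc)
        non_myo = ~ff.myocardial
        assert non_myo.any()
        assert not ff.f[non_myo].any()  # null triads outside the myocardium
        assert np.all(np.isin(mesh.element_tags[ff.myocardial], [1, 2]))


class TestHelixProfile:
    def test_constant_angle_rule_gives_flat_profile(self, lv_annulus):
        mesh, bc = lv_annulus
        ff = assign_fibers(mesh, bc, FiberConfig(alpha_endo=45.0, alpha_epi=45.0))
        prof = helix_angle_profile(mesh, ff, n_bins=6)
        valid = ~np.isnan(prof["mean_angle_deg"])
        assert np.allclose(prof["mean_angle_deg"][valid], 45.0, atol=2.0)

    def test_single_bin_equals_global_mean(self, lv_annulus):
        mesh, bc = lv_annulus
        ff = assign_fibers(mesh, bc)
        prof = helix_angle_profile(mesh, ff, n_bins=1)
        ang = ff.helix_angles_deg()
        assert np.isclose(prof["mean_angle_deg"][0], np.nanmean(ang))
        assert prof["count"][0] == int(ff.myocardial.sum())

    def test_default_rule_profile_monotone(self, lv_annulus):
        mesh, bc = lv_annulus
        ff = assign_fibers(mesh, bc)
        prof = helix_angle_profile(mesh, ff, n_bins=9)
        m = prof["mean_angle_deg"]
        assert np.all(np.diff(m[~np.isnan(m)]) < 0)  # endo +60 to epi -60
        assert m[0] > 40 and m[-1] < -40
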