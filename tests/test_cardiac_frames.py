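"""Local cardiac frames, implicit surface fitting, helix/transverse angles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srcdti.cardiac_frames import (
    LocalFrameField,
    angles_to_fiber,
    fit_lv_surface,
    frames_from_normals,
    helix_transverse_angles,
    local_frames,
    wall_depth,
)
from srcdti.tensor_fit import eigen_decompose, fit_tensor

from conftest import ellipsoid_contours


class TestFramesFromNormals:
    def test_cylinder_wall_frames(self):
        # points on an axis-aligned cylinder: er radial, ec tangent, el = z
        th = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        pts_normals = np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], axis=1)
        fr = frames_from_normals(pts_normals, np.array([0, 0, 1.0]))
        assert fr.valid.all()
        assert np.allclose(fr.er, pts_normals, atol=1e-12)
        assert np.allclose(fr.el, [0, 0, 1.0], atol=1e-12)
        tangent = np.stack([-np.sin(th), np.cos(th), np.zeros_like(th)], axis=1)
        assert np.allclose(fr.ec, tangent, atol=1e-12)

    def test_apex_normal_parallel_to_axis_flagged(self):
        fr = frames_from_normals(np.array([[0.0, 0.0, -1.0]]), np.array([0, 0, 1.0]))
        assert not fr.valid[0]

    def test_orthonormality_check_raises_on_bad_frames(self):
        fr = LocalFrameField(er=np.array([[1.0, 0, 0]]), ec=np.array([[1.0, 0, 0]]),
                             el=np.array([[0, 0, 1.0]]), valid=np.array([True]))
        with pytest.raises(ValueError, match="orthonormal"):
            fr.check_orthonormal()


class TestSurfaceFit:
    def test_ellipsoid_contours_recover_surface(self):
        surf = fit_lv_surface(ellipsoid_contours(), long_axis=np.array([0, 0, 1.0]))
        rng = np.random.default_rng(0)
        t = rng.uniform(-0.45 * np.pi, -0.02 * np.pi, 300)
        ph = rng.uniform(0, 2 * np.pi, 300)
        pts = np.stack([16 * np.cos(t) * np.cos(ph), 16 * np.cos(t) * np.sin(ph),
                        60 * np.sin(t)], axis=1)
        v = surf(pts)
        g = np.linalg.norm(surf.gradient(pts), axis=-1)
        rms = np.sqrt(np.mean((v / np.maximum(g, 1e-9)) ** 2))
        assert rms < 0.5

    def test_noisy_contours_still_within_millimetre(self):
        rng = np.random.default_rng(1)
        noisy = [c + rng.normal(0, 0.5, c.shape) for c in ellipsoid_contours()]
        surf = fit_lv_surface(noisy, long_axis=np.array([0, 0, 1.0]),
                              smoothing=100.0, rms_tol_mm=2.0)
        t = rng.uniform(-0.45 * np.pi, -0.02 * np.pi, 300)
        ph = rng.uniform(0, 2 * np.pi, 300)
        pts = np.stack([16 * np.cos(t) * np.cos(ph), 16 * np.cos(t) * np.sin(ph),
                        60 * np.sin(t)], axis=1)
        v = surf(pts)
        g = np.linalg.norm(surf.gradient(pts), axis=-1)
        assert np.sqrt(np.mean((v / np.maximum(g, 1e-9)) ** 2)) < 1.0

    def test_single_contour_insufficient(self):
        with pytest.raises(ValueError):
            fit_lv_surface([ellipsoid_contours()[0]])

    def test_coplanar_contours_rejected(self):
        ring = ellipsoid_contours()[0]
        with pytest.raises(ValueError, match="coplanar"):
            fit_lv_surface([ring, ring + [0.01, 0, 0], ring + [0, 0.01, 0]])

    def test_fitted_frames_match_analytic_away_from_apex(self):
        surf = fit_lv_surface(ellipsoid_contours(), long_axis=np.array([0, 0, 1.0]))
        rng = np.random.default_rng(2)
        t = rng.uniform(-0.4 * np.pi, -0.05 * np.pi, 300)
        ph = rng.uniform(0, 2 * np.pi, 300)
        pts = np.stack([16 * np.cos(t) * np.cos(ph), 16 * np.cos(t) * np.sin(ph),
                        60 * np.sin(t)], axis=1)
        fr = local_frames(surf, pts)
        n_true = np.stack([pts[:, 0] / 16**2, pts[:, 1] / 16**2,
                           pts[:, 2] / 60**2], axis=1)
        n_true /= np.linalg.norm(n_true, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(
            np.abs((fr.er * n_true).sum(1)), 0, 1)))
        assert ang[fr.valid].mean() < 2.0


class TestAngles:
    def test_circumferential_fiber_zero_angles(self):
        fr = frames_from_normals(np.array([[1.0, 0, 0]]), np.array([0, 0, 1.0]))
        angles = helix_transverse_angles(fr.ec, fr)
        assert angles.ha_deg[0] == pytest.approx(0.0, abs=1e-12)
        assert angles.ta_deg[0] == pytest.approx(0.0, abs=1e-12)

    def test_equal_components_give_45_degrees(self):
        fr = frames_from_normals(np.array([[1.0, 0, 0]]), np.array([0, 0, 1.0]))
        e1 = (fr.ec + fr.el) / np.sqrt(2)
        assert helix_transverse_angles(e1, fr).ha_deg[0] == pytest.approx(45.0)

    def test_radial_fiber_flagged(self):
        fr = frames_from_normals(np.array([[1.0, 0, 0]]), np.array([0, 0, 1.0]))
        angles = helix_transverse_angles(fr.er, fr)
        assert not angles.valid[0]

    @given(ha=st.floats(-89.0, 89.0), ta=st.floats(-89.0, 89.0),
           seed=st.integers(0, 100))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_angle_round_trip(self, ha, ta, seed):
        rng = np.random.default_rng(seed)
        n = rng.normal(size=3)
        L = rng.normal(size=3)
        fr = frames_from_normals(n[None], L)
        if not fr.valid[0]:
            return
        e1 = angles_to_fiber(np.array([ha]), np.array([ta]), fr)
        back = helix_transverse_angles(e1, fr)
        assert back.ha_deg[0] == pytest.approx(ha, abs=1e-6)
        assert back.ta_deg[0] == pytest.approx(ta, abs=1e-6)

    @given(ha=st.floats(-89.0, 89.0), ta=st.floats(-45.0, 45.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_ha_invariant_under_fiber_sign_flip(self, ha, ta):
        fr = frames_from_normals(np.array([[1.0, 0, 0]]), np.array([0, 0, 1.0]))
        e1 = angles_to_fiber(np.array([ha]), np.array([ta]), fr)
        a = helix_transverse_angles(e1, fr)
        b = helix_transverse_angles(-e1, fr)
        assert a.ha_deg[0] == pytest.approx(b.ha_deg[0], abs=1e-9)

    def test_phantom_round_trip_noiseless(self, lv_small, lv_small_fit):
        angles = lv_small_fit["angles"]
        ok = lv_small.mask & angles.valid & lv_small.frames.valid
        assert np.abs(angles.ha_deg[ok] - lv_small.ha[ok]).max() <= 1e-6
        assert np.abs(angles.ta_deg[ok] - lv_small.ta[ok]).max() <= 1e-6

    def test_phantom_ha_with_fitted_surface(self, lv_small, lv_small_fit):
        spec = lv_small.spec
        xc, yc, zc = spec.center
        contours = ellipsoid_contours(a=spec.r_min, c=spec.r_max,
                                      center=(xc, yc, zc))
        surf = fit_lv_surface(contours, long_axis=np.array([0, 0, 1.0]))
        world = np.argwhere(lv_small.mask).astype(float)
        keep = world[:, 2] > zc - 0.8 * spec.r_max  # away from the apex cap
        fr = local_frames(surf, world[keep])
        e1 = lv_small_fit["eigs"].e1[lv_small.mask][keep]
        angles = helix_transverse_angles(e1, fr)
        ok = fr.valid & angles.valid
        err = np.abs(angles.ha_deg[ok] - lv_small.ha[lv_small.mask][keep][ok])
        assert err.mean() < 3.0


class TestWallDepth:
    def test_midwall_point_near_half_depth(self):
        endo = fit_lv_surface(ellipsoid_contours(a=10, c=40),
                              long_axis=np.array([0, 0, 1.0]))
        epi = fit_lv_surface(ellipsoid_contours(a=14, c=44),
                             long_axis=np.array([0, 0, 1.0]))
        pts = np.array([[12.0, 0.0, -5.0], [0.0, 12.0, -10.0]])
        d = wall_depth(endo, epi, pts)
        assert np.all(np.abs(d - 0.5) < 0.12)
        inner = np.array([[10.1, 0.0, -5.0]])
        outer = np.array([[13.9, 0.0, -5.0]])
        assert wall_depth(endo, epi, inner)[0] < 0.15
        assert wall_depth(endo, epi, outer)[0] > 0.85
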