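"""Local cardiac coordinate frames and helix/transverse angle maps.

Myofiber orientation is reported relative to a local orthonormal frame
attached to the left-ventricular wall: ``er`` (radial, outward surface
normal), ``ec`` (circumferential) and ``el`` (longitudinal).  Given the
primary diffusion eigenvector e1, the helix angle (HA) is the angle of
e1's projection onto the wall tangent plane measured from ``ec`` toward
``el``, and the transverse angle (TA) is the elevation of e1 out of the
tangent plane toward ``er``.

Sign conventions (pinned so all tests are deterministic):

* ``el`` has a non-negative component along the apex-to-base long axis.
* ``ec = normalize(long_axis x er)``, so (er, ec, el) is right-handed.
* HA is positive when e1 tilts toward the base while running
  counter-clockwise viewed from the base (right-handed helix); a +84 deg
  endocardial fiber in the numerical phantom has positive HA.
* e1 is defined up to sign; it is flipped so its circumferential
  component is non-negative (ties broken by a positive longitudinal
  component), which maps HA into [-90, 90] deg and makes HA invariant
  under antipodal flips of e1.

The LV surface is represented implicitly: a smooth scalar field whose
zero level set is the surface, negative inside the cavity, fitted to
sparse planar contours with a thin-plate-spline radial basis
interpolant (off-surface constraint points are placed along approximate
outward directions, the classic variational-implicit-surface trick).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator

__all__ = [
    "LocalFrameField",
    "LvSurface",
    "AngleMaps",
    "frames_from_normals",
    "fit_lv_surface",
    "local_frames",
    "helix_transverse_angles",
    "angles_to_fiber",
    "wall_depth",
]

_DEGENERATE_TOL = 1e-6


@dataclass
class LocalFrameField:
    """Per-point orthonormal (radial, circumferential, longitudinal) axes.

    ``valid`` flags points where the triad is well defined (the surface
    normal is not parallel to the long axis and not degenerate).
    """

    er: np.ndarray
    ec: np.ndarray
    el: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        for name in ("er", "ec", "el"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape[-1] != 3:
                raise ValueError(f"{name} must have a trailing axis of 3")
            setattr(self, name, v)
        self.valid = np.asarray(self.valid, dtype=bool)

    def check_orthonormal(self, atol: float = 1e-8) -> None:
        """Raise if any valid triad is not orthonormal and right-handed."""
        er, ec, el, ok = self.er[self.valid], self.ec[self.valid], self.el[self.valid], True
        for v in (er, ec, el):
            ok &= bool(np.allclose(np.linalg.norm(v, axis=-1), 1.0, atol=atol))
        ok &= bool(np.allclose((er * ec).sum(-1), 0.0, atol=atol))
        ok &= bool(np.allclose((er * el).sum(-1), 0.0, atol=atol))
        ok &= bool(np.allclose(np.cross(er, ec), el, atol=1e-6))
        if not ok:
            raise ValueError("local frames are not an orthonormal right-handed triad")


@dataclass
class AngleMaps:
    ha_deg: np.ndarray
    ta_deg: np.ndarray
    valid: np.ndarray


def frames_from_normals(normals: np.ndarray, long_axis: np.ndarray) -> LocalFrameField:
    """Build (er, ec, el) from outward surface normals and the long axis.

    er is the normalized normal; ec = normalize(L x er); el = er x ec
    (the tangent-plane projection of L, hence non-negative along L).
    Points where the normal is (nearly) parallel to the long axis, or
    (nearly) zero, are flagged invalid and given identity placeholders.
    """
    n = np.asarray(normals, dtype=float)
    L = np.asarray(long_axis, dtype=float)
    L = L / np.linalg.norm(L)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    valid = norm[..., 0] > _DEGENERATE_TOL
    er = np.where(valid[..., None], n / np.where(norm > 0, norm, 1.0), 0.0)
    c = np.cross(np.broadcast_to(L, er.shape), er)
    cn = np.linalg.norm(c, axis=-1, keepdims=True)
    valid = valid & (cn[..., 0] > _DEGENERATE_TOL)
    ec = np.where(valid[..., None], c / np.where(cn > 0, cn, 1.0), 0.0)
    el = np.cross(er, ec)
    # identity placeholders on invalid points keep downstream algebra finite
    er = np.where(valid[..., None], er, [1.0, 0.0, 0.0])
    ec = np.where(valid[..., None], ec, [0.0, 1.0, 0.0])
    el = np.where(valid[..., None], el, [0.0, 0.0, 1.0])
    return LocalFrameField(er=er, ec=ec, el=el, valid=valid)


@dataclass
class LvSurface:
    """Implicit LV surface: f < 0 inside the cavity, f = 0 on the surface."""

    interpolator: object
    long_axis: np.ndarray
    apex: np.ndarray | None = None
    base: np.ndarray | None = None
    grad_step_mm: float = 0.25
    fit_rms_mm: float = field(default=np.nan)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        return np.asarray(self.interpolator(p)).reshape(np.asarray(points).shape[:-1])

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """Central-difference gradient of the implicit field (outward)."""
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        h = self.grad_step_mm
        g = np.empty_like(p)
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = h
            g[:, ax] = (self(p + dp) - self(p - dp)) / (2 * h)
        return g.reshape(np.asarray(points).shape)


def fit_lv_surface(
    contours: list[np.ndarray],
    long_axis: np.ndarray | None = None,
    offset_mm: float = 2.0,
    smoothing: float = 0.0,
    rms_tol_mm: float = 1.5,
    kernel: str = "cubic",
) -> LvSurface:
    """Fit a smooth implicit surface to sparse planar contours.

    Parameters
    ----------
    contours
        List of (Ni, 3) world-coordinate point arrays, one per segmented
        contour (already pose-corrected).  At least three non-coplanar
        contours are required.
    long_axis
        Apex-to-base unit vector; estimated as the principal axis of the
        pooled points if omitted.
    offset_mm
        Distance of the off-surface RBF constraint points.  Two fitting
        passes are made: the second re-derives the offset directions
        from the first fit's gradient, removing the bias of the crude
        initial directions.
    smoothing
        RBF smoothing parameter (0 interpolates the constraints).
    kernel
        RBF kernel; the cubic polyharmonic spline gives the most
        accurate normals on sparse cardiac-style contour sets.
    rms_tol_mm
        Raise if the fitted zero set misses the contour points by more
        than this RMS (normalized by the local gradient magnitude).
    """
    contours = [np.asarray(c, dtype=float).reshape(-1, 3) for c in contours]
    if len(contours) < 3:
        raise ValueError("at least three contours are required")
    pts = np.concatenate(contours, axis=0)
    # contours can share points (e.g. both long-axis contours pass
    # through the apex); exact duplicates make the system singular
    _, keep = np.unique(np.round(pts, 6), axis=0, return_index=True)
    pts = pts[np.sort(keep)]
    if pts.shape[0] < 9:
        raise ValueError("too few contour points")
    centered = pts - pts.mean(axis=0)
    # coplanarity check: the smallest principal spread must be non-negligible
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] < 1e-6 * svals[0]:
        raise ValueError("degenerate (coplanar) contour set")
    if long_axis is None:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        long_axis = vt[0]
    L = np.asarray(long_axis, dtype=float)
    L = L / np.linalg.norm(L)

    # reference point on the long-axis line, used to orient off-surface offsets
    c_ref = pts.mean(axis=0)
    d = pts - c_ref  # first pass: offsets point away from an interior reference
    dn = np.linalg.norm(d, axis=1, keepdims=True)
    d = d / np.where(dn > 0, dn, 1.0)

    # apex/base landmarks from the extremes of the long-axis coordinate
    t = (pts - c_ref) @ L
    apex = pts[np.argmin(t)]
    base = pts[np.argmax(t)]

    surf = None
    for _ in range(2):
        x = np.concatenate([pts, pts + offset_mm * d, pts - offset_mm * d])
        y = np.concatenate(
            [np.zeros(len(pts)), np.full(len(pts), offset_mm), np.full(len(pts), -offset_mm)]
        )
        interp = RBFInterpolator(x, y, kernel=kernel, smoothing=smoothing, degree=1)
        surf = LvSurface(interpolator=interp, long_axis=L, apex=apex, base=base)
        # second pass: re-fit with the fitted surface's own (outward) normals
        # as offset directions, removing the crude-direction gradient bias
        g = surf.gradient(pts)
        gn = np.linalg.norm(g, axis=1, keepdims=True)
        good = gn[:, 0] > 1e-9
        d = np.where(good[:, None], g / np.where(gn > 0, gn, 1.0), d)
    val = surf(pts)
    gnorm = np.linalg.norm(surf.gradient(pts), axis=-1)
    gnorm = np.where(gnorm > 1e-9, gnorm, 1.0)
    rms = float(np.sqrt(np.mean((val / gnorm) ** 2)))
    surf.fit_rms_mm = rms
    if rms > rms_tol_mm:
        raise ValueError(f"implicit surface fit RMS {rms:.2f} mm exceeds {rms_tol_mm} mm")
    return surf


def local_frames(surface: LvSurface, points: np.ndarray) -> LocalFrameField:
    """Evaluate (er, ec, el) at world points from the implicit surface gradient."""
    g = surface.gradient(points)
    return frames_from_normals(g, surface.long_axis)


def helix_transverse_angles(e1: np.ndarray, frames: LocalFrameField) -> AngleMaps:
    """Helix and transverse angle (degrees) of a unit fiber direction field.

    HA = atan2(e1.el, e1.ec) after the hemisphere flip, in [-90, 90];
    TA = atan2(e1.er, |projection onto the (ec, el) plane|), in [-90, 90].
    Points where e1 is parallel to er (HA undefined) or where the frame
    itself is invalid are flagged.
    """
    e1 = np.asarray(e1, dtype=float)
    c = (e1 * frames.ec).sum(-1)
    l = (e1 * frames.el).sum(-1)
    r = (e1 * frames.er).sum(-1)
    flip = (c < 0) | ((c == 0) & (l < 0))
    sgn = np.where(flip, -1.0, 1.0)
    c, l, r = c * sgn, l * sgn, r * sgn
    inplane = np.hypot(c, l)
    valid = frames.valid & (inplane > _DEGENERATE_TOL)
    ha = np.degrees(np.arctan2(l, c))
    ta = np.degrees(np.arctan2(r, inplane))
    return AngleMaps(ha_deg=ha, ta_deg=ta, valid=valid)


def angles_to_fiber(ha_deg: np.ndarray, ta_deg: np.ndarray, frames: LocalFrameField) -> np.ndarray:
    """Unit fiber direction from helix/transverse angles (inverse of the above)."""
    ha = np.radians(np.asarray(ha_deg, dtype=float))
    ta = np.radians(np.asarray(ta_deg, dtype=float))
    e1 = (
        np.cos(ta)[..., None]
        * (np.cos(ha)[..., None] * frames.ec + np.sin(ha)[..., None] * frames.el)
        + np.sin(ta)[..., None] * frames.er
    )
    return e1


def wall_depth(endo: LvSurface, epi: LvSurface, points: np.ndarray) -> np.ndarray:
    """Normalized transmural depth in [0, 1]: 0 at endocardium, 1 at epicardium.

    Uses gradient-normalized implicit values as signed-distance
    surrogates; linear interpolation between the two boundaries.
    """
    p = np.asarray(points, dtype=float)

    def signed_dist(surf: LvSurface) -> np.ndarray:
        v = surf(p)
        g = np.linalg.norm(surf.gradient(p), axis=-1)
        return v / np.where(g > 1e-9, g, 1.0)

    d_endo = signed_dist(endo)   # >= 0 in the wall
    d_epi = signed_dist(epi)     # <= 0 in the wall
    denom = d_endo - d_epi
    denom = np.where(np.abs(denom) > 1e-9, denom, 1.0)
    return np.clip(d_endo / denom, 0.0, 1.0)
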