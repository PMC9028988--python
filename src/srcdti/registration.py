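"""Slice-to-stack rigid motion correction by intersection-profile consistency.

Each 2D slice acquired in its own breath-hold may be displaced by a
small rigid motion.  Because every slice of one stack intersects slices
of the other stacks along lines, the intensity profiles sampled along
those intersection lines must agree when all slices are correctly
positioned.  Motion is therefore corrected by maximizing, per floating
slice, the sum of Pearson correlation coefficients between its line
profiles and those of every intersecting target slice, over a bounded
6-parameter rigid transform (rotations < 5 deg, translations < 8 mm).
Slices are optimized sequentially (Gauss-Seidel: each corrected slice
immediately informs the next) and the whole dataset is swept a fixed
number of outer iterations.

Conventions: rotations are intrinsic Z-Y-X Euler angles about the
slice's field-of-view center (decoupling rotation from translation);
translations are world mm.  Profiles from all DWI channels of a slice
pair are standardized per channel and concatenated, giving a single
correlation per (floating, target) pair; degenerate pairs (too few
samples, or zero variance) are skipped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .forward_model import SliceStack, rigid_matrix

__all__ = [
    "RigidTransform",
    "RegistrationSettings",
    "intersection_line",
    "profile_similarity",
    "register_slice",
    "register_all",
    "pose_error",
]

logger = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    """6-parameter rigid transform: (rx, ry, rz) deg intrinsic Z-Y-X about
    ``center``, then (tx, ty, tz) mm in world coordinates."""

    params: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float).reshape(6)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def matrix(self) -> np.ndarray:
        return rigid_matrix(self.params, self.center)


@dataclass
class RegistrationSettings:
    rot_bound_deg: float = 5.0
    trans_bound_mm: float = 8.0
    sample_spacing_mm: float | None = None  # default: floating in-plane spacing
    min_samples: int = 8
    n_outer: int = 5
    multistart_threshold: float = 1e-3
    maxiter: int = 40
    # per-term similarity gain required before the rotational degrees of
    # freedom of a slice correction are accepted (see register_slice)
    rotation_acceptance_ds: float = 0.01
    # channels whose profile SD falls below this fraction of the stack's
    # intensity scale carry no anatomy (background noise / ringing only)
    # and are excluded from the correlation
    signal_sd_frac: float = 0.05
    # taps used to average each profile over the other slice's slab
    # thickness before correlating (1 = treat slices as thin planes);
    # symmetric slab averaging makes both profiles carry the same double
    # blur at the true pose
    slab_taps: int = 4
    # optional parallel line offsets (mm, within the floating plane,
    # perpendicular to the intersection line); for orthogonal stacks the
    # offset direction degenerates with the target normal, so the
    # default is the single intersection line
    band_offsets_mm: tuple[float, ...] = (0.0,)


class _SlicePlane:
    """Geometry + image of one slice for profile sampling (inverse cached).

    ``thickness`` is the physical slab thickness the image integrates
    over along its normal; profile sampling accounts for it.
    """

    __slots__ = ("data", "affine", "inv", "scale", "thickness")

    def __init__(self, data: np.ndarray, affine: np.ndarray,
                 scale: float | None = None, thickness: float | None = None):
        self.data = data
        self.affine = affine
        self.inv = np.linalg.inv(affine)
        self.scale = float(np.abs(data).max()) if scale is None else scale
        self.thickness = (float(np.linalg.norm(affine[:3, 2]))
                          if thickness is None else thickness)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3]

    @property
    def normal(self) -> np.ndarray:
        n = self.affine[:3, 2]
        return n / np.linalg.norm(n)

    @property
    def center(self) -> np.ndarray:
        nx, ny = self.data.shape[:2]
        return self.affine[:3, :2] @ np.array([(nx - 1) / 2.0, (ny - 1) / 2.0]) + self.origin


def _slice_plane(stack: SliceStack, k: int) -> _SlicePlane:
    data = stack.data[:, :, k]
    if data.ndim == 2:
        data = data[..., None]
    # intensity scale of the whole stack, not the single slice
    return _SlicePlane(data, stack.slice_affine(k),
                       scale=float(np.abs(stack.data).max()),
                       thickness=stack.thickness_mm)


def intersection_line(
    plane_a: _SlicePlane,
    plane_b: _SlicePlane,
    omega_box: np.ndarray | None,
    spacing_mm: float,
    parallel_tol: float = 1e-6,
):
    """World-space sample points along the intersection of two slice planes.

    Returns an (P, 3) array of points clipped to both slices' in-plane
    fields of view and to the world bounding box of Omega, or ``None``
    when the planes are parallel or the clipped segment is empty.
    """
    n1, n2 = plane_a.normal, plane_b.normal
    d = np.cross(n1, n2)
    dn = np.linalg.norm(d)
    if dn < parallel_tol:
        return None
    d = d / dn
    # least-norm point satisfying both plane equations (closed form)
    c1 = n1 @ plane_a.origin
    c2 = n2 @ plane_b.origin
    dot = n1 @ n2
    denom = 1.0 - dot * dot
    p0 = ((c1 - c2 * dot) * n1 + (c2 - c1 * dot) * n2) / denom

    t_lo, t_hi = -np.inf, np.inf

    def clip_interval(lo, hi, a_coef, b_coef, vmin, vmax):
        # vmin <= a + b t <= vmax
        if abs(b_coef) < 1e-12:
            if a_coef < vmin or a_coef > vmax:
                return 1.0, -1.0  # empty
            return lo, hi
        t1, t2 = (vmin - a_coef) / b_coef, (vmax - a_coef) / b_coef
        if t1 > t2:
            t1, t2 = t2, t1
        return max(lo, t1), min(hi, t2)

    for plane in (plane_a, plane_b):
        inv = plane.inv
        a_vox = inv[:3, :3] @ p0 + inv[:3, 3]
        b_vox = inv[:3, :3] @ d
        nx, ny = plane.data.shape[:2]
        t_lo, t_hi = clip_interval(t_lo, t_hi, a_vox[0], b_vox[0], 0.0, nx - 1.0)
        t_lo, t_hi = clip_interval(t_lo, t_hi, a_vox[1], b_vox[1], 0.0, ny - 1.0)
    if omega_box is not None:
        for ax in range(3):
            t_lo, t_hi = clip_interval(t_lo, t_hi, p0[ax], d[ax], omega_box[0, ax], omega_box[1, ax])
    if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi <= t_lo:
        return None
    n_samples = int(np.floor((t_hi - t_lo) / spacing_mm)) + 1
    if n_samples < 2:
        return None
    ts = t_lo + (np.arange(n_samples) + 0.5) * (t_hi - t_lo) / n_samples
    return p0[None, :] + ts[:, None] * d[None, :]


def _slab_band_profile(
    plane: _SlicePlane,
    band_pts: np.ndarray,
    other_normal: np.ndarray,
    other_thickness: float,
    n_taps: int,
) -> np.ndarray:
    """Profile of ``plane`` at band points, slab-averaged along the other normal.

    ``band_pts`` has shape (B, P, 3) — B parallel lines of P samples.
    Each pixel of the *other* slice integrates ``other_thickness`` mm of
    tissue along its normal, so this plane's image is sampled at
    ``n_taps`` offsets across that slab and averaged, in one gather.
    Returns (C, B * P).
    """
    b, p = band_pts.shape[:2]
    if n_taps <= 1 or other_thickness <= 0:
        prof = _bilinear_profile(plane, band_pts.reshape(-1, 3))
        return prof.reshape(-1, b * p)
    offs = (np.arange(n_taps) - (n_taps - 1) / 2.0) * (other_thickness / n_taps)
    pts = band_pts[None] + offs[:, None, None, None] * other_normal  # (T, B, P, 3)
    prof = _bilinear_profile(plane, pts.reshape(-1, 3))  # (C, T*B*P)
    return prof.reshape(-1, n_taps, b * p).mean(axis=1)


def _bilinear_profile(plane: _SlicePlane, world_pts: np.ndarray) -> np.ndarray:
    """Sample all channels of a slice image at world points, shape (C, P)."""
    inv = plane.inv
    vox = world_pts @ inv[:3, :3].T + inv[:3, 3]
    u, v = vox[:, 0], vox[:, 1]
    nx, ny = plane.data.shape[:2]
    u = np.clip(u, 0.0, nx - 1.0)
    v = np.clip(v, 0.0, ny - 1.0)
    u0 = np.clip(np.floor(u).astype(int), 0, nx - 2) if nx > 1 else np.zeros(len(u), int)
    v0 = np.clip(np.floor(v).astype(int), 0, ny - 2) if ny > 1 else np.zeros(len(v), int)
    fu = u - u0
    fv = v - v0
    img = plane.data  # (nx, ny, C)
    p00 = img[u0, v0]
    p10 = img[np.minimum(u0 + 1, nx - 1), v0]
    p01 = img[u0, np.minimum(v0 + 1, ny - 1)]
    p11 = img[np.minimum(u0 + 1, nx - 1), np.minimum(v0 + 1, ny - 1)]
    out = (
        p00 * ((1 - fu) * (1 - fv))[:, None]
        + p10 * (fu * (1 - fv))[:, None]
        + p01 * ((1 - fu) * fv)[:, None]
        + p11 * (fu * fv)[:, None]
    )
    return out.T  # (C, P)


def _pair_correlation(
    prof_f: np.ndarray, prof_t: np.ndarray, sd_floor: float = 0.0
) -> float | None:
    """Pearson r of per-channel standardized, concatenated profiles.

    Channels whose profile SD on either side falls below ``sd_floor``
    are skipped: constant profiles make the correlation undefined, and
    near-constant ones (background noise or truncation ringing, no
    anatomy crossing the line) would contribute meaningless terms.
    """
    segs_f, segs_t = [], []
    floor = max(sd_floor, 1e-12)
    for c in range(prof_f.shape[0]):
        a, b = prof_f[c], prof_t[c]
        sa, sb = a.std(), b.std()
        if sa < floor or sb < floor:
            continue
        segs_f.append((a - a.mean()) / sa)
        segs_t.append((b - b.mean()) / sb)
    if not segs_f:
        return None
    x = np.concatenate(segs_f)
    y = np.concatenate(segs_t)
    sx, sy = x.std(), y.std()
    if sx < 1e-12 or sy < 1e-12:
        return None
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def profile_similarity(
    mu: np.ndarray,
    floating: _SlicePlane,
    targets: list[_SlicePlane],
    omega_box: np.ndarray | None,
    settings: RegistrationSettings,
    center: np.ndarray | None = None,
    active_targets: list[int] | None = None,
) -> float:
    """Similarity S(mu): sum of intersection-profile correlations.

    ``mu`` moves the floating slice; each term is the Pearson
    correlation (in [-1, 1]) between the paired line profiles of the
    moved floating slice and one target slice.  Raises ``ValueError``
    when every intersection is degenerate (unregisterable slice).

    When ``active_targets`` is given, the term set is fixed to those
    target indices regardless of the trial pose (a pair that becomes
    degenerate under the pose contributes 0); during optimization this
    prevents the objective from growing simply by acquiring additional
    valid intersections.
    """
    if center is None:
        center = floating.center
    m = rigid_matrix(np.asarray(mu, dtype=float), center)
    moved = _SlicePlane(floating.data, m @ floating.affine, scale=floating.scale)
    spacing = settings.sample_spacing_mm
    if spacing is None:
        spacing = float(np.linalg.norm(moved.affine[:3, 0]))
    bands = np.asarray(settings.band_offsets_mm, dtype=float)
    n_moved = moved.normal
    fixed_set = active_targets is not None
    indices = active_targets if fixed_set else range(len(targets))
    total = 0.0
    n_terms = 0
    for ti in indices:
        tgt = targets[ti]
        pts = intersection_line(moved, tgt, omega_box, spacing)
        if pts is None or len(pts) < settings.min_samples:
            if fixed_set:
                n_terms += 1  # pair lost under this pose: contributes 0
            continue
        # band direction: in the floating plane, perpendicular to the line
        d_line = pts[-1] - pts[0]
        u = np.cross(n_moved, d_line)
        un = np.linalg.norm(u)
        u = u / un if un > 0 else np.zeros(3)
        band_pts = pts[None] + bands[:, None, None] * u  # (B, P, 3)
        sd_floor = settings.signal_sd_frac * max(moved.scale, tgt.scale)
        prof_f = _slab_band_profile(moved, band_pts, tgt.normal, tgt.thickness,
                                    settings.slab_taps)
        prof_t = _slab_band_profile(tgt, band_pts, n_moved, moved.thickness,
                                    settings.slab_taps)
        r = _pair_correlation(prof_f, prof_t, sd_floor)
        if r is None:
            if fixed_set:
                n_terms += 1
            continue
        total += r
        n_terms += 1
    if n_terms == 0:
        raise ValueError("all intersections degenerate: slice cannot be registered")
    return total


def register_slice(
    stack: SliceStack,
    k: int,
    target_stacks: list[SliceStack],
    omega_box: np.ndarray | None,
    settings: RegistrationSettings | None = None,
    bounds: list[tuple[float, float]] | None = None,
) -> RigidTransform:
    """Bounded maximization of S for slice ``k`` of ``stack`` from the identity.

    Uses a bounded quasi-Newton search (L-BFGS-B with finite-difference
    gradients on the linearly interpolated objective); gradient-sized
    steps leave near-unidentifiable directions (out-of-plane rotations
    of a slab, in-plane rotation of near-rotationally-symmetric
    anatomy) close to the identity instead of wandering to the bounds.
    When the improvement over the identity similarity stalls and the
    similarity is poor in absolute terms, additional bounded starts at
    half-bound translations are tried to escape symmetric local maxima.
    On optimizer failure the identity is returned with a logged warning.
    """
    if settings is None:
        settings = RegistrationSettings()
    floating = _slice_plane(stack, k)
    targets = [_slice_plane(ts, i) for ts in target_stacks for i in range(ts.n_slices)]
    center = floating.center
    rb, tb = settings.rot_bound_deg, settings.trans_bound_mm
    if bounds is None:
        bounds = [(-rb, rb)] * 3 + [(-tb, tb)] * 3

    # the term set is fixed at the identity pose: pairs with a usable,
    # signal-bearing intersection before correction
    spacing = settings.sample_spacing_mm or float(np.linalg.norm(floating.affine[:3, 0]))
    active: list[int] = []
    for ti, tgt in enumerate(targets):
        pts = intersection_line(floating, tgt, omega_box, spacing)
        if pts is None or len(pts) < settings.min_samples:
            continue
        band_pts = pts[None]
        sd_floor = settings.signal_sd_frac * max(floating.scale, tgt.scale)
        prof_f = _slab_band_profile(floating, band_pts, tgt.normal, tgt.thickness,
                                    settings.slab_taps)
        prof_t = _slab_band_profile(tgt, band_pts, floating.normal, floating.thickness,
                                    settings.slab_taps)
        if _pair_correlation(prof_f, prof_t, sd_floor) is not None:
            active.append(ti)
    if not active:
        logger.warning("slice %d: no non-degenerate intersections; skipped", k)
        return RigidTransform(params=np.zeros(6), center=center)

    def neg_s(mu):
        try:
            return -profile_similarity(mu, floating, targets, omega_box, settings,
                                       center, active_targets=active)
        except ValueError:
            return 0.0  # no usable intersections under this pose

    s_id = profile_similarity(np.zeros(6), floating, targets, omega_box,
                              settings, center, active_targets=active)

    opts = {"maxiter": settings.maxiter, "eps": 0.05, "ftol": 1e-10, "gtol": 1e-7}
    trans_bounds = [(0.0, 0.0)] * 3 + bounds[3:]
    # stage 1: translations (well identified by the profile peaks)
    best = minimize(neg_s, np.zeros(6), method="L-BFGS-B", bounds=trans_bounds,
                    options=opts)
    # local-minimum fallback: only worthwhile when the search stalled AND the
    # achieved similarity is materially below its per-term maximum of 1
    stalled = (-best.fun) - s_id < settings.multistart_threshold
    poor = -best.fun < 0.45 * len(active)
    if stalled and poor:
        half = min(tb / 2.0, min(b[1] for b in bounds[3:]))
        for ax in range(3):
            for sgn in (+1.0, -1.0):
                x0 = np.zeros(6)
                x0[3 + ax] = np.clip(sgn * half, bounds[3 + ax][0], bounds[3 + ax][1])
                r2 = minimize(neg_s, x0, method="L-BFGS-B", bounds=trans_bounds,
                              options=opts)
                if r2.fun < best.fun:
                    best = r2
    # stage 2: full 6-DOF refinement.  Out-of-plane rotation of a thick
    # slab is near-unidentifiable from intersection profiles (a 1 deg
    # tilt moves the sampled content by a fraction of a voxel), so the
    # extra degrees of freedom are accepted only when they raise the
    # similarity above the interpolation-noise floor; otherwise they
    # would drift toward the search bounds along flat directions.
    full = minimize(neg_s, best.x, method="L-BFGS-B", bounds=bounds, options=opts)
    if np.isfinite(full.fun) and (
        best.fun - full.fun > settings.rotation_acceptance_ds * len(active)
    ):
        best = full
    if not np.isfinite(best.fun):
        logger.warning("slice %d: optimizer failure; identity returned", k)
        return RigidTransform(params=np.zeros(6), center=center)
    params = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    return RigidTransform(params=params, center=center)


def register_all(
    stacks: list[SliceStack],
    omega_box: np.ndarray | None,
    settings: RegistrationSettings | None = None,
) -> dict:
    """Sequential (Gauss-Seidel) registration of every slice, repeated sweeps.

    Stacks are processed in order, slices base-to-apex within each
    stack; each optimized correction is composed into the slice's pose
    immediately so later slices see the updated geometry.  Returns the
    per-slice cumulative pose matrices, the per-sweep total-similarity
    trajectory, and the per-sweep maximum parameter change (monitoring
    stabilization of the outer loop).
    """
    if len(stacks) < 2:
        raise ValueError("at least two stacks are required")
    if settings is None:
        settings = RegistrationSettings()
    for st in stacks:
        if st.slice_poses is None:
            st.slice_poses = np.broadcast_to(np.eye(4), (st.n_slices, 4, 4)).copy()
    s_trajectory = []
    max_changes = []
    corrections = [np.zeros((st.n_slices, 6)) for st in stacks]
    for sweep in range(settings.n_outer):
        sweep_max = 0.0
        total_s = 0.0
        for n, st in enumerate(stacks):
            others = [s for m, s in enumerate(stacks) if m != n]
            for k in range(st.n_slices):
                # the cumulative correction of a slice must stay within the
                # search limits, so later sweeps only get the leftover budget
                cum = corrections[n][k]
                caps = [settings.rot_bound_deg] * 3 + [settings.trans_bound_mm] * 3
                slice_bounds = [
                    (max(-c - q, -c), min(c - q, c))
                    for c, q in zip(caps, cum)
                ]
                slice_bounds = [(min(lo, 0.0), max(hi, 0.0)) for lo, hi in slice_bounds]
                tr = register_slice(st, k, others, omega_box, settings,
                                    bounds=slice_bounds)
                st.slice_poses[k] = tr.matrix @ st.slice_poses[k]
                corrections[n][k] += tr.params
                sweep_max = max(sweep_max, np.abs(tr.params).max())
                try:
                    total_s += profile_similarity(
                        np.zeros(6), _slice_plane(st, k),
                        [_slice_plane(ts, i) for ts in others for i in range(ts.n_slices)],
                        omega_box, settings,
                    )
                except ValueError:
                    pass
        s_trajectory.append(total_s)
        max_changes.append(sweep_max)
        logger.info("sweep %d: total S = %.4f, max parameter change = %.4f",
                    sweep + 1, total_s, sweep_max)
    return {
        "poses": [st.slice_poses for st in stacks],
        "cumulative_params": corrections,
        "similarity_trajectory": s_trajectory,
        "max_param_change": max_changes,
    }


def pose_error(
    recovered: np.ndarray, planted: np.ndarray, point: np.ndarray | None = None
) -> tuple[float, float]:
    """Residual (rotation deg, translation mm) of recovered @ planted vs identity.

    The translation residual is measured as the displacement of
    ``point`` (e.g. the slice center) so it is not inflated by the
    lever arm of a small residual rotation about a distant origin.
    """
    m = np.asarray(recovered) @ np.asarray(planted)
    r = m[:3, :3]
    angle = np.degrees(np.arccos(np.clip((np.trace(r) - 1) / 2.0, -1.0, 1.0)))
    p = np.zeros(3) if point is None else np.asarray(point, dtype=float)
    trans = float(np.linalg.norm(r @ p + m[:3, 3] - p))
    return float(angle), trans
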