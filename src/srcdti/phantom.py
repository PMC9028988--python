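"""Synthetic cardiac DTI phantoms and their degradation into thick-slice stacks.

Two ground-truth objects are provided:

* a semi-ellipsoid left-ventricle phantom whose wall is the union of
  confocal-offset ellipsoid shells indexed by the distance to the
  endocardium ``dr``, with a linear transmural helix-angle ramp
  (+84 deg at the endocardial border to -84 deg at the epicardial
  border) and a zero transverse angle;
* a helicoidal fiber-bundle phantom (annulus around the z axis) whose
  helix angle varies linearly with the distance to the axis, emulating a
  physical phantom of artificial fibers wound on a helicoidal holder and
  immersed in water.

Degradation emulates a thick-slice 2D multi-slice acquisition: in-plane
resolution is reduced by cropping the 2D k-space of every slice, slice
selection is an ideal rectangular profile averaging consecutive planes,
and Rician noise is added at a target SNR.
"""
from __future__ import annotations

import numpy as np

from .cardiac_frames import LocalFrameField, angles_to_fiber, frames_from_normals
from .tensor_fit import DiffusionProtocol, DwiSeries, TensorField

from dataclasses import dataclass, field

__all__ = [
    "LvPhantomSpec",
    "HelixPhantomSpec",
    "DegradationSpec",
    "DistanceField",
    "make_lv_mask",
    "lv_fields_at_points",
    "assign_angles",
    "lv_local_frames",
    "build_tensor_field",
    "synthesize_dwi",
    "degrade_inplane",
    "slice_select",
    "add_rician_noise",
    "rician_sigma",
    "make_helix_phantom",
    "helix_local_frames",
    "helix_roi_mask",
]


@dataclass
class LvPhantomSpec:
    """Geometry, fiber architecture and diffusion parameters of the LV phantom.

    All lengths are in voxels of the isotropic generation grid
    (``voxel_size_mm`` each).  ``r_min``/``r_max`` are the semi-minor
    (x, y) and semi-major (z) radii of the endocardial ellipsoid; the
    wall is the shell family ``dr`` in ``[0, dr_max]``.  ``center``
    defaults to the in-plane grid center with the z center placed so the
    apex-down half ellipsoid fits the grid symmetrically.
    """

    grid_shape: tuple[int, int, int] = (160, 160, 128)
    voxel_size_mm: float = 1.0
    center: tuple[float, float, float] | None = None
    r_min: float = 16.0
    r_max: float = 60.0
    dr_max: float = 14.0
    ha_endo_deg: float = 84.0
    ha_epi_deg: float = -84.0
    ta_deg: float = 0.0
    eigenvalues_mm2_s: tuple[float, float, float] = (2.0e-3, 1.5e-3, 1.0e-3)
    b_value_s_mm2: float = 350.0
    s0: float = 1.0

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be smaller than r_max")
        if self.dr_max < 0:
            raise ValueError("dr_max must be non-negative")
        l1, l2, l3 = self.eigenvalues_mm2_s
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if abs(self.ha_endo_deg) > 90 or abs(self.ha_epi_deg) > 90:
            raise ValueError("|HA| endpoints must not exceed 90 degrees")
        if self.center is None:
            nx, ny, nz = self.grid_shape
            zc = (nz - 1 + self.r_max + self.dr_max) / 2.0
            self.center = ((nx - 1) / 2.0, (ny - 1) / 2.0, zc)
        self._check_fits()

    def _check_fits(self) -> None:
        nx, ny, nz = self.grid_shape
        xc, yc, zc = self.center
        r_out = self.r_min + self.dr_max
        z_out = self.r_max + self.dr_max
        if xc - r_out < -0.5 or xc + r_out > nx - 0.5:
            raise ValueError(f"ellipsoid shell exits the grid along x (extent {2 * r_out:.1f})")
        if yc - r_out < -0.5 or yc + r_out > ny - 0.5:
            raise ValueError(f"ellipsoid shell exits the grid along y (extent {2 * r_out:.1f})")
        if zc - z_out < -0.5 or zc > nz - 0.5:
            raise ValueError(f"ellipsoid shell exits the grid along z (extent {z_out:.1f})")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] *= self.voxel_size_mm
        return a


@dataclass
class HelixPhantomSpec:
    """Helicoidal fiber-bundle phantom on an annulus around the z axis.

    The helix angle ramps linearly with the distance ``r`` to the z axis
    between the two stated endpoints; the midpoint of the ramp is the
    nominal ground-truth mean angle.  The bundle is immersed in a water
    compartment with isotropic diffusion.
    """

    inner_radius_mm: float = 19.08
    outer_radius_mm: float = 27.12
    ha_at_inner_deg: float = 34.57
    ha_at_outer_deg: float = 49.57
    height_mm: float = 40.0
    eigenvalues_mm2_s: tuple[float, float, float] = (2.0e-3, 1.5e-3, 1.0e-3)
    b_values_s_mm2: tuple[float, ...] = (0.0, 500.0)
    s0: float = 1.0
    water_diffusivity_mm2_s: float = 2.0e-3

    def __post_init__(self) -> None:
        if not self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError("inner radius must be smaller than outer radius")

    @property
    def mean_ha_deg(self) -> float:
        return 0.5 * (self.ha_at_inner_deg + self.ha_at_outer_deg)

    @property
    def mid_radius_mm(self) -> float:
        return 0.5 * (self.inner_radius_mm + self.outer_radius_mm)


@dataclass
class DistanceField:
    """Continuous distance to the endocardium on the LV mask.

    ``values`` holds the per-voxel shell parameter ``dr`` (voxels;
    meaningful only on the mask); ``wall_fraction`` is ``dr``
    normalized to [0, 1] (0 = endocardial border, 1 = epicardial).
    """

    values: np.ndarray
    wall_fraction: np.ndarray
    mask: np.ndarray


@dataclass
class DegradationSpec:
    """Parameters of the low-resolution acquisition emulation."""

    inplane_crop_factor: int = 2
    slice_thickness_vox: int = 8
    slice_profile: str = "rect"
    stack_orientations: tuple[str, ...] = ("xy", "yz", "xz")
    snr_lr: float | None = 40.0
    snr_ratio_lr_hr: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.inplane_crop_factor < 1:
            raise ValueError("crop factor must be >= 1")
        if self.slice_profile not in ("rect",):
            raise ValueError(f"unknown slice profile {self.slice_profile!r}")

    @property
    def snr_hr(self) -> float | None:
        if self.snr_lr is None:
            return None
        return self.snr_lr / self.snr_ratio_lr_hr


# ---------------------------------------------------------------------------
# semi-ellipsoid LV phantom
# ---------------------------------------------------------------------------

def _shell_residual(spec: LvPhantomSpec, dx, dy, dz, dr):
    """LHS - 1 of the shell equation at offset (dx, dy, dz) for shell dr."""
    a = spec.r_min + dr
    c = spec.r_max + dr
    return (dx / a) ** 2 + (dy / a) ** 2 + (dz / c) ** 2 - 1.0


def _solve_dr(spec: LvPhantomSpec, dx, dy, dz, iters: int = 60):
    """Continuous shell parameter by bisection (residual decreases in dr)."""
    lo = np.zeros_like(dx, dtype=float)
    hi = np.full_like(lo, float(spec.dr_max))
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        f = _shell_residual(spec, dx, dy, dz, mid)
        lo = np.where(f > 0, mid, lo)
        hi = np.where(f > 0, hi, mid)
    return 0.5 * (lo + hi)


def make_lv_mask(spec: LvPhantomSpec) -> tuple[np.ndarray, DistanceField]:
    """Binary semi-ellipsoid wall mask and the continuous ``dr`` field.

    A voxel belongs to the wall when it lies between the endocardial
    (dr = 0) and epicardial (dr = dr_max) shells and on the apex half of
    the ellipsoid (z <= zc; the object is truncated at the equator,
    which the generation places as the base).  ``dr`` is solved per
    voxel from the shell equation, keeping the wall fraction continuous
    so the transmural helix-angle ramp is not stair-cased.
    """
    nx, ny, nz = spec.grid_shape
    xc, yc, zc = spec.center
    x, y, z = np.meshgrid(
        np.arange(nx, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nz, dtype=float),
        indexing="ij",
    )
    dx, dy, dz = x - xc, y - yc, z - zc
    inside_outer = _shell_residual(spec, dx, dy, dz, spec.dr_max) <= 0
    outside_inner = _shell_residual(spec, dx, dy, dz, 0.0) >= 0
    mask = inside_outer & outside_inner & (z <= zc)

    dr = np.zeros(spec.grid_shape, dtype=float)
    dr[mask] = _solve_dr(spec, dx[mask], dy[mask], dz[mask])
    wall_fraction = np.zeros_like(dr)
    if spec.dr_max > 0:
        wall_fraction[mask] = dr[mask] / spec.dr_max
    return mask, DistanceField(values=dr, wall_fraction=wall_fraction, mask=mask)


def lv_fields_at_points(spec: LvPhantomSpec, points_vox: np.ndarray):
    """Mask, wall fraction and analytic frames at arbitrary voxel-space points.

    Used to evaluate the ground truth on grids other than the generation
    grid (e.g. the reconstruction grid).  Returns ``(mask, wall_fraction,
    frames)`` with shapes following ``points_vox[..., 3]``.
    """
    p = np.asarray(points_vox, dtype=float)
    dx = p[..., 0] - spec.center[0]
    dy = p[..., 1] - spec.center[1]
    dz = p[..., 2] - spec.center[2]
    mask = (
        (_shell_residual(spec, dx, dy, dz, spec.dr_max) <= 0)
        & (_shell_residual(spec, dx, dy, dz, 0.0) >= 0)
        & (dz <= 0)
    )
    dr = np.zeros(mask.shape, dtype=float)
    dr[mask] = _solve_dr(spec, dx[mask], dy[mask], dz[mask])
    wall_fraction = dr / spec.dr_max if spec.dr_max > 0 else dr
    frames = _lv_frames(spec, dx, dy, dz, dr)
    return mask, wall_fraction, frames


def _lv_frames(spec: LvPhantomSpec, dx, dy, dz, dr) -> LocalFrameField:
    a = spec.r_min + dr
    c = spec.r_max + dr
    normals = np.stack([dx / a**2, dy / a**2, dz / c**2], axis=-1)
    return frames_from_normals(normals, np.array([0.0, 0.0, 1.0]))


def lv_local_frames(spec: LvPhantomSpec, mask: np.ndarray, dr: DistanceField) -> LocalFrameField:
    """Analytic local cardiac frames on the generation grid.

    The outward normal of the shell through each voxel is exact
    (gradient of the shell equation), so the ground-truth frames carry
    no surface-fitting error.  The long axis is +z (apex at low z).
    """
    nx, ny, nz = spec.grid_shape
    xc, yc, zc = spec.center
    x, y, z = np.meshgrid(
        np.arange(nx, dtype=float), np.arange(ny, dtype=float), np.arange(nz, dtype=float),
        indexing="ij",
    )
    return _lv_frames(spec, x - xc, y - yc, z - zc, dr.values)


def assign_angles(mask: np.ndarray, dr: DistanceField, spec: LvPhantomSpec):
    """Transmural HA ramp and constant TA on the wall mask (degrees)."""
    if mask.shape != dr.wall_fraction.shape:
        raise ValueError("mask and distance field shapes disagree")
    ha = np.zeros(mask.shape, dtype=float)
    ha[mask] = spec.ha_endo_deg + dr.wall_fraction[mask] * (spec.ha_epi_deg - spec.ha_endo_deg)
    ta = np.zeros(mask.shape, dtype=float)
    ta[mask] = spec.ta_deg
    return ha, ta


def build_tensor_field(
    ha_deg: np.ndarray,
    ta_deg: np.ndarray,
    frames: LocalFrameField,
    eigenvalues: tuple[float, float, float],
    mask: np.ndarray,
) -> TensorField:
    """Diffusion tensors D = sum_k lambda_k e_k e_k^T from angle maps.

    e1 is the fiber direction built from (HA, TA) in the local frame,
    e2 the in-tangent-plane direction orthogonal to e1's projection and
    e3 = e1 x e2 completes the right-handed triad.
    """
    frames.check_orthonormal()
    l1, l2, l3 = eigenvalues
    ha = np.radians(np.asarray(ha_deg, dtype=float))
    e1 = angles_to_fiber(ha_deg, ta_deg, frames)
    e2 = -np.sin(ha)[..., None] * frames.ec + np.cos(ha)[..., None] * frames.el
    e3 = np.cross(e1, e2)
    d = (
        l1 * e1[..., :, None] * e1[..., None, :]
        + l2 * e2[..., :, None] * e2[..., None, :]
        + l3 * e3[..., :, None] * e3[..., None, :]
    )
    d[~mask] = 0.0
    return TensorField.from_matrices(d, mask=mask)


def synthesize_dwi(
    tensors: TensorField,
    protocol: DiffusionProtocol,
    s0: float | np.ndarray = 1.0,
    affine: np.ndarray | None = None,
    background: float = 0.0,
) -> DwiSeries:
    """Noiseless DWI series S = S0 exp(-b g^T D g), one volume per channel.

    Outside the tensor mask the signal is the constant ``background``
    (zero by default) in every channel.
    """
    d = tensors.to_matrices()[tensors.mask]  # (V, 3, 3)
    b = protocol.bvals
    g = protocol.bvecs
    # ADC per voxel and channel: g_n . D g_n
    adc = np.einsum("ni,vij,nj->vn", g, d, g)
    s0_arr = np.broadcast_to(np.asarray(s0, dtype=float), tensors.mask.shape)
    sig = s0_arr[tensors.mask][:, None] * np.exp(-b[None, :] * adc)
    data = np.full(tensors.mask.shape + (protocol.n_volumes,), float(background))
    data[tensors.mask] = sig
    if affine is None:
        affine = np.eye(4)
    return DwiSeries(data=data, protocol=protocol, affine=affine)


# ---------------------------------------------------------------------------
# degradation chain
# ---------------------------------------------------------------------------

def degrade_inplane(volume: np.ndarray, factor: int, axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Reduce in-plane resolution by cropping the centered 2D k-space band.

    Each plane spanned by ``axes`` is Fourier transformed, the central
    ``n/factor`` band retained (for even sizes the extra sample sits on
    the negative-frequency side of the fftshifted spectrum) and
    transformed back; amplitudes are rescaled so a constant image keeps
    its value.  The output voxel size along ``axes`` is ``factor`` times
    the input's.
    """
    vol = np.asarray(volume, dtype=float)
    if factor == 1:
        return vol.copy()
    n0, n1 = vol.shape[axes[0]], vol.shape[axes[1]]
    if n0 % factor or n1 % factor:
        raise ValueError(f"crop factor {factor} does not divide in-plane dims {(n0, n1)}")
    m0, m1 = n0 // factor, n1 // factor
    f = np.fft.fftshift(np.fft.fft2(vol, axes=axes), axes=axes)
    sl = [slice(None)] * vol.ndim
    sl[axes[0]] = slice(n0 // 2 - m0 // 2, n0 // 2 - m0 // 2 + m0)
    sl[axes[1]] = slice(n1 // 2 - m1 // 2, n1 // 2 - m1 // 2 + m1)
    f = f[tuple(sl)]
    out = np.fft.ifft2(np.fft.ifftshift(f, axes=axes), axes=axes)
    return out.real * (m0 * m1) / (n0 * n1)


_ORIENTATION_SLICE_AXIS = {"xy": 2, "yz": 0, "xz": 1}
# stack data axes = (in-plane 1, in-plane 2, slice)
ORIENTATION_AXIS_ORDER = {"xy": (0, 1, 2), "yz": (1, 2, 0), "xz": (0, 2, 1)}


def slice_profile_weights(profile: str, thickness: int) -> np.ndarray:
    if profile == "rect":
        return np.full(thickness, 1.0 / thickness)
    raise ValueError(f"unknown slice profile {profile!r}")


def slice_select(
    volume: np.ndarray,
    orientation: str,
    thickness: int,
    profile: str = "rect",
) -> np.ndarray:
    """Collapse ``thickness`` consecutive planes into one thick slice.

    The slice axis is implied by the orientation label ('xy' -> z,
    'yz' -> x, 'xz' -> y); output axes are reordered to
    (in-plane, in-plane, slice).  Each output slice is the
    profile-weighted mean of its planes (ideal rectangle by default).
    """
    if orientation not in _ORIENTATION_SLICE_AXIS:
        raise ValueError(f"unknown orientation label {orientation!r}")
    w = slice_profile_weights(profile, thickness)
    axis = _ORIENTATION_SLICE_AXIS[orientation]
    vol = np.asarray(volume, dtype=float)
    n = vol.shape[axis]
    if n % thickness:
        raise ValueError(f"thickness {thickness} does not divide extent {n} along axis {axis}")
    vol = np.moveaxis(vol, axis, -1)
    shp = vol.shape[:-1] + (n // thickness, thickness)
    slabs = (vol.reshape(shp) * w).sum(axis=-1)
    # reorder in-plane axes to the orientation's order
    order = ORIENTATION_AXIS_ORDER[orientation]
    inplane = [a for a in order[:2]]
    # current axes: remaining volume axes in original order, then slice
    remaining = [a for a in range(3) if a != axis]
    perm = [remaining.index(a) for a in inplane] + [2]
    return np.transpose(slabs, perm)


def rician_sigma(reference_signal: float, target_snr: float) -> float:
    """Gaussian channel noise level for a target SNR = signal / sigma."""
    if target_snr <= 0:
        raise ValueError("target SNR must be positive")
    return float(reference_signal) / float(target_snr)


def add_rician_noise(
    volume: np.ndarray,
    sigma: float | None = None,
    rng: np.random.Generator | int | None = None,
    target_snr: float | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Magnitude (Rician) noise: sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma).

    Either ``sigma`` is given directly, or ``target_snr`` together with
    ``mask`` (sigma = mean in-mask signal / target SNR).  Reproducible
    when ``rng`` is a seeded generator or an integer seed.
    """
    vol = np.asarray(volume, dtype=float)
    if sigma is None:
        if target_snr is None:
            raise ValueError("provide sigma or target_snr")
        if target_snr <= 0:
            raise ValueError("target SNR must be positive")
        if mask is None:
            raise ValueError("a mask is required to derive sigma from target_snr")
        sigma = float(vol[mask].mean()) / target_snr
    if sigma == 0:
        return vol.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n1 = rng.normal(0.0, sigma, vol.shape)
    n2 = rng.normal(0.0, sigma, vol.shape)
    return np.sqrt((vol + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# helicoidal fiber phantom
# ---------------------------------------------------------------------------

def _helix_ha_of_radius(spec: HelixPhantomSpec, r_mm: np.ndarray) -> np.ndarray:
    t = (r_mm - spec.inner_radius_mm) / (spec.outer_radius_mm - spec.inner_radius_mm)
    return spec.ha_at_inner_deg + t * (spec.ha_at_outer_deg - spec.ha_at_inner_deg)


def helix_local_frames(points_mm: np.ndarray) -> LocalFrameField:
    """Cylindrical frames about the z axis: er radial, ec tangential, el = z."""
    p = np.asarray(points_mm, dtype=float)
    normals = np.concatenate([p[..., :2], np.zeros(p.shape[:-1] + (1,))], axis=-1)
    return frames_from_normals(normals, np.array([0.0, 0.0, 1.0]))


def make_helix_phantom(
    spec: HelixPhantomSpec,
    grid_shape: tuple[int, int, int] = (64, 64, 40),
    voxel_size_mm: float = 1.0,
) -> tuple[TensorField, np.ndarray, np.ndarray]:
    """Helicoidal fiber phantom: tensors, bundle mask and world affine.

    At each voxel of the annulus the fiber direction is tangent to a
    helix around z with elevation HA(r) from the transverse plane, HA
    linear in the axial distance r; the transverse-angle component is
    zero by construction.  Voxels outside the bundle are filled with an
    isotropic water compartment; the tensor-field mask covers bundle
    plus water while the returned ``mask`` is the bundle only.
    """
    nx, ny, nz = grid_shape
    if (spec.outer_radius_mm - spec.inner_radius_mm) / voxel_size_mm < 3:
        raise ValueError("voxel size too coarse to resolve the annulus (< 3 voxels across)")
    if min(nx, ny) * voxel_size_mm < 2 * spec.outer_radius_mm:
        raise ValueError("grid does not cover the annulus")
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size_mm
    affine[:3, 3] = -np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0]) * voxel_size_mm

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pts = np.stack([i, j, k], axis=-1).astype(float)
    world = pts * voxel_size_mm + affine[:3, 3]
    r = np.hypot(world[..., 0], world[..., 1])
    bundle = (r >= spec.inner_radius_mm) & (r <= spec.outer_radius_mm)

    frames = helix_local_frames(world)
    ha = np.zeros(grid_shape)
    ha[bundle] = _helix_ha_of_radius(spec, r[bundle])
    full_mask = np.ones(grid_shape, dtype=bool)
    tensors = build_tensor_field(ha, np.zeros(grid_shape), frames, spec.eigenvalues_mm2_s, bundle)
    # water compartment: isotropic diffusion everywhere outside the bundle
    d = tensors.to_matrices()
    iso = np.eye(3) * spec.water_diffusivity_mm2_s
    d[~bundle] = iso
    tensors = TensorField.from_matrices(d, mask=full_mask)
    return tensors, bundle, affine


def helix_roi_mask(
    spec: HelixPhantomSpec,
    bundle: np.ndarray,
    affine: np.ndarray,
    roi_radius_mm: float = 8.0,
    azimuth_rad: float = 0.0,
) -> np.ndarray:
    """Per-slice circular ROI over the bundle section, replicated along z.

    Mirrors the measurement protocol of the physical phantom: a disc of
    ``roi_radius_mm`` centred on the mid-annulus radius (at a fixed
    azimuth), intersected with the bundle.  Because HA is linear in r
    and the disc is symmetric about the mid radius, the ROI mean of the
    ground-truth HA equals the mid-radius (nominal mean) angle.
    """
    shape = bundle.shape
    i, j = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    vox = np.stack([i, j, np.zeros_like(i)], axis=-1).astype(float)
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    cx = spec.mid_radius_mm * np.cos(azimuth_rad)
    cy = spec.mid_radius_mm * np.sin(azimuth_rad)
    disc = (world[..., 0] - cx) ** 2 + (world[..., 1] - cy) ** 2 <= roi_radius_mm**2
    return disc[:, :, None] & bundle
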