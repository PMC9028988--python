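"""Linear acquisition operators mapping an isotropic volume to thick-slice stacks.

A stack acquisition is modeled as ``D B T``: ``T`` resamples the
isotropic volume into the stack frame (trilinear interpolation), ``B``
blurs along the slice-selection axis with the slice profile, and ``D``
keeps one sample per thick slice.  The three operators are realized
jointly as one sparse matrix so the adjoint is the exact matrix
transpose — required for gradient-based solvers of the reconstruction
problem, and not equal to resampling with the inverse rotation.

Conventions: world coordinates follow the NIfTI RAS+ convention, voxel
indices are 0-based, affines map voxel centers to world mm.  Per-slice
rigid poses (motion) enter as world-space 4x4 matrices composed with
the slice's nominal affine.  Out-of-footprint contributions are zero
(Dirichlet), matching zero-background phantoms and keeping the operator
linear.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "IsoVolume",
    "SliceStack",
    "StackGeometry",
    "StackOperator",
    "forward_project",
    "adjoint_project",
    "domain_intersection",
    "axis_stack_affine",
    "rigid_matrix",
    "resample_to_grid",
]


@dataclass
class IsoVolume:
    """3D scalar lattice with an isotropic world affine."""

    data: np.ndarray
    affine: np.ndarray
    domain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        sp = self.spacing
        if not np.allclose(sp, sp[0], rtol=1e-6):
            raise ValueError(f"IsoVolume spacing must be isotropic, got {sp}")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class SliceStack:
    """Ordered thick slices with geometry.

    ``data`` axes are (in-plane, in-plane, slice[, channel]).
    ``affine`` maps stack voxel indices (slice axis = axis 2) to world
    mm, with the slice-axis column scaled to the slice spacing.
    ``slice_poses`` is an optional (n_slices, 4, 4) array of world-space
    rigid corrections (identity when absent).
    """

    data: np.ndarray
    affine: np.ndarray
    thickness_mm: float
    orientation: str = ""
    slice_poses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("stack data must be 3D or 4D (with channels)")

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def inplane_shape(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    def pose(self, k: int) -> np.ndarray:
        if self.slice_poses is None:
            return np.eye(4)
        return self.slice_poses[k]

    def slice_affine(self, k: int) -> np.ndarray:
        """Voxel->world affine of slice k (its pose applied)."""
        shift = np.eye(4)
        shift[:3, 3] = self.affine[:3, 2] * k
        base = self.affine.copy()
        base[:3, 3] += self.affine[:3, 2] * k
        return self.pose(k) @ base


@dataclass
class StackGeometry:
    """Geometry of one stack relative to an isotropic reconstruction grid."""

    stack_affine: np.ndarray
    inplane_shape: tuple[int, int]
    n_slices: int
    thickness_ratio: int
    profile: np.ndarray = None
    orientation: str = ""
    slice_poses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stack_affine = np.asarray(self.stack_affine, dtype=float)
        if self.thickness_ratio < 1 or int(self.thickness_ratio) != self.thickness_ratio:
            raise ValueError("thickness_ratio must be a positive integer")
        self.thickness_ratio = int(self.thickness_ratio)
        if self.profile is None:
            self.profile = np.full(self.thickness_ratio, 1.0 / self.thickness_ratio)
        self.profile = np.asarray(self.profile, dtype=float)
        if np.any(self.profile < 0):
            raise ValueError("profile weights must be non-negative")
        s = self.profile.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError("profile weights must sum to 1")
        if abs(np.linalg.det(self.stack_affine)) < 1e-12:
            raise ValueError("stack affine is singular")

    @classmethod
    def from_stack(cls, stack: SliceStack, iso_spacing_mm: float) -> "StackGeometry":
        ratio = stack.thickness_mm / iso_spacing_mm
        return cls(
            stack_affine=stack.affine,
            inplane_shape=stack.inplane_shape,
            n_slices=stack.n_slices,
            thickness_ratio=int(round(ratio)),
            orientation=stack.orientation,
            slice_poses=stack.slice_poses,
        )

    def slice_affine(self, k: int) -> np.ndarray:
        base = self.stack_affine.copy()
        base[:3, 3] += self.stack_affine[:3, 2] * k
        pose = np.eye(4) if self.slice_poses is None else self.slice_poses[k]
        return pose @ base


def rigid_matrix(params: np.ndarray, center: np.ndarray) -> np.ndarray:
    """World-space rigid 4x4 from 6 parameters about a pivot point.

    ``params`` = (rx, ry, rz, tx, ty, tz): intrinsic Z-Y-X Euler angles
    in degrees applied about ``center``, then translations in mm.
    """
    rx, ry, rz = np.radians(np.asarray(params[:3], dtype=float))
    t = np.asarray(params[3:6], dtype=float)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    R = Rz @ Ry @ Rx
    m = np.eye(4)
    m[:3, :3] = R
    c = np.asarray(center, dtype=float)
    m[:3, 3] = c - R @ c + t
    return m


def axis_stack_affine(
    orientation: str,
    vol_affine: np.ndarray,
    inplane_factor: int,
    thickness_vox: int,
) -> np.ndarray:
    """Stack affine for an axis-aligned stack degraded from a source volume.

    The stack's in-plane axes are the orientation's two axes at
    ``inplane_factor`` times the source voxel size; the slice axis is
    the remaining one at ``thickness_vox`` source voxels.  Voxel-center
    offsets place output sample 0 at the centroid of the source samples
    it aggregates.
    """
    from .phantom import ORIENTATION_AXIS_ORDER  # axis conventions live with the degrader

    order = ORIENTATION_AXIS_ORDER[orientation]
    scales = (inplane_factor, inplane_factor, thickness_vox)
    a = np.asarray(vol_affine, dtype=float)
    out = np.eye(4)
    out[:3, 3] = a[:3, 3]
    for new_ax, (src_ax, s) in enumerate(zip(order, scales)):
        out[:3, new_ax] = a[:3, src_ax] * s
        out[:3, 3] += a[:3, src_ax] * (s - 1) / 2.0
    return out


def _trilinear_rows(pts_vox: np.ndarray, vol_shape: tuple[int, int, int]):
    """Trilinear interpolation stencil: (col indices, weights, row validity)."""
    p = np.asarray(pts_vox, dtype=float)
    base = np.floor(p).astype(int)
    frac = p - base
    nx, ny, nz = vol_shape
    cols = []
    wts = []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ix, iy, iz = base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
                col = np.where(inside, (ix * ny + iy) * nz + iz, 0)
                cols.append(col)
                wts.append(np.where(inside, w, 0.0))
    return np.stack(cols, axis=1), np.stack(wts, axis=1)


class StackOperator:
    """Sparse-matrix realization of D B T for one stack geometry."""

    def __init__(self, geom: StackGeometry, vol_shape: tuple[int, int, int], vol_affine: np.ndarray):
        self.geom = geom
        self.vol_shape = tuple(vol_shape)
        self.vol_affine = np.asarray(vol_affine, dtype=float)
        self.matrix = self._build()

    @property
    def stack_shape(self) -> tuple[int, int, int]:
        g = self.geom
        return (g.inplane_shape[0], g.inplane_shape[1], g.n_slices)

    def _build(self) -> sparse.csr_matrix:
        g = self.geom
        nx, ny = g.inplane_shape
        inv_vol = np.linalg.inv(self.vol_affine)
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        inplane = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(float)
        n_inplane = inplane.shape[0]
        # profile taps subdivide the slab: spacing = slice spacing / ratio
        tap_step = float(np.linalg.norm(g.stack_affine[:3, 2])) / g.thickness_ratio
        taps = (np.arange(g.thickness_ratio) - (g.thickness_ratio - 1) / 2.0) * tap_step

        rows_all, cols_all, vals_all = [], [], []
        for k in range(g.n_slices):
            a = g.slice_affine(k)
            n_slice = a[:3, 2] / np.linalg.norm(a[:3, 2])
            centers = inplane @ a[:3, :2].T + a[:3, 3]
            row_idx = (inplane[:, 0].astype(int) * ny + inplane[:, 1].astype(int)) * g.n_slices + k
            for t_off, w_prof in zip(taps, g.profile):
                world = centers + n_slice * t_off
                vox = world @ inv_vol[:3, :3].T + inv_vol[:3, 3]
                cols, wts = _trilinear_rows(vox, self.vol_shape)
                rows_all.append(np.repeat(row_idx, 8))
                cols_all.append(cols.ravel())
                vals_all.append((wts * w_prof).ravel())
        n_rows = n_inplane * g.n_slices
        n_cols = int(np.prod(self.vol_shape))
        m = sparse.coo_matrix(
            (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(n_rows, n_cols),
        )
        return m.tocsr()

    def forward(self, vol: np.ndarray) -> np.ndarray:
        return (self.matrix @ np.asarray(vol, dtype=float).ravel()).reshape(self.stack_shape)

    def adjoint(self, stack: np.ndarray) -> np.ndarray:
        return (self.matrix.T @ np.asarray(stack, dtype=float).ravel()).reshape(self.vol_shape)


def forward_project(vol: IsoVolume, geom: StackGeometry) -> np.ndarray:
    """Apply D B T to an isotropic volume, returning stack-shaped samples."""
    return StackOperator(geom, vol.data.shape, vol.affine).forward(vol.data)


def adjoint_project(stack_data: np.ndarray, geom: StackGeometry, vol: IsoVolume) -> np.ndarray:
    """Exact adjoint of :func:`forward_project` onto the volume grid."""
    return StackOperator(geom, vol.data.shape, vol.affine).adjoint(stack_data)


def domain_intersection(
    geoms: list[StackGeometry],
    vol_shape: tuple[int, int, int],
    vol_affine: np.ndarray,
) -> np.ndarray:
    """Voxels of the iso grid inside every stack's slab footprint (Omega).

    Footprints use the stacks' nominal (pose-free) geometry.  Raises on
    an empty intersection.
    """
    if len(geoms) == 0:
        raise ValueError("at least one stack geometry is required")
    nx, ny, nz = vol_shape
    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox = np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1).astype(float)
    world = vox @ np.asarray(vol_affine)[:3, :3].T + np.asarray(vol_affine)[:3, 3]
    mask = np.ones(world.shape[0], dtype=bool)
    for g in geoms:
        inv = np.linalg.inv(g.stack_affine)
        s = world @ inv[:3, :3].T + inv[:3, 3]
        lims = (g.inplane_shape[0], g.inplane_shape[1], g.n_slices)
        for ax, n in enumerate(lims):
            mask &= (s[:, ax] >= -0.5) & (s[:, ax] <= n - 0.5)
    mask = mask.reshape(vol_shape)
    if not mask.any():
        raise ValueError("empty intersection domain Omega: stacks do not overlap")
    return mask


def resample_to_grid(
    data: np.ndarray,
    src_affine: np.ndarray,
    dst_shape: tuple[int, int, int],
    dst_affine: np.ndarray,
    order: int = 1,
) -> np.ndarray:
    """Resample a (possibly multi-channel) volume onto another grid.

    Trilinear by default; zero fill outside the source footprint.
    """
    from scipy.ndimage import map_coordinates

    src_affine = np.asarray(src_affine, dtype=float)
    dst_affine = np.asarray(dst_affine, dtype=float)
    t = np.linalg.inv(src_affine) @ dst_affine
    i, j, k = np.meshgrid(*[np.arange(n) for n in dst_shape], indexing="ij")
    vox = np.stack([i, j, k], axis=0).astype(float)
    coords = np.einsum("ab,b...->a...", t[:3, :3], vox) + t[:3, 3][:, None, None, None]
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 3:
        return map_coordinates(arr, coords, order=order, mode="constant", cval=0.0)
    out = np.empty(tuple(dst_shape) + (arr.shape[3],))
    for c in range(arr.shape[3]):
        out[..., c] = map_coordinates(arr[..., c], coords, order=order, mode="constant", cval=0.0)
    return out
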