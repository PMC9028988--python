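"""Diffusion tensor estimation and scalar metrics.

The diffusion-weighted signal follows the mono-exponential tensor model

    S(g, b) = S0 * exp(-b * g^T D g)

with ``D`` a symmetric positive-definite 3x3 tensor (mm^2/s), ``b`` the
diffusion weighting (s/mm^2) and ``g`` a unit gradient direction.  The
tensor is recovered per voxel by log-linear least squares: taking logs
turns the model into a linear system in the six unique tensor components
plus ``ln S0``.  With the minimal six-direction "dual gradient" scheme and
one b=0 image the system is exactly determined and the fit is exact on
noiseless data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionProtocol",
    "DwiSeries",
    "TensorField",
    "EigenSystem",
    "dual_gradient_directions",
    "fit_tensor",
    "eigen_decompose",
    "mean_diffusivity",
    "fractional_anisotropy",
]

# Six dual-gradient encoding directions (pairs of coordinate axes), the
# minimal determined set for tensor fitting.
_DUAL_GRADIENT_RAW = np.array(
    [
        [1, 0, -1],
        [1, 0, 1],
        [0, -1, -1],
        [0, -1, 1],
        [1, -1, 0],
        [1, 1, 0],
    ],
    dtype=float,
)


def dual_gradient_directions() -> np.ndarray:
    """Unit-norm dual-gradient scheme directions, shape (6, 3)."""
    g = _DUAL_GRADIENT_RAW.copy()
    return g / np.linalg.norm(g, axis=1, keepdims=True)


@dataclass
class DiffusionProtocol:
    """Acquisition protocol: per-volume b-values and gradient directions.

    Non-unit directions with b > 0 are normalized on construction with a
    warning.  Directions for b = 0 volumes are irrelevant and left as-is.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    scheme_name: str = ""
    n_reps: int = 1

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise ValueError(
                f"bvals ({self.bvals.shape[0]}) and bvecs ({self.bvecs.shape[0]}) "
                "must have the same number of entries"
            )
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        bad = dw & (np.abs(norms - 1.0) > 1e-8)
        if np.any(bad):
            warnings.warn(
                f"normalizing {int(bad.sum())} non-unit gradient direction(s)",
                stacklevel=2,
            )
            self.bvecs[bad] /= norms[bad, None]

    @property
    def n_volumes(self) -> int:
        return self.bvals.shape[0]

    @classmethod
    def dual_gradient(cls, b_value: float, n_b0: int = 1) -> "DiffusionProtocol":
        """b=0 volume(s) followed by the six dual-gradient directions."""
        g = dual_gradient_directions()
        bvals = np.concatenate([np.zeros(n_b0), np.full(6, float(b_value))])
        bvecs = np.concatenate([np.zeros((n_b0, 3)), g])
        return cls(bvals=bvals, bvecs=bvecs, scheme_name="dual gradient")


@dataclass
class DwiSeries:
    """A set of diffusion-weighted volumes sharing a grid.

    ``data`` has the channel (b-value/direction) axis last: (X, Y, Z, N).
    """

    data: np.ndarray
    protocol: DiffusionProtocol
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (X, Y, Z, channel)")
        if self.data.shape[-1] != self.protocol.n_volumes:
            raise ValueError(
                f"image has {self.data.shape[-1]} channels but the protocol "
                f"lists {self.protocol.n_volumes}"
            )

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


# Lower-triangular component order used throughout (and in NIfTI exports).
TENSOR_COMPONENT_ORDER = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors over a mask.

    ``components`` stores the six unique elements in the order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), units mm^2/s, shape (..., 6).
    """

    components: np.ndarray
    mask: np.ndarray
    residual_norm: np.ndarray | None = None
    s0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.components.shape[-1] != 6:
            raise ValueError("tensor components must have a trailing axis of 6")
        if self.components.shape[:-1] != self.mask.shape:
            raise ValueError("components and mask shapes disagree")

    def to_matrices(self) -> np.ndarray:
        """Full symmetric 3x3 matrices, shape (..., 3, 3)."""
        c = self.components
        out = np.empty(c.shape[:-1] + (3, 3), dtype=float)
        out[..., 0, 0] = c[..., 0]
        out[..., 1, 1] = c[..., 1]
        out[..., 2, 2] = c[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
        return out

    @classmethod
    def from_matrices(cls, d: np.ndarray, mask: np.ndarray, **kw) -> "TensorField":
        d = np.asarray(d, dtype=float)
        comp = np.stack(
            [d[..., 0, 0], d[..., 1, 1], d[..., 2, 2],
             d[..., 0, 1], d[..., 0, 2], d[..., 1, 2]],
            axis=-1,
        )
        return cls(components=comp, mask=mask, **kw)

    def nonpositive_definite(self) -> np.ndarray:
        """Boolean flag per masked voxel where the tensor is not PD (flagged, never fixed)."""
        flags = np.zeros(self.mask.shape, dtype=bool)
        if not self.mask.any():
            return flags
        w = np.linalg.eigvalsh(self.to_matrices()[self.mask])
        flags[self.mask] = w[:, 0] <= 0
        return flags


@dataclass
class EigenSystem:
    """Sorted eigen-decomposition of a tensor field.

    eigenvalues: (..., 3) descending; eigenvectors: (..., 3, 3) with
    ``eigenvectors[..., :, k]`` the unit eigenvector of eigenvalue k; the
    triad is right-handed.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mask: np.ndarray

    @property
    def e1(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]


def _design_matrix(protocol: DiffusionProtocol) -> np.ndarray:
    b = protocol.bvals
    g = protocol.bvecs
    x = np.empty((protocol.n_volumes, 7))
    x[:, 0] = -b * g[:, 0] ** 2
    x[:, 1] = -b * g[:, 1] ** 2
    x[:, 2] = -b * g[:, 2] ** 2
    x[:, 3] = -2 * b * g[:, 0] * g[:, 1]
    x[:, 4] = -2 * b * g[:, 0] * g[:, 2]
    x[:, 5] = -2 * b * g[:, 1] * g[:, 2]
    x[:, 6] = 1.0
    return x


def fit_tensor(
    dwi: DwiSeries,
    mask: np.ndarray | None = None,
    clamp_frac: float = 1e-6,
    weighted: bool = False,
) -> TensorField:
    """Per-voxel log-linear least-squares tensor fit.

    Signals are clamped at ``clamp_frac`` times the voxel's estimated S0
    (max over b=0 channels, falling back to the channel max) before the
    log transform.  With ``weighted=True`` a single reweighted pass with
    weights proportional to the predicted signal is applied (WLS).

    Raises ``np.linalg.LinAlgError`` if the protocol's design matrix is
    singular (fewer than six independent directions).
    """
    protocol = dwi.protocol
    x = _design_matrix(protocol)
    if np.linalg.matrix_rank(x) < 7:
        raise np.linalg.LinAlgError(
            "singular design matrix: protocol does not determine the tensor"
        )
    if mask is None:
        mask = np.ones(dwi.data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    s = dwi.data[mask]  # (V, N)
    b0 = protocol.bvals == 0
    s0_ref = s[:, b0].max(axis=1) if b0.any() else s.max(axis=1)
    s0_ref = np.maximum(s0_ref, np.finfo(float).tiny)
    s_clamped = np.maximum(s, clamp_frac * s0_ref[:, None])
    y = np.log(s_clamped)

    pinv = np.linalg.pinv(x)
    coef = y @ pinv.T  # (V, 7)
    if weighted:
        # one IRLS pass: weights = predicted signals
        w = np.exp(coef @ x.T)
        for v in range(coef.shape[0]):
            xw = x * w[v][:, None]
            coef[v] = np.linalg.lstsq(xw, y[v] * w[v], rcond=None)[0]

    resid = y - coef @ x.T
    comp_flat = coef[:, [0, 1, 2, 3, 4, 5]]
    # design order is (xx, yy, zz, xy, xz, yz) == storage order
    components = np.zeros(mask.shape + (6,), dtype=float)
    components[mask] = comp_flat
    residual_norm = np.zeros(mask.shape, dtype=float)
    residual_norm[mask] = np.linalg.norm(resid, axis=1)
    s0 = np.zeros(mask.shape, dtype=float)
    s0[mask] = np.exp(coef[:, 6])
    return TensorField(components=components, mask=mask,
                       residual_norm=residual_norm, s0=s0)


def eigen_decompose(tensors: TensorField) -> EigenSystem:
    """Eigen-system with descending eigenvalues and a fixed sign convention.

    Each eigenvector's sign is chosen so that its largest-magnitude
    component is positive (deterministic under the antipodal ambiguity);
    the third axis is then recomputed as e1 x e2 so the triad is
    right-handed.  For (near-)degenerate eigenvalues the ordering of the
    eigenvectors follows the numerical decomposition and downstream angle
    maps are documented as unstable there.
    """
    mask = tensors.mask
    d = tensors.to_matrices()[mask]
    w, v = np.linalg.eigh(d)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    # sign fix: largest-|component| positive for e1 and e2
    for k in range(2):
        vk = v[:, :, k]
        idx = np.argmax(np.abs(vk), axis=1)
        sign = np.sign(vk[np.arange(vk.shape[0]), idx])
        sign[sign == 0] = 1.0
        v[:, :, k] = vk * sign[:, None]
    v[:, :, 2] = np.cross(v[:, :, 0], v[:, :, 1])

    evals = np.zeros(mask.shape + (3,), dtype=float)
    evecs = np.zeros(mask.shape + (3, 3), dtype=float)
    evecs[..., 0, 0] = evecs[..., 1, 1] = evecs[..., 2, 2] = 1.0
    evals[mask] = w
    evecs[mask] = v
    return EigenSystem(eigenvalues=evals, eigenvectors=evecs, mask=mask)


def mean_diffusivity(eigenvalues: np.ndarray) -> np.ndarray:
    """MD = (l1 + l2 + l3) / 3, mm^2/s."""
    return np.asarray(eigenvalues)[..., :3].mean(axis=-1)


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||l - MD|| / ||l||, in [0, 1]; 0 for the zero tensor."""
    lam = np.asarray(eigenvalues, dtype=float)[..., :3]
    md = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - md, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)
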