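"""File formats, pipeline configuration and the end-to-end runner.

Formats: NIfTI-1 for volumes and stacks (one 4D file per DWI series),
FSL-style ``.bval``/``.bvec`` text files, a JSON sidecar per stack
(orientation label, thickness, per-slice poses, seed, spec echo), YAML
configs and a JSON manifest with SHA-256 hashes of every artifact.
World-coordinate handling uses the NIfTI RAS+ convention with 0-based
voxel indices and voxel-center alignment throughout, checked by a
geometry self-test at import.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .forward_model import SliceStack, StackGeometry, domain_intersection
from .metrics import eroded_mask_stats, mae_by_slice, transmural_profile
from .phantom import DegradationSpec, LvPhantomSpec
from .registration import RegistrationSettings
from .sr_recon import ReconConfig, reconstruct_sr_series
from .simulation import (
    degrade_stack,
    generate_lv_ground_truth,
    lv_fields_on_grid,
    fit_metrics,
    recon_grid,
)
from .tensor_fit import DiffusionProtocol, DwiSeries

logger = logging.getLogger(__name__)

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_stack",
    "write_stack",
    "PipelineConfig",
    "run_pipeline",
]


def _geometry_self_test() -> None:
    """Voxel-center/affine round trip sanity check (runs once at import)."""
    a = np.eye(4)
    a[:3, :3] = np.diag([2.0, 2.0, 8.0])
    a[:3, 3] = [-5.0, 3.0, 1.0]
    vox = np.array([3.0, 4.0, 5.0])
    world = a[:3, :3] @ vox + a[:3, 3]
    back = np.linalg.inv(a)[:3, :3] @ world + np.linalg.inv(a)[:3, 3]
    assert np.allclose(back, vox, atol=1e-12), "geometry convention self-test failed"


_geometry_self_test()


# ---------------------------------------------------------------------------
# DWI / stack I/O
# ---------------------------------------------------------------------------

def write_dwi(series: DwiSeries, path: str | Path) -> list[Path]:
    """Write a DWI series as 4D NIfTI plus FSL-style .bval/.bvec files."""
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float64), series.affine)
    nib.save(img, str(path))
    stem = path.with_suffix("") if path.suffix == ".nii" else Path(str(path)[: -len(".nii.gz")])
    bval_path = stem.with_suffix(".bval")
    bvec_path = stem.with_suffix(".bvec")
    np.savetxt(bval_path, series.protocol.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, series.protocol.bvecs.T, fmt="%.8f")
    return [path, bval_path, bvec_path]


def read_dwi(path: str | Path) -> DwiSeries:
    """Read a 4D NIfTI + companion .bval/.bvec into a DwiSeries.

    Raises FileNotFoundError when the b-table is missing and ValueError
    on a channel-count mismatch; non-unit b-vectors are normalized with
    a warning (protocol contract).
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    stem = path.with_suffix("") if path.suffix == ".nii" else Path(str(path)[: -len(".nii.gz")])
    bval_path = stem.with_suffix(".bval")
    bvec_path = stem.with_suffix(".bvec")
    if not bval_path.exists() or not bvec_path.exists():
        raise FileNotFoundError(f"missing b-table ({bval_path.name} / {bvec_path.name})")
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path).reshape(3, -1).T
    if bvals.size != data.shape[-1]:
        raise ValueError(
            f"image has {data.shape[-1]} channels but the b-table lists {bvals.size}"
        )
    protocol = DiffusionProtocol(bvals=bvals, bvecs=bvecs)
    return DwiSeries(data=data, protocol=protocol, affine=np.asarray(img.affine))


def write_stack(stack: SliceStack, protocol: DiffusionProtocol, path: str | Path,
                extra_sidecar: dict | None = None) -> list[Path]:
    """Stack as NIfTI + b-table + JSON sidecar (geometry and poses)."""
    series = DwiSeries(data=stack.data, protocol=protocol, affine=stack.affine)
    paths = write_dwi(series, path)
    sidecar = {
        "orientation": stack.orientation,
        "thickness_mm": stack.thickness_mm,
        "slice_poses": None if stack.slice_poses is None else stack.slice_poses.tolist(),
    }
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    sc_path = Path(str(paths[0]) + ".json") if str(path).endswith(".nii") else Path(str(path) + ".json")
    sc_path = paths[0].with_suffix(".json")
    sc_path.write_text(json.dumps(sidecar, indent=2))
    return paths + [sc_path]


def read_stack(path: str | Path) -> tuple[SliceStack, DiffusionProtocol]:
    series = read_dwi(path)
    sc_path = Path(path).with_suffix(".json")
    sidecar = json.loads(sc_path.read_text()) if sc_path.exists() else {}
    poses = sidecar.get("slice_poses")
    stack = SliceStack(
        data=series.data,
        affine=series.affine,
        thickness_mm=float(sidecar.get("thickness_mm",
                                       np.linalg.norm(series.affine[:3, 2]))),
        orientation=sidecar.get("orientation", ""),
        slice_poses=None if poses is None else np.asarray(poses),
    )
    return stack, series.protocol


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

def _from_dict(cls, d: dict):
    """Strict dataclass construction: unknown keys are rejected."""
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        if isinstance(v, list):
            v = tuple(v) if k in ("grid_shape", "center", "eigenvalues_mm2_s",
                                  "stack_orientations", "b_values_s_mm2") else v
        kwargs[k] = v
    return cls(**kwargs)


@dataclass
class PerturbConfig:
    fraction: float = 0.0
    max_rot_deg: float = 2.5
    max_trans_mm: float = 3.5


@dataclass
class AnalysisConfig:
    erosion_vox: int = 1
    n_layers: int = 5


@dataclass
class PipelineConfig:
    """Full run description; round-trips losslessly through YAML."""

    phantom: LvPhantomSpec = field(default_factory=LvPhantomSpec)
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)
    recon: ReconConfig = field(default_factory=ReconConfig)
    perturb: PerturbConfig = field(default_factory=PerturbConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    register_slices: bool = False
    strategies: tuple[str, ...] = ("sr", "lr", "hr")
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "phantom": LvPhantomSpec,
            "degradation": DegradationSpec,
            "registration": RegistrationSettings,
            "recon": ReconConfig,
            "perturb": PerturbConfig,
            "analysis": AnalysisConfig,
        }
        unknown = set(d) - set(sub) - {"register_slices", "seed", "strategies"}
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        kwargs = {}
        for key, klass in sub.items():
            if key in d:
                kwargs[key] = _from_dict(klass, d.pop(key))
        if "strategies" in d:
            d["strategies"] = tuple(d["strategies"])
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return conv(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _save_map(data: np.ndarray, affine: np.ndarray, path: Path) -> Path:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))
    return path


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """simulate -> degrade -> (perturb/register) -> reconstruct -> fit -> report.

    Writes all artifacts plus ``report.json``, the resolved config and a
    manifest with SHA-256 hashes; deterministic under a fixed seed.
    Stage failures abort with the stage name; artifacts written up to
    that point are left in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "configure"
    try:
        config.to_yaml(outdir / "resolved_config.yaml")
        artifacts.append(outdir / "resolved_config.yaml")

        stage = "simulate"
        spec = config.phantom
        gt = generate_lv_ground_truth(spec)
        artifacts += write_dwi(gt.dwi, outdir / "gt_dwi.nii")
        artifacts.append(_save_map(gt.mask, spec.affine, outdir / "gt_mask.nii"))
        artifacts.append(_save_map(gt.ha, spec.affine, outdir / "gt_ha.nii"))

        stage = "degrade"
        deg = config.degradation
        rng = np.random.default_rng(config.seed)
        pert_cfg = config.perturb
        from .phantom import ORIENTATION_AXIS_ORDER

        stacks = []
        for o in deg.stack_orientations:
            pert = None
            if pert_cfg.fraction > 0:
                n_slices = spec.grid_shape[ORIENTATION_AXIS_ORDER[o][2]] // deg.slice_thickness_vox
                pert = {}
                for k in range(n_slices):
                    if rng.random() < pert_cfg.fraction:
                        pert[k] = np.concatenate([
                            rng.uniform(-pert_cfg.max_rot_deg, pert_cfg.max_rot_deg, 3),
                            rng.uniform(-pert_cfg.max_trans_mm, pert_cfg.max_trans_mm, 3),
                        ])
                pert = pert or None
            st = degrade_stack(gt, o, deg.inplane_crop_factor, deg.slice_thickness_vox,
                               deg.snr_lr, rng, slice_pose_params=pert)
            if pert is not None:
                st.slice_poses = None  # acquired geometry does not know the motion
            stacks.append(st)
            artifacts += write_stack(st, gt.dwi.protocol, outdir / f"stack_{o}.nii",
                                     extra_sidecar={"seed": config.seed})

        shape2, affine2 = recon_grid(spec, deg.inplane_crop_factor)

        stage = "register"
        if config.register_slices:
            from .registration import register_all

            geoms = [StackGeometry.from_stack(s, float(np.linalg.norm(affine2[:3, 0])))
                     for s in stacks]
            omega = domain_intersection(geoms, shape2, affine2)
            idx = np.argwhere(omega)
            w = idx @ affine2[:3, :3].T + affine2[:3, 3]
            omega_box = np.stack([w.min(axis=0), w.max(axis=0)])
            reg = register_all(stacks, omega_box, config.registration)
            poses_path = outdir / "poses.json"
            poses_path.write_text(json.dumps(
                {
                    "convention": "world-space 4x4 per slice; rotations intrinsic Z-Y-X "
                                  "about the slice FOV center; translations mm",
                    "poses": [p.tolist() for p in reg["poses"]],
                    "similarity_trajectory": reg["similarity_trajectory"],
                }, indent=2))
            artifacts.append(poses_path)

        stage = "reconstruct"
        geoms = [StackGeometry.from_stack(s, float(np.linalg.norm(affine2[:3, 0])))
                 for s in stacks]
        sr_data, logs = reconstruct_sr_series([s.data for s in stacks], geoms,
                                              config.recon, shape2, affine2)
        artifacts += write_dwi(
            DwiSeries(data=sr_data, protocol=gt.dwi.protocol, affine=affine2),
            outdir / "sr_dwi.nii",
        )
        log_path = outdir / "recon_log.csv"
        with open(log_path, "w") as fh:
            fh.write("channel,iter,objective,step,grad_norm\n")
            for c, log in enumerate(logs):
                for row in log:
                    fh.write(f"{c},{row['iter']},{row['objective']:.8e},"
                             f"{row['step']:.4e},{row['grad_norm']:.4e}\n")
        artifacts.append(log_path)

        stage = "fit"
        mask2, wf2, frames2, ha2, ta2 = lv_fields_on_grid(spec, shape2, affine2)
        res = fit_metrics(sr_data, gt.dwi.protocol, mask2, frames2)
        artifacts.append(_save_map(res["md"], affine2, outdir / "sr_md.nii"))
        artifacts.append(_save_map(res["fa"], affine2, outdir / "sr_fa.nii"))
        artifacts.append(_save_map(res["ha"], affine2, outdir / "sr_ha.nii"))
        artifacts.append(_save_map(res["ta"], affine2, outdir / "sr_ta.nii"))

        stage = "report"
        ana = config.analysis
        valid = mask2 & res["angles_valid"]
        curve, ha_mae = mae_by_slice(res["ha"], ha2, valid)
        profile = transmural_profile(res["ha"], wf2, valid, n_layers=ana.n_layers)
        report = {
            "seed": config.seed,
            "md_stats": eroded_mask_stats(res["md"], mask2, ana.erosion_vox),
            "fa_stats": eroded_mask_stats(res["fa"], mask2, ana.erosion_vox),
            "ta_stats": eroded_mask_stats(res["ta"], valid, ana.erosion_vox),
            "ha_mae_deg": ha_mae,
            "ha_mae_by_slice": [None if np.isnan(v) else v for v in curve],
            "ha_slope_deg_per_pct": profile.ha_slope_deg_per_pct,
        }
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2))
        artifacts.append(report_path)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {p.name: _sha256(p) for p in artifacts}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"manifest": manifest, "report": report, "outdir": str(outdir)}
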