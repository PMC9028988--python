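"""Shared fixtures: phantoms, degraded stacks and the full simulation study.

Heavy products (the full-scale strategy comparison, the registration
experiment) are session-scoped so several tests can share one run.
"""
from __future__ import annotations

import numpy as np
import pytest

from srcdti.cardiac_frames import helix_transverse_angles
from srcdti.forward_model import StackGeometry, domain_intersection
from srcdti.phantom import (
    DegradationSpec,
    HelixPhantomSpec,
    LvPhantomSpec,
    helix_local_frames,
    helix_roi_mask,
    make_helix_phantom,
    synthesize_dwi,
)
from srcdti.registration import RegistrationSettings
from srcdti.simulation import (
    degrade_stack,
    generate_lv_ground_truth,
    recon_grid,
    registration_experiment,
    simulate_comparison,
)
from srcdti.sr_recon import ReconConfig
from srcdti.tensor_fit import (
    DiffusionProtocol,
    eigen_decompose,
    fit_tensor,
    fractional_anisotropy,
    mean_diffusivity,
)


@pytest.fixture(scope="session")
def lv_small_spec():
    return LvPhantomSpec(grid_shape=(48, 48, 40), r_min=8, r_max=14, dr_max=6)


@pytest.fixture(scope="session")
def lv_small(lv_small_spec):
    return generate_lv_ground_truth(lv_small_spec)


@pytest.fixture(scope="session")
def lv_small_fit(lv_small):
    tensors = fit_tensor(lv_small.dwi, mask=lv_small.mask)
    eigs = eigen_decompose(tensors)
    angles = helix_transverse_angles(eigs.e1, lv_small.frames)
    return {
        "tensors": tensors,
        "eigs": eigs,
        "md": mean_diffusivity(eigs.eigenvalues),
        "fa": fractional_anisotropy(eigs.eigenvalues),
        "angles": angles,
    }


@pytest.fixture(scope="session")
def full_spec():
    """The numerical LV phantom at the reduced full-study grid."""
    return LvPhantomSpec(grid_shape=(96, 96, 80))


@pytest.fixture(scope="session")
def gt_full(full_spec):
    gt = generate_lv_ground_truth(full_spec)
    tensors = fit_tensor(gt.dwi, mask=gt.mask)
    eigs = eigen_decompose(tensors)
    angles = helix_transverse_angles(eigs.e1, gt.frames)
    return {
        "gt": gt,
        "eigs": eigs,
        "md": mean_diffusivity(eigs.eigenvalues),
        "angles": angles,
    }


@pytest.fixture(scope="session")
def full_sim(full_spec):
    """The three-strategy acquisition comparison at study conditions."""
    return simulate_comparison(
        full_spec, DegradationSpec(), ReconConfig(max_iters=150), seed=1
    )


@pytest.fixture(scope="session")
def helix_products():
    spec = HelixPhantomSpec()
    tensors, bundle, affine = make_helix_phantom(spec)
    protocol = DiffusionProtocol(
        bvals=np.concatenate([[0.0], np.full(6, 500.0)]),
        bvecs=np.concatenate(
            [np.zeros((1, 3)), DiffusionProtocol.dual_gradient(500.0).bvecs[1:]]
        ),
    )
    dwi = synthesize_dwi(tensors, protocol, s0=spec.s0, affine=affine)
    fitted = fit_tensor(dwi, mask=bundle)
    eigs = eigen_decompose(fitted)
    idx = np.argwhere(bundle)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    frames = helix_local_frames(world)
    angles = helix_transverse_angles(eigs.e1[bundle], frames)
    ha_map = np.zeros(bundle.shape)
    ha_map[bundle] = angles.ha_deg
    roi = helix_roi_mask(spec, bundle, affine)
    return {
        "spec": spec, "tensors": tensors, "bundle": bundle, "affine": affine,
        "dwi": dwi, "eigs": eigs, "ha_map": ha_map, "roi": roi,
    }


@pytest.fixture(scope="session")
def reg_spec():
    return LvPhantomSpec(grid_shape=(64, 64, 48), r_min=10, r_max=28, dr_max=8)


@pytest.fixture(scope="session")
def reg_stacks(reg_spec):
    """Noiseless aligned stacks plus Omega box for registration tests."""
    gt = generate_lv_ground_truth(reg_spec)
    rng = np.random.default_rng(0)
    stacks = [degrade_stack(gt, o, 2, 8, None, rng) for o in ("xy", "yz", "xz")]
    shape2, affine2 = recon_grid(reg_spec, 2)
    geoms = [StackGeometry.from_stack(s, 2.0) for s in stacks]
    omega = domain_intersection(geoms, shape2, affine2)
    idx = np.argwhere(omega)
    w = idx @ affine2[:3, :3].T + affine2[:3, 3]
    box = np.stack([w.min(axis=0), w.max(axis=0)])
    return {"gt": gt, "stacks": stacks, "omega_box": box}


@pytest.fixture(scope="session")
def reg_experiment_result(reg_spec):
    return registration_experiment(
        reg_spec, DegradationSpec(snr_lr=None), seed=3,
        settings=RegistrationSettings(n_outer=5),
    )


def ellipsoid_contours(a=16.0, c=60.0, center=(0.0, 0.0, 0.0)):
    """Five sparse contours (3 short-axis rings + 2 long-axis loops) of an
    apex-down half ellipsoid x^2/a^2 + y^2/a^2 + z^2/c^2 = 1, z <= 0."""
    cx, cy, cz = center

    def ring(z, n=40):
        r = a * np.sqrt(max(0.0, 1 - (z / c) ** 2))
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.stack(
            [cx + r * np.cos(th), cy + r * np.sin(th), np.full(n, cz + z)], axis=1
        )

    def lax(phi, n=60):
        t = np.linspace(-np.pi / 2, 0, n)
        p1 = np.stack([cx + a * np.cos(t) * np.cos(phi), cy + a * np.cos(t) * np.sin(phi),
                       cz + c * np.sin(t)], axis=1)
        p2 = np.stack([cx - a * np.cos(t) * np.cos(phi), cy - a * np.cos(t) * np.sin(phi),
                       cz + c * np.sin(t)], axis=1)
        return np.concatenate([p1, p2[::-1]])

    return [ring(-0.08 * c), ring(-0.4 * c), ring(-0.75 * c), lax(0.0), lax(np.pi / 2)]
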