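"""Slice-to-stack rigid registration by intersection-profile consistency."""
import numpy as np
import pytest

from srcdti.forward_model import SliceStack, rigid_matrix
from srcdti.registration import (
    RegistrationSettings,
    _pair_correlation,
    _slice_plane,
    intersection_line,
    pose_error,
    profile_similarity,
    register_slice,
)
from srcdti.simulation import degrade_stack


def make_plane(normal, point, shape=(20, 20), data=None):
    """SlicePlane with the given unit normal through the given point."""
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    # build in-plane axes
    a = np.array([1.0, 0, 0]) if abs(n[0]) < 0.9 else np.array([0, 1.0, 0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    aff = np.eye(4)
    aff[:3, 0], aff[:3, 1], aff[:3, 2] = u, v, n
    aff[:3, 3] = np.asarray(point, float) - aff[:3, :2] @ (np.array(shape) - 1) / 2.0
    if data is None:
        data = np.zeros(shape + (1,))
    from srcdti.registration import _SlicePlane

    return _SlicePlane(data, aff, thickness=1.0)


class TestIntersectionLine:
    def test_orthogonal_planes_meet_along_axis(self):
        a = make_plane([0, 0, 1], [0, 0, 0])
        b = make_plane([1, 0, 0], [0, 0, 0])
        pts = intersection_line(a, b, None, 0.5)
        assert pts is not None
        # the line z=0, x=0 runs along y
        assert np.abs(pts[:, 0]).max() < 1e-9
        assert np.abs(pts[:, 2]).max() < 1e-9
        assert np.ptp(pts[:, 1]) > 1.0

    def test_parallel_planes_return_none(self):
        a = make_plane([0, 0, 1], [0, 0, 0])
        b = make_plane([0, 0, 1], [0, 0, 5.0])
        assert intersection_line(a, b, None, 0.5) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_returned_points_lie_on_both_planes(self, seed):
        rng = np.random.default_rng(seed)
        a = make_plane(rng.normal(size=3), rng.normal(size=3))
        b = make_plane(rng.normal(size=3), rng.normal(size=3))
        pts = intersection_line(a, b, None, 0.5)
        if pts is None:
            return
        for plane in (a, b):
            d = (pts - plane.origin) @ plane.normal
            assert np.abs(d).max() <= 1e-9

    def test_omega_box_clips_segment(self):
        a = make_plane([0, 0, 1], [0, 0, 0])
        b = make_plane([1, 0, 0], [0, 0, 0])
        box = np.array([[-1.0, -2.0, -1.0], [1.0, 2.0, 1.0]])
        pts = intersection_line(a, b, box, 0.25)
        assert pts[:, 1].min() >= -2.0 and pts[:, 1].max() <= 2.0


class TestProfileSimilarity:
    def test_identical_thin_slices_correlate_perfectly(self, lv_small):
        # thin (1-voxel) noiseless slices sample the same ground truth, so
        # matched profiles must correlate to 1 at the aligned pose
        rng = np.random.default_rng(0)
        stacks = [degrade_stack(lv_small, o, 1, 1, None, rng) for o in ("xy", "yz")]
        fl = _slice_plane(stacks[0], 20)
        targets = [_slice_plane(stacks[1], i) for i in range(stacks[1].n_slices)]
        settings = RegistrationSettings(slab_taps=1)
        s = profile_similarity(np.zeros(6), fl, targets, None, settings)
        n_valid = sum(
            1 for t in targets
            if intersection_line(fl, t, None, 1.0) is not None
        )
        assert s >= 0.995 * n_valid * 0.5  # most pairs near-perfect
        assert s > 0

    def test_negated_profiles_give_minus_one(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(1, 50))
        assert _pair_correlation(p, -p) == pytest.approx(-1.0)

    def test_constant_profiles_skipped(self):
        rng = np.random.default_rng(2)
        varying = rng.normal(size=50)
        prof_a = np.stack([np.zeros(50), varying])
        prof_b = np.stack([np.ones(50), varying])
        r = _pair_correlation(prof_a, prof_b, sd_floor=1e-6)
        assert r == pytest.approx(1.0)  # the constant channel was dropped
        assert _pair_correlation(np.zeros((1, 50)), np.zeros((1, 50))) is None


class TestRegisterSlice:
    def test_aligned_slice_stays_near_identity(self, reg_stacks):
        stacks = reg_stacks["stacks"]
        tr = register_slice(stacks[0], 3, stacks[1:], reg_stacks["omega_box"])
        assert np.abs(tr.params[:3]).max() <= 0.5
        assert np.abs(tr.params[3:]).max() <= 0.75

    def test_planted_translation_recovered(self, reg_stacks):
        gt = reg_stacks["gt"]
        planted = np.array([0.0, 0.0, 0.0, 3.0, -2.0, 1.0])
        st_p = degrade_stack(gt, "xy", 2, 8, None, np.random.default_rng(1),
                             slice_pose_params={3: planted})
        p_mat = st_p.slice_poses[3].copy()
        st_p.slice_poses = None
        tr = register_slice(st_p, 3, reg_stacks["stacks"][1:],
                            reg_stacks["omega_box"])
        nominal = st_p.slice_affine(3)
        nx, ny = st_p.inplane_shape
        center = nominal[:3, :2] @ [(nx - 1) / 2, (ny - 1) / 2] + nominal[:3, 3]
        rot, trans = pose_error(tr.matrix @ np.linalg.inv(p_mat), np.eye(4),
                                point=center)
        assert trans < 0.75
        assert rot < 1.0

    def test_planted_pose_with_rotation_improves_alignment(self, reg_stacks):
        # rotations of a thick slab are near-unidentifiable from line
        # profiles; the contract is that the correction reduces the
        # slice-center displacement without inventing large rotations
        gt = reg_stacks["gt"]
        planted = np.array([2.0, 2.0, 0.0, 3.0, -2.0, 1.0])
        st_p = degrade_stack(gt, "xy", 2, 8, None, np.random.default_rng(1),
                             slice_pose_params={3: planted})
        p_mat = st_p.slice_poses[3].copy()
        st_p.slice_poses = None
        tr = register_slice(st_p, 3, reg_stacks["stacks"][1:],
                            reg_stacks["omega_box"])
        nominal = st_p.slice_affine(3)
        nx, ny = st_p.inplane_shape
        center = nominal[:3, :2] @ [(nx - 1) / 2, (ny - 1) / 2] + nominal[:3, 3]
        _, before = pose_error(p_mat, np.eye(4), point=center)
        _, after = pose_error(tr.matrix @ np.linalg.inv(p_mat), np.eye(4),
                              point=center)
        assert after < 0.5 * before
        assert np.abs(tr.params[:3]).max() <= 5.0

    def test_out_of_bounds_perturbation_clipped_to_bounds(self, reg_stacks):
        gt = reg_stacks["gt"]
        planted = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 12.0])  # beyond the 8 mm bound
        st_p = degrade_stack(gt, "xy", 2, 8, None, np.random.default_rng(2),
                             slice_pose_params={3: planted})
        p_mat = st_p.slice_poses[3].copy()
        st_p.slice_poses = None
        tr = register_slice(st_p, 3, reg_stacks["stacks"][1:],
                            reg_stacks["omega_box"])
        assert np.abs(tr.params[3:]).max() <= 8.0 + 1e-9
        nominal = st_p.slice_affine(3)
        nx, ny = st_p.inplane_shape
        center = nominal[:3, :2] @ [(nx - 1) / 2, (ny - 1) / 2] + nominal[:3, 3]
        _, resid = pose_error(tr.matrix @ np.linalg.inv(p_mat), np.eye(4),
                              point=center)
        assert resid >= 3.0  # residual misalignment remains and is reported

    def test_registration_translation_equivariance(self, reg_stacks):
        # shifting every stack by a common rigid offset leaves the
        # recovered relative corrections (approximately) unchanged
        stacks = reg_stacks["stacks"]
        tr0 = register_slice(stacks[0], 3, stacks[1:], reg_stacks["omega_box"])
        shift = np.eye(4)
        shift[:3, 3] = [2.0, -1.0, 1.5]
        moved = []
        for st in stacks:
            aff = shift @ st.affine
            moved.append(SliceStack(data=st.data, affine=aff,
                                    thickness_mm=st.thickness_mm,
                                    orientation=st.orientation))
        box = reg_stacks["omega_box"] + shift[:3, 3]
        tr1 = register_slice(moved[0], 3, moved[1:], box)
        assert np.abs(tr1.params - tr0.params).max() < 0.5


class TestRegisterAll:
    def test_planted_perturbations_recovered(self, reg_experiment_result):
        errors = reg_experiment_result["errors"]
        pert = [e for e in errors if e["perturbed"]]
        assert len(pert) >= 3
        assert np.median([e["rot_err_deg"] for e in pert]) < 1.0
        assert np.median([e["trans_err_mm"] for e in pert]) < 1.0

    def test_unperturbed_slices_left_nearly_alone(self, reg_experiment_result):
        rest = [e for e in reg_experiment_result["errors"] if not e["perturbed"]]
        assert np.median([e["rot_err_deg"] for e in rest]) < 0.5
        assert np.median([e["trans_err_mm"] for e in rest]) < 1.0

    def test_all_corrections_respect_bounds(self, reg_experiment_result):
        assert all(e["within_bounds"] for e in reg_experiment_result["errors"])

    def test_outer_iterations_stabilize(self, reg_experiment_result):
        changes = reg_experiment_result["registration"]["max_param_change"]
        assert len(changes) == 5
        assert changes[-1] < 0.1 * max(changes[0], 1e-9)

    def test_requires_two_stacks(self, reg_stacks):
        from srcdti.registration import register_all

        with pytest.raises(ValueError, match="two stacks"):
            register_all([reg_stacks["stacks"][0]], reg_stacks["omega_box"])
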