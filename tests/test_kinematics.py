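import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from handkin import (
    DegenerateBasisError,
    IncompleteFrameError,
    Recording,
    cardan_angles,
    compose_cardan,
    compute_joint_angle_series,
    default_skeleton,
    forward_kinematics,
    joint_rotation,
    orthonormalize,
    relative_rotation,
)
from handkin.kinematics import (
    BoneState,
    Frame,
    rotation_x,
    rotation_y,
    rotation_z,
    unwrap_degrees,
)

from conftest import random_rotations


# ---------------------------------------------------------------------------
# orthonormalize
# ---------------------------------------------------------------------------

class TestOrthonormalize:
    def test_identity(self):
        assert np.allclose(orthonormalize(np.eye(3)), np.eye(3), atol=1e-15)

    def test_idempotent_on_rotations(self):
        for rot in random_rotations(20, seed=1):
            assert np.abs(orthonormalize(rot) - rot).max() <= 1e-12

    def test_perturbed_rotation_recovered(self):
        # oracle: scipy's polar decomposition, computed independently
        rng = np.random.default_rng(2)
        for rot in random_rotations(20, seed=3):
            raw = rot + rng.uniform(-1e-3, 1e-3, size=(3, 3))
            fixed = orthonormalize(raw)
            u, _ = scipy.linalg.polar(raw)
            assert np.abs(fixed - u).max() <= 1e-12
            assert np.linalg.norm(fixed - rot) <= 2e-3

    def test_result_is_rotation(self):
        rng = np.random.default_rng(4)
        raw = np.eye(3) + rng.normal(0, 0.05, (3, 3))
        fixed = orthonormalize(raw)
        assert np.abs(fixed @ fixed.T - np.eye(3)).max() <= 1e-12
        assert np.linalg.det(fixed) == pytest.approx(1.0, abs=1e-12)

    def test_reflection_rejected(self):
        reflection = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(DegenerateBasisError):
            orthonormalize(reflection)

    def test_singular_rejected(self):
        with pytest.raises(DegenerateBasisError):
            orthonormalize(np.ones((3, 3)))

    def test_nonfinite_rejected(self):
        bad = np.eye(3)
        bad[0, 0] = np.nan
        with pytest.raises(DegenerateBasisError):
            orthonormalize(bad)


# ---------------------------------------------------------------------------
# relative_rotation / joint_rotation (the two matrix identities)
# ---------------------------------------------------------------------------

class TestRelativeRotation:
    def test_same_rotation_gives_identity(self):
        for rot in random_rotations(10, seed=5):
            assert np.abs(relative_rotation(rot, rot) - np.eye(3)).max() <= 1e-12

    def test_identity_reference_gives_transpose(self):
        for rot in random_rotations(10, seed=6):
            assert np.abs(relative_rotation(np.eye(3), rot) - rot.T).max() <= 1e-14

    def test_chain_property(self):
        # relative(t0,t1) @ relative(t1,t2) == relative(t0,t2), algebraically
        rots = random_rotations(3000, seed=7).reshape(1000, 3, 3, 3)
        worst = 0.0
        for r0, r1, r2 in rots:
            chained = relative_rotation(r0, r1) @ relative_rotation(r1, r2)
            direct = relative_rotation(r0, r2)
            worst = max(worst, np.abs(chained - direct).max())
        assert worst <= 1e-12

    def test_invalid_input_rejected(self):
        with pytest.raises(DegenerateBasisError):
            relative_rotation(np.eye(3) * 2.0, np.eye(3))


class TestJointRotation:
    def test_no_motion(self):
        assert np.abs(joint_rotation(np.eye(3), np.eye(3)) - np.eye(3)).max() == 0.0

    def test_rigid_corotation_cancels(self):
        for rot in random_rotations(10, seed=8):
            assert np.abs(joint_rotation(rot, rot) - np.eye(3)).max() <= 1e-12

    def test_parent_fixed_child_x_rotation(self):
        # direct substitution: joint = I @ (Rx)^T
        rx = rotation_x(37.0)
        assert np.abs(joint_rotation(np.eye(3), rx) - rx.T).max() <= 1e-15


# ---------------------------------------------------------------------------
# cardan_angles
# ---------------------------------------------------------------------------

class TestCardanAngles:
    def test_identity(self):
        assert cardan_angles(np.eye(3)) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("alpha", [-179.0, -90.0, -10.0, 10.0, 45.0, 179.0])
    def test_pure_flexion(self, alpha):
        phi, theta, psi = cardan_angles(rotation_x(alpha))
        assert phi == pytest.approx(alpha, abs=1e-9)
        assert theta == pytest.approx(0.0, abs=1e-9)
        assert psi == pytest.approx(0.0, abs=1e-9)

    def test_composed_rotation_recovered(self):
        # oracle: numeric composition of elementary matrices via scipy
        oracle = (Rotation.from_euler("x", 10, degrees=True)
                  * Rotation.from_euler("y", 20, degrees=True)
                  * Rotation.from_euler("z", 30, degrees=True)).as_matrix()
        phi, theta, psi = cardan_angles(oracle)
        assert phi == pytest.approx(10.0, abs=1e-9)
        assert theta == pytest.approx(20.0, abs=1e-9)
        assert psi == pytest.approx(30.0, abs=1e-9)

    def test_matches_scipy_euler_xyz(self):
        for rot in random_rotations(200, seed=9):
            ours = np.array(cardan_angles(rot))
            theirs = Rotation.from_matrix(rot).as_euler("XYZ", degrees=True)
            if abs(abs(ours[1]) - 90.0) < 1e-6:
                continue  # gimbal tie-break conventions may differ
            assert np.abs(ours - theirs).max() <= 1e-8

    def test_recompose_round_trip_seeded(self):
        # 1000 seeded triples with |theta| < 85 deg
        rng = np.random.default_rng(10)
        phis = rng.uniform(-179, 179, 1000)
        thetas = rng.uniform(-85, 85, 1000)
        psis = rng.uniform(-179, 179, 1000)
        for phi, theta, psi in zip(phis, thetas, psis):
            back = cardan_angles(compose_cardan(phi, theta, psi))
            assert np.abs(np.array(back) - (phi, theta, psi)).max() <= 1e-9

    def test_recompose_frobenius(self):
        for rot in random_rotations(1000, seed=11):
            phi, theta, psi = cardan_angles(rot)
            if abs(theta) >= 85.0:
                continue
            assert np.linalg.norm(compose_cardan(phi, theta, psi) - rot) <= 1e-9

    def test_gimbal_lock_tie_break(self):
        # theta = +/-90: psi is set to 0 and the residual folded into phi,
        # but the recomposed matrix must still match
        for sign in (1.0, -1.0):
            mat = rotation_x(25.0) @ rotation_y(sign * 90.0) @ rotation_z(40.0)
            phi, theta, psi = cardan_angles(mat)
            assert psi == 0.0
            assert theta == pytest.approx(sign * 90.0, abs=1e-9)
            assert np.linalg.norm(compose_cardan(phi, theta, psi) - mat) <= 1e-9

    @given(
        phi=st.floats(-179.0, 179.0),
        theta=st.floats(-85.0, 85.0),
        psi=st.floats(-179.0, 179.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_property(self, phi, theta, psi):
        back = cardan_angles(compose_cardan(phi, theta, psi))
        assert np.abs(np.array(back) - (phi, theta, psi)).max() <= 1e-9


# ---------------------------------------------------------------------------
# compute_joint_angle_series
# ---------------------------------------------------------------------------

def _static_recording(skeleton, n=5):
    ref = skeleton.reference_posture()
    frames = []
    for i in range(n):
        states = {b: BoneState(bone=b, position=ref.positions[b].copy(),
                               basis=ref.bases[b].copy())
                  for b in skeleton.bones}
        frames.append(Frame(index=i, time_s=i / 60.0, states=states))
    return Recording(skeleton=skeleton, frames=frames, frame_rate=60.0)


class TestJointAngleSeries:
    def test_static_recording_all_zero(self, skeleton):
        series = compute_joint_angle_series(_static_recording(skeleton))
        for s in series:
            assert np.abs(s.angles).max() <= 1e-9

    def test_frame0_is_zero_with_default_reference(self, fist_series):
        for s in fist_series:
            assert np.abs(s.angles[0]).max() <= 1e-9

    def test_round_trip_recovers_fist(self, fist_trajectories, fist_series):
        for s in fist_series:
            truth = fist_trajectories.get(s.joint.name)
            expected = truth.angles if truth is not None else np.zeros_like(s.angles)
            assert np.abs(s.angles - expected).max() < 1e-6

    def test_rigid_global_motion_cancels(self, skeleton):
        # rigidly rotate+translate every bone state of every frame
        rec = _static_recording(skeleton, n=2)
        wobble = Rotation.from_euler("XYZ", [31.0, -12.0, 77.0], degrees=True).as_matrix()
        shift = np.array([10.0, -5.0, 3.0])
        for frame in rec.frames:
            for b, st_ in frame.states.items():
                st_.position = wobble @ st_.position + shift
                st_.basis = st_.basis @ wobble.T
        series = compute_joint_angle_series(rec)
        for s in series:
            assert np.abs(s.angles).max() <= 1e-9

    def test_missing_bone_state_names_frame_and_bone(self, skeleton):
        rec = _static_recording(skeleton, n=3)
        del rec.frames[1].states["proximal2"]
        with pytest.raises(IncompleteFrameError, match="frame 1.*proximal2"):
            Recording(skeleton=skeleton, frames=rec.frames, frame_rate=60.0)

    def test_explicit_reference_posture(self, skeleton):
        # a recording that starts mid-flexion still yields zero angles at
        # frame 0 of... the flat reference, not the first frame
        ramp = np.zeros((4, 3))
        ramp[:, 0] = [20.0, 30.0, 40.0, 50.0]
        rec = forward_kinematics(skeleton, {"pip2": ramp}, 60.0)
        series = compute_joint_angle_series(rec, reference=skeleton.reference_posture())
        pip2 = next(s for s in series if s.joint.name == "pip2")
        assert pip2.angles[:, 0] == pytest.approx([20, 30, 40, 50], abs=1e-9)

    def test_unwrapped_no_big_jumps(self, skeleton):
        # a psi sweep crossing the +/-180 branch cut must come out continuous
        sweep = np.zeros((40, 3))
        sweep[:, 2] = np.linspace(0.0, 300.0, 40)
        rec = forward_kinematics(skeleton, {"cmc1": sweep}, 60.0)
        series = compute_joint_angle_series(rec)
        for s in series:
            assert np.all(np.isfinite(s.angles))
            assert np.abs(np.diff(s.angles, axis=0)).max() < 180.0
        cmc1 = next(s for s in series if s.joint.name == "cmc1")
        assert cmc1.angles[-1, 2] == pytest.approx(300.0, abs=1e-6)


def test_unwrap_degrees_removes_wraps():
    wrapped = np.array([[170.0], [-170.0], [-150.0]])
    out = unwrap_degrees(wrapped)
    assert out[:, 0] == pytest.approx([170.0, 190.0, 210.0])
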