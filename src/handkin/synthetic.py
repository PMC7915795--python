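"""Forward-kinematics motion generator standing in for the hardware sensor.

Produces :class:`~handkin.kinematics.Recording` objects with known
ground-truth joint-angle trajectories.  The generator and the extractor in
:mod:`handkin.kinematics` share one convention — a child bone's stored
basis is the parent's stored basis right-multiplied by the joint rotation
``Rx(phi) @ Ry(theta) @ Rz(psi)`` — so extraction recovers the input
trajectories exactly (up to floating point) in the noise-free case.

Bone positions propagate distally along each bone's local Z axis; the
recorded position of a bone is its distal joint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np

from .errors import FrameCountMismatchError, HandkinError
from .kinematics import BoneState, Frame, Recording, compose_cardan, orthonormalize
from .skeleton import DIGITS, HandSkeleton, JointId, joints_of

__all__ = ["AngleTrajectory", "NoiseSpec", "forward_kinematics", "fist_scenario", "add_noise"]

#: |theta| limit keeping trajectories clear of gimbal lock
THETA_LIMIT_DEG = 90.0


@dataclass
class AngleTrajectory:
    """Per-frame target Cardan triples (degrees) for one joint."""

    joint: str  # joint name, e.g. "pip2"
    angles: np.ndarray  # (n_frames, 3)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != 3:
            raise HandkinError("trajectory angles must be (n_frames, 3)")
        if self.angles.shape[0] < 2:
            raise HandkinError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.angles)):
            raise HandkinError("trajectory angles must be finite")
        if np.any(np.abs(self.angles[:, 1]) > THETA_LIMIT_DEG):
            raise HandkinError(
                f"|theta| must stay <= {THETA_LIMIT_DEG} deg to avoid gimbal lock")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]


@dataclass(frozen=True)
class NoiseSpec:
    """Synthetic sensor-noise model: small random rotation per bone per frame
    (axis uniform on the sphere, angle ``|Normal(0, orientation_sigma)|``)
    plus isotropic Gaussian position jitter."""

    orientation_sigma_deg: float = 0.0
    position_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.orientation_sigma_deg < 0 or self.position_sigma_mm < 0:
            raise HandkinError("noise sigmas must be >= 0")


TrajectoryMap = Mapping[str, Union[AngleTrajectory, np.ndarray]]


def _as_angle_array(value: Union[AngleTrajectory, np.ndarray]) -> np.ndarray:
    if isinstance(value, AngleTrajectory):
        return value.angles
    return AngleTrajectory(joint="", angles=np.asarray(value, dtype=float)).angles


def forward_kinematics(
    skeleton: HandSkeleton,
    trajectories: TrajectoryMap,
    frame_rate: float,
    root_position=(0.0, 0.0, 0.0),
) -> Recording:
    """Compose per-frame bone states from joint-angle trajectories.

    Joints absent from ``trajectories`` stay at zero.  All supplied
    trajectories must agree on the frame count.
    """
    if frame_rate <= 0:
        raise HandkinError("frame_rate must be > 0")
    joints = joints_of(skeleton)
    known = {j.name: j for j in joints}
    for name in trajectories:
        if name not in known:
            raise HandkinError(f"unknown joint '{name}' in trajectories")

    arrays = {name: _as_angle_array(t) for name, t in trajectories.items()}
    counts = {a.shape[0] for a in arrays.values()}
    if len(counts) > 1:
        raise FrameCountMismatchError(f"trajectories disagree on frame count: {sorted(counts)}")
    if not counts:
        raise HandkinError("at least one trajectory is required")
    n = counts.pop()

    zero = np.zeros((n, 3))
    joint_of_child = {j.child_bone: j for j in joints}
    root = np.asarray(root_position, dtype=float)

    frames: list[Frame] = []
    for i in range(n):
        states: dict[str, BoneState] = {}
        bases: dict[str, np.ndarray] = {}
        positions: dict[str, np.ndarray] = {}
        for bone in skeleton.bones:
            parent = skeleton.parents[bone]
            parent_basis = np.eye(3) if parent is None else bases[parent]
            joint = joint_of_child.get(bone)
            if joint is None:
                rot = np.eye(3)  # rigid link (hand -> metacarpal)
            else:
                phi, theta, psi = arrays.get(joint.name, zero)[i]
                rot = compose_cardan(phi, theta, psi)
            basis = parent_basis @ rot
            start = root if parent is None else positions[parent]
            # local Z (row 2 of the stored basis) points distally
            pos = start + skeleton.lengths_mm[bone] * basis[2, :]
            bases[bone] = basis
            positions[bone] = pos
            states[bone] = BoneState(bone=bone, position=pos, basis=basis)
        frames.append(Frame(index=i, time_s=i / frame_rate, states=states))
    return Recording(skeleton=skeleton, frames=frames, frame_rate=frame_rate)


def _cosine_ramp(n_frames: int, peak_deg: float) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n_frames)
    return peak_deg * 0.5 * (1.0 - np.cos(np.pi * u))


def fist_scenario(skeleton: HandSkeleton, n_frames: int,
                  peak_flexion_deg: float = 100.0) -> dict[str, AngleTrajectory]:
    """Outstretched hand closing to a fist: cosine-eased simultaneous flexion.

    Finger PIP joints ramp 0 -> ``peak_flexion_deg``; MCP joints to 0.9x
    and DIP joints to 0.7x of it.  The thumb performs an opposition ramp
    (CMC flexion/abduction/rotation plus MCP/IP flexion).  Peak angles are
    placeholders — no quantitative per-joint fist trajectory is published
    for the validation motion this mimics.
    """
    if n_frames < 2:
        raise HandkinError("n_frames must be >= 2")
    if not (0.0 < peak_flexion_deg <= 110.0):
        raise HandkinError("peak flexion must be in (0, 110] degrees")

    def traj(name: str, phi_peak: float, theta_peak: float = 0.0,
             psi_peak: float = 0.0) -> AngleTrajectory:
        angles = np.zeros((n_frames, 3))
        angles[:, 0] = _cosine_ramp(n_frames, phi_peak)
        angles[:, 1] = _cosine_ramp(n_frames, theta_peak)
        angles[:, 2] = _cosine_ramp(n_frames, psi_peak)
        return AngleTrajectory(joint=name, angles=angles)

    out: dict[str, AngleTrajectory] = {}
    for d in DIGITS[1:]:  # fingers 2..5
        out[f"mcp{d}"] = traj(f"mcp{d}", 0.9 * peak_flexion_deg)
        out[f"pip{d}"] = traj(f"pip{d}", peak_flexion_deg)
        out[f"dip{d}"] = traj(f"dip{d}", 0.7 * peak_flexion_deg)
    # thumb opposition
    out["cmc1"] = traj("cmc1", 0.35 * peak_flexion_deg, 0.2 * peak_flexion_deg,
                       0.15 * peak_flexion_deg)
    out["mcp1"] = traj("mcp1", 0.4 * peak_flexion_deg, 0.1 * peak_flexion_deg)
    out["ip1"] = traj("ip1", 0.5 * peak_flexion_deg)
    return out


def add_noise(recording: Recording, spec: NoiseSpec) -> Recording:
    """Perturb bases by small random rotations and jitter positions.

    Reproducible from ``spec.seed``; zero sigmas return an identical copy.
    """
    if spec.orientation_sigma_deg == 0.0 and spec.position_sigma_mm == 0.0:
        frames = [Frame(index=f.index, time_s=f.time_s,
                        states={b: BoneState(bone=b, position=s.position.copy(),
                                             basis=s.basis.copy())
                                for b, s in f.states.items()})
                  for f in recording.frames]
        return Recording(skeleton=recording.skeleton, frames=frames,
                         frame_rate=recording.frame_rate)

    rng = np.random.default_rng(spec.seed)
    frames = []
    for f in recording.frames:
        states = {}
        for bone in recording.skeleton.bones:
            st = f.states[bone]
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = abs(rng.normal(0.0, np.radians(spec.orientation_sigma_deg)))
            k = np.array([[0.0, -axis[2], axis[1]],
                          [axis[2], 0.0, -axis[0]],
                          [-axis[1], axis[0], 0.0]])
            rot = np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)
            basis = orthonormalize(st.basis @ rot)
            position = st.position + rng.normal(0.0, spec.position_sigma_mm, size=3) \
                if spec.position_sigma_mm > 0 else st.position.copy()
            states[bone] = BoneState(bone=bone, position=position, basis=basis)
        frames.append(Frame(index=f.index, time_s=f.time_s, states=states))
    return Recording(skeleton=recording.skeleton, frames=frames,
                     frame_rate=recording.frame_rate)
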