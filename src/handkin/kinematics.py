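"""Core rotation algebra and Cardan joint-angle extraction.

A bone's orientation is stored as a 3x3 orthonormal *basis* whose **rows**
are the bone's local axis vectors (x: flexion axis, y: abduction axis,
z: longitudinal axis) expressed in the global frame.

Given stored bases ``B(t0)`` and ``B(ti)`` of one bone, the rotation of the
bone between the reference time and time ``ti`` is ``B(t0) @ B(ti).T``
(:func:`relative_rotation`).  The rotation in a joint, relative to the
neutral-zero posture, is ``parent_rel @ child_rel.T``
(:func:`joint_rotation`).  Cardan angles (phi, theta, psi) are extracted
from that matrix under the fixed intrinsic X-Y-Z factorization

    R = Rx(phi) @ Ry(theta) @ Rz(psi)

so phi is flexion/extension, theta abduction/adduction and psi axial
rotation.  The synthetic generator composes bases with exactly this
factorization (``B_child = B_parent @ R``), which makes
generation/extraction an exact round trip.

Angles are degrees everywhere.  ``AXIS_SIGNS`` maps the algebraic sign of
the factorization to the physiological sign convention (flexion of a
finger, i.e. curling towards the palm, is positive); with the default
``(+1, +1, +1)`` the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    DegenerateBasisError,
    FrameCountMismatchError,
    HandkinError,
    IncompleteFrameError,
)
from .skeleton import HandSkeleton, JointId, ReferencePosture, joints_of

__all__ = [
    "AXIS_SIGNS",
    "ORTHONORMAL_TOL",
    "INGEST_TOL",
    "CardanTriple",
    "BoneState",
    "Frame",
    "Recording",
    "JointAngleSeries",
    "rotation_x",
    "rotation_y",
    "rotation_z",
    "compose_cardan",
    "cardan_angles",
    "is_rotation",
    "orthonormalize",
    "relative_rotation",
    "joint_rotation",
    "compute_joint_angle_series",
    "unwrap_degrees",
]

#: physiological sign of (phi, theta, psi) relative to the algebraic factorization
AXIS_SIGNS = (1.0, 1.0, 1.0)

#: tolerance for accepting a matrix as a rotation in the core algebra
ORTHONORMAL_TOL = 1e-6
#: looser tolerance applied when ingesting (possibly noisy) recorded bases
INGEST_TOL = 1e-3

_GIMBAL_EPS = 1e-12


class CardanTriple(tuple):
    """(phi, theta, psi) in degrees; phi,psi in (-180,180], theta in [-90,90]."""

    __slots__ = ()

    def __new__(cls, phi: float, theta: float, psi: float):
        return super().__new__(cls, (float(phi), float(theta), float(psi)))

    @property
    def phi(self) -> float:
        return self[0]

    @property
    def theta(self) -> float:
        return self[1]

    @property
    def psi(self) -> float:
        return self[2]


# ---------------------------------------------------------------------------
# elementary rotations and Cardan factorization
# ---------------------------------------------------------------------------

def rotation_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def compose_cardan(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rx(phi) @ Ry(theta) @ Rz(psi), angles in degrees (physiological signs)."""
    sx, sy, sz = AXIS_SIGNS
    return rotation_x(sx * phi) @ rotation_y(sy * theta) @ rotation_z(sz * psi)


def _cardan_batch(mats: np.ndarray) -> np.ndarray:
    """Vectorized Cardan extraction; mats (n,3,3) -> angles (n,3) degrees."""
    m02 = np.clip(mats[:, 0, 2], -1.0, 1.0)
    theta = np.arcsin(m02)
    phi = np.arctan2(-mats[:, 1, 2], mats[:, 2, 2])
    psi = np.arctan2(-mats[:, 0, 1], mats[:, 0, 0])
    locked = np.abs(m02) > 1.0 - _GIMBAL_EPS
    if np.any(locked):
        # |theta| = 90 deg: only phi +/- psi is defined; set psi = 0 and
        # fold the residual rotation into phi.
        folded = np.arctan2(mats[:, 1, 0], mats[:, 1, 1])
        phi = np.where(locked, np.sign(m02) * folded, phi)
        psi = np.where(locked, 0.0, psi)
    out = np.degrees(np.stack([phi, theta, psi], axis=1))
    out /= np.asarray(AXIS_SIGNS)
    return out


def cardan_angles(rotation: np.ndarray, validate: bool = True) -> CardanTriple:
    """Extract (phi, theta, psi) degrees from a rotation matrix.

    Inverse of :func:`compose_cardan` for |theta| < 90 deg; at gimbal lock
    psi is set to zero and the residual folded into phi.
    """
    rotation = np.asarray(rotation, dtype=float)
    if validate:
        _require_rotation(rotation, ORTHONORMAL_TOL)
    phi, theta, psi = _cardan_batch(rotation[None, :, :])[0]
    return CardanTriple(phi, theta, psi)


# ---------------------------------------------------------------------------
# rotation-matrix hygiene
# ---------------------------------------------------------------------------

def is_rotation(matrix: np.ndarray, tol: float = ORTHONORMAL_TOL) -> bool:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3) or not np.all(np.isfinite(matrix)):
        return False
    if np.abs(matrix @ matrix.T - np.eye(3)).max() > tol:
        return False
    return abs(np.linalg.det(matrix) - 1.0) <= tol


def _require_rotation(matrix: np.ndarray, tol: float) -> None:
    if not is_rotation(matrix, tol):
        raise DegenerateBasisError(
            "matrix is not orthonormal with determinant +1 within tolerance"
        )


def orthonormalize(raw: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix to ``raw`` in the Frobenius/polar sense.

    Idempotent on valid rotations.  Raises :class:`DegenerateBasisError`
    for singular or reflecting input.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (3, 3) or not np.all(np.isfinite(raw)):
        raise DegenerateBasisError("expected a finite 3x3 matrix")
    u, s, vt = np.linalg.svd(raw)
    if s[-1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateBasisError("singular basis cannot be orthonormalized")
    rot = u @ vt
    if np.linalg.det(rot) <= 0:
        raise DegenerateBasisError("basis has negative determinant (reflection)")
    return rot


def relative_rotation(r_ref: np.ndarray, r_now: np.ndarray,
                      validate: bool = True) -> np.ndarray:
    """Rotation of a bone from the reference pose: ``r_ref @ r_now.T``."""
    r_ref = np.asarray(r_ref, dtype=float)
    r_now = np.asarray(r_now, dtype=float)
    if validate:
        _require_rotation(r_ref, ORTHONORMAL_TOL)
        _require_rotation(r_now, ORTHONORMAL_TOL)
    return r_ref @ r_now.T


def joint_rotation(parent_rel: np.ndarray, child_rel: np.ndarray,
                   validate: bool = True) -> np.ndarray:
    """Joint rotation relative to neutral-zero: ``parent_rel @ child_rel.T``.

    Both arguments are reference-relative rotations of the parent and
    child bone (outputs of :func:`relative_rotation`).
    """
    parent_rel = np.asarray(parent_rel, dtype=float)
    child_rel = np.asarray(child_rel, dtype=float)
    if validate:
        _require_rotation(parent_rel, ORTHONORMAL_TOL)
        _require_rotation(child_rel, ORTHONORMAL_TOL)
    return parent_rel @ child_rel.T


# ---------------------------------------------------------------------------
# recording containers
# ---------------------------------------------------------------------------

@dataclass
class BoneState:
    """Position (mm, global frame, distal joint of the bone) plus basis.

    The basis is orthonormalized on construction; input more than
    ``INGEST_TOL`` away from a rotation is rejected.
    """

    bone: str
    position: np.ndarray
    basis: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        basis = np.asarray(self.basis, dtype=float)
        if basis.shape != (3, 3):
            raise DegenerateBasisError(f"bone '{self.bone}': basis must be 3x3")
        if is_rotation(basis, 1e-9):
            self.basis = basis  # already clean: keep bit-for-bit
        elif is_rotation(basis, INGEST_TOL):
            self.basis = orthonormalize(basis)
        else:
            raise DegenerateBasisError(
                f"bone '{self.bone}': basis is not orthonormal within {INGEST_TOL}"
            )


@dataclass
class Frame:
    """One time step: a BoneState per skeleton bone."""

    index: int
    time_s: float
    states: dict[str, BoneState]


@dataclass
class Recording:
    """A time-sequence of frames over one skeleton at a fixed frame rate."""

    skeleton: HandSkeleton
    frames: list[Frame]
    frame_rate: float

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise HandkinError("frame_rate must be > 0")
        if len(self.frames) < 2:
            raise HandkinError("a recording needs at least 2 frames")
        for frame in self.frames:
            for bone in self.skeleton.bones:
                if bone not in frame.states:
                    raise IncompleteFrameError(frame.index, bone)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])

    def basis_array(self, bone: str) -> np.ndarray:
        """(n,3,3) stacked bases of one bone across frames."""
        return np.stack([f.states[bone].basis for f in self.frames])

    def position_array(self, bone: str) -> np.ndarray:
        """(n,3) stacked positions of one bone across frames."""
        return np.stack([f.states[bone].position for f in self.frames])


@dataclass
class JointAngleSeries:
    """Per-frame Cardan triples (degrees) of one joint, reference-relative."""

    joint: JointId
    angles: np.ndarray  # (n_frames, 3) columns = (phi, theta, psi)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != 3:
            raise HandkinError("angles must be (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def phi(self) -> np.ndarray:
        return self.angles[:, 0]

    @property
    def theta(self) -> np.ndarray:
        return self.angles[:, 1]

    @property
    def psi(self) -> np.ndarray:
        return self.angles[:, 2]


def unwrap_degrees(angles: np.ndarray) -> np.ndarray:
    """Remove +/-360 deg jumps along axis 0 (per-series phase unwrap)."""
    return np.unwrap(np.asarray(angles, dtype=float), axis=0, period=360.0)


def compute_joint_angle_series(
    recording: Recording,
    reference: Optional[ReferencePosture] = None,
    unwrap: bool = True,
) -> list[JointAngleSeries]:
    """Joint-angle time series for every articulated joint of the skeleton.

    For each joint and frame i the angles are
    ``cardan_angles(joint_rotation(relative_rotation(Rp(t0), Rp(ti)),
    relative_rotation(Rc(t0), Rc(ti))))`` where t0 is frame 0 unless an
    explicit ``reference`` posture is given.  Series are unwrapped across
    frames so no consecutive step exceeds 180 deg.
    """
    skeleton = recording.skeleton
    bases = {b: recording.basis_array(b) for b in skeleton.bones}
    if reference is None:
        ref = {b: bases[b][0] for b in skeleton.bones}
    else:
        ref = {}
        for b in skeleton.bones:
            if b not in reference.bases:
                raise HandkinError(f"reference posture is missing bone '{b}'")
            ref[b] = np.asarray(reference.bases[b], dtype=float)

    n = recording.n_frames
    rel = {}
    for b in skeleton.bones:
        # relative_rotation, vectorized over frames
        rel[b] = ref[b] @ bases[b].transpose(0, 2, 1)
    identity_rel = np.broadcast_to(np.eye(3), (n, 3, 3))

    out: list[JointAngleSeries] = []
    for joint in joints_of(skeleton):
        parent_rel = identity_rel if joint.parent_bone is None else rel[joint.parent_bone]
        child_rel = rel[joint.child_bone]
        mats = parent_rel @ child_rel.transpose(0, 2, 1)
        angles = _cardan_batch(mats)
        if unwrap:
            angles = unwrap_degrees(angles)
        out.append(JointAngleSeries(joint=joint, angles=angles))
    return out
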