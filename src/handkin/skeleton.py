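"""Hand skeleton topology, joint definitions and the neutral-zero reference posture.

The skeleton is a tree rooted at the forearm::

    forearm -> hand -> metacarpal(d) -> proximal(d) -> intermediate(d) -> distal(d)

for each digit d in 1..5 (1=thumb, 2=index, 3=middle, 4=ring, 5=pinky),
22 bones in total.  Every bone carries a length in millimetres; the thumb
metacarpal may have length zero (the sensor's internal hand model uses a
zero-length thumb metacarpal, so the thumb is kept on the same four-bone
chain as the other digits).

Coordinate convention (used throughout the package): right-handed frames
with X the flexion/extension axis, Y the abduction/adduction axis and Z the
longitudinal axis of the bone pointing distally.  In the neutral-zero
reference posture every bone basis is the identity, so all relative joint
rotations are the identity by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .errors import HandkinError, RecordingParseError

__all__ = [
    "FOREARM",
    "HAND",
    "DIGITS",
    "DIGIT_NAMES",
    "BONE_PARTS",
    "DOF_FLEXION",
    "DOF_ABDUCTION",
    "DOF_ROTATION",
    "JointId",
    "HandSkeleton",
    "ReferencePosture",
    "bone_name",
    "default_skeleton",
    "joints_of",
]

FOREARM = "forearm"
HAND = "hand"
DIGITS = (1, 2, 3, 4, 5)
DIGIT_NAMES = {1: "thumb", 2: "index", 3: "middle", 4: "ring", 5: "pinky"}
#: chain order within one digit, proximal to distal
BONE_PARTS = ("metacarpal", "proximal", "intermediate", "distal")

DOF_FLEXION = "flexion"
DOF_ABDUCTION = "abduction"
DOF_ROTATION = "rotation"
#: column order of a Cardan triple (phi, theta, psi) <-> (X, Y, Z)
DOF_ORDER = (DOF_FLEXION, DOF_ABDUCTION, DOF_ROTATION)


def bone_name(part: str, digit: int) -> str:
    """Canonical bone identifier for a digit segment, e.g. ``proximal2``."""
    if part not in BONE_PARTS:
        raise HandkinError(f"unknown bone part '{part}'")
    if digit not in DIGITS:
        raise HandkinError(f"digit must be 1..5, got {digit}")
    return f"{part}{digit}"


@dataclass(frozen=True)
class JointId:
    """A named joint between ``parent_bone`` and ``child_bone``.

    ``parent_bone`` is ``None`` only for the elbow, whose parent segment
    (the upper arm) is not tracked and stands in for the global frame.
    ``dof_mask`` lists the anatomically enabled degrees of freedom as a
    subset of ``(flexion, abduction, rotation)`` in that fixed order.
    """

    name: str
    child_bone: str
    parent_bone: Optional[str]
    dof_mask: tuple[str, ...]

    def __post_init__(self):
        for dof in self.dof_mask:
            if dof not in DOF_ORDER:
                raise HandkinError(f"unknown dof '{dof}' in joint {self.name}")

    @property
    def digit(self) -> Optional[int]:
        """Digit number 1..5 for digit joints, None for elbow/wrist."""
        tail = self.child_bone[-1]
        return int(tail) if tail.isdigit() else None


# default segment lengths in mm for scale=1.0 (plausible adult right hand);
# digit entries are (metacarpal, proximal, intermediate, distal)
_DEFAULT_LENGTHS_MM = {
    FOREARM: 250.0,
    HAND: 80.0,
    1: (0.0, 46.0, 32.0, 24.0),
    2: (65.0, 40.0, 25.0, 18.0),
    3: (62.0, 45.0, 28.0, 19.0),
    4: (58.0, 42.0, 27.0, 19.0),
    5: (54.0, 33.0, 20.0, 17.0),
}


@dataclass
class HandSkeleton:
    """Bone tree with per-segment lengths.

    ``bones`` is ordered parent-before-child and is the canonical traversal
    order for every module in the package.
    """

    handedness: str
    bones: tuple[str, ...]
    parents: dict[str, Optional[str]] = field(repr=False)
    lengths_mm: dict[str, float] = field(repr=False)

    def __post_init__(self):
        if self.handedness not in ("left", "right"):
            raise HandkinError(f"handedness must be left|right, got '{self.handedness}'")
        if not self.bones or self.bones[0] != FOREARM:
            raise HandkinError("skeleton must be rooted at the forearm")
        seen: set[str] = set()
        for b in self.bones:
            parent = self.parents.get(b)
            if b == FOREARM:
                if parent is not None:
                    raise HandkinError("forearm is the root and has no parent")
            else:
                if parent is None or parent not in seen:
                    raise HandkinError(f"bone '{b}' must appear after its parent")
            if b in seen:
                raise HandkinError(f"duplicate bone '{b}'")
            seen.add(b)
            length = self.lengths_mm.get(b)
            if length is None:
                raise HandkinError(f"missing length for bone '{b}'")
            if b == bone_name("metacarpal", 1):
                if length < 0:
                    raise HandkinError("thumb metacarpal length must be >= 0")
            elif length <= 0:
                raise HandkinError(f"length of '{b}' must be > 0")

    def parent(self, bone: str) -> Optional[str]:
        return self.parents[bone]

    def children(self, bone: str) -> tuple[str, ...]:
        return tuple(b for b in self.bones if self.parents.get(b) == bone)

    def digit_bones(self, digit: int) -> tuple[str, ...]:
        """The four-bone chain of one digit, proximal to distal."""
        return tuple(bone_name(p, digit) for p in BONE_PARTS)

    # ---- reference posture ------------------------------------------------

    def reference_posture(self, root_position=(0.0, 0.0, 0.0)) -> "ReferencePosture":
        """Neutral-zero posture: identity bases, bones chained along +Z.

        Positions are the *distal* joint locations of each bone (the
        convention used by recordings), propagated from ``root_position``
        (the elbow) along the longitudinal axis.
        """
        bases = {b: np.eye(3) for b in self.bones}
        positions: dict[str, np.ndarray] = {}
        root = np.asarray(root_position, dtype=float)
        for b in self.bones:
            p = self.parents[b]
            start = root if p is None else positions[p]
            positions[b] = start + np.array([0.0, 0.0, self.lengths_mm[b]])
        return ReferencePosture(bases=bases, positions=positions)

    # ---- serialization ----------------------------------------------------

    def to_text(self) -> str:
        """Plain-text skeleton definition: one ``bone name parent length`` per line."""
        lines = [f"handedness {self.handedness}"]
        for b in self.bones:
            parent = self.parents[b] or "-"
            lines.append(f"bone {b} {parent} {self.lengths_mm[b]!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "HandSkeleton":
        handedness = None
        bones: list[str] = []
        parents: dict[str, Optional[str]] = {}
        lengths: dict[str, float] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] == "handedness":
                if len(fields) != 2:
                    raise RecordingParseError(lineno, "handedness needs one value")
                handedness = fields[1]
            elif fields[0] == "bone":
                if len(fields) != 4:
                    raise RecordingParseError(lineno, "expected: bone name parent length")
                name, parent, length = fields[1], fields[2], fields[3]
                bones.append(name)
                parents[name] = None if parent == "-" else parent
                try:
                    lengths[name] = float(length)
                except ValueError:
                    raise RecordingParseError(lineno, f"bad length '{length}'") from None
            else:
                raise RecordingParseError(lineno, f"unknown directive '{fields[0]}'")
        if handedness is None:
            raise RecordingParseError(0, "missing handedness line")
        return cls(handedness=handedness, bones=tuple(bones), parents=parents, lengths_mm=lengths)


@dataclass
class ReferencePosture:
    """Per-bone basis and (distal-joint) position at the neutral-zero posture."""

    bases: dict[str, np.ndarray]
    positions: dict[str, np.ndarray]


def default_skeleton(handedness: str = "right", scale: float = 1.0) -> HandSkeleton:
    """Canonical 22-bone test skeleton with adult segment lengths times ``scale``.

    Left and right skeletons share lengths; handedness is carried as
    metadata (the neutral-zero bases are the identity either way).
    """
    if scale <= 0:
        raise HandkinError(f"scale must be > 0, got {scale}")
    bones: list[str] = [FOREARM, HAND]
    parents: dict[str, Optional[str]] = {FOREARM: None, HAND: FOREARM}
    lengths: dict[str, float] = {
        FOREARM: _DEFAULT_LENGTHS_MM[FOREARM] * scale,
        HAND: _DEFAULT_LENGTHS_MM[HAND] * scale,
    }
    for d in DIGITS:
        chain = [bone_name(p, d) for p in BONE_PARTS]
        prev = HAND
        for bone, length in zip(chain, _DEFAULT_LENGTHS_MM[d]):
            bones.append(bone)
            parents[bone] = prev
            lengths[bone] = length * scale
            prev = bone
    return HandSkeleton(handedness=handedness, bones=tuple(bones),
                        parents=parents, lengths_mm=lengths)


def _digit_joints(digit: int) -> list[JointId]:
    mc, pp, ip, dp = (bone_name(p, digit) for p in BONE_PARTS)
    if digit == 1:
        # thumb: the zero-length metacarpal makes hand->MC rigid; the
        # articulated chain is exposed under the anatomical aliases
        # CMC (3 dof, opposition), MCP, IP.
        return [
            JointId("cmc1", pp, mc, (DOF_FLEXION, DOF_ABDUCTION, DOF_ROTATION)),
            JointId("mcp1", ip, pp, (DOF_FLEXION, DOF_ABDUCTION)),
            JointId("ip1", dp, ip, (DOF_FLEXION,)),
        ]
    return [
        JointId(f"mcp{digit}", pp, mc, (DOF_FLEXION, DOF_ABDUCTION)),
        JointId(f"pip{digit}", ip, pp, (DOF_FLEXION,)),
        JointId(f"dip{digit}", dp, ip, (DOF_FLEXION,)),
    ]


def joints_of(skeleton: HandSkeleton) -> tuple[JointId, ...]:
    """Deterministically ordered articulated joints of the skeleton.

    Order: elbow, wrist, then digits 1..5 proximal-to-distal.  The elbow
    gets flexion/extension plus pronation/supination (2 dof); the wrist
    flexion/extension plus radial/ulnar deviation.  Hand->metacarpal links
    of the digits are rigid and therefore not listed here (they still
    appear as channel-bearing nodes in BVH output, with zero rotation).
    """
    joints: list[JointId] = [
        JointId("elbow", FOREARM, None, (DOF_FLEXION, DOF_ROTATION)),
        JointId("wrist", HAND, FOREARM, (DOF_FLEXION, DOF_ABDUCTION)),
    ]
    for d in DIGITS:
        joints.extend(_digit_joints(d))
    known = set(skeleton.bones)
    for j in joints:
        if j.child_bone not in known or (j.parent_bone is not None and j.parent_bone not in known):
            raise HandkinError(f"skeleton is missing bones for joint {j.name}")
    return tuple(joints)


def joint_by_name(skeleton: HandSkeleton, name: str) -> JointId:
    for j in joints_of(skeleton):
        if j.name == name:
            return j
    raise HandkinError(f"unknown joint '{name}'")


def joint_for_child_bone(skeleton: HandSkeleton, bone: str) -> Optional[JointId]:
    """The articulated joint whose child is ``bone``, or None for rigid links."""
    for j in joints_of(skeleton):
        if j.child_bone == bone:
            return j
    return None
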