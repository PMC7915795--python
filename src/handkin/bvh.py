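"""Biovision Hierarchy (BVH) reading and writing.

Dialect choices (documented, since BVH fixes neither):

* rotation channel order ``Zrotation Xrotation Yrotation`` (the dominant
  dialect), applied intrinsically in that order;
* the root node carries ``Xposition Yposition Zposition`` plus the three
  rotation channels;
* offsets in mm, rotations in degrees, numerics at 6 decimal places;
* 0-based frame indices, half-open slices.

Channel values are a genuine re-expression of the package's Cardan triples:
``Rx(phi) Ry(theta) Rz(psi)`` is converted to intrinsic Z-X-Y angles on
write and back on read, so any BVH player reproduces the same rotation.

A parsed :class:`BvhDocument` keeps the raw channel values; serializing it
again is byte-identical (floats parsed from 6-decimal text re-format to the
same text).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import BvhParseError, FrameCountMismatchError, HandkinError
from .kinematics import JointAngleSeries, _cardan_batch
from .skeleton import (
    BONE_PARTS,
    DIGITS,
    FOREARM,
    HAND,
    HandSkeleton,
    JointId,
    bone_name,
    joints_of,
)

__all__ = ["BvhNode", "BvhDocument", "write_bvh", "read_bvh", "slice_frames",
           "bvh_to_series", "node_name_for_bone", "bone_for_node_name"]

ROT_CHANNELS = ("Zrotation", "Xrotation", "Yrotation")
POS_CHANNELS = ("Xposition", "Yposition", "Zposition")
_INDENT = "  "


# ---------------------------------------------------------------------------
# Euler order conversions (intrinsic Z-X-Y <-> the package's X-Y-Z triples)
# ---------------------------------------------------------------------------

def _matrices_from_xyz(angles_deg: np.ndarray) -> np.ndarray:
    """(n,3) Cardan (phi,theta,psi) degrees -> (n,3,3) Rx@Ry@Rz."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(a[:, 0]), np.sin(a[:, 0])
    cy, sy = np.cos(a[:, 1]), np.sin(a[:, 1])
    cz, sz = np.cos(a[:, 2]), np.sin(a[:, 2])
    m = np.empty((a.shape[0], 3, 3))
    m[:, 0, 0] = cy * cz
    m[:, 0, 1] = -cy * sz
    m[:, 0, 2] = sy
    m[:, 1, 0] = cx * sz + sx * sy * cz
    m[:, 1, 1] = cx * cz - sx * sy * sz
    m[:, 1, 2] = -sx * cy
    m[:, 2, 0] = sx * sz - cx * sy * cz
    m[:, 2, 1] = sx * cz + cx * sy * sz
    m[:, 2, 2] = cx * cy
    return m


def _zxy_from_matrices(mats: np.ndarray) -> np.ndarray:
    """(n,3,3) -> (n,3) intrinsic Z-X-Y angles (z, x, y) in degrees."""
    m21 = np.clip(mats[:, 2, 1], -1.0, 1.0)
    x = np.arcsin(m21)
    z = np.arctan2(-mats[:, 0, 1], mats[:, 1, 1])
    y = np.arctan2(-mats[:, 2, 0], mats[:, 2, 2])
    locked = np.abs(m21) > 1.0 - 1e-12
    if np.any(locked):
        folded = np.arctan2(mats[:, 0, 2] * np.sign(m21), mats[:, 0, 0])
        z = np.where(locked, folded, z)
        y = np.where(locked, 0.0, y)
    return np.degrees(np.stack([z, x, y], axis=1))


_ELEM = {
    "Xrotation": lambda c, s: np.stack([
        np.stack([np.ones_like(c), np.zeros_like(c), np.zeros_like(c)], -1),
        np.stack([np.zeros_like(c), c, -s], -1),
        np.stack([np.zeros_like(c), s, c], -1)], -2),
    "Yrotation": lambda c, s: np.stack([
        np.stack([c, np.zeros_like(c), s], -1),
        np.stack([np.zeros_like(c), np.ones_like(c), np.zeros_like(c)], -1),
        np.stack([-s, np.zeros_like(c), c], -1)], -2),
    "Zrotation": lambda c, s: np.stack([
        np.stack([c, -s, np.zeros_like(c)], -1),
        np.stack([s, c, np.zeros_like(c)], -1),
        np.stack([np.zeros_like(c), np.zeros_like(c), np.ones_like(c)], -1)], -2),
}


def _matrices_from_channels(values_deg: np.ndarray, order: Sequence[str]) -> np.ndarray:
    """Compose intrinsic rotations in channel order; values (n,len(order))."""
    values = np.radians(np.asarray(values_deg, dtype=float))
    mats = None
    for k, channel in enumerate(order):
        c, s = np.cos(values[:, k]), np.sin(values[:, k])
        elem = _ELEM[channel](c, s)
        mats = elem if mats is None else mats @ elem
    return mats


# ---------------------------------------------------------------------------
# document model
# ---------------------------------------------------------------------------

@dataclass
class BvhNode:
    name: str
    offset: np.ndarray
    channels: tuple[str, ...]
    children: list["BvhNode"] = field(default_factory=list)
    end_site_offset: Optional[np.ndarray] = None

    def walk(self):
        """Depth-first, declaration order."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class BvhDocument:
    root: BvhNode
    frame_time_s: float
    frames: np.ndarray  # (n_frames, total_channels)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frame_time_s <= 0:
            raise HandkinError("frame time must be > 0")
        if self.frames.ndim != 2 or self.frames.shape[1] != self.channel_count:
            raise HandkinError("channel values per frame must match declared channels")

    @property
    def nodes(self) -> list[BvhNode]:
        return list(self.root.walk())

    @property
    def channel_count(self) -> int:
        return sum(len(n.channels) for n in self.root.walk())

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_time_s

    def channel_slice(self, node_name: str) -> slice:
        """Column range of a node's channels in the motion rows."""
        start = 0
        for node in self.root.walk():
            if node.name == node_name:
                return slice(start, start + len(node.channels))
            start += len(node.channels)
        raise HandkinError(f"no node named '{node_name}'")

    def to_text(self) -> str:
        lines: list[str] = ["HIERARCHY"]
        self._write_node(lines, self.root, 0, root=True)
        lines.append("MOTION")
        lines.append(f"Frames: {self.n_frames}")
        lines.append(f"Frame Time: {self.frame_time_s:.6f}")
        for row in self.frames:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"

    def _write_node(self, lines: list[str], node: BvhNode, depth: int, root: bool = False):
        pad = _INDENT * depth
        lines.append(f"{pad}{'ROOT' if root else 'JOINT'} {node.name}")
        lines.append(f"{pad}{{")
        inner = _INDENT * (depth + 1)
        lines.append(inner + "OFFSET " + " ".join(f"{v:.6f}" for v in node.offset))
        lines.append(inner + f"CHANNELS {len(node.channels)} " + " ".join(node.channels))
        for child in node.children:
            self._write_node(lines, child, depth + 1)
        if node.end_site_offset is not None:
            lines.append(inner + "End Site")
            lines.append(inner + "{")
            lines.append(inner + _INDENT + "OFFSET "
                         + " ".join(f"{v:.6f}" for v in node.end_site_offset))
            lines.append(inner + "}")
        lines.append(f"{pad}}}")

    def save(self, destination: Union[str, Path]) -> None:
        Path(destination).write_text(self.to_text())


def slice_frames(doc: BvhDocument, start: int, end: int) -> BvhDocument:
    """Keep motion rows [start, end) (0-based, half-open); hierarchy unchanged."""
    if not (0 <= start < end <= doc.n_frames):
        raise HandkinError(
            f"slice [{start}, {end}) out of range for {doc.n_frames} frames")
    return BvhDocument(root=doc.root, frame_time_s=doc.frame_time_s,
                       frames=doc.frames[start:end].copy())


# ---------------------------------------------------------------------------
# skeleton <-> hierarchy naming
# ---------------------------------------------------------------------------

def node_name_for_bone(bone: str) -> str:
    if bone == FOREARM:
        return "Forearm"
    if bone == HAND:
        return "Hand"
    part, digit = bone[:-1], bone[-1]
    return f"Finger{digit}{part.capitalize()}"


def bone_for_node_name(name: str) -> Optional[str]:
    if name == "Forearm":
        return FOREARM
    if name == "Hand":
        return HAND
    if name.startswith("Finger") and len(name) > 7 and name[6].isdigit():
        digit, part = int(name[6]), name[7:].lower()
        if digit in DIGITS and part in BONE_PARTS:
            return bone_name(part, digit)
    return None


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _build_hierarchy(skeleton: HandSkeleton) -> BvhNode:
    nodes: dict[str, BvhNode] = {}
    for bone in skeleton.bones:
        parent = skeleton.parents[bone]
        offset = np.zeros(3) if parent is None \
            else np.array([0.0, 0.0, skeleton.lengths_mm[parent]])
        channels = POS_CHANNELS + ROT_CHANNELS if parent is None else ROT_CHANNELS
        node = BvhNode(name=node_name_for_bone(bone), offset=offset, channels=channels)
        nodes[bone] = node
        if parent is not None:
            nodes[parent].children.append(node)
    for bone in skeleton.bones:
        if not nodes[bone].children:
            nodes[bone].end_site_offset = np.array(
                [0.0, 0.0, skeleton.lengths_mm[bone]])
    return nodes[skeleton.bones[0]]


def write_bvh(
    skeleton: HandSkeleton,
    series: Sequence[JointAngleSeries],
    frame_rate: float,
    destination: Optional[Union[str, Path]] = None,
) -> BvhDocument:
    """Serialize joint-angle series as a BVH document (optionally persisted)."""
    if not series:
        raise HandkinError("empty series")
    if frame_rate <= 0:
        raise HandkinError("frame_rate must be > 0")
    counts = {s.n_frames for s in series}
    if len(counts) != 1:
        raise FrameCountMismatchError(f"series disagree on frame count: {sorted(counts)}")
    n = counts.pop()
    by_joint = {s.joint.name: s for s in series}
    required = {j.name for j in joints_of(skeleton)}
    missing = required - set(by_joint)
    if missing:
        raise HandkinError(f"series do not cover joints: {sorted(missing)}")

    joint_of_child = {j.child_bone: j for j in joints_of(skeleton)}
    columns: list[np.ndarray] = []
    for bone in skeleton.bones:
        if skeleton.parents[bone] is None:
            columns.append(np.zeros((n, 3)))  # root translation
        joint = joint_of_child.get(bone)
        angles = by_joint[joint.name].angles if joint is not None else np.zeros((n, 3))
        columns.append(_zxy_from_matrices(_matrices_from_xyz(angles)))
    doc = BvhDocument(root=_build_hierarchy(skeleton),
                      frame_time_s=1.0 / frame_rate,
                      frames=np.concatenate(columns, axis=1))
    if destination is not None:
        doc.save(destination)
    return doc


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

class _Tokens:
    """Line-oriented token stream tracking line numbers for error reporting."""

    def __init__(self, text: str):
        self.lines = text.splitlines()
        self.pos = 0

    def next_line(self) -> tuple[int, list[str]]:
        while self.pos < len(self.lines):
            self.pos += 1
            fields = self.lines[self.pos - 1].split()
            if fields:
                return self.pos, fields
        raise BvhParseError(len(self.lines), "unexpected end of file")

    def peek_line(self) -> tuple[int, list[str]]:
        saved = self.pos
        try:
            return self.next_line()
        finally:
            self.pos = saved


def _parse_node(tokens: _Tokens, keyword: str) -> BvhNode:
    lineno, fields = tokens.next_line()
    if fields[0] != keyword or len(fields) != 2:
        raise BvhParseError(lineno, f"expected '{keyword} <name>'")
    name = fields[1]
    lineno, fields = tokens.next_line()
    if fields[0] != "{":
        raise BvhParseError(lineno, "expected '{'")
    lineno, fields = tokens.next_line()
    if fields[0] != "OFFSET" or len(fields) != 4:
        raise BvhParseError(lineno, "expected 'OFFSET x y z'")
    try:
        offset = np.array([float(v) for v in fields[1:]])
    except ValueError:
        raise BvhParseError(lineno, "bad OFFSET value") from None
    lineno, fields = tokens.next_line()
    if fields[0] != "CHANNELS":
        raise BvhParseError(lineno, "expected CHANNELS")
    try:
        n_ch = int(fields[1])
    except (IndexError, ValueError):
        raise BvhParseError(lineno, "bad CHANNELS count") from None
    channels = tuple(fields[2:])
    if len(channels) != n_ch:
        raise BvhParseError(lineno, "CHANNELS count does not match names")
    for ch in channels:
        if ch not in POS_CHANNELS + ROT_CHANNELS:
            raise BvhParseError(lineno, f"unsupported channel '{ch}'")
    node = BvhNode(name=name, offset=offset, channels=channels)
    while True:
        lineno, fields = tokens.peek_line()
        if fields[0] == "JOINT":
            node.children.append(_parse_node(tokens, "JOINT"))
        elif fields[0] == "End" and len(fields) >= 2 and fields[1] == "Site":
            tokens.next_line()
            lineno, fields = tokens.next_line()
            if fields[0] != "{":
                raise BvhParseError(lineno, "expected '{' after End Site")
            lineno, fields = tokens.next_line()
            if fields[0] != "OFFSET" or len(fields) != 4:
                raise BvhParseError(lineno, "expected End Site OFFSET")
            node.end_site_offset = np.array([float(v) for v in fields[1:]])
            lineno, fields = tokens.next_line()
            if fields[0] != "}":
                raise BvhParseError(lineno, "expected '}' closing End Site")
        elif fields[0] == "}":
            tokens.next_line()
            return node
        else:
            raise BvhParseError(lineno, f"unexpected token '{fields[0]}' in joint block")


def read_bvh(source: Union[str, Path]) -> BvhDocument:
    """Parse a BVH file; raises :class:`BvhParseError` with line numbers."""
    text = Path(source).read_text()
    tokens = _Tokens(text)
    lineno, fields = tokens.next_line()
    if fields[0] != "HIERARCHY":
        raise BvhParseError(lineno, "expected HIERARCHY")
    root = _parse_node(tokens, "ROOT")
    lineno, fields = tokens.next_line()
    if fields[0] != "MOTION":
        raise BvhParseError(lineno, "expected MOTION")
    lineno, fields = tokens.next_line()
    if fields[0] != "Frames:" or len(fields) != 2:
        raise BvhParseError(lineno, "expected 'Frames: <n>'")
    try:
        n_frames = int(fields[1])
    except ValueError:
        raise BvhParseError(lineno, "bad frame count") from None
    lineno, fields = tokens.next_line()
    if fields[:2] != ["Frame", "Time:"] or len(fields) != 3:
        raise BvhParseError(lineno, "expected 'Frame Time: <s>'")
    try:
        frame_time = float(fields[2])
    except ValueError:
        raise BvhParseError(lineno, "bad frame time") from None

    n_channels = sum(len(n.channels) for n in root.walk())
    rows = np.empty((n_frames, n_channels))
    for i in range(n_frames):
        try:
            lineno, fields = tokens.next_line()
        except BvhParseError:
            raise BvhParseError(
                len(tokens.lines),
                f"MOTION truncated: expected {n_frames} frames, got {i}") from None
        if len(fields) != n_channels:
            raise BvhParseError(
                lineno, f"expected {n_channels} channel values, got {len(fields)}")
        try:
            rows[i] = [float(v) for v in fields]
        except ValueError:
            raise BvhParseError(lineno, "bad channel value") from None
    return BvhDocument(root=root, frame_time_s=frame_time, frames=rows)


def bvh_to_series(doc: BvhDocument) -> tuple[Optional[HandSkeleton],
                                             dict[str, JointAngleSeries], float]:
    """Recover a hand skeleton and joint-angle series from a BVH document.

    Returns ``(skeleton, series_by_joint_name, frame_rate)``.  When node
    names do not conform to the package's hand naming, the skeleton is
    ``None`` and the series dict is empty (the generic hierarchy stays
    available on ``doc``); no silent renaming is attempted.
    """
    bones: dict[str, BvhNode] = {}
    for node in doc.root.walk():
        bone = bone_for_node_name(node.name)
        if bone is None or bone in bones:
            return None, {}, doc.frame_rate
        bones[bone] = node

    # lengths: a bone's length is the offset norm of its children (or its
    # End Site for leaves)
    lengths: dict[str, float] = {}
    parents: dict[str, Optional[str]] = {}
    order: list[str] = []
    for bone, node in bones.items():
        order.append(bone)
        for child in node.children:
            child_bone = bone_for_node_name(child.name)
            parents[child_bone] = bone
            lengths[bone] = float(np.linalg.norm(child.offset))
        if node.end_site_offset is not None:
            lengths[bone] = float(np.linalg.norm(node.end_site_offset))
    root_bone = bone_for_node_name(doc.root.name)
    parents[root_bone] = None
    try:
        skeleton = HandSkeleton(handedness="right", bones=tuple(order),
                                parents=parents, lengths_mm=lengths)
    except HandkinError:
        return None, {}, doc.frame_rate

    series: dict[str, JointAngleSeries] = {}
    for joint in joints_of(skeleton):
        node = bones[joint.child_bone]
        sl = doc.channel_slice(node.name)
        values = doc.frames[:, sl]
        rot_order = [c for c in node.channels if c.endswith("rotation")]
        rot_values = values[:, [node.channels.index(c) for c in rot_order]]
        mats = _matrices_from_channels(rot_values, rot_order)
        series[joint.name] = JointAngleSeries(joint=joint, angles=_cardan_batch(mats))
    return skeleton, series, doc.frame_rate
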