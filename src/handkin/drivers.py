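"""Joint-driver vector files, normalized time series and finger lengths.

One file is written per body part: ``Finger1.any`` ... ``Finger5.any``,
``Wrist.any``, ``Elbow.any``, plus ``TimeSeries.any`` and
``FingerLength.any``.  The syntax is a minimal declarative text format::

    // comment
    Finger2.Joint_PP_IP.Flexion = {0.000000, 12.345678, ...};
    Finger2.PP = 40.000000;

one assignment per vector or scalar.  Angle vectors are **degrees** (the
downstream interpolation treats them as plain numbers; the unit choice is
ours and is stated here deliberately).  Per joint, one vector is written
per enabled degree of freedom (Flexion, Abduction, Rotation); disabled
DOFs are suppressed.  Compatibility with any particular simulation
package's own file syntax is not claimed; a reader for this grammar ships
for testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .errors import DriverParseError, FrameCountMismatchError, HandkinError
from .kinematics import JointAngleSeries, Recording
from .skeleton import (
    BONE_PARTS,
    DIGITS,
    DOF_ORDER,
    HandSkeleton,
    JointId,
    bone_name,
)

__all__ = [
    "DriverFileSet",
    "make_time_series",
    "export_driver_files",
    "compute_finger_lengths",
    "write_finger_lengths",
    "read_driver_file",
    "driver_vector_name",
    "part_of_joint",
]

_DOF_LABEL = {"flexion": "Flexion", "abduction": "Abduction", "rotation": "Rotation"}
_PART_ABBREV = {"metacarpal": "MC", "proximal": "PP", "intermediate": "IP", "distal": "DP"}
_FLOAT_FMT = "{:.6f}"


def part_of_joint(joint: JointId) -> str:
    """Body-part group a joint belongs to: FingerN, Wrist or Elbow."""
    if joint.name == "elbow":
        return "Elbow"
    if joint.name == "wrist":
        return "Wrist"
    digit = joint.digit
    if digit is None:
        raise HandkinError(f"cannot group joint '{joint.name}'")
    return f"Finger{digit}"


def _joint_label(joint: JointId) -> str:
    if joint.name == "elbow":
        return "Joint_Elbow"
    if joint.name == "wrist":
        return "Joint_Wrist"
    child = _PART_ABBREV[joint.child_bone[:-1]]
    parent = _PART_ABBREV[joint.parent_bone[:-1]]
    return f"Joint_{parent}_{child}"


def driver_vector_name(joint: JointId, dof: str) -> str:
    """Deterministic vector name, e.g. ``Finger2.Joint_PP_IP.Flexion``."""
    return f"{part_of_joint(joint)}.{_joint_label(joint)}.{_DOF_LABEL[dof]}"


@dataclass
class DriverFileSet:
    """In-memory image of the exported driver files."""

    vectors: dict[str, np.ndarray]  # full vector name -> (n_frames,) degrees
    time_series: np.ndarray
    finger_lengths: dict[str, float]  # e.g. "Finger2.PP" -> mm
    files: dict[str, Path] = field(default_factory=dict)  # part -> written path

    @property
    def n_frames(self) -> int:
        return len(self.time_series)


def make_time_series(n_frames: int) -> np.ndarray:
    """Evenly spaced values from 0 to 1, one per recorded frame."""
    if n_frames < 2:
        raise HandkinError(f"n_frames must be >= 2, got {n_frames}")
    return np.linspace(0.0, 1.0, n_frames)


def _format_vector(name: str, values: np.ndarray) -> str:
    body = ", ".join(_FLOAT_FMT.format(v) for v in values)
    return f"{name} = {{{body}}};"


def export_driver_files(
    series: Sequence[JointAngleSeries],
    destination: Union[str, Path],
    finger_lengths: Optional[Mapping[str, float]] = None,
    header_comments: Iterable[str] = (),
) -> DriverFileSet:
    """Write per-part driver files plus TimeSeries.any (and FingerLength.any).

    Angle values are degrees at 6 decimal places.  Returns the in-memory
    file set with the written paths recorded.
    """
    if not series:
        raise HandkinError("empty series")
    counts = {s.n_frames for s in series}
    if len(counts) != 1:
        raise FrameCountMismatchError(f"series disagree on frame count: {sorted(counts)}")
    n = counts.pop()

    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    header = [f"// {c}" for c in header_comments]

    vectors: dict[str, np.ndarray] = {}
    per_part: dict[str, list[str]] = {}
    dof_column = {dof: k for k, dof in enumerate(DOF_ORDER)}
    for s in series:
        part = part_of_joint(s.joint)
        for dof in s.joint.dof_mask:
            name = driver_vector_name(s.joint, dof)
            values = s.angles[:, dof_column[dof]]
            vectors[name] = values
            per_part.setdefault(part, []).append(_format_vector(name, values))

    files: dict[str, Path] = {}
    for part, lines in per_part.items():
        path = dest / f"{part}.any"
        path.write_text("\n".join(header + lines) + "\n")
        files[part] = path

    time_series = make_time_series(n)
    ts_path = dest / "TimeSeries.any"
    ts_path.write_text("\n".join(header + [_format_vector("TimeSeries", time_series)]) + "\n")
    files["TimeSeries"] = ts_path

    lengths = dict(finger_lengths) if finger_lengths else {}
    if lengths:
        files["FingerLength"] = write_finger_lengths(
            lengths, dest / "FingerLength.any", header_comments)

    return DriverFileSet(vectors=vectors, time_series=time_series,
                         finger_lengths=lengths, files=files)


def finger_length_key(digit: int, part: str) -> str:
    return f"Finger{digit}.{_PART_ABBREV[part]}"


def compute_finger_lengths(recording: Recording,
                           estimator: str = "frame0") -> dict[str, float]:
    """Per-digit per-bone segment lengths (mm) from recorded joint positions.

    A bone's length is the distance between its proximal joint (the
    parent's recorded distal position) and its own distal position.  By
    default frame 0 is used (the sensor model keeps lengths constant);
    ``estimator="mean"`` averages over all frames for noisy input.
    """
    if estimator not in ("frame0", "mean"):
        raise HandkinError(f"unknown estimator '{estimator}'")
    sk = recording.skeleton
    out: dict[str, float] = {}
    for digit in DIGITS:
        for part in BONE_PARTS:
            bone = bone_name(part, digit)
            parent = sk.parents[bone]
            child_pos = recording.position_array(bone)
            parent_pos = recording.position_array(parent)
            dist = np.linalg.norm(child_pos - parent_pos, axis=1)
            value = dist[0] if estimator == "frame0" else dist.mean()
            out[finger_length_key(digit, part)] = float(value)
    return out


def write_finger_lengths(lengths: Mapping[str, float], destination: Union[str, Path],
                         header_comments: Iterable[str] = ()) -> Path:
    path = Path(destination)
    lines = [f"// {c}" for c in header_comments]
    for name, value in lengths.items():
        lines.append(f"{name} = {_FLOAT_FMT.format(value)};")
    path.write_text("\n".join(lines) + "\n")
    return path


_ASSIGN_RE = re.compile(r"^\s*([A-Za-z0-9_.]+)\s*=\s*(.+?);\s*$")


def read_driver_file(source: Union[str, Path]) -> dict[str, np.ndarray]:
    """Parse a driver file back into name -> vector (scalars become length-1)."""
    out: dict[str, np.ndarray] = {}
    for lineno, raw in enumerate(Path(source).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("//"):
            continue
        m = _ASSIGN_RE.match(line)
        if m is None:
            raise DriverParseError(f"line {lineno}: expected 'Name = value;'")
        name, rhs = m.group(1), m.group(2).strip()
        try:
            if rhs.startswith("{") and rhs.endswith("}"):
                inner = rhs[1:-1].strip()
                values = np.array([float(v) for v in inner.split(",")]) if inner \
                    else np.empty(0)
            else:
                values = np.array([float(rhs)])
        except ValueError:
            raise DriverParseError(f"line {lineno}: bad numeric value") from None
        out[name] = values
    return out
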