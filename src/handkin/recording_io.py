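"""Plain-text recording file format.

Grammar (blank lines and ``#`` comments ignored; whitespace separated)::

    format handkin-recording 1
    frame_rate <hz>
    handedness <left|right>
    bone <name> <parent|-> <length_mm>        # one line per bone, parent first
    frames <n>
    frame <index> <time_s>
    <bone> <px> <py> <pz> <b11> <b12> <b13> <b21> <b22> <b23> <b31> <b32> <b33>
    ...

Positions are mm in the global frame (the bone's distal joint); the nine
basis scalars are row-major, rows = the bone's local axis vectors in the
global frame.  Floats are written with ``repr`` precision so a write/read
cycle is lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from .errors import HandkinError, RecordingParseError
from .kinematics import BoneState, Frame, Recording
from .skeleton import HandSkeleton

__all__ = ["write_recording", "read_recording", "recording_to_text"]

_FORMAT_LINE = "format handkin-recording 1"


def _fmt(x: float) -> str:
    return repr(float(x))


def recording_to_text(recording: Recording, header_comments: Iterable[str] = ()) -> str:
    sk = recording.skeleton
    lines = [_FORMAT_LINE]
    for comment in header_comments:
        lines.append(f"# {comment}")
    lines.append(f"frame_rate {_fmt(recording.frame_rate)}")
    lines.append(f"handedness {sk.handedness}")
    for b in sk.bones:
        lines.append(f"bone {b} {sk.parents[b] or '-'} {_fmt(sk.lengths_mm[b])}")
    lines.append(f"frames {recording.n_frames}")
    for frame in recording.frames:
        lines.append(f"frame {frame.index} {_fmt(frame.time_s)}")
        for b in sk.bones:
            st = frame.states[b]
            nums = list(st.position) + list(st.basis.reshape(9))
            lines.append(b + " " + " ".join(_fmt(v) for v in nums))
    return "\n".join(lines) + "\n"


def write_recording(recording: Recording, destination: Union[str, Path],
                    header_comments: Iterable[str] = ()) -> None:
    Path(destination).write_text(recording_to_text(recording, header_comments))


def read_recording(source: Union[str, Path]) -> Recording:
    """Parse a recording file; raises :class:`RecordingParseError` with line numbers."""
    path = Path(source)
    lines = path.read_text().splitlines()

    frame_rate: Optional[float] = None
    handedness: Optional[str] = None
    bones: list[str] = []
    parents: dict[str, Optional[str]] = {}
    lengths: dict[str, float] = {}
    declared_frames: Optional[int] = None
    frames: list[Frame] = []
    current: Optional[Frame] = None
    saw_format = False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        key = fields[0]
        try:
            if not saw_format:
                if line != _FORMAT_LINE:
                    raise RecordingParseError(lineno, "missing or unknown format line")
                saw_format = True
            elif key == "frame_rate":
                frame_rate = float(fields[1])
            elif key == "handedness":
                handedness = fields[1]
            elif key == "bone":
                name, parent, length = fields[1], fields[2], fields[3]
                bones.append(name)
                parents[name] = None if parent == "-" else parent
                lengths[name] = float(length)
            elif key == "frames":
                declared_frames = int(fields[1])
            elif key == "frame":
                current = Frame(index=int(fields[1]), time_s=float(fields[2]), states={})
                frames.append(current)
            elif key in parents:
                if current is None:
                    raise RecordingParseError(lineno, "bone state before any frame line")
                if len(fields) != 13:
                    raise RecordingParseError(
                        lineno, f"expected 12 numbers after bone name, got {len(fields) - 1}")
                nums = np.array([float(v) for v in fields[1:]])
                current.states[key] = BoneState(
                    bone=key, position=nums[:3], basis=nums[3:].reshape(3, 3))
            else:
                raise RecordingParseError(lineno, f"unknown directive '{key}'")
        except RecordingParseError:
            raise
        except (IndexError, ValueError) as exc:
            raise RecordingParseError(lineno, f"malformed line: {exc}") from None

    if frame_rate is None or handedness is None:
        raise RecordingParseError(0, "missing frame_rate or handedness header")
    if declared_frames is not None and declared_frames != len(frames):
        raise RecordingParseError(
            0, f"declared {declared_frames} frames but found {len(frames)}")
    skeleton = HandSkeleton(handedness=handedness, bones=tuple(bones),
                            parents=parents, lengths_mm=lengths)
    try:
        return Recording(skeleton=skeleton, frames=frames, frame_rate=frame_rate)
    except HandkinError as exc:
        raise RecordingParseError(0, str(exc)) from exc
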