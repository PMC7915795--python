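"""Exception hierarchy for handkin."""


class HandkinError(Exception):
    """Base class for all handkin errors."""


class DegenerateBasisError(HandkinError):
    """A 3x3 matrix is singular, reflecting, or too far from a rotation."""


class IncompleteFrameError(HandkinError):
    """A frame is missing the state of a bone required by the skeleton."""

    def __init__(self, frame_index: int, bone: str):
        self.frame_index = frame_index
        self.bone = bone
        super().__init__(f"frame {frame_index}: missing state for bone '{bone}'")


class FrameCountMismatchError(HandkinError):
    """Series or trajectories disagree on the number of frames."""


class RecordingParseError(HandkinError):
    """Malformed recording text file."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class BvhParseError(HandkinError):
    """Malformed BVH file."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class DriverParseError(HandkinError):
    """Malformed driver vector file."""


class DegenerateMarkerError(HandkinError):
    """Two or more 2D markers coincide; no angle is defined."""


class NoOverlapError(HandkinError):
    """Two trajectories share no common time span."""
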