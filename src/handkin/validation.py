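"""Marker-based validation: 2D joint angles and trajectory comparison.

The accuracy-measurement path mirrors a video-tracking setup: three labeled
markers on the index finger (MCP joint, PIP joint, and a distal marker)
yield the PIP flexion angle from the two segment vectors, with 0 deg =
straight finger and angles in [0, 180).  A synthetic orthographic camera
(:func:`project_recording`) replaces the physical one: for planar flexion
viewed perpendicular to the motion plane the 2D angle equals the 3D Cardan
flexion angle exactly, which is the bridge property the validation tests
rely on.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .errors import DegenerateMarkerError, HandkinError, NoOverlapError
from .kinematics import Recording
from .skeleton import bone_name

__all__ = [
    "MarkerTrack2D",
    "TrajectoryComparison",
    "angle_from_markers",
    "track_angles",
    "project_recording",
    "compare_trajectories",
    "write_marker_csv",
    "read_marker_csv",
]

_EPS = 1e-12


@dataclass
class MarkerTrack2D:
    """Per-frame 2D positions of the three finger markers.

    ``positions`` has shape (n_frames, 3, 2); marker order is
    (MCP, PIP, distal).  Units are arbitrary planar units — the angle is
    scale-invariant.
    """

    positions: np.ndarray
    frame_rate: float
    start_time_s: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (3, 2):
            raise HandkinError("positions must be (n_frames, 3, 2)")
        if self.positions.shape[0] < 2:
            raise HandkinError("a marker track needs at least 2 frames")
        if self.frame_rate <= 0:
            raise HandkinError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_frames) / self.frame_rate


@dataclass
class TrajectoryComparison:
    """Two angle trajectories resampled to a common grid, plus summary stats."""

    times_s: np.ndarray
    a: np.ndarray
    b: np.ndarray
    diff: np.ndarray  # a - b, degrees
    rmse: float
    max_abs: float
    bias: float


def angle_from_markers(p_mcp, p_pip, p_tip) -> float:
    """Angle in degrees, [0, 180], between the two finger segments.

    0 = straight finger (collinear markers).  Raises
    :class:`DegenerateMarkerError` if either segment has zero length.
    """
    p_mcp = np.asarray(p_mcp, dtype=float)
    p_pip = np.asarray(p_pip, dtype=float)
    p_tip = np.asarray(p_tip, dtype=float)
    v1 = p_pip - p_mcp
    v2 = p_tip - p_pip
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < _EPS or n2 < _EPS:
        raise DegenerateMarkerError("coincident markers: segment of zero length")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = float(v1 @ v2)
    return float(np.degrees(np.arctan2(abs(cross), dot)))


def track_angles(track: MarkerTrack2D) -> np.ndarray:
    """Per-frame marker angle of a track, degrees."""
    return np.array([
        angle_from_markers(track.positions[i, 0], track.positions[i, 1],
                           track.positions[i, 2])
        for i in range(track.n_frames)
    ])


# orthographic view planes: (u, v) columns of the projection, global frame.
# side: camera along the flexion axis X -> project onto the Z-Y plane;
# top: camera along the palm normal Y -> project onto the Z-X plane.
_VIEWS = {
    "side": np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]]),  # u=Z, v=Y
    "top": np.array([[0.0, 1.0], [0.0, 0.0], [1.0, 0.0]]),   # u=Z, v=X
}


def project_recording(recording: Recording, digit: int = 2, view: str = "side",
                      distal_marker: str = "dip") -> MarkerTrack2D:
    """Orthographic projection of a digit's MCP, PIP and distal marker.

    ``distal_marker``: ``"dip"`` (the DIP joint, default — keeps the
    PIP->distal segment along the intermediate phalanx so the 2D angle is
    the PIP flexion angle) or ``"tip"`` (the fingertip).
    """
    if view not in _VIEWS:
        raise HandkinError(f"view must be side|top, got '{view}'")
    if distal_marker not in ("dip", "tip"):
        raise HandkinError("distal_marker must be dip|tip")
    # recorded positions are distal joints: MCP = end of metacarpal,
    # PIP = end of proximal phalanx, DIP = end of intermediate, tip = end of distal
    mcp = recording.position_array(bone_name("metacarpal", digit))
    pip = recording.position_array(bone_name("proximal", digit))
    distal_bone = "intermediate" if distal_marker == "dip" else "distal"
    tip = recording.position_array(bone_name(distal_bone, digit))
    proj = _VIEWS[view]
    positions = np.stack([mcp @ proj, pip @ proj, tip @ proj], axis=1)
    return MarkerTrack2D(positions=positions, frame_rate=recording.frame_rate)


def compare_trajectories(
    a: np.ndarray, a_rate: float,
    b: np.ndarray, b_rate: float,
    a_start_s: float = 0.0, b_start_s: float = 0.0,
) -> TrajectoryComparison:
    """Compare two angle trajectories sampled at (possibly different) rates.

    Both are linearly resampled onto the coarser rate's time grid over the
    overlapping span, then differenced (a - b).  Raises
    :class:`NoOverlapError` when the spans are disjoint.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise HandkinError("both series need at least 2 frames")
    if a_rate <= 0 or b_rate <= 0:
        raise HandkinError("frame rates must be > 0")
    ta = a_start_s + np.arange(a.size) / a_rate
    tb = b_start_s + np.arange(b.size) / b_rate
    t0 = max(ta[0], tb[0])
    t1 = min(ta[-1], tb[-1])
    if t1 <= t0:
        raise NoOverlapError("trajectories share no common time span")
    coarse = ta if a_rate <= b_rate else tb
    grid = coarse[(coarse >= t0) & (coarse <= t1)]
    if grid.size < 2:
        raise NoOverlapError("overlap contains fewer than 2 samples")
    ra = np.interp(grid, ta, a)
    rb = np.interp(grid, tb, b)
    diff = ra - rb
    return TrajectoryComparison(
        times_s=grid, a=ra, b=rb, diff=diff,
        rmse=float(np.sqrt(np.mean(diff ** 2))),
        max_abs=float(np.max(np.abs(diff))),
        bias=float(np.mean(diff)),
    )


_CSV_HEADER = ["frame", "t", "x_mcp", "y_mcp", "x_pip", "y_pip", "x_tip", "y_tip"]


def write_marker_csv(track: MarkerTrack2D, destination: Union[str, Path]) -> None:
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        times = track.times()
        for i in range(track.n_frames):
            row = [i, repr(float(times[i]))]
            for m in range(3):
                row.extend([repr(float(track.positions[i, m, 0])),
                            repr(float(track.positions[i, m, 1]))])
            writer.writerow(row)


def read_marker_csv(source: Union[str, Path]) -> MarkerTrack2D:
    with open(source, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _CSV_HEADER:
            raise HandkinError(f"marker CSV must start with header {','.join(_CSV_HEADER)}")
        times = []
        rows = []
        for row in reader:
            if not row:
                continue
            times.append(float(row[1]))
            vals = [float(v) for v in row[2:8]]
            rows.append([[vals[0], vals[1]], [vals[2], vals[3]], [vals[4], vals[5]]])
    if len(rows) < 2:
        raise HandkinError("marker CSV needs at least 2 frames")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise HandkinError("marker CSV times must be strictly increasing")
    return MarkerTrack2D(positions=np.array(rows), frame_rate=1.0 / float(np.mean(dt)),
                         start_time_s=float(times[0]))
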