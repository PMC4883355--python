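"""Motion-capture coordinate tables and named joint-axis channels.

A capture session exports a flat numeric table: one row per frame, 84
columns holding the (x, y, z) position of each of the 28 tracked body
sites, at 100 frames per second.  This module reads and writes that table
as delimited text and extracts single joint-axis channels, e.g. the hip
vertical coordinate that drives gait classification downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SITE_NAMES",
    "AXES",
    "N_SITES",
    "N_CHANNELS",
    "MotionSequence",
    "ChannelSeries",
    "MotionTableError",
    "read_motion_table",
    "write_motion_table",
    "extract_channel",
    "channel_index",
    "channel_names",
]

#: The 28 tracked body sites, in canonical export order.
SITE_NAMES: tuple[str, ...] = (
    "hips",
    "breast",
    "breast2",
    "breast3",
    "breast4",
    "neck",
    "head",
    "head_end",
    "right_nape",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "right_wrist_end",
    "left_nape",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "left_wrist_end",
    "right_hip",
    "right_knee",
    "right_ankle",
    "right_toe",
    "right_tiptoe",
    "left_hip",
    "left_knee",
    "left_ankle",
    "left_toe",
    "left_tiptoe",
)

AXES: tuple[str, ...] = ("x", "y", "z")
N_SITES = len(SITE_NAMES)
N_CHANNELS = N_SITES * len(AXES)  # 84


class MotionTableError(ValueError):
    """Raised for malformed motion tables or invalid channel lookups."""


def channel_names() -> list[str]:
    """All 84 channel names ``"<joint>_<axis>"`` in column order."""
    return [f"{joint}_{axis}" for joint in SITE_NAMES for axis in AXES]


def channel_index(joint: str, axis: str) -> int:
    """Column index of a (joint, axis) pair.

    Columns are laid out joint-major: the three axes of one site are
    adjacent, sites follow the canonical listing order.
    """
    if joint not in SITE_NAMES:
        raise MotionTableError(
            f"unknown joint {joint!r}; valid joints: {', '.join(SITE_NAMES)}"
        )
    if axis not in AXES:
        raise MotionTableError(f"unknown axis {axis!r}; valid axes: x, y, z")
    return SITE_NAMES.index(joint) * 3 + AXES.index(axis)


@dataclass
class MotionSequence:
    """Frames x 84 coordinate matrix with joint/axis labelling.

    Parameters
    ----------
    values : ndarray, shape (n_frames, 84)
        Per-frame coordinates; units are carried opaquely from the export.
    frame_rate : float
        Capture rate in frames per second (default 100).
    joint_names : tuple of str
        The 28 site names, in column-block order.
    """

    values: np.ndarray
    frame_rate: float = 100.0
    joint_names: tuple[str, ...] = field(default=SITE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise MotionTableError(
                f"motion values must be (n_frames, {N_CHANNELS}); "
                f"got shape {self.values.shape}"
            )
        if len(self.joint_names) != N_SITES:
            raise MotionTableError(
                f"expected {N_SITES} joint names, got {len(self.joint_names)}"
            )
        if not self.frame_rate > 0:
            raise MotionTableError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class ChannelSeries:
    """A single scalar channel (one joint, one axis) over frames."""

    samples: np.ndarray
    joint: str
    axis: str
    frame_rate: float = 100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise MotionTableError("channel must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise MotionTableError("channel contains non-finite values")


def read_motion_table(
    path: str | Path, delimiter: str = ",", frame_rate: float = 100.0
) -> MotionSequence:
    """Read a delimited motion table into a :class:`MotionSequence`.

    The file holds one frame per line with exactly 84 numeric columns; an
    optional first line naming the channels (``hips_x,hips_y,...``) is
    skipped automatically.  Malformed rows raise :class:`MotionTableError`
    naming the offending line.
    """
    path = Path(path)
    # Line-by-line parse: the contract requires exact column counts and
    # errors that name the bad line, which bulk readers do not report.
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    start = 0
    if lines and _is_header(lines[0], delimiter):
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split(delimiter)
        if len(fields) != N_CHANNELS:
            raise MotionTableError(
                f"{path.name}, line {lineno}: expected {N_CHANNELS} columns, "
                f"got {len(fields)}"
            )
        try:
            row = [float(f) for f in fields]
        except ValueError as exc:
            raise MotionTableError(
                f"{path.name}, line {lineno}: non-numeric value ({exc})"
            ) from None
        if not all(np.isfinite(row)):
            raise MotionTableError(
                f"{path.name}, line {lineno}: non-finite value"
            )
        rows.append(row)
    if not lines:
        raise MotionTableError(f"{path.name}: empty file")
    # header-only files are valid 0-frame sequences
    values = np.array(rows, dtype=float).reshape(len(rows), N_CHANNELS)
    return MotionSequence(values=values, frame_rate=frame_rate)


def _is_header(line: str, delimiter: str) -> bool:
    fields = line.split(delimiter)
    try:
        float(fields[0])
    except ValueError:
        return True
    return False


def write_motion_table(
    seq: MotionSequence, path: str | Path, delimiter: str = ","
) -> None:
    """Write a motion table re-readable by :func:`read_motion_table`.

    Values are printed with 17 significant digits so a round trip is
    bitwise exact for doubles.
    """
    path = Path(path)
    header = delimiter.join(channel_names())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in seq.values:
            fh.write(delimiter.join(f"{v:.17g}" for v in row) + "\n")


def extract_channel(seq: MotionSequence, joint: str, axis: str) -> ChannelSeries:
    """Extract the single (joint, axis) column, e.g. ``("hips", "y")`` for
    the hip vertical value used as the gait signal."""
    col = channel_index(joint, axis)
    return ChannelSeries(
        samples=seq.values[:, col].copy(),
        joint=joint,
        axis=axis,
        frame_rate=seq.frame_rate,
    )
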