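"""Per-frame skeleton parameters from BODY_25 joint coordinates.

Eleven parameters are computed per frame, all in image space (pixels,
y-down): shoulder angles/lengths from joint pairs (2,1) and (5,1), hip
angles/lengths from (9,8) and (12,8), the right thigh from (10,9), and the
trunk angle from (1,8).

Segment angles are the absolute arctangent of the segment slope, in
[0, 90] degrees; a vertical segment maps to exactly 90.  The trunk angle
uses the signed arctangent folded into [0, 180).  Lengths are Euclidean
distances in pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSegmentError, InputError
from .keypoints_io import KeypointFrame, SkeletonSequence

#: Canonical parameter order used for every table, CSV and feature vector.
PARAMETER_NAMES: tuple[str, ...] = (
    "left_shoulder_angle",
    "left_shoulder_length",
    "right_shoulder_angle",
    "right_shoulder_length",
    "left_hip_angle",
    "left_hip_length",
    "right_hip_angle",
    "right_hip_length",
    "right_thigh_angle",
    "right_thigh_length",
    "trunk_angle",
)

# (joint a, joint b) pairs; angle/length parameters share the pair.
_SEGMENTS = {
    "left_shoulder": (5, 1),
    "right_shoulder": (2, 1),
    "left_hip": (12, 8),
    "right_hip": (9, 8),
    "right_thigh": (10, 9),
}
_TRUNK = (1, 8)

GEOMETRY_JOINTS = frozenset({1, 2, 5, 8, 9, 10, 12})


def segment_angle(a: Sequence[float], b: Sequence[float]) -> float:
    """|arctan(slope)| of segment a-b, in degrees within [0, 90].

    A vertical segment returns exactly 90 (the arctangent limit).  The value
    is symmetric under endpoint swap.
    """
    dx = float(a[0]) - float(b[0])
    dy = float(a[1]) - float(b[1])
    if dx == 0.0 and dy == 0.0:
        raise DegenerateSegmentError(f"coincident joints at {tuple(a)}")
    # atan2(|dy|, |dx|) == |atan(dy/dx)| and handles dx == 0 -> 90 exactly
    return math.degrees(math.atan2(abs(dy), abs(dx)))


def segment_length(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two joints, in pixels."""
    return math.hypot(float(a[0]) - float(b[0]), float(a[1]) - float(b[1]))


def trunk_angle(neck: Sequence[float], mid_hip: Sequence[float]) -> float:
    """Signed slope angle of the neck-to-mid-hip segment folded into [0, 180).

    phi = arctan((y_neck - y_hip) / (x_neck - x_hip)) in degrees; the result
    is phi when phi >= 0 and phi + 180 otherwise.  A vertical trunk gives 90.
    """
    dx = float(neck[0]) - float(mid_hip[0])
    dy = float(neck[1]) - float(mid_hip[1])
    if dx == 0.0 and dy == 0.0:
        raise DegenerateSegmentError("neck and mid-hip coincide")
    return math.degrees(math.atan2(dy, dx)) % 180.0


def compute_parameter_frame(frame: KeypointFrame) -> dict[str, float]:
    """The 11 skeleton parameters for one frame, keyed in canonical order.

    Requires joints {1, 2, 5, 8, 9, 10, 12} to be valid.
    """
    missing = [j for j in sorted(GEOMETRY_JOINTS) if not frame.valid[j]]
    if missing:
        raise InputError(
            f"frame {frame.frame_index}: required joints missing: {missing}"
        )
    xy = frame.xy
    out: dict[str, float] = {}
    for stem, (ja, jb) in _SEGMENTS.items():
        try:
            out[f"{stem}_angle"] = segment_angle(xy[ja], xy[jb])
        except DegenerateSegmentError as exc:
            raise DegenerateSegmentError(
                f"frame {frame.frame_index}, {stem}_angle: {exc}"
            ) from exc
        out[f"{stem}_length"] = segment_length(xy[ja], xy[jb])
    try:
        out["trunk_angle"] = trunk_angle(xy[_TRUNK[0]], xy[_TRUNK[1]])
    except DegenerateSegmentError as exc:
        raise DegenerateSegmentError(
            f"frame {frame.frame_index}, trunk_angle: {exc}"
        ) from exc
    return {name: out[name] for name in PARAMETER_NAMES}


@dataclass
class ParameterSeries:
    """One skeleton parameter's value across the T frames of a recording."""

    parameter_name: str
    values: np.ndarray
    subject_id: str = "unknown"
    session_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.parameter_name not in PARAMETER_NAMES:
            raise InputError(f"unknown parameter name: {self.parameter_name!r}")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def compute_parameter_series(seq: SkeletonSequence) -> list[ParameterSeries]:
    """All 11 parameter series for a cleaned sequence, in canonical order.

    Vectorised over frames; raises :class:`DegenerateSegmentError` naming the
    first offending frame if any segment collapses to a point.
    """
    if not seq.frames:
        raise InputError("empty sequence")
    valid = seq.valid_mask()
    req = sorted(GEOMETRY_JOINTS)
    bad = ~valid[:, req].all(axis=1)
    if bad.any():
        t = int(np.flatnonzero(bad)[0])
        raise InputError(
            f"frame {seq.frames[t].frame_index}: required joints missing"
        )
    xy = seq.coords()  # (T, 25, 2)
    values: dict[str, np.ndarray] = {}
    for stem, (ja, jb) in list(_SEGMENTS.items()) + [("trunk", _TRUNK)]:
        dx = xy[:, ja, 0] - xy[:, jb, 0]
        dy = xy[:, ja, 1] - xy[:, jb, 1]
        degenerate = (dx == 0) & (dy == 0)
        if degenerate.any():
            t = int(np.flatnonzero(degenerate)[0])
            raise DegenerateSegmentError(
                f"frame {seq.frames[t].frame_index}, {stem}: coincident joints"
            )
        if stem == "trunk":
            values["trunk_angle"] = np.degrees(np.arctan2(dy, dx)) % 180.0
        else:
            values[f"{stem}_angle"] = np.degrees(np.arctan2(np.abs(dy), np.abs(dx)))
            values[f"{stem}_length"] = np.hypot(dx, dy)
    return [
        ParameterSeries(name, values[name], seq.subject_id, seq.session_label)
        for name in PARAMETER_NAMES
    ]


def series_to_frame(series_list: Sequence[ParameterSeries]) -> pd.DataFrame:
    """Parameter series as a tidy DataFrame (subject_id, session, frame, 11 columns)."""
    if not series_list:
        raise InputError("no series given")
    first = series_list[0]
    df = pd.DataFrame(
        {
            "subject_id": first.subject_id,
            "session": first.session_label,
            "frame": np.arange(len(first)),
        }
    )
    for s in series_list:
        df[s.parameter_name] = s.values
    return df


def write_parameter_csv(series_list: Sequence[ParameterSeries], path: str | Path) -> Path:
    path = Path(path)
    series_to_frame(series_list).to_csv(path, index=False)
    return path


def read_parameter_csv(path: str | Path) -> list[list[ParameterSeries]]:
    """Read a parameter CSV; returns one series set per (subject, session) group."""
    df = pd.read_csv(path)
    needed = ["subject_id", "session"] + list(PARAMETER_NAMES)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    groups = []
    for (subject, session), g in df.groupby(["subject_id", "session"], sort=False):
        groups.append(
            [
                ParameterSeries(name, g[name].to_numpy(), str(subject), str(session))
                for name in PARAMETER_NAMES
            ]
        )
    return groups
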