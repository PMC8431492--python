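"""Reading, writing and cleaning BODY_25 keypoint sequences.

The on-disk dialects are:

* the OpenPose per-frame JSON dialect — one file per frame, a top-level
  ``"people"`` array, each person carrying a flat ``"pose_keypoints_2d"``
  array of 75 numbers (25 joints x (x, y, confidence));
* a flat CSV dialect — header ``frame, x0, y0, c0, ..., x24, y24, c24``,
  one row per frame.

Coordinates stay in raw image convention (origin top-left, y increases
downward, units pixels).  An undetected joint is encoded ``(0, 0, 0)`` and
is always treated as missing; a joint whose confidence falls below the
validity threshold is missing as well.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, KeypointFormatError, UnusableRecordingError

N_JOINTS = 25

#: Joints consumed by the geometry stage: neck, shoulders, mid/left/right hip,
#: right knee.
DEFAULT_REQUIRED_JOINTS = frozenset({1, 2, 5, 8, 9, 10, 12})

DEFAULT_CONF_THRESHOLD = 0.1
DEFAULT_JUMP_THRESHOLD = 150.0

CSV_COLUMNS = ["frame"] + [
    f"{axis}{j}" for j in range(N_JOINTS) for axis in ("x", "y", "c")
]


def _validity_mask(joints: np.ndarray, conf_threshold: float) -> np.ndarray:
    """A joint is missing when encoded (0,0,0) or when confidence < threshold."""
    undetected = np.all(joints == 0.0, axis=-1)
    low_conf = joints[..., 2] < conf_threshold
    return ~(undetected | low_conf)


@dataclass
class KeypointFrame:
    """One frame's 25 detected joints.

    Attributes
    ----------
    frame_index
        Non-negative frame number.
    joints
        ``(25, 3)`` float array of (x, y, confidence) in BODY_25 order.
    valid
        ``(25,)`` boolean mask; ``False`` marks a missing joint.
    """

    frame_index: int
    joints: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    conf_threshold: float = DEFAULT_CONF_THRESHOLD

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.shape != (N_JOINTS, 3):
            raise KeypointFormatError(
                f"frame {self.frame_index}: expected (25, 3) joints, "
                f"got {self.joints.shape}"
            )
        if self.frame_index < 0:
            raise KeypointFormatError("frame_index must be non-negative")
        if self.valid is None:
            self.valid = _validity_mask(self.joints, self.conf_threshold)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (N_JOINTS,):
                raise KeypointFormatError("valid mask must have shape (25,)")

    @property
    def xy(self) -> np.ndarray:
        """``(25, 2)`` view of the joint coordinates."""
        return self.joints[:, :2]

    @property
    def confidence(self) -> np.ndarray:
        return self.joints[:, 2]


@dataclass
class SkeletonSequence:
    """A single subject's ordered keypoint frames for one recording."""

    subject_id: str
    session_label: str
    frames: list[KeypointFrame]
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InputError("fps must be positive")
        indices = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise InputError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def T(self) -> int:
        return len(self.frames)

    def coords(self) -> np.ndarray:
        """Stacked ``(T, 25, 2)`` coordinate array."""
        return np.stack([f.xy for f in self.frames]) if self.frames else np.empty((0, N_JOINTS, 2))

    def valid_mask(self) -> np.ndarray:
        """Stacked ``(T, 25)`` validity array."""
        return np.stack([f.valid for f in self.frames]) if self.frames else np.empty((0, N_JOINTS), bool)


# ---------------------------------------------------------------------------
# OpenPose JSON dialect
# ---------------------------------------------------------------------------

_DIGITS = re.compile(r"(\d+)")


def _frame_sort_key(path: Path) -> tuple:
    """Order files by the last run of digits in the stem, then lexically."""
    runs = _DIGITS.findall(path.stem)
    return (int(runs[-1]) if runs else -1, path.name)


def _parse_person(raw: dict, path: Path) -> np.ndarray:
    kp = raw.get("pose_keypoints_2d")
    if kp is None or len(kp) != 3 * N_JOINTS:
        n = "absent" if kp is None else len(kp)
        raise KeypointFormatError(
            f"{path}: pose_keypoints_2d must hold 75 numbers, got {n}"
        )
    return np.asarray(kp, dtype=float).reshape(N_JOINTS, 3)


def _required_conf(person: np.ndarray, required: frozenset[int]) -> float:
    idx = sorted(required)
    return float(person[idx, 2].sum())


def _centroid(person: np.ndarray, required: frozenset[int], conf_threshold: float) -> np.ndarray | None:
    idx = sorted(required)
    pts = person[idx]
    ok = _validity_mask(pts, conf_threshold)
    if not ok.any():
        return None
    return pts[ok, :2].mean(axis=0)


def read_openpose_json_dir(
    path: str | Path,
    *,
    person_policy: str = "track",
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    required_joints: Iterable[int] = DEFAULT_REQUIRED_JOINTS,
    jump_threshold: float = DEFAULT_JUMP_THRESHOLD,
    subject_id: str = "unknown",
    session_label: str = "unknown",
    fps: float = 30.0,
) -> SkeletonSequence:
    """Read a directory of per-frame OpenPose JSON files into one sequence.

    ``person_policy`` is ``"max-confidence"`` (per frame, pick the person with
    the highest summed confidence over the required joints) or ``"track"``
    (same rule for the first usable frame, then nearest-centroid tracking with
    a max-confidence fallback when the centroid jumps more than
    ``jump_threshold`` pixels).
    """
    if person_policy not in ("track", "max-confidence"):
        raise InputError(f"unknown person_policy: {person_policy!r}")
    required = frozenset(required_joints)
    directory = Path(path)
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() == ".json"),
        key=_frame_sort_key,
    ) if directory.is_dir() else []
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    if not files:
        raise InputError(f"no JSON files in {directory}")

    empty = np.zeros((N_JOINTS, 3))
    frames: list[KeypointFrame] = []
    prev_centroid: np.ndarray | None = None
    for i, file in enumerate(files):
        try:
            payload = json.loads(file.read_text())
        except json.JSONDecodeError as exc:
            raise KeypointFormatError(f"{file}: malformed JSON ({exc})") from exc
        if "people" not in payload:
            raise KeypointFormatError(f"{file}: missing top-level 'people' array")
        people = [_parse_person(p, file) for p in payload["people"]]
        if not people:
            chosen = empty
        elif len(people) == 1:
            chosen = people[0]
        else:
            chosen = _select_person(
                people, required, conf_threshold, person_policy,
                prev_centroid, jump_threshold,
            )
        frames.append(KeypointFrame(i, chosen, conf_threshold=conf_threshold))
        if people:
            c = _centroid(chosen, required, conf_threshold)
            if c is not None:
                prev_centroid = c
    return SkeletonSequence(subject_id, session_label, frames, fps=fps)


def _select_person(
    people: list[np.ndarray],
    required: frozenset[int],
    conf_threshold: float,
    policy: str,
    prev_centroid: np.ndarray | None,
    jump_threshold: float,
) -> np.ndarray:
    by_conf = max(people, key=lambda p: _required_conf(p, required))
    if policy == "max-confidence" or prev_centroid is None:
        return by_conf
    best, best_dist = None, np.inf
    for person in people:
        c = _centroid(person, required, conf_threshold)
        if c is None:
            continue
        d = float(np.hypot(*(c - prev_centroid)))
        if d < best_dist:
            best, best_dist = person, d
    if best is None or best_dist > jump_threshold:
        return by_conf
    return best


def write_openpose_json_dir(seq: SkeletonSequence, path: str | Path) -> list[Path]:
    """Write one OpenPose-dialect JSON file per frame; returns the paths."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for frame in seq.frames:
        payload = {
            "version": 1.3,
            "people": [
                {"pose_keypoints_2d": [float(v) for v in frame.joints.ravel()]}
            ],
        }
        file = directory / f"frame_{frame.frame_index:012d}_keypoints.json"
        file.write_text(json.dumps(payload))
        out.append(file)
    return out


# ---------------------------------------------------------------------------
# Flat CSV dialect
# ---------------------------------------------------------------------------

def read_keypoints_csv(
    path: str | Path,
    *,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    subject_id: str = "unknown",
    session_label: str = "unknown",
    fps: float = 30.0,
) -> SkeletonSequence:
    """Read the flat keypoint CSV dialect (frame, x0, y0, c0, ..., c24)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise KeypointFormatError(f"{path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise KeypointFormatError(f"{path}: missing columns {missing}")
    frames = []
    for _, row in df.iterrows():
        joints = row[CSV_COLUMNS[1:]].to_numpy(dtype=float).reshape(N_JOINTS, 3)
        frames.append(
            KeypointFrame(int(row["frame"]), joints, conf_threshold=conf_threshold)
        )
    return SkeletonSequence(subject_id, session_label, frames, fps=fps)


def write_keypoints_csv(seq: SkeletonSequence, path: str | Path) -> Path:
    """Write the flat CSV dialect; round-trips with :func:`read_keypoints_csv`."""
    path = Path(path)
    rows = np.column_stack(
        [
            np.array([f.frame_index for f in seq.frames], dtype=float),
            np.stack([f.joints.ravel() for f in seq.frames]),
        ]
    ) if seq.frames else np.empty((0, 76))
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def clean_sequence(
    seq: SkeletonSequence,
    required_joints: Iterable[int] = DEFAULT_REQUIRED_JOINTS,
) -> SkeletonSequence:
    """Trim unusable edges and interpolate internal detection gaps.

    Leading and trailing frames in which any required joint is missing are
    dropped.  Internal gaps are filled by per-coordinate linear interpolation
    between the nearest valid frames; interpolated joints get confidence 0 but
    are marked valid.  The result has no missing required joints and at least
    two frames, otherwise :class:`UnusableRecordingError` is raised.

    Idempotent, and never increases the frame count.
    """
    required = sorted(set(required_joints))
    if not seq.frames:
        raise UnusableRecordingError("empty sequence")
    valid = seq.valid_mask()
    usable = valid[:, required].all(axis=1)
    if not usable.any():
        raise UnusableRecordingError(
            f"no frame has all required joints {required} detected"
        )
    first, last = np.flatnonzero(usable)[[0, -1]]
    if last - first + 1 < 2:
        raise UnusableRecordingError("fewer than 2 usable frames after trimming")

    joints = np.stack([f.joints for f in seq.frames])[first : last + 1].copy()
    valid = valid[first : last + 1].copy()
    indices = [f.frame_index for f in seq.frames][first : last + 1]
    t = np.arange(joints.shape[0])
    for j in range(N_JOINTS):
        ok = valid[:, j]
        gaps = ~ok
        if not gaps.any() or not ok.any():
            continue
        # only fill positions bracketed by valid frames of this joint
        lo, hi = np.flatnonzero(ok)[[0, -1]]
        fill = gaps & (t >= lo) & (t <= hi)
        if not fill.any():
            continue
        for axis in range(2):
            joints[fill, j, axis] = np.interp(t[fill], t[ok], joints[ok, j, axis])
        joints[fill, j, 2] = 0.0
        valid[fill, j] = True

    frames = [
        KeypointFrame(idx, joints[k], valid=valid[k])
        for k, idx in enumerate(indices)
    ]
    return SkeletonSequence(seq.subject_id, seq.session_label, frames, fps=seq.fps)
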