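import json
from pathlib import Path

import numpy as np
import pytest

from skelquant.keypoints_io import KeypointFrame, N_JOINTS, SkeletonSequence

#: Axis-aligned posture used in hand-checked geometry examples:
#: neck (100,100), shoulders +-30 px on the same row, mid-hip (100,200),
#: hips +-20 px on the same row, right knee straight below the right hip.
AXIS_ALIGNED = {
    1: (100.0, 100.0),   # neck
    2: (130.0, 100.0),   # right shoulder
    5: (70.0, 100.0),    # left shoulder
    8: (100.0, 200.0),   # mid hip
    9: (120.0, 200.0),   # right hip
    10: (120.0, 260.0),  # right knee
    12: (80.0, 200.0),   # left hip
}


def make_frame(coords: dict[int, tuple[float, float]], frame_index: int = 0,
               confidence: float = 0.9) -> KeypointFrame:
    """Frame with the given joints detected and all others missing."""
    joints = np.zeros((N_JOINTS, 3))
    for j, (x, y) in coords.items():
        joints[j] = (x, y, confidence)
    return KeypointFrame(frame_index, joints)


def make_sequence(frames, subject="s1", session="before", fps=30.0) -> SkeletonSequence:
    return SkeletonSequence(subject, session, list(frames), fps=fps)


def static_sequence(T: int, coords=None, **kwargs) -> SkeletonSequence:
    coords = coords or AXIS_ALIGNED
    return make_sequence([make_frame(coords, i) for i in range(T)], **kwargs)


def write_openpose_frame(path: Path, people_joints, version=1.3) -> None:
    """Write one OpenPose-dialect JSON file; people_joints is a list of
    (25, 3) arrays (or raw keypoint lists)."""
    people = []
    for joints in people_joints:
        flat = np.asarray(joints, dtype=float).ravel().tolist()
        people.append({"pose_keypoints_2d": flat})
    path.write_text(json.dumps({"version": version, "people": people}))


@pytest.fixture
def axis_aligned_frame() -> KeypointFrame:
    return make_frame(AXIS_ALIGNED)


@pytest.fixture
def openpose_dir(tmp_path):
    """Factory: write a directory of per-frame JSON files, return its path."""
    counter = {"n": 0}

    def _write(frames_people):
        counter["n"] += 1
        d = tmp_path / f"op{counter['n']}"
        d.mkdir()
        for i, people in enumerate(frames_people):
            write_openpose_frame(d / f"frame_{i:012d}_keypoints.json", people)
        return d

    return _write
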