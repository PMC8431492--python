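"""Synthetic seated-child keypoint streams with controllable motion.

Generates BODY_25 sequences from a hard-coded seated base posture in a
640x480 image (y down).  Per-joint jitter follows independent stationary
AR(1) displacement processes whose stationary SD is the configured
``jitter_sd`` (the innovation SD is derived, so ground truth is comparable
across persistence values).  Two correlated, body-plausible motion modes
are layered on top: a sinusoidal horizontal sway of the head/shoulder
girdle and an oscillating swivel of the hip/leg joints about the mid-hip.
Optional dropout replaces joints with the (0, 0, 0) undetected encoding.

Identical configs and seeds reproduce identical sequences bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import ConfigError
from .keypoints_io import KeypointFrame, N_JOINTS, SkeletonSequence

#: Seated child facing the camera, image 640x480, origin top-left, y down.
#: Mirror-image convention: the subject's right side appears at smaller x.
BASE_SEATED_POSTURE: np.ndarray = np.array(
    [
        [320.0, 140.0],  # 0  nose
        [320.0, 185.0],  # 1  neck
        [272.0, 190.0],  # 2  right shoulder
        [262.0, 245.0],  # 3  right elbow
        [268.0, 295.0],  # 4  right wrist
        [368.0, 190.0],  # 5  left shoulder
        [378.0, 245.0],  # 6  left elbow
        [372.0, 295.0],  # 7  left wrist
        [320.0, 305.0],  # 8  middle hip
        [285.0, 305.0],  # 9  right hip
        [272.0, 385.0],  # 10 right knee
        [268.0, 455.0],  # 11 right ankle
        [355.0, 305.0],  # 12 left hip
        [368.0, 385.0],  # 13 left knee
        [372.0, 455.0],  # 14 left ankle
        [308.0, 132.0],  # 15 right eye
        [332.0, 132.0],  # 16 left eye
        [296.0, 140.0],  # 17 right ear
        [344.0, 140.0],  # 18 left ear
        [380.0, 470.0],  # 19 left big toe
        [388.0, 468.0],  # 20 left small toe
        [370.0, 462.0],  # 21 left heel
        [260.0, 470.0],  # 22 right big toe
        [252.0, 468.0],  # 23 right small toe
        [270.0, 462.0],  # 24 right heel
    ]
)

_SWAY_JOINTS = (0, 1, 2, 5, 15, 16, 17, 18)  # head + shoulder girdle
_SWIVEL_JOINTS = (9, 10, 11, 12, 13, 14, 19, 20, 21, 22, 23, 24)  # hips + legs
_SWIVEL_CENTER = 8  # mid hip

DETECTED_CONFIDENCE = 0.9


@dataclass
class MotionConfig:
    """Generation settings for one synthetic recording."""

    T: int = 300
    fps: float = 30.0
    ar_coefficient: float = 0.8
    jitter_sd: float = 2.0
    sway_amplitude: float = 2.0
    sway_frequency_hz: float = 0.25
    swivel_amplitude_deg: float = 2.0
    swivel_frequency_hz: float = 0.2
    dropout_rate: float = 0.0
    seed: int = 0
    base_posture: np.ndarray = field(
        default_factory=lambda: BASE_SEATED_POSTURE.copy()
    )

    def __post_init__(self) -> None:
        self.base_posture = np.asarray(self.base_posture, dtype=float)
        if self.base_posture.shape != (N_JOINTS, 2):
            raise ConfigError("base_posture must have shape (25, 2)")
        if self.T < 2:
            raise ConfigError("T must be >= 2")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ConfigError("ar_coefficient must be in [0, 1)")
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must be in [0, 1)")


def _ar1_displacements(rng: np.random.Generator, T: int, phi: float, sd: float) -> np.ndarray:
    """(T, 25, 2) stationary AR(1) paths with stationary SD exactly ``sd``."""
    u = np.empty((T, N_JOINTS, 2))
    u[0] = rng.normal(scale=1.0, size=(N_JOINTS, 2)) * sd
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(scale=1.0, size=(T - 1, N_JOINTS, 2)) * innov_sd
    for t in range(1, T):
        u[t] = phi * u[t - 1] + eps[t - 1]
    return u


def generate_sequence(
    cfg: MotionConfig,
    *,
    subject_id: str = "sim",
    session_label: str = "before",
) -> SkeletonSequence:
    """One synthetic recording as a :class:`SkeletonSequence`."""
    rng = np.random.default_rng(cfg.seed)
    T = cfg.T
    coords = np.broadcast_to(cfg.base_posture, (T, N_JOINTS, 2)).copy()
    coords += _ar1_displacements(rng, T, cfg.ar_coefficient, cfg.jitter_sd)

    t = np.arange(T)
    if cfg.sway_amplitude > 0:
        sway = cfg.sway_amplitude * np.sin(
            2.0 * np.pi * cfg.sway_frequency_hz * t / cfg.fps
        )
        coords[:, _SWAY_JOINTS, 0] += sway[:, None]
    if cfg.swivel_amplitude_deg > 0:
        angle = np.radians(
            cfg.swivel_amplitude_deg
            * np.sin(2.0 * np.pi * cfg.swivel_frequency_hz * t / cfg.fps)
        )
        center = coords[:, _SWIVEL_CENTER, :][:, None, :]
        rel = coords[:, _SWIVEL_JOINTS, :] - center
        cos, sin = np.cos(angle)[:, None], np.sin(angle)[:, None]
        rotated = np.stack(
            [
                cos * rel[..., 0] - sin * rel[..., 1],
                sin * rel[..., 0] + cos * rel[..., 1],
            ],
            axis=-1,
        )
        coords[:, _SWIVEL_JOINTS, :] = center + rotated

    joints = np.concatenate(
        [coords, np.full((T, N_JOINTS, 1), DETECTED_CONFIDENCE)], axis=-1
    )
    if cfg.dropout_rate > 0:
        dropped = rng.random((T, N_JOINTS)) < cfg.dropout_rate
        joints[dropped] = 0.0

    frames = [KeypointFrame(i, joints[i]) for i in range(T)]
    return SkeletonSequence(subject_id, session_label, frames, fps=cfg.fps)


@dataclass
class CohortConfig:
    """Paired-cohort generation: per-subject body variation, shared templates."""

    n_subjects: int = 25
    before: MotionConfig = field(default_factory=MotionConfig)
    after: MotionConfig = field(default_factory=MotionConfig)
    posture_jitter_sd: float = 6.0
    posture_scale_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.posture_jitter_sd < 0 or self.posture_scale_sd < 0:
            raise ConfigError("posture perturbation SDs must be >= 0")


def _subject_posture(cfg: CohortConfig, subject_index: int) -> np.ndarray:
    """Distinct body proportions: global scale about mid-hip plus joint offsets."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, subject_index, 2])
    )
    scale = 1.0 + rng.normal() * cfg.posture_scale_sd
    scale = max(scale, 0.5)
    base = BASE_SEATED_POSTURE
    center = base[_SWIVEL_CENTER]
    posture = center + scale * (base - center)
    posture = posture + rng.normal(size=base.shape) * cfg.posture_jitter_sd
    return posture


def generate_paired_cohort(
    cfg: CohortConfig,
) -> Iterator[tuple[str, SkeletonSequence, SkeletonSequence]]:
    """Yield (subject_id, before_sequence, after_sequence) per subject.

    Before/after share the subject's perturbed base posture and differ only
    in motion parameters and noise realisation; seeds are derived
    deterministically from the cohort seed and subject index.
    """
    for i in range(cfg.n_subjects):
        subject_id = f"subj_{i + 1:03d}"
        posture = _subject_posture(cfg, i)
        seq_pair = []
        for session_code, (label, template) in enumerate(
            [("before", cfg.before), ("after", cfg.after)]
        ):
            seed = int(
                np.random.SeedSequence(
                    [cfg.seed, i, session_code]
                ).generate_state(1)[0]
            )
            session_cfg = replace(template, seed=seed, base_posture=posture.copy())
            seq_pair.append(
                generate_sequence(
                    session_cfg, subject_id=subject_id, session_label=label
                )
            )
        yield subject_id, seq_pair[0], seq_pair[1]
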