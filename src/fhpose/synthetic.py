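"""Synthetic labeled sedentary poses with a controllable forward-head mechanism.

The generator articulates a 17-joint skeleton from fixed anthropometric
segment proportions, draws head pitch and shoulder protraction from
class-conditional distributions, and assigns the class label by a proxy of
the clinical tragus/acromion criterion: a pose is FHP when the head keypoint
lies anterior (+x) to the shoulder midpoint by more than a margin, measured
in the normalized coordinate frame.  The drawn head pitch is clamped (by a
root solve on the normalized anterior offset) so every emitted pose satisfies
its label's criterion before yaw and noise are applied; classes therefore
touch at the margin boundary, mirroring the overlap seen in real shoulder
angle distributions.

Emitted poses follow the upstream lifter's convention: coordinates are
max-abs normalized to roughly [-1, 1], with a random global yaw and additive
Gaussian keypoint noise on top.  Downstream :func:`~fhpose.preprocess.normalize_pose`
exactly recovers the canonical frame in which the label was enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError
from .preprocess import normalize_pose, yaw_rotation
from .skeleton import N_JOINTS

NORMAL, FHP = 0, 1
LABEL_NAMES = {NORMAL: "Normal", FHP: "FHP"}

# Anthropometric segment proportions (pre-normalization units; absolute
# values are irrelevant after max-abs scaling).
HIP_HALFWIDTH = 0.12
THIGH_FORWARD = 0.35          # seated: thigh roughly horizontal
KNEE_DROP = 0.05
SHIN_DROP = 0.35
LOWER_SPINE = 0.22
UPPER_SPINE = 0.22
NECK_LEN = 0.10
HEAD_LEN = 0.22               # thorax → head keypoint along the pitched axis
SHOULDER_HALFWIDTH = 0.18
SHOULDER_RAISE = 0.02

# Arm templates: (elbow offset from shoulder, wrist offset from elbow),
# given for the left side; the right side mirrors y.
ARM_TEMPLATES = {
    "driving": ((0.10, 0.00, -0.11), (0.18, -0.05, 0.02)),
    "phone":   ((0.03, 0.00, -0.15), (0.14, -0.08, 0.12)),
    "tablet":  ((0.05, 0.00, -0.14), (0.15, -0.04, -0.04)),
    "rest":    ((0.00, 0.00, -0.15), (0.02, 0.00, -0.15)),
}

_PITCH_LO, _PITCH_HI = -1.3, 1.45      # rad, search bracket for the clamp
_PITCH_NUDGE = 0.015                   # rad, keeps clamped poses strictly off the boundary
_HEAD, _LSHO, _RSHO = 10, 11, 14       # original 17-joint indices


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Angle distributions are (mean, sd) in degrees.  ``fhp_fraction`` defaults
    to the 859/2387 class balance of the reference data collection.
    ``margin`` is the anterior-offset threshold of the labeling criterion in
    post-normalization coordinate units; ``noise_sd`` is additive keypoint
    noise in the same units.
    """

    n_samples: int = 2387
    fhp_fraction: float = 859 / 2387
    head_pitch_normal: tuple[float, float] = (0.0, 6.0)
    head_pitch_fhp: tuple[float, float] = (35.0, 8.0)
    shoulder_protraction_normal: tuple[float, float] = (5.0, 5.0)
    shoulder_protraction_fhp: tuple[float, float] = (20.0, 8.0)
    arm_pose_set: tuple[str, ...] = ("driving", "phone", "tablet", "rest")
    arm_jitter_sd: float = 0.01
    yaw_range: float = 30.0
    noise_sd: float = 0.02
    margin: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.fhp_fraction < 1.0:
            raise ValidationError("fhp_fraction must lie in (0, 1)")
        for name in ("head_pitch_normal", "head_pitch_fhp",
                     "shoulder_protraction_normal", "shoulder_protraction_fhp"):
            if getattr(self, name)[1] < 0:
                raise ValidationError(f"{name} sd must be non-negative")
        if self.head_pitch_fhp[0] <= self.head_pitch_normal[0]:
            raise ValidationError("FHP head-pitch mean must exceed the normal mean")
        if self.margin <= 0:
            raise ValidationError("margin must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        unknown = set(self.arm_pose_set) - set(ARM_TEMPLATES)
        if unknown:
            raise ValidationError(f"unknown arm templates: {sorted(unknown)}")


@dataclass(frozen=True)
class PoseDataset:
    """A labeled collection of 17-joint poses."""

    poses: np.ndarray                 # (n, 17, 3)
    labels: np.ndarray                # (n,), 0 = Normal, 1 = FHP
    provenance: tuple = ()            # per-sample generator parameters
    config: GeneratorConfig | None = None

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices) -> "PoseDataset":
        idx = np.asarray(indices, dtype=int)
        prov = tuple(self.provenance[i] for i in idx) if self.provenance else ()
        return PoseDataset(self.poses[idx], self.labels[idx], prov, self.config)


def _build_canonical(pitch_rad, protraction_rad, template, arm_jitter):
    """Articulate the 17-joint skeleton in the canonical (yaw-free) frame."""
    p = np.zeros((N_JOINTS, 3))
    # Pelvis and seated legs.
    p[1] = (0.0, -HIP_HALFWIDTH, 0.0)                       # right hip
    p[4] = (0.0, HIP_HALFWIDTH, 0.0)                        # left hip
    for hip, knee, ankle in ((1, 2, 3), (4, 5, 6)):
        p[knee] = p[hip] + (THIGH_FORWARD, 0.0, -KNEE_DROP)
        p[ankle] = p[knee] + (0.0, 0.0, -SHIN_DROP)
    # Spine chain.
    p[7] = (0.0, 0.0, LOWER_SPINE)                          # spine
    p[8] = (0.0, 0.0, LOWER_SPINE + UPPER_SPINE)            # thorax
    axis = np.array([np.sin(pitch_rad), 0.0, np.cos(pitch_rad)])
    p[9] = p[8] + NECK_LEN * axis                           # neck
    p[10] = p[8] + HEAD_LEN * axis                          # head
    # Shoulder girdle with protraction (forward rotation in the x-y plane).
    sx = SHOULDER_HALFWIDTH * np.sin(protraction_rad)
    sy = SHOULDER_HALFWIDTH * np.cos(protraction_rad)
    p[11] = p[8] + (sx, sy, SHOULDER_RAISE)                 # left shoulder
    p[14] = p[8] + (sx, -sy, SHOULDER_RAISE)                # right shoulder
    # Arms from the scenario template (left given, right mirrored in y).
    elbow_off, wrist_off = (np.array(v) for v in ARM_TEMPLATES[template])
    mirror = np.array([1.0, -1.0, 1.0])
    p[12] = p[11] + elbow_off + arm_jitter[0]
    p[13] = p[12] + wrist_off + arm_jitter[1]
    p[15] = p[14] + elbow_off * mirror + arm_jitter[2]
    p[16] = p[15] + wrist_off * mirror + arm_jitter[3]
    return p


def _normalized_offset(pitch_rad, protraction_rad, template, arm_jitter) -> float:
    """Head-to-shoulder-midpoint anterior offset in the normalized frame."""
    pose, _ = normalize_pose(_build_canonical(pitch_rad, protraction_rad,
                                              template, arm_jitter))
    return float(pose[_HEAD, 0] - 0.5 * (pose[_LSHO, 0] + pose[_RSHO, 0]))


def head_shoulder_offset(pose) -> float:
    """Anterior (depth) offset of the head relative to the shoulder midpoint.

    The pose must already be in the normalized canonical frame.
    """
    arr = np.asarray(pose, dtype=float)
    return float(arr[_HEAD, 0] - 0.5 * (arr[_LSHO, 0] + arr[_RSHO, 0]))


def label_by_alignment(pose, margin: float) -> int:
    """Tragus/acromion proxy criterion on the available keypoints.

    Returns :data:`FHP` iff the head keypoint lies anterior to the shoulder
    midpoint by more than ``margin`` along +x.  The pose must be normalized
    (pelvis at the origin, yaw-aligned so +x is anterior).
    """
    arr = np.asarray(pose, dtype=float)
    if np.max(np.abs(arr[0])) > 1e-6:
        raise ValidationError("pose is not normalized: pelvis is not at the origin")
    return FHP if head_shoulder_offset(arr) > margin else NORMAL


def generate_pose(label: int, rng: np.random.Generator,
                  config: GeneratorConfig | None = None):
    """Draw one labeled pose; returns ``(pose, provenance)``.

    The head pitch is clamped so the emitted pose satisfies its label's
    margin criterion in the canonical frame; yaw and noise are applied
    afterwards and never change the stored label.
    """
    config = config or GeneratorConfig()
    config.validate()
    if label not in (NORMAL, FHP):
        raise ValidationError(f"label must be 0 (Normal) or 1 (FHP), got {label!r}")

    pitch_dist = config.head_pitch_fhp if label == FHP else config.head_pitch_normal
    prot_dist = (config.shoulder_protraction_fhp if label == FHP
                 else config.shoulder_protraction_normal)
    pitch = np.radians(rng.normal(*pitch_dist))
    prot = np.radians(rng.normal(*prot_dist))
    template = str(rng.choice(np.array(config.arm_pose_set)))
    jitter = rng.normal(0.0, config.arm_jitter_sd, size=(4, 3))

    pitch = float(np.clip(pitch, _PITCH_LO + 0.05, _PITCH_HI - 0.05))
    margin = config.margin

    def offset(th):
        return _normalized_offset(th, prot, template, jitter)

    off = offset(pitch)
    if label == FHP and off <= margin:
        root = brentq(lambda t: offset(t) - margin, _PITCH_LO, _PITCH_HI)
        pitch = root + _PITCH_NUDGE
    elif label == NORMAL and abs(off) > margin:
        target = margin if off > margin else -margin
        root = brentq(lambda t: offset(t) - target, _PITCH_LO, _PITCH_HI)
        pitch = root - _PITCH_NUDGE if off > margin else root + _PITCH_NUDGE

    canonical, _ = normalize_pose(_build_canonical(pitch, prot, template, jitter))
    yaw = float(rng.uniform(-config.yaw_range, config.yaw_range))
    pose = canonical @ yaw_rotation(np.radians(yaw)).T
    pose = pose + rng.normal(0.0, config.noise_sd, size=pose.shape)

    provenance = {
        "label": int(label),
        "head_pitch_deg": float(np.degrees(pitch)),
        "shoulder_protraction_deg": float(np.degrees(prot)),
        "arm_template": template,
        "yaw_deg": yaw,
    }
    return pose, provenance


def generate_dataset(config: GeneratorConfig | None = None) -> PoseDataset:
    """Generate a labeled dataset with the configured class balance.

    Class counts follow rounding of ``n_samples × fhp_fraction``; sample
    order is shuffled.  Deterministic (bitwise) under a fixed seed.
    """
    config = config or GeneratorConfig()
    config.validate()
    n = config.n_samples
    if n < 2:
        raise ValidationError("n_samples must be at least 2")
    n_fhp = int(round(n * config.fhp_fraction))
    n_fhp = min(max(n_fhp, 1), n - 1)
    labels = np.array([NORMAL] * (n - n_fhp) + [FHP] * n_fhp, dtype=int)

    rng = np.random.default_rng(config.seed)
    rng.shuffle(labels)
    poses = np.empty((n, N_JOINTS, 3))
    provenance = []
    for i, lab in enumerate(labels):
        poses[i], prov = generate_pose(int(lab), rng, config)
        provenance.append(prov)
    return PoseDataset(poses, labels, tuple(provenance), config)


def with_noise(config: GeneratorConfig, noise_sd: float) -> GeneratorConfig:
    """Convenience: the same study conditions at a different noise level."""
    return replace(config, noise_sd=noise_sd)
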