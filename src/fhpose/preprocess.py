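"""Pose normalization, the shoulder-angle feature, KDE, and feature flattening.

Normalization makes classification resilient to viewing direction: each pose
is pelvis-centred, rotated about the vertical axis so the pelvis→left-hip
vector's horizontal projection points along +y, and uniformly rescaled so the
largest absolute coordinate equals 1.  Only yaw is removed — postural pitch
and roll carry the forward-head signal and are deliberately left intact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DegeneratePoseError, ValidationError
from .skeleton import as_pose13, as_pose17

LEFT_HIP = 4          # original 17-joint index
_THORAX13 = 4         # upper-body (13-joint) indices
_LSHOULDER13 = 7
_RSHOULDER13 = 10

FLATTENED_DIM = 39    # 13 joints × 3 coordinates

_EPS = 1e-12


@dataclass(frozen=True)
class NormalizationReport:
    """Record of the rigid transform + scaling applied by :func:`normalize_pose`.

    ``normalized = (pose - pelvis_offset) @ applied_rotation.T * scale_factor``
    """

    applied_rotation: np.ndarray  # 3 × 3, det = +1 (yaw-only)
    scale_factor: float           # multiplicative, > 0
    pelvis_offset: np.ndarray     # 3-vector subtracted before rotation

    def to_json(self) -> str:
        return json.dumps(
            {
                "applied_rotation": self.applied_rotation.tolist(),
                "scale_factor": self.scale_factor,
                "pelvis_offset": self.pelvis_offset.tolist(),
            }
        )


def yaw_rotation(angle_rad: float) -> np.ndarray:
    """Rotation matrix about the vertical (z) axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def normalize_pose(pose, align_yaw: bool = True):
    """Normalize a 17-joint pose; returns ``(normalized_pose, report)``.

    Steps: (1) translate the pelvis to the origin; (2) if ``align_yaw``,
    rotate about z so the horizontal projection of pelvis→left-hip points
    along +y; (3) uniformly scale so ``max |coordinate|`` equals 1.

    Raises
    ------
    DegeneratePoseError
        If the pelvis→left-hip horizontal projection vanishes (with
        ``align_yaw``) or the centred pose collapses to a point.
    """
    arr = as_pose17(pose)
    offset = arr[0].copy()
    centred = arr - offset

    R = np.eye(3)
    if align_yaw:
        lh = centred[LEFT_HIP]
        if np.hypot(lh[0], lh[1]) < _EPS:
            raise DegeneratePoseError(
                "pelvis and left hip are vertically aligned; yaw is undefined"
            )
        beta = np.arctan2(lh[1], lh[0])
        R = yaw_rotation(np.pi / 2.0 - beta)

    rotated = centred @ R.T
    max_abs = float(np.max(np.abs(rotated)))
    if max_abs < _EPS:
        raise DegeneratePoseError("pose collapses to a single point")
    scale = 1.0 / max_abs
    return rotated * scale, NormalizationReport(R, scale, offset)


def shoulder_angle(pose) -> float:
    """Mean shoulder protraction angle in degrees for an upper-body pose.

    For each side, the thorax→shoulder vector is projected onto the
    horizontal (x–y) plane and the angle between that projection and the
    lateral axis (+y for the left side, −y for the right) is measured,
    signed positive when the depth (x) component points anterior.  The
    returned value is the mean of the two sides.
    """
    arr = as_pose13(pose)
    thorax = arr[_THORAX13]
    angles = []
    for idx, lat_sign in ((_LSHOULDER13, 1.0), (_RSHOULDER13, -1.0)):
        v = arr[idx] - thorax
        anterior, lateral = v[0], lat_sign * v[1]
        if np.hypot(anterior, lateral) < _EPS:
            raise DegeneratePoseError(
                "shoulder coincides with thorax in the horizontal plane"
            )
        angles.append(np.degrees(np.arctan2(anterior, lateral)))
    return float(np.mean(angles))


def scott_bandwidth(samples) -> float:
    """Scott's rule-of-thumb bandwidth for a 1-D Gaussian KDE."""
    s = np.asarray(samples, dtype=float)
    sd = float(np.std(s, ddof=1)) if s.size > 1 else 0.0
    if sd <= 0.0:
        return 1.0
    return sd * s.size ** (-1.0 / 5.0)


def kde_density(samples, eval_points, bandwidth: float | None = None) -> np.ndarray:
    """Gaussian kernel density estimate evaluated at ``eval_points``.

    ``bandwidth`` is the kernel standard deviation (same units as the
    samples); by default Scott's rule is used.
    """
    s = np.asarray(samples, dtype=float).ravel()
    if s.size == 0:
        raise ValidationError("KDE requires at least one sample")
    if bandwidth is None:
        bandwidth = scott_bandwidth(s)
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be positive")
    x = np.asarray(eval_points, dtype=float).ravel()
    z = (x[:, None] - s[None, :]) / bandwidth
    return norm.pdf(z).sum(axis=1) / (s.size * bandwidth)


def flatten_features(pose) -> np.ndarray:
    """Flatten a 13-joint pose into a length-39 vector, joint-major order."""
    return as_pose13(pose).ravel().copy()
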