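"""Skeleton topology: the 17-joint convention, the 13-joint upper-body subset,
and the graph adjacency consumed by the classifier.

The 17-joint order is the Human3.6M convention emitted by standard 2D→3D
lifting tools: pelvis, right leg, left leg, spine chain, head, left arm,
right arm.  Axis semantics throughout the package: column 0 = x (depth,
anterior positive), column 1 = y (width, subject's left positive),
column 2 = z (height).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError, ValidationError

N_JOINTS = 17
N_UPPER_BODY = 13

JOINT_NAMES_17: tuple[str, ...] = (
    "pelvis",          # 0
    "right_hip",       # 1
    "right_knee",      # 2
    "right_ankle",     # 3
    "left_hip",        # 4
    "left_knee",       # 5
    "left_ankle",      # 6
    "spine",           # 7
    "thorax",          # 8
    "neck",            # 9
    "head",            # 10
    "left_shoulder",   # 11
    "left_elbow",      # 12
    "left_wrist",      # 13
    "right_shoulder",  # 14
    "right_elbow",     # 15
    "right_wrist",     # 16
)

#: Original 17-joint indices retained for classification, in subset order.
#: The lower body (knees, ankles) is dropped because it is typically occluded
#: in sedentary scenes; reindexed 0–12 these are:
#: 0 pelvis, 1 R-hip, 2 L-hip, 3 spine, 4 thorax, 5 neck, 6 head,
#: 7 L-shoulder, 8 L-elbow, 9 L-wrist, 10 R-shoulder, 11 R-elbow, 12 R-wrist.
UPPER_BODY_INDEX_MAP: tuple[int, ...] = (0, 1, 4, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16)

UPPER_BODY_JOINT_NAMES: tuple[str, ...] = tuple(
    JOINT_NAMES_17[i] for i in UPPER_BODY_INDEX_MAP
)

#: Undirected bone edges of the 13-node upper-body graph (reindexed).
UPPER_BODY_EDGES: tuple[tuple[int, int], ...] = (
    (0, 1),    # pelvis – right hip
    (0, 2),    # pelvis – left hip
    (0, 3),    # pelvis – spine
    (3, 4),    # spine – thorax
    (4, 5),    # thorax – neck
    (5, 6),    # neck – head
    (4, 7),    # thorax – left shoulder
    (7, 8),    # left shoulder – left elbow
    (8, 9),    # left elbow – left wrist
    (4, 10),   # thorax – right shoulder
    (10, 11),  # right shoulder – right elbow
    (11, 12),  # right elbow – right wrist
)


def as_pose17(pose) -> np.ndarray:
    """Validate and return a (17, 3) float array.

    Raises
    ------
    ShapeError
        If the array is not 17 × 3.
    ValidationError
        If any coordinate is non-finite.
    """
    arr = np.asarray(pose, dtype=float)
    if arr.shape != (N_JOINTS, 3):
        raise ShapeError(f"expected a (17, 3) pose, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("pose contains non-finite coordinates")
    return arr


def as_pose13(pose) -> np.ndarray:
    """Validate and return a (13, 3) float array (upper-body subset)."""
    arr = np.asarray(pose, dtype=float)
    if arr.shape != (N_UPPER_BODY, 3):
        raise ShapeError(f"expected a (13, 3) upper-body pose, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("pose contains non-finite coordinates")
    return arr


def upper_body_subset(pose) -> np.ndarray:
    """Project a 17-joint pose onto the 13 upper-body joints.

    Rows are selected in :data:`UPPER_BODY_INDEX_MAP` order and copied
    unchanged; this is a pure projection.
    """
    arr = as_pose17(pose)
    return arr[list(UPPER_BODY_INDEX_MAP)].copy()


@dataclass(frozen=True)
class SkeletonGraph:
    """An undirected joint graph with a dense binary adjacency matrix."""

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self):
        A = self.adjacency
        if A.shape != (self.n_nodes, self.n_nodes):
            raise ShapeError("adjacency shape inconsistent with n_nodes")
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValidationError("adjacency must have a zero diagonal")


def build_adjacency(edges, n: int) -> np.ndarray:
    """Build a dense symmetric 0/1 adjacency matrix from an edge list.

    Raises
    ------
    ValidationError
        On a self-pair (i, i).
    IndexError
        On a node index outside [0, n).
    """
    if n <= 0:
        raise ValidationError("node count must be positive")
    A = np.zeros((n, n), dtype=float)
    for i, j in edges:
        if i == j:
            raise ValidationError(f"self-pair ({i}, {j}) is not a valid edge")
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"edge ({i}, {j}) out of range for {n} nodes")
        A[i, j] = 1.0
        A[j, i] = 1.0
    return A


def build_upper_body_graph() -> SkeletonGraph:
    """Return the fixed 13-node upper-body graph.

    The pelvis (node 0) connects to both hips and the spine, giving the
    first adjacency row [0, 1, 1, 1, 0, ..., 0].
    """
    A = build_adjacency(UPPER_BODY_EDGES, N_UPPER_BODY)
    return SkeletonGraph(n_nodes=N_UPPER_BODY, edges=UPPER_BODY_EDGES, adjacency=A)


def joint_table() -> str:
    """Human-readable reindexed joint table (for CLI inspection)."""
    lines = ["idx  orig  joint"]
    for new, orig in enumerate(UPPER_BODY_INDEX_MAP):
        lines.append(f"{new:>3}  {orig:>4}  {JOINT_NAMES_17[orig]}")
    return "\n".join(lines)
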