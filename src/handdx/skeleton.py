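"""The 21-landmark hand model: landmark naming, joint triplets, mesh topology.

The hand is decomposed into 21 key joint landmarks following the layout that
monocular hand-pose estimators output: one node for the carpal block (wrist)
and four nodes per finger including the fingertip.

Landmark index map
==================

===== ==============  ===== ==============  ===== ==============
Index  Name           Index  Name           Index  Name
===== ==============  ===== ==============  ===== ==============
0      wrist          7      index_DIP      14     ring_PIP
1      thumb_CMC      8      index_tip      15     ring_DIP
2      thumb_MCP      9      middle_MCP     16     ring_tip
3      thumb_IP       10     middle_PIP     17     little_MCP
4      thumb_tip      11     middle_DIP     18     little_PIP
5      index_MCP      12     middle_tip     19     little_DIP
6      index_PIP      13     ring_MCP       20     little_tip
===== ==============  ===== ==============  ===== ==============

Fourteen flexion/extension joints are measured: MCP, PIP and DIP for index,
middle, ring and little fingers, plus the thumb's MCP and interphalangeal
joint.  The thumb IP joint is reported under the name ``thumb_DIP`` to match
the clinical reporting convention used for the other fingers; ``thumb_IP``
is accepted as an alias.

Each joint is an angle vertex with one proximal and one distal reference
landmark.  A finger's MCP angle is anchored at the wrist (the metacarpal
direction is not separately observable in the 21-point model); the thumb MCP
is anchored at the thumb CMC node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import NonFiniteCoordinate, WrongLandmarkCount

N_LANDMARKS = 21

#: index -> canonical landmark name
LANDMARK_NAMES: dict[int, str] = {
    0: "wrist",
    1: "thumb_CMC", 2: "thumb_MCP", 3: "thumb_IP", 4: "thumb_tip",
    5: "index_MCP", 6: "index_PIP", 7: "index_DIP", 8: "index_tip",
    9: "middle_MCP", 10: "middle_PIP", 11: "middle_DIP", 12: "middle_tip",
    13: "ring_MCP", 14: "ring_PIP", 15: "ring_DIP", 16: "ring_tip",
    17: "little_MCP", 18: "little_PIP", 19: "little_DIP", 20: "little_tip",
}

LANDMARK_INDEX: dict[str, int] = {v: k for k, v in LANDMARK_NAMES.items()}

#: measured joint names in reporting order (thumb first, then radial->ulnar)
JOINT_NAMES: tuple[str, ...] = (
    "thumb_MCP", "thumb_DIP",
    "index_MCP", "index_PIP", "index_DIP",
    "middle_MCP", "middle_PIP", "middle_DIP",
    "ring_MCP", "ring_PIP", "ring_DIP",
    "little_MCP", "little_PIP", "little_DIP",
)

#: alias -> canonical joint name (thumb IP is reported as thumb_DIP)
JOINT_ALIASES: dict[str, str] = {"thumb_IP": "thumb_DIP"}


@dataclass(frozen=True)
class JointSpec:
    """One measurable hinge joint.

    ``triplet`` is (proximal_idx, vertex_idx, distal_idx): the flexion angle
    is the angle at ``vertex_idx`` between the two bone vectors, with 0
    degrees meaning a fully extended (collinear) chain.
    """

    name: str
    triplet: tuple[int, int, int]
    joint_class: str  # "MCP" | "PIP" | "DIP"

    def __post_init__(self) -> None:
        p, v, d = self.triplet
        if len({p, v, d}) != 3:
            raise ValueError(f"joint {self.name}: triplet indices must be distinct")


@dataclass(frozen=True)
class SkeletonTopology:
    """Landmark names, measured joints, bone edges and triangular face set."""

    landmark_names: dict[int, str]
    joints: tuple[JointSpec, ...]
    edges: tuple[tuple[int, int], ...]
    faces: tuple[tuple[int, int, int], ...]

    def joint(self, name: str) -> JointSpec:
        """Look up a joint by name (aliases accepted)."""
        canonical = JOINT_ALIASES.get(name, name)
        for j in self.joints:
            if j.name == canonical:
                return j
        raise KeyError(f"unknown joint {name!r}")

    @property
    def joint_names(self) -> tuple[str, ...]:
        return tuple(j.name for j in self.joints)


@dataclass
class LandmarkFrame:
    """A single capture frame: 21 named 3D points in millimetres."""

    points: np.ndarray  # (21, 3) float64
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.timestamp is not None and self.timestamp < 0:
            raise ValueError("timestamp must be nonnegative")

    def __getitem__(self, landmark: int | str) -> np.ndarray:
        if isinstance(landmark, str):
            landmark = LANDMARK_INDEX[landmark]
        return self.points[landmark]


@dataclass
class MotionSequence:
    """An ordered sequence of frames, optionally with a sampling rate in Hz."""

    frames: list[LandmarkFrame]
    frame_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a motion sequence needs at least one frame")
        if self.frame_rate is not None and self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def as_array(self) -> np.ndarray:
        """Stack all frames into an (n_frames, 21, 3) array."""
        return np.stack([f.points for f in self.frames])


def validate_frame(frame: LandmarkFrame) -> LandmarkFrame:
    """Return ``frame`` unchanged if it holds exactly 21 finite points.

    Raises
    ------
    WrongLandmarkCount
        if the point array is not (21, 3).
    NonFiniteCoordinate
        if any coordinate is NaN or infinite.
    """
    pts = frame.points
    if pts.shape != (N_LANDMARKS, 3):
        raise WrongLandmarkCount(
            f"expected {N_LANDMARKS} 3D landmarks, got array of shape {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        bad = np.argwhere(~np.isfinite(pts))[0]
        raise NonFiniteCoordinate(
            f"non-finite coordinate at landmark {bad[0]} "
            f"({LANDMARK_NAMES[int(bad[0])]}), axis {bad[1]}"
        )
    return frame


def _finger_chains() -> dict[str, tuple[int, int, int, int]]:
    return {
        "index": (5, 6, 7, 8),
        "middle": (9, 10, 11, 12),
        "ring": (13, 14, 15, 16),
        "little": (17, 18, 19, 20),
    }


def default_topology() -> SkeletonTopology:
    """The canonical 21-landmark topology: 14 joints, 20 bone edges, 14 faces.

    Joint triplets: a finger's MCP angle uses (wrist, MCP, PIP); the thumb MCP
    uses (CMC, MCP, IP); every PIP/DIP uses its two flanking landmarks.  The
    face set for the surface-normal consistency metric is the 14 joint
    triplets themselves — every three connected joints form one joint surface.
    """
    joints: list[JointSpec] = [
        JointSpec("thumb_MCP", (1, 2, 3), "MCP"),
        JointSpec("thumb_DIP", (2, 3, 4), "DIP"),
    ]
    for finger, (mcp, pip, dip, tip) in _finger_chains().items():
        joints.append(JointSpec(f"{finger}_MCP", (0, mcp, pip), "MCP"))
        joints.append(JointSpec(f"{finger}_PIP", (mcp, pip, dip), "PIP"))
        joints.append(JointSpec(f"{finger}_DIP", (pip, dip, tip), "DIP"))
    # keep reporting order
    joints.sort(key=lambda j: JOINT_NAMES.index(j.name))

    edges: list[tuple[int, int]] = []
    for base in (1, 5, 9, 13, 17):
        edges.append((0, base))
        for k in range(base, base + 3):
            edges.append((k, k + 1))

    faces = tuple(j.triplet for j in joints)
    return SkeletonTopology(
        landmark_names=dict(LANDMARK_NAMES),
        joints=tuple(joints),
        edges=tuple(edges),
        faces=faces,
    )
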