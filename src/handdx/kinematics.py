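"""Joint-angle kinematics on 21-landmark frames.

A joint's flexion angle at vertex Y between proximal landmark X and distal
landmark Z is the angle between the bone vectors XY and YZ,

    angle(XYZ) = arccos( XY . YZ / (|XY| |YZ|) ),

reported in degrees, so a fully extended (collinear) chain reads 0 deg and
the angle grows monotonically with flexion up to 180 deg.  Internally the
mathematically identical form atan2(|XY x YZ|, XY . YZ) is used: arccos is
ill-conditioned where the bone vectors are nearly (anti)parallel, while the
atan2 form is uniformly well-conditioned and recovers programmed flexions of
exactly 0 deg to machine precision.

Range of motion (ROM) over a sequence is the range between the maximum and
minimum of the per-frame angle trajectory.  Thumb opposition is measured as
the Euclidean distance between the thumb tip and the little-finger MCP
landmark, with success defined as any frame closing below a 30 mm contact
margin (3 cm).

The module also provides the hand-joint surface-normal consistency metric:
treating every three connected joints (the 14 joint triplets) as a joint
surface, it sums |unit predicted edge . unit ground-truth face normal| over
the three edges of every evaluable face.  The metric is zero exactly when
every predicted edge lies in its own ground-truth face plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSegment, NoEvaluableFaces, TooFewFrames
from .skeleton import (
    LANDMARK_INDEX,
    JointSpec,
    LandmarkFrame,
    MotionSequence,
    SkeletonTopology,
    validate_frame,
)

#: bone vectors shorter than this (mm) are considered degenerate
MIN_SEGMENT_NORM = 1e-9

#: gt faces whose normal is shorter than this fraction of the edge-norm
#: product are treated as collinear and skipped by the normal metric
COLLINEAR_TOL = 1e-9

THUMB_TIP = LANDMARK_INDEX["thumb_tip"]
LITTLE_MCP = LANDMARK_INDEX["little_MCP"]

#: opposition contact margin: 3 cm expressed in mm
OPPOSITION_THRESHOLD_MM = 30.0


@dataclass
class AngleTrajectory:
    """Per-frame flexion angles (degrees) of one joint."""

    joint_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class NormalConsistency:
    """Surface-normal consistency value and the number of faces it used."""

    value: float
    n_faces_evaluated: int


@dataclass(frozen=True)
class OppositionResult:
    outcome: str  # "achieved" | "not_achieved"
    min_distance_mm: float
    threshold_mm: float


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu <= MIN_SEGMENT_NORM or nv <= MIN_SEGMENT_NORM:
        raise DegenerateSegment(
            f"bone vector with norm {min(nu, nv):.3g} mm is too short to orient"
        )
    cross = float(np.linalg.norm(np.cross(u, v)))
    dot = float(np.dot(u, v))
    return float(np.degrees(np.arctan2(cross, dot)))


def joint_angle(frame: LandmarkFrame, joint: JointSpec) -> float:
    """Flexion angle of ``joint`` in ``frame``, in degrees in [0, 180]."""
    validate_frame(frame)
    p, v, d = joint.triplet
    xy = frame.points[v] - frame.points[p]
    yz = frame.points[d] - frame.points[v]
    try:
        return _angle_deg(xy, yz)
    except DegenerateSegment as err:
        raise DegenerateSegment(f"joint {joint.name}: {err}") from None


def angle_trajectory(seq: MotionSequence, joint: JointSpec) -> AngleTrajectory:
    """Per-frame :func:`joint_angle`, order-preserving."""
    values = np.empty(len(seq))
    for t, frame in enumerate(seq):
        try:
            values[t] = joint_angle(frame, joint)
        except DegenerateSegment as err:
            raise DegenerateSegment(f"frame {t}: {err}") from None
    return AngleTrajectory(joint.name, values)


def range_of_motion(traj: AngleTrajectory) -> float:
    """max - min of the trajectory, degrees; requires at least 2 frames."""
    if len(traj) < 2:
        raise TooFewFrames(
            f"range of motion needs >= 2 frames, got {len(traj)}"
        )
    return float(traj.values.max() - traj.values.min())


def opposition_distance(frame: LandmarkFrame) -> float:
    """Euclidean thumb-tip to little-finger-MCP distance, mm."""
    validate_frame(frame)
    return float(np.linalg.norm(frame.points[THUMB_TIP] - frame.points[LITTLE_MCP]))


def opposition_test(
    seq: MotionSequence, threshold_mm: float = OPPOSITION_THRESHOLD_MM
) -> OppositionResult:
    """Thumb opposition over a sequence.

    The test is achieved iff the minimum thumb-tip to little-MCP distance
    over all frames falls strictly below ``threshold_mm`` (distances below
    the contact margin count as successful opposition; the boundary value
    itself does not).
    """
    dmin = min(opposition_distance(f) for f in seq)
    outcome = "achieved" if dmin < threshold_mm else "not_achieved"
    return OppositionResult(outcome, dmin, threshold_mm)


def thumb_total_arom(seq: MotionSequence, topo: SkeletonTopology) -> float:
    """Summed ROM of the thumb MCP and interphalangeal joints, degrees."""
    return sum(
        range_of_motion(angle_trajectory(seq, topo.joint(name)))
        for name in ("thumb_MCP", "thumb_DIP")
    )


def normal_consistency(
    pred: LandmarkFrame, gt: LandmarkFrame, topo: SkeletonTopology
) -> NormalConsistency:
    """Hand-joint surface-normal consistency between ``pred`` and ``gt``.

    For every face (i, j, k) in the topology whose ground-truth vertices are
    not collinear, accumulates |unit(pred_a - pred_b) . n_f| over the three
    edges (i,j), (j,k), (k,i), where n_f is the unit normal of the
    ground-truth face.  Collinear ground-truth faces have no defined normal
    and are skipped (excluded from ``n_faces_evaluated``).
    """
    validate_frame(pred)
    validate_frame(gt)
    total = 0.0
    n_eval = 0
    for face in topo.faces:
        i, j, k = face
        e1 = gt.points[j] - gt.points[i]
        e2 = gt.points[k] - gt.points[i]
        n = np.cross(e1, e2)
        nn = float(np.linalg.norm(n))
        if nn <= COLLINEAR_TOL * float(np.linalg.norm(e1)) * float(np.linalg.norm(e2)):
            continue  # collinear gt triplet: normal undefined
        n_hat = n / nn
        for a, b in ((i, j), (j, k), (k, i)):
            edge = pred.points[a] - pred.points[b]
            ne = float(np.linalg.norm(edge))
            if ne <= MIN_SEGMENT_NORM:
                raise DegenerateSegment(
                    f"predicted edge ({a},{b}) has zero length"
                )
            total += abs(float(np.dot(edge / ne, n_hat)))
        n_eval += 1
    if n_eval == 0:
        raise NoEvaluableFaces(
            "all ground-truth faces are collinear; the normal metric is undefined"
        )
    return NormalConsistency(total, n_eval)


def joint_table(seq: MotionSequence, topo: SkeletonTopology):
    """Per-joint min/max/ROM summary as a pandas DataFrame (degrees)."""
    import pandas as pd

    rows = []
    for joint in topo.joints:
        traj = angle_trajectory(seq, joint)
        rows.append(
            {
                "joint": joint.name,
                "min_deg": float(traj.values.min()),
                "max_deg": float(traj.values.max()),
                "rom_deg": range_of_motion(traj),
            }
        )
    return pd.DataFrame(rows)
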