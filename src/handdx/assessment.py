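"""Functional scoring of hand joint motion.

Implements the clinical activity-standard rubric: each joint class (MCP, PIP,
DIP) has four ROM bands mapped to score ranges, plus a thumb opposition score
and a thumb active-range-of-motion score.

Scoring bands (degrees -> points):

=====  ==========  ==========  ==========  ==========
Class  Band 1      Band 2      Band 3      Band 4
=====  ==========  ==========  ==========  ==========
MCP    <30: 0-2.5  30-49:      50-69:      70-90:
                   2.5-5       5-7.5       7.5-10
PIP    <30: 0-2.5  30-59:      60-79:      80-100:
                   2.5-5       5-7.5       7.5-10
DIP    <15: 0-2.5  15-19:      20-29:      30-45:
                   2.5-5       5-7.5       7.5-10
=====  ==========  ==========  ==========  ==========

The printed bands have integer gaps (e.g. 50-69 then 70-90); they are
implemented as contiguous half-open intervals ([30, 50), [50, 70), [70, inf)
for MCP and analogously for PIP/DIP) so every nonnegative real ROM falls in
exactly one band.  Within a band the score is a linear interpolation between
the band's score endpoints; ROM above the top band's printed maximum clamps
at the maximum score (hypermobility is not graded).  This mapping is
continuous and non-decreasing, and at every shared band boundary the two
adjacent bands agree.

Thumb opposition: achieved -> 10, hard -> 5, not achieved -> 0.
Thumb AROM (summed thumb MCP + IP ROM): >90 deg -> 10, up to 90 deg -> 5,
no measurable motion (stiffness) -> 0.

Normal reference ranges (flexion/extension ROM): MCP 70-90 deg, PIP
80-100 deg, DIP 30-45 deg.  A ROM at or above the class's lower reference
bound is classified normal; above the upper bound it stays normal but is
flagged ``above_reference``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import UnknownJointClass, UnknownOutcome
from .kinematics import (
    OPPOSITION_THRESHOLD_MM,
    OppositionResult,
    angle_trajectory,
    opposition_test,
    range_of_motion,
    thumb_total_arom,
)
from .skeleton import MotionSequence, SkeletonTopology


@dataclass(frozen=True)
class ScoreBand:
    """One rubric band: ROM interval [rom_low, rom_high) with the score
    interpolated linearly from score_low at rom_low to score_high at the
    band's printed top endpoint ``score_anchor_high`` (== rom_high except in
    the top band, which is open above but anchored at the printed maximum)."""

    joint_class: str
    rom_low: float
    rom_high: float  # upper edge of the band; inf for the top band
    score_low: float
    score_high: float
    anchor_high: float  # ROM value at which score_high is reached

    def contains(self, rom: float) -> bool:
        return self.rom_low <= rom < self.rom_high

    def score(self, rom: float) -> float:
        span = self.anchor_high - self.rom_low
        frac = (rom - self.rom_low) / span
        return min(self.score_high,
                   self.score_low + frac * (self.score_high - self.score_low))


def _bands(edges: tuple[float, float, float, float], cls: str) -> tuple[ScoreBand, ...]:
    """Build the four contiguous bands from the three printed cut points and
    the printed top maximum: edges = (cut1, cut2, cut3, top_max)."""
    c1, c2, c3, top = edges
    return (
        ScoreBand(cls, 0.0, c1, 0.0, 2.5, c1),
        ScoreBand(cls, c1, c2, 2.5, 5.0, c2),
        ScoreBand(cls, c2, c3, 5.0, 7.5, c3),
        ScoreBand(cls, c3, float("inf"), 7.5, 10.0, top),
    )


SCORE_BANDS: dict[str, tuple[ScoreBand, ...]] = {
    "MCP": _bands((30.0, 50.0, 70.0, 90.0), "MCP"),
    "PIP": _bands((30.0, 60.0, 80.0, 100.0), "PIP"),
    "DIP": _bands((15.0, 20.0, 30.0, 45.0), "DIP"),
}

#: normal flexion/extension ROM reference intervals, degrees
NORMAL_RANGES: dict[str, tuple[float, float]] = {
    "MCP": (70.0, 90.0),
    "PIP": (80.0, 100.0),
    "DIP": (30.0, 45.0),
}

OPPOSITION_SCORES = {"achieved": 10.0, "hard": 5.0, "not_achieved": 0.0}

#: thumb AROM threshold, degrees: summed thumb MCP + IP ROM must exceed this
THUMB_AROM_THRESHOLD = 90.0


def score_joint_rom(joint_class: str, rom: float) -> float:
    """Rubric score in [0, 10] for a flexion/extension ROM in degrees."""
    if joint_class not in SCORE_BANDS:
        raise UnknownJointClass(f"no scoring bands for joint class {joint_class!r}")
    if rom < 0:
        raise ValueError("ROM must be nonnegative")
    for band in SCORE_BANDS[joint_class]:
        if band.contains(rom):
            return band.score(rom)
    raise AssertionError("bands cover [0, inf)")  # pragma: no cover


def score_opposition(outcome: str) -> float:
    """Thumb-opposition score: achieved 10, hard 5, not_achieved 0."""
    try:
        return OPPOSITION_SCORES[outcome]
    except KeyError:
        raise UnknownOutcome(f"opposition outcome {outcome!r}") from None


def score_thumb_arom(arom: float) -> float:
    """Thumb AROM score: >90 deg -> 10; measurable but <=90 -> 5; 0 -> 0."""
    if arom < 0:
        raise ValueError("AROM must be nonnegative")
    if arom > THUMB_AROM_THRESHOLD:
        return 10.0
    if arom > 0:
        return 5.0
    return 0.0


def classify_normal_range(joint_class: str, rom: float) -> str:
    """'normal' iff the ROM reaches the class's lower reference bound."""
    if joint_class not in NORMAL_RANGES:
        raise UnknownJointClass(f"no reference range for joint class {joint_class!r}")
    low, _ = NORMAL_RANGES[joint_class]
    return "normal" if rom >= low else "reduced"


@dataclass
class JointAssessment:
    joint_name: str
    joint_class: str
    angle_min: float
    angle_max: float
    rom: float
    score: float
    normal_flag: str  # "normal" | "reduced"
    above_reference: bool


@dataclass
class AssessmentReport:
    """Full functional assessment of one motion sequence."""

    joints: list[JointAssessment]
    opposition: OppositionResult
    opposition_score: float
    thumb_arom_deg: float
    thumb_arom_score: float
    total_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_score = (
            sum(j.score for j in self.joints)
            + self.opposition_score
            + self.thumb_arom_score
        )

    def to_dict(self) -> dict:
        return {
            "joints": [
                {
                    "joint": j.joint_name,
                    "class": j.joint_class,
                    "angle_min_deg": j.angle_min,
                    "angle_max_deg": j.angle_max,
                    "rom_deg": j.rom,
                    "score": j.score,
                    "normal": j.normal_flag,
                    "above_reference": j.above_reference,
                }
                for j in self.joints
            ],
            "opposition": {
                "outcome": self.opposition.outcome,
                "min_distance_mm": self.opposition.min_distance_mm,
                "threshold_mm": self.opposition.threshold_mm,
                "score": self.opposition_score,
            },
            "thumb_arom": {
                "value_deg": self.thumb_arom_deg,
                "score": self.thumb_arom_score,
            },
            "total_score": self.total_score,
        }

    def to_text(self) -> str:
        lines = [
            f"{'joint':<12} {'class':<5} {'min':>7} {'max':>7} "
            f"{'ROM':>7} {'score':>6}  flag",
        ]
        for j in self.joints:
            flag = j.normal_flag + ("+" if j.above_reference else "")
            lines.append(
                f"{j.joint_name:<12} {j.joint_class:<5} {j.angle_min:7.2f} "
                f"{j.angle_max:7.2f} {j.rom:7.2f} {j.score:6.2f}  {flag}"
            )
        lines.append(
            f"opposition: {self.opposition.outcome} "
            f"(min {self.opposition.min_distance_mm:.1f} mm, "
            f"threshold {self.opposition.threshold_mm:.0f} mm) "
            f"score {self.opposition_score:.1f}"
        )
        lines.append(
            f"thumb AROM: {self.thumb_arom_deg:.2f} deg "
            f"score {self.thumb_arom_score:.1f}"
        )
        lines.append(f"total score: {self.total_score:.2f}")
        return "\n".join(lines)


def assess_sequence(
    seq: MotionSequence,
    topo: SkeletonTopology,
    opposition_threshold_mm: float = OPPOSITION_THRESHOLD_MM,
    hard_threshold_mm: Optional[float] = None,
) -> AssessmentReport:
    """Assess all 14 joints, thumb opposition and thumb AROM of a sequence.

    ``hard_threshold_mm`` optionally enables the intermediate "hard"
    opposition grade: a minimum distance in [opposition_threshold_mm,
    hard_threshold_mm) is graded "hard" (5 points) instead of
    "not_achieved".  Off by default.
    """
    joints: list[JointAssessment] = []
    for joint in topo.joints:
        traj = angle_trajectory(seq, joint)
        rom = range_of_motion(traj)
        _, high = NORMAL_RANGES[joint.joint_class]
        joints.append(
            JointAssessment(
                joint_name=joint.name,
                joint_class=joint.joint_class,
                angle_min=float(traj.values.min()),
                angle_max=float(traj.values.max()),
                rom=rom,
                score=score_joint_rom(joint.joint_class, rom),
                normal_flag=classify_normal_range(joint.joint_class, rom),
                # 1e-9 deg guard: measured ROMs sit a few ulps above exact
                # programmed endpoints
                above_reference=rom > high + 1e-9,
            )
        )

    opp = opposition_test(seq, threshold_mm=opposition_threshold_mm)
    outcome = opp.outcome
    if (
        hard_threshold_mm is not None
        and outcome == "not_achieved"
        and opp.min_distance_mm < hard_threshold_mm
    ):
        outcome = "hard"
        opp = OppositionResult(outcome, opp.min_distance_mm, opp.threshold_mm)

    arom = thumb_total_arom(seq, topo)
    return AssessmentReport(
        joints=joints,
        opposition=opp,
        opposition_score=score_opposition(outcome),
        thumb_arom_deg=arom,
        thumb_arom_score=score_thumb_arom(arom),
    )
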