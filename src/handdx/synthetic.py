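"""Forward-kinematic synthetic hand motion generator.

Emulates the keypoint sequences a monocular hand-pose estimator would produce
during a clinical range-of-motion protocol (repetitions of a continuous
movement from an open palm to a clenched fist), with exactly known joint
angles — so every kinematic operation has a ground-truth oracle.

Model
-----
The wrist sits at the origin; at rest the palm lies in the z = 0 plane with
the fingers fanning out in +y.  Each finger is a planar kinematic chain of
hinge joints: flexing by a cumulative angle phi rotates the next bone vector
within the finger's flexion plane (spanned by the finger's rest direction and
a flexion direction, -z for the four fingers so flexion curls toward the
palm).  The thumb column (CMC, MCP, IP, tip) uses a flexion plane tilted
toward the ulnar side of the palm so that flexing the thumb sweeps its tip
across the palm toward the little-finger MCP, as in an opposition movement.

Bone lengths default to rounded adult-hand magnitudes in millimetres; they
are implementation fixtures, configurable per instance, not measured values.

Optional measurement noise is isotropic Gaussian per landmark per frame with
a caller-supplied standard deviation and seed; sequences are deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidAngle, InvalidSpec
from .skeleton import (
    LANDMARK_INDEX,
    JOINT_ALIASES,
    JOINT_NAMES,
    LandmarkFrame,
    MotionSequence,
)

_FINGERS = ("index", "middle", "ring", "little")

#: rest positions of the four finger MCP landmarks (mm, palm plane z=0)
_MCP_REST: dict[str, tuple[float, float]] = {
    "index": (25.0, 85.0),
    "middle": (8.0, 90.0),
    "ring": (-8.0, 85.0),
    "little": (-22.0, 75.0),
}

#: (proximal, middle, distal) phalanx lengths per finger, mm
_PHALANX_LENGTHS: dict[str, tuple[float, float, float]] = {
    "index": (40.0, 25.0, 20.0),
    "middle": (45.0, 28.0, 21.0),
    "ring": (42.0, 26.0, 20.0),
    "little": (32.0, 19.0, 17.0),
}


@dataclass
class HandGeometry:
    """Per-segment bone lengths and palm layout (millimetres).

    The thumb column has three segments distal to the CMC node (metacarpal,
    proximal phalanx, distal phalanx) — it lacks a middle phalanx.
    """

    mcp_rest: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_MCP_REST)
    )
    phalanx_lengths: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_PHALANX_LENGTHS)
    )
    #: wrist->CMC offset of the thumb column, mm
    thumb_cmc: tuple[float, float, float] = (28.0, 20.0, 0.0)
    #: thumb metacarpal, proximal phalanx, distal phalanx lengths, mm
    thumb_lengths: tuple[float, float, float] = (45.0, 32.0, 25.0)

    def __post_init__(self) -> None:
        for lengths in (*self.phalanx_lengths.values(), self.thumb_lengths):
            if any(l <= 0 for l in lengths):
                raise ValueError("bone lengths must be positive")
        if len(self.thumb_lengths) != 3:
            raise ValueError("the thumb column has exactly 3 segments")


#: per-joint flexion angles accepted by generate_pose; thumb_CMC drives the
#: (unmeasured) carpometacarpal flexion used for opposition movements
POSE_ANGLE_KEYS: tuple[str, ...] = JOINT_NAMES + ("thumb_CMC",)


def _chain(
    start: np.ndarray,
    d: np.ndarray,
    e: np.ndarray,
    lengths: list[float],
    angles_deg: list[float],
) -> list[np.ndarray]:
    """Chain bone vectors in the plane spanned by (d, e): each segment is
    rotated by the cumulative flexion, direction cos(phi) d - sin(phi) e."""
    pts = []
    pos = start
    phi = 0.0
    for length, ang in zip(lengths, angles_deg):
        phi += np.radians(ang)
        pos = pos + length * (np.cos(phi) * d - np.sin(phi) * e)
        pts.append(pos)
    return pts


def _thumb_plane(geom: HandGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Rest direction and flexion direction of the thumb column."""
    d = np.asarray(geom.thumb_cmc, dtype=float)
    d = d / np.linalg.norm(d)
    # flexion sweeps the tip toward the little-finger MCP: the flexion plane
    # is spanned by the column direction and the CMC-to-little-MCP direction,
    # so an opposition movement can close onto its target
    lx, ly = geom.mcp_rest["little"]
    target = np.array([lx, ly, 0.0]) - np.asarray(geom.thumb_cmc, dtype=float)
    target = target / np.linalg.norm(target)
    raw = -target
    e = raw - np.dot(raw, d) * d
    e = e / np.linalg.norm(e)
    return d, e


def generate_pose(
    geom: HandGeometry, angles: dict[str, float] | None = None
) -> LandmarkFrame:
    """Place the 21 landmarks for the given per-joint flexion angles.

    ``angles`` maps joint names (the 14 measured joints, thumb_IP alias
    accepted, plus ``thumb_CMC``) to flexion in degrees; missing joints are
    fully extended (0 deg).  Every hinge bends in its finger's plane by
    exactly the requested angle and bone lengths are preserved, so
    :func:`handdx.kinematics.joint_angle` recovers the programmed values.
    """
    angles = dict(angles or {})
    for alias, canon in JOINT_ALIASES.items():
        if alias in angles:
            angles[canon] = angles.pop(alias)
    for name, value in angles.items():
        if name not in POSE_ANGLE_KEYS:
            raise InvalidAngle(f"unknown joint {name!r}")
        if not 0.0 <= value <= 180.0:
            raise InvalidAngle(f"{name}: angle {value} outside [0, 180]")

    pts = np.zeros((21, 3))
    ez = np.array([0.0, 0.0, 1.0])

    # thumb column: wrist -> CMC -> MCP -> IP -> tip
    d_t, e_t = _thumb_plane(geom)
    cmc = np.asarray(geom.thumb_cmc, dtype=float)
    pts[LANDMARK_INDEX["thumb_CMC"]] = cmc
    thumb_pts = _chain(
        cmc, d_t, e_t,
        list(geom.thumb_lengths),
        [angles.get("thumb_CMC", 0.0),
         angles.get("thumb_MCP", 0.0),
         angles.get("thumb_DIP", 0.0)],
    )
    for name, p in zip(("thumb_MCP", "thumb_IP", "thumb_tip"), thumb_pts):
        pts[LANDMARK_INDEX[name]] = p

    for finger in _FINGERS:
        mx, my = geom.mcp_rest[finger]
        mcp = np.array([mx, my, 0.0])
        d = mcp / np.linalg.norm(mcp)  # metacarpal direction from the wrist
        pts[LANDMARK_INDEX[f"{finger}_MCP"]] = mcp
        finger_pts = _chain(
            mcp, d, ez,
            list(geom.phalanx_lengths[finger]),
            [angles.get(f"{finger}_MCP", 0.0),
             angles.get(f"{finger}_PIP", 0.0),
             angles.get(f"{finger}_DIP", 0.0)],
        )
        for part, p in zip(("PIP", "DIP", "tip"), finger_pts):
            pts[LANDMARK_INDEX[f"{finger}_{part}"]] = p

    return LandmarkFrame(pts)


@dataclass
class TrajectorySpec:
    """Programmed per-joint flexion profiles for a motion sequence.

    ``profiles`` maps joint names to sorted (frame_index, angle_deg)
    breakpoints; angles between breakpoints are linearly interpolated, and
    held constant outside the breakpoint range.
    """

    profiles: dict[str, list[tuple[int, float]]]
    n_frames: int
    noise_sd_mm: float = 0.0
    seed: int | None = None
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise InvalidSpec(f"n_frames must be >= 2, got {self.n_frames}")
        if self.noise_sd_mm < 0:
            raise InvalidSpec("noise_sd_mm must be nonnegative")
        for joint, bps in self.profiles.items():
            key = JOINT_ALIASES.get(joint, joint)
            if key not in POSE_ANGLE_KEYS:
                raise InvalidSpec(f"unknown joint {joint!r}")
            if not bps:
                raise InvalidSpec(f"{joint}: empty breakpoint list")
            if any(b[0] > a[0] for b, a in zip(bps, bps[1:])):
                raise InvalidSpec(f"{joint}: breakpoints must be sorted")
            if any(not 0.0 <= ang <= 180.0 for _, ang in bps):
                raise InvalidSpec(f"{joint}: angles must be in [0, 180]")

    def angles_at(self, t: int) -> dict[str, float]:
        out = {}
        for joint, bps in self.profiles.items():
            xs = [b[0] for b in bps]
            ys = [b[1] for b in bps]
            out[joint] = float(np.interp(t, xs, ys))
        return out


def generate_motion(geom: HandGeometry, spec: TrajectorySpec) -> MotionSequence:
    """Render a :class:`TrajectorySpec` into a landmark sequence.

    Noise, when enabled, is isotropic Gaussian per landmark per frame with
    sd ``spec.noise_sd_mm``; the sequence is deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for t in range(spec.n_frames):
        frame = generate_pose(geom, spec.angles_at(t))
        if spec.noise_sd_mm > 0:
            frame.points = frame.points + rng.normal(
                0.0, spec.noise_sd_mm, size=(21, 3)
            )
        frame.timestamp = t / spec.frame_rate
        frames.append(frame)
    return MotionSequence(frames, frame_rate=spec.frame_rate)


#: peak flexion targets of the fist-cycle preset, degrees: the top of each
#: scoring band (MCP 90, PIP 100, DIP 45) and a thumb path that reaches
#: opposition at mid-cycle
FIST_CYCLE_TARGETS: dict[str, float] = {
    **{f"{f}_MCP": 90.0 for f in _FINGERS},
    **{f"{f}_PIP": 100.0 for f in _FINGERS},
    **{f"{f}_DIP": 45.0 for f in _FINGERS},
    "thumb_CMC": 35.0,
    "thumb_MCP": 90.0,
    "thumb_DIP": 50.0,
}


def preset_fist_cycle(
    geom: HandGeometry | None = None,
    n_repetitions: int = 3,
    frames_per_repetition: int = 40,
    noise_sd_mm: float = 0.0,
    seed: int | None = None,
) -> MotionSequence:
    """Open-palm-to-fist protocol: periodic flexion of all joints.

    Every joint ramps from fully extended to its peak target and back once
    per repetition (triangle wave); the thumb flexes across the palm so the
    thumb tip passes within the 30 mm opposition margin of the little-finger
    MCP at each mid-cycle.
    """
    if n_repetitions < 1:
        raise InvalidSpec("n_repetitions must be >= 1")
    if frames_per_repetition < 2 or frames_per_repetition % 2:
        raise InvalidSpec("frames_per_repetition must be even and >= 2")
    profiles: dict[str, list[tuple[int, float]]] = {}
    for joint, peak in FIST_CYCLE_TARGETS.items():
        bps: list[tuple[int, float]] = []
        for rep in range(n_repetitions):
            start = rep * frames_per_repetition
            bps += [
                (start, 0.0),
                (start + frames_per_repetition // 2, peak),
            ]
        bps.append((n_repetitions * frames_per_repetition, 0.0))
        profiles[joint] = bps
    spec = TrajectorySpec(
        profiles=profiles,
        n_frames=n_repetitions * frames_per_repetition + 1,
        noise_sd_mm=noise_sd_mm,
        seed=seed,
    )
    return generate_motion(geom or HandGeometry(), spec)
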