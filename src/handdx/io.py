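"""Keypoint sequence file formats.

Two interchangeable on-disk representations of a :class:`MotionSequence`:

* JSON: ``{"frame_rate": <Hz or null>, "frames": [[[x,y,z] * 21], ...]}``
* CSV: long format with columns ``frame, landmark, x, y, z`` where
  ``landmark`` is the canonical landmark name.

Both round-trip losslessly (coordinates are written with full float
precision).  Coordinates are millimetres throughout.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .skeleton import (
    LANDMARK_INDEX,
    LANDMARK_NAMES,
    N_LANDMARKS,
    LandmarkFrame,
    MotionSequence,
    validate_frame,
)


def write_json(seq: MotionSequence, path: str | Path) -> None:
    payload = {
        "frame_rate": seq.frame_rate,
        "frames": [f.points.tolist() for f in seq.frames],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_json(path: str | Path) -> MotionSequence:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if "frames" not in payload or not payload["frames"]:
        raise ValueError(f"{path}: no frames")
    frames = [
        validate_frame(LandmarkFrame(np.asarray(pts, dtype=float)))
        for pts in payload["frames"]
    ]
    return MotionSequence(frames, frame_rate=payload.get("frame_rate"))


def write_csv(seq: MotionSequence, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "landmark", "x", "y", "z"])
        for t, frame in enumerate(seq.frames):
            for i in range(N_LANDMARKS):
                x, y, z = (repr(float(v)) for v in frame.points[i])
                writer.writerow([t, LANDMARK_NAMES[i], x, y, z])


def read_csv(path: str | Path) -> MotionSequence:
    by_frame: dict[int, np.ndarray] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            t = int(row["frame"])
            pts = by_frame.setdefault(t, np.full((N_LANDMARKS, 3), np.nan))
            pts[LANDMARK_INDEX[row["landmark"]]] = (
                float(row["x"]), float(row["y"]), float(row["z"]),
            )
    if not by_frame:
        raise ValueError(f"{path}: no frames")
    frames = [
        validate_frame(LandmarkFrame(by_frame[t])) for t in sorted(by_frame)
    ]
    return MotionSequence(frames)
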