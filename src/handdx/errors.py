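"""Exception hierarchy for handdx.

Kinematic errors carry enough context (joint name, frame index) to locate the
offending sample in a motion sequence; graph/QA errors name the entity or
schema element involved.
"""

from __future__ import annotations


class HanddxError(Exception):
    """Base class for all handdx errors."""


# --- landmark / kinematics ------------------------------------------------

class WrongLandmarkCount(HanddxError):
    """A frame does not contain exactly 21 landmarks."""


class NonFiniteCoordinate(HanddxError):
    """A landmark coordinate is NaN or infinite."""


class DegenerateSegment(HanddxError):
    """A bone vector has (near-)zero length, so no angle/direction exists."""


class TooFewFrames(HanddxError):
    """An operation needing a motion range was given fewer than 2 frames."""


class NoEvaluableFaces(HanddxError):
    """Every ground-truth face is collinear; the normal metric is undefined."""


class InvalidAngle(HanddxError):
    """A programmed flexion angle lies outside [0, 180] degrees."""


class InvalidSpec(HanddxError):
    """A trajectory specification is malformed."""


# --- assessment -----------------------------------------------------------

class UnknownJointClass(HanddxError):
    """Joint class is not one of MCP / PIP / DIP."""


class UnknownOutcome(HanddxError):
    """Opposition outcome is not achieved / hard / not_achieved."""


# --- knowledge graph ------------------------------------------------------

class DuplicateDiseaseName(HanddxError):
    """Two records in one load share a disease name."""


class SchemaViolation(HanddxError):
    """A record or relation violates the entity/relation schema."""


class UnknownEntity(HanddxError):
    """The named entity does not exist in the graph."""


class UnknownAttribute(HanddxError):
    """The attribute type is not part of the disease attribute schema."""


# --- QA engine ------------------------------------------------------------

class EmptyGraph(HanddxError):
    """Cannot build a matching dictionary from an empty graph."""


class UnsupportedIntent(HanddxError):
    """No query template exists for the requested intent type."""
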