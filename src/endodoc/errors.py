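"""Exception hierarchy for the endodoc pipeline.

Every error raised by the package derives from :class:`EndodocError` so
callers can catch pipeline failures without masking programming errors.
"""


class EndodocError(Exception):
    """Base class for all endodoc errors."""


# --- stream I/O -------------------------------------------------------------

class MissingLabelColumn(EndodocError):
    """A prediction-stream file lacks a required label column."""


class NonMonotoneTimestamps(EndodocError):
    """Frame timestamps are not strictly increasing."""


class ConfidenceOutOfRange(EndodocError):
    """A confidence value falls outside [0, 1]."""


class UnwritablePath(EndodocError):
    """An output path could not be written."""


class UnreadableImage(EndodocError):
    """An image file could not be decoded."""


# --- configuration ----------------------------------------------------------

class InvalidThreshold(EndodocError):
    """A binarization or divergence threshold lies outside (0, 1)."""


class NegativeDuration(EndodocError):
    """A duration parameter is negative."""


# --- segmentation -----------------------------------------------------------

class EmptyStream(EndodocError):
    """An operation requires at least one frame."""


class NoBodyDetected(EndodocError):
    """No sustained in-body interval was found (scope never entered the body)."""


class NoCecumDetected(EndodocError):
    """No sustained cecal-landmark evidence was found within the body interval.

    Mirrors the clinical failure mode in which no withdrawal time can be
    reported because cecal intubation was never documented by the classifier.
    """


class InvalidTimeline(EndodocError):
    """Exam timeline anchors or segments violate their ordering invariants."""


# --- timing / evaluation ----------------------------------------------------

class NonPositiveMeasurement(EndodocError):
    """A reference withdrawal-time measurement must be > 0."""


class EmptyInput(EndodocError):
    """An aggregate statistic was requested over an empty collection."""


class ZeroPredicted(EndodocError):
    """Specificity is undefined when no images were predicted."""


class ZeroDenominator(EndodocError):
    """A representation rate is undefined for zero documented events."""


# --- report -----------------------------------------------------------------

class FrameSourceMismatch(EndodocError):
    """A selected frame index has no corresponding image in the frame source."""


# --- simulation -------------------------------------------------------------

class InvalidSpec(EndodocError):
    """A synthetic exam specification violates its invariants."""


# --- streaming --------------------------------------------------------------

class OutOfOrderFrame(EndodocError):
    """A pushed frame's timestamp does not exceed the previous frame's."""
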