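"""Exception hierarchy for the pipeline.

Validation errors signal malformed or contract-violating inputs; runtime
errors signal conditions arising from otherwise valid data (degenerate
geometry, empty selections).
"""


class GustofaceError(Exception):
    """Base class for all package errors."""


class ValidationError(GustofaceError, ValueError):
    """Input violates a documented schema or invariant."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending line."""


class MissingSectionError(GustofaceError, LookupError):
    """A task section (e.g. SII) was requested but is not annotated."""


class MissingLandmarkError(GustofaceError, KeyError):
    """A landmark id required by the map is absent from a frame."""

    def __init__(self, landmark_id: int, region: str):
        self.landmark_id = landmark_id
        self.region = region
        super().__init__(f"landmark id {landmark_id} (region '{region}') missing from frame")

    def __str__(self) -> str:  # KeyError quotes its arg by default
        return self.args[0]


class DegenerateFrameError(GustofaceError, ValueError):
    """Geometry is degenerate (zero reference distance, coincident points)."""


class UndefinedFitError(DegenerateFrameError):
    """A line or angle fit is undefined (e.g. all points coincident)."""


class EmptySeriesError(GustofaceError, ValueError):
    """No frames were retained for a measure series or feature matrix."""
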