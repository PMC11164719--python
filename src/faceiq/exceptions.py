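"""Exception hierarchy shared across the package."""


class FaceIQError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(FaceIQError):
    """Image file has a bit depth or mode the pipeline does not handle."""


class BoundsError(FaceIQError, ValueError):
    """A crop box extends beyond its host image."""


class InvalidInputError(FaceIQError, ValueError):
    """Input violates a documented precondition."""


class ConsistencyError(InvalidInputError):
    """Structured assessment fields contradict each other."""


class IncompleteRecordError(FaceIQError):
    """A triage record is missing one or more required components."""


class DegenerateDataError(FaceIQError):
    """Data admit no meaningful statistic (e.g. all values tied)."""


class DegenerateFitError(FaceIQError):
    """Model fitting is impossible (e.g. a single outcome class)."""


class FixtureSpecError(InvalidInputError):
    """A synthetic-fixture specification is infeasible or inconsistent."""
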