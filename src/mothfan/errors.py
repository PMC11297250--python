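"""Exception hierarchy for the fanning-analysis pipeline."""


class MothfanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MothfanError):
    """A spec or config object violates one of its invariants."""


class DegenerateGeometryError(MothfanError):
    """Geometric input admits no well-defined answer (e.g. coincident points)."""


class ProjectionError(MothfanError):
    """A 3D point cannot be imaged by a camera (behind the optical centre)."""


class OutOfDomainError(MothfanError):
    """A probe or trace point lies outside the flow-field grid box."""

    def __init__(self, message: str, point=None):
        super().__init__(message)
        self.point = point


class InsufficientDataError(MothfanError):
    """Fewer samples than the operation requires (e.g. < 1 full wingbeat)."""


class ValidationError(MothfanError):
    """A file does not conform to one of the package's format dialects."""
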