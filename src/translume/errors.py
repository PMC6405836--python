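"""Exception hierarchy shared across the pipeline."""


class TranslumeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TranslumeError, ValueError):
    """Inconsistent shapes, axes or parameters supplied by the caller."""


class DomainError(TranslumeError, ValueError):
    """Input outside the mathematical/physical domain of an operation."""


class FormatError(TranslumeError, ValueError):
    """A file container is missing a required dataset or attribute."""


class DegenerateGeometryError(DomainError):
    """Geometry (e.g. collinear fiducials) does not determine a transform."""
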