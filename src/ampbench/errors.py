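"""Exception hierarchy.

Every error raised by ampbench derives from :class:`AmpbenchError` so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class AmpbenchError(Exception):
    """Base class for all ampbench errors."""


class FormatError(AmpbenchError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(AmpbenchError):
    """A table or record violates a domain invariant."""


class ConsistencyError(AmpbenchError):
    """Derived read totals are internally inconsistent (e.g. negative)."""


class ConfigError(AmpbenchError):
    """A configuration value is out of range or incoherent."""


class InsufficientDepthError(AmpbenchError):
    """A sample has fewer mapped reads than the requested downsampling depth."""


class UndefinedMetricError(AmpbenchError):
    """A metric is undefined for this input (zero denominator, constant vector)."""


class AnnotationMismatchError(AmpbenchError):
    """Gene sets of counts and annotation (or bulk profile) do not agree."""
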