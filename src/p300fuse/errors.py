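"""Exception hierarchy for the p300fuse pipeline.

All domain-level failures derive from :class:`P300FuseError` so callers can
catch pipeline errors without masking programming errors.
"""


class P300FuseError(Exception):
    """Base class for all p300fuse errors."""


class DomainError(P300FuseError, ValueError):
    """A value is outside the domain an operation is defined on."""


class ConfigurationError(P300FuseError, ValueError):
    """A configuration object is internally inconsistent."""


class FormatError(P300FuseError, ValueError):
    """A session file does not match its declared dialect."""


class ValidationError(P300FuseError, ValueError):
    """Data read from a file violates a structural invariant."""


class AlignmentError(P300FuseError, ValueError):
    """Epoch sets offered for fusion are not event-aligned."""


class ShapeError(P300FuseError, ValueError):
    """Epoch sets offered for fusion have incompatible shapes."""


class IntegrityError(P300FuseError, RuntimeError):
    """A realized model diverges from its closed-form specification."""
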